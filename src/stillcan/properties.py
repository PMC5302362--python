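"""Thermophysical properties of the covering syrup and the peach flesh.

The syrup (20 % w/v aqueous sucrose) carries temperature-dependent density,
dynamic viscosity, specific heat and thermal conductivity, each fitted as a
low-order polynomial in temperature (°C) over the process range 20–130 °C.
The peach flesh is treated as a constant-property solid.  Derived quantities
needed by the flow solver — volumetric thermal expansivity, thermal
diffusivity and the Rayleigh number — are computed from the same fits.

A note on the density fit: the quadratic coefficient is −2.4201e−3 kg/(m³·°C²).
The magnitude is sometimes reproduced elsewhere with a sign-flipped exponent
(−2.4201e+3), which would drive the density negative above roughly 1 °C; the
physically meaningful value is used by default and the implausible variant is
kept behind ``as_printed=True`` purely for provenance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Tuple

import numpy as np

__all__ = [
    "PropertyPolynomial",
    "SolidProperties",
    "PropertyModel",
    "PropertyRangeError",
    "SYRUP_PROPERTY_NAMES",
    "default_property_model",
    "constant_property_model",
    "eval_property",
    "thermal_expansion",
    "thermal_diffusivity",
    "kinematic_viscosity",
    "rayleigh_number",
]

SYRUP_PROPERTY_NAMES = ("density", "viscosity", "specific_heat", "conductivity")

#: Fitted polynomial coefficients for 20 % w/v sugar syrup, constant term
#: first, argument in °C, value in SI units.
SYRUP_COEFFS: Dict[str, Tuple[float, ...]] = {
    "density": (1.0868e3, -2.4377e-1, -2.4201e-3),            # kg/m^3
    "viscosity": (3.3817e-3, -8.2745e-5, 8.3164e-7, -2.8823e-9),  # Pa s
    "specific_heat": (3.6839e3, 1.4510e0, 3.4965e-4),          # J/(kg K)
    "conductivity": (5.0486e-1, 1.5929e-3, -5.0000e-6),        # W/(m K)
}

#: Density quadratic coefficient as it sometimes appears with a flipped
#: exponent sign; unphysical, retained for provenance only.
PRINTED_DENSITY_QUADRATIC = -2.4201e3

DEFAULT_VALID_RANGE = (20.0, 130.0)

PEACH_DENSITY = 1022.0        # kg/m^3
PEACH_SPECIFIC_HEAT = 3992.0  # J/(kg K)
PEACH_CONDUCTIVITY = 0.58     # W/(m K)

STANDARD_GRAVITY = 9.81  # m/s^2


class PropertyRangeError(ValueError):
    """Temperature outside the supported range of a property fit."""


@dataclass(frozen=True)
class PropertyPolynomial:
    """Polynomial property fit, constant coefficient first, T in °C."""

    coefficients: Tuple[float, ...]
    valid_range: Tuple[float, float] = DEFAULT_VALID_RANGE
    name: str = "property"

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("polynomial needs at least one coefficient")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be an increasing interval")

    def _check(self, T) -> None:
        lo, hi = self.valid_range
        T = np.asarray(T, dtype=float)
        if T.size and (float(T.min()) < lo - 1e-12 or float(T.max()) > hi + 1e-12):
            raise PropertyRangeError(
                f"temperature outside [{lo}, {hi}] °C for property "
                f"'{self.name}'"
            )

    def evaluate(self, T, check: bool = True):
        """Evaluate the fit at temperature ``T`` (°C, scalar or array)."""
        if check:
            self._check(T)
        T = np.asarray(T, dtype=float)
        out = np.zeros_like(T)
        for c in reversed(self.coefficients):
            out = out * T + c
        return out if out.ndim else float(out)

    def derivative(self, T, check: bool = True):
        """Analytic d(property)/dT at ``T``."""
        if check:
            self._check(T)
        T = np.asarray(T, dtype=float)
        out = np.zeros_like(T)
        for power in range(len(self.coefficients) - 1, 0, -1):
            out = out * T + power * self.coefficients[power]
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class SolidProperties:
    """Constant thermophysical properties of a solid particle."""

    density: float = PEACH_DENSITY
    specific_heat: float = PEACH_SPECIFIC_HEAT
    conductivity: float = PEACH_CONDUCTIVITY

    def __post_init__(self) -> None:
        for name in ("density", "specific_heat", "conductivity"):
            if getattr(self, name) <= 0:
                raise ValueError(f"solid {name} must be positive")

    @property
    def volumetric_heat_capacity(self) -> float:
        return self.density * self.specific_heat

    @property
    def diffusivity(self) -> float:
        return self.conductivity / self.volumetric_heat_capacity


@dataclass(frozen=True)
class PropertyModel:
    """Syrup polynomial fits plus constant peach properties and gravity."""

    syrup: Dict[str, PropertyPolynomial] = field(default_factory=dict)
    peach: SolidProperties = field(default_factory=SolidProperties)
    gravity_magnitude: float = STANDARD_GRAVITY

    def __post_init__(self) -> None:
        missing = set(SYRUP_PROPERTY_NAMES) - set(self.syrup)
        extra = set(self.syrup) - set(SYRUP_PROPERTY_NAMES)
        if missing or extra:
            raise ValueError(
                f"syrup must define exactly {SYRUP_PROPERTY_NAMES}; "
                f"missing={sorted(missing)} extra={sorted(extra)}"
            )


def default_property_model(
    as_printed: bool = False,
    gravity_magnitude: float = STANDARD_GRAVITY,
) -> PropertyModel:
    """Property model with the fitted syrup polynomials and peach constants.

    ``as_printed=True`` swaps in the sign-flipped density quadratic exponent
    (see module docstring); it is unphysical and exists for provenance only.
    """
    syrup = {}
    for name in SYRUP_PROPERTY_NAMES:
        coeffs = SYRUP_COEFFS[name]
        if name == "density" and as_printed:
            coeffs = (coeffs[0], coeffs[1], PRINTED_DENSITY_QUADRATIC)
        syrup[name] = PropertyPolynomial(coeffs, DEFAULT_VALID_RANGE, name)
    return PropertyModel(syrup=syrup, gravity_magnitude=gravity_magnitude)


def constant_property_model(
    density: float = 1000.0,
    viscosity: float = 1.0e-3,
    specific_heat: float = 4000.0,
    conductivity: float = 0.6,
    gravity_magnitude: float = 0.0,
    valid_range: Tuple[float, float] = (-50.0, 200.0),
) -> PropertyModel:
    """Constant-coefficient model (handy for analytic verification runs)."""
    syrup = {
        name: PropertyPolynomial((value,), valid_range, name)
        for name, value in {
            "density": density,
            "viscosity": viscosity,
            "specific_heat": specific_heat,
            "conductivity": conductivity,
        }.items()
    }
    return PropertyModel(syrup=syrup, gravity_magnitude=gravity_magnitude)


def eval_property(model: PropertyModel, property_name: str, T, check: bool = True):
    """Evaluate a syrup property (SI units) at temperature ``T`` in °C."""
    if property_name not in SYRUP_PROPERTY_NAMES:
        raise KeyError(
            f"unknown property '{property_name}'; one of {SYRUP_PROPERTY_NAMES}"
        )
    return model.syrup[property_name].evaluate(T, check=check)


def thermal_expansion(model: PropertyModel, T, check: bool = True):
    """Volumetric thermal expansivity β = −(dρ/dT)/ρ of the syrup, 1/K."""
    poly = model.syrup["density"]
    rho = poly.evaluate(T, check=check)
    return -poly.derivative(T, check=False) / rho


def kinematic_viscosity(model: PropertyModel, T, check: bool = True):
    """ν = μ/ρ of the syrup, m²/s."""
    return eval_property(model, "viscosity", T, check) / eval_property(
        model, "density", T, False
    )


def thermal_diffusivity(model: PropertyModel, T, check: bool = True):
    """α = k/(ρ·Cp) of the syrup, m²/s."""
    return eval_property(model, "conductivity", T, check) / (
        eval_property(model, "density", T, False)
        * eval_property(model, "specific_heat", T, False)
    )


def rayleigh_number(
    model: PropertyModel, L: float, delta_T: float, T_film: float
) -> float:
    """Rayleigh number g·β·ΔT·L³/(ν·α) at a film temperature.

    ``L`` is the characteristic length in metres; the laminar-regime check for
    the still can uses the annular peach–wall gap.  ``delta_T`` is the driving
    temperature difference in K.
    """
    if L <= 0:
        raise ValueError("characteristic length must be positive")
    if delta_T < 0:
        raise ValueError("delta_T must be non-negative")
    beta = thermal_expansion(model, T_film)
    nu = kinematic_viscosity(model, T_film, check=False)
    alpha = thermal_diffusivity(model, T_film, check=False)
    return model.gravity_magnitude * beta * delta_T * L**3 / (nu * alpha)
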