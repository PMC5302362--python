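"""File writers: CSV reports, probe series, legacy-ASCII VTK fields, manifest.

CSV output uses a fixed 6-significant-digit float format so that repeated
identical runs are bit-stable; VTK snapshots keep full precision.  All
coordinates in CSV outputs are millimetres from the can centre.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Mapping, Optional, Sequence

import numpy as np

from .geometry import VoxelScene
from .pipeline import CaseReport, StudyReport

__all__ = [
    "format_float",
    "write_csv",
    "write_report_csv",
    "write_probe_csv",
    "write_study_csv",
    "write_vtk_rectilinear",
    "write_outputs",
]


def format_float(x) -> str:
    if isinstance(x, (bool, int, np.integer)):
        return str(x)
    if isinstance(x, float) or isinstance(x, np.floating):
        return f"{float(x):.6g}"
    return str(x)


def write_csv(path, header: Sequence[str], rows: Iterable[Sequence]) -> None:
    """RFC-4180-style CSV, UTF-8, header row, fixed float formatting."""
    lines = [",".join(header)]
    for row in rows:
        lines.append(",".join(format_float(v) for v in row))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_report_csv(report: CaseReport, path) -> None:
    row = report.to_row()
    write_csv(path, list(row.keys()), [list(row.values())])


def write_probe_csv(report: CaseReport, path) -> None:
    """Probe time series: time_s, probe_id, x_mm, y_mm, z_mm, T_C."""
    header = ["time_s", "probe_id", "x_mm", "y_mm", "z_mm", "T_C"]
    coords = {p.probe_id: (p.x_mm, p.y_mm, p.z_mm) for p in report.probes}
    rows = []
    for series in (report.heating_series, report.cooling_series):
        for pid, temps in series.probe_temperatures.items():
            x, y, z = coords.get(pid, ("", "", ""))
            for t, T in zip(series.times, temps):
                rows.append([t, pid, x, y, z, T])
    write_csv(path, header, rows)


def write_study_csv(reports: Mapping[str, CaseReport], study: StudyReport,
                    path) -> None:
    rows = [list(r.to_row().values()) for r in reports.values()]
    header = list(next(iter(reports.values())).to_row().keys())
    write_csv(path, header, rows)
    summary = {
        "critical_F": study.critical_F,
        "critical_F_ordering_holds": study.critical_F_ordering_holds,
        "upward_heats_slowest_at_critical": study.upward_heats_slowest_at_critical,
        "per_particle_spread": study.per_particle_spread,
        "sideward_tightest_spread": study.sideward_tightest_spread,
        "upward_critical_in_bottom_half": study.upward_critical_in_bottom_half,
        "downward_critical_in_bottom_half": study.downward_critical_in_bottom_half,
        "upward_coincidence_distance_mm": study.upward_coincidence_distance_mm,
    }
    Path(str(path) + ".summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True), encoding="utf-8"
    )


def write_vtk_rectilinear(
    path, scene: VoxelScene, cell_data: Mapping[str, np.ndarray]
) -> None:
    """Legacy-ASCII VTK rectilinear grid with per-voxel cell data."""
    nx, ny, nz = scene.dims
    h = scene.spacing
    coords = [
        scene.origin[a] + np.arange(scene.dims[a] + 1) * h for a in range(3)
    ]
    lines = [
        "# vtk DataFile Version 3.0",
        f"stillcan field snapshot ({scene.case_name})",
        "ASCII",
        "DATASET RECTILINEAR_GRID",
        f"DIMENSIONS {nx + 1} {ny + 1} {nz + 1}",
    ]
    for name, axis in (("X", 0), ("Y", 1), ("Z", 2)):
        lines.append(f"{name}_COORDINATES {scene.dims[axis] + 1} double")
        lines.append(" ".join(repr(float(c)) for c in coords[axis]))
    lines.append(f"CELL_DATA {nx * ny * nz}")
    for name, arr in cell_data.items():
        if arr.shape != tuple(scene.dims):
            raise ValueError(f"cell data '{name}' has wrong shape")
        kind = "int" if np.issubdtype(arr.dtype, np.integer) else "double"
        lines.append(f"SCALARS {name} {kind} 1")
        lines.append("LOOKUP_TABLE default")
        flat = arr.transpose(2, 1, 0).ravel()  # VTK iterates x fastest
        if kind == "int":
            lines.append(" ".join(str(int(v)) for v in flat))
        else:
            lines.append(" ".join(repr(float(v)) for v in flat))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def write_outputs(
    report: CaseReport,
    directory,
    scene: Optional[VoxelScene] = None,
    fields: Optional[Mapping[str, np.ndarray]] = None,
    log_lines: Sequence[str] = (),
) -> Dict[str, str]:
    """Write per-case outputs and return a {filename: sha256} manifest.

    ``fields`` (for example final temperature and accumulated F) are written
    as one VTK rectilinear file when a scene is supplied; omit both to write
    the CSV report and log only.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written = []

    report_path = directory / f"{report.case_name}_report.csv"
    write_report_csv(report, report_path)
    written.append(report_path)

    if report.heating_series.probe_temperatures:
        probe_path = directory / f"{report.case_name}_probes.csv"
        write_probe_csv(report, probe_path)
        written.append(probe_path)

    if scene is not None and fields:
        vtk_path = directory / f"{report.case_name}_fields.vtk"
        write_vtk_rectilinear(vtk_path, scene, fields)
        written.append(vtk_path)

    log_path = directory / f"{report.case_name}_run.log"
    log_path.write_text("\n".join(log_lines) + "\n", encoding="utf-8")
    written.append(log_path)

    manifest = {p.name: _sha256(p) for p in written}
    (directory / f"{report.case_name}_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8"
    )
    return manifest
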