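"""Output writers: legacy-ASCII VTK unstructured grids and CSV time series."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import Mesh


def write_vtk(path, mesh: Mesh, point_data: dict[str, np.ndarray] | None = None) -> None:
    """Write the (r, z) mesh and nodal fields as a legacy-ASCII VTK file.

    The half-plane mesh is emitted with r as x and z as y (z_vtk = 0) so any
    VTK viewer shows the meridional section directly.
    """
    path = Path(path)
    n, m = mesh.num_nodes, len(mesh.triangles)
    lines = [
        "# vtk DataFile Version 3.0",
        "mwablate axisymmetric section",
        "ASCII",
        "DATASET UNSTRUCTURED_GRID",
        f"POINTS {n} double",
    ]
    for r, z in mesh.nodes:
        lines.append(f"{r:.9e} {z:.9e} 0.0")
    lines.append(f"CELLS {m} {4 * m}")
    for t in mesh.triangles:
        lines.append(f"3 {t[0]} {t[1]} {t[2]}")
    lines.append(f"CELL_TYPES {m}")
    lines.extend(["5"] * m)
    # region tags as cell data
    regions = sorted(set(mesh.region.tolist()))
    code = {rg: i for i, rg in enumerate(regions)}
    lines.append(f"CELL_DATA {m}")
    lines.append("SCALARS region int 1")
    lines.append("LOOKUP_TABLE default")
    lines.extend(str(code[rg]) for rg in mesh.region)
    if point_data:
        lines.append(f"POINT_DATA {n}")
        for name, vals in point_data.items():
            lines.append(f"SCALARS {name} double 1")
            lines.append("LOOKUP_TABLE default")
            lines.extend(f"{v:.9e}" for v in np.asarray(vals, dtype=float))
    path.write_text("\n".join(lines) + "\n")


def metrics_frame(metrics) -> pd.DataFrame:
    """Coverage time series as a DataFrame (times in s, volumes in cm^3)."""
    return pd.DataFrame(
        {
            "time_s": [m.time for m in metrics],
            "tumor_coverage": [m.tumor_coverage for m in metrics],
            "collateral_cm3": [m.collateral_volume * 1e6 for m in metrics],
            "lethal_isotherm_cm3": [m.lethal_isotherm_volume * 1e6 for m in metrics],
            "peak_temperature_C": [m.peak_temperature for m in metrics],
        }
    )


def write_metrics_csv(path, metrics) -> None:
    metrics_frame(metrics).to_csv(path, index=False)
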