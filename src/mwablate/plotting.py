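"""Quick-look matplotlib plots of axisymmetric fields and coverage series."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import matplotlib.tri as mtri
import numpy as np

from .geometry import Mesh


def plot_field(
    mesh: Mesh,
    values: np.ndarray,
    title: str = "",
    levels: int | list = 40,
    contour_levels=None,
    path=None,
):
    """Filled contours of a nodal field on the (r, z) half-plane (mm)."""
    tri = mtri.Triangulation(
        mesh.nodes[:, 0] * 1e3, mesh.nodes[:, 1] * 1e3, mesh.triangles
    )
    fig, ax = plt.subplots(figsize=(5, 6))
    c = ax.tricontourf(tri, np.asarray(values, dtype=float), levels=levels)
    if contour_levels is not None:
        ax.tricontour(tri, values, levels=contour_levels, colors="w", linewidths=0.8)
    fig.colorbar(c, ax=ax)
    ax.set_xlabel("r (mm)")
    ax.set_ylabel("z (mm)")
    ax.set_title(title)
    ax.set_aspect("equal")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_metrics(report, path=None):
    """Tumor coverage, collateral volume and lethal-isotherm volume vs time."""
    df = report.to_frame()
    fig, ax1 = plt.subplots(figsize=(6, 4))
    ax1.plot(df.time_s, df.tumor_coverage, "k-", label="tumor coverage")
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel("tumor coverage")
    ax1.set_ylim(0, 1.05)
    ax2 = ax1.twinx()
    ax2.plot(df.time_s, df.collateral_cm3, "r--", label="collateral")
    ax2.plot(df.time_s, df.lethal_isotherm_cm3, "b:", label="60 degC volume")
    ax2.set_ylabel("volume (cm$^3$)")
    fig.legend(loc="upper left", bbox_to_anchor=(0.12, 0.95))
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
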