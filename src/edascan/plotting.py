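"""Surface heatmaps in the two layouts used for attack-trajectory maps:
the Cartesian nucleophile-position view (x = r cos t, y = r sin t around
the carbonyl carbon at the origin) and the rectangular angle-vs-distance
view that exposes angular structure."""

from __future__ import annotations

import math

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .surface import SurfaceError, SurfaceField, to_view  # noqa: E402

_UNITS = {"S_overlap": "overlap (dimensionless)"}


def plot_surface(
    sf: SurfaceField,
    view: str = "cartesian",
    out=None,
    overlay_angle: float | None = None,
    cmap: str = "viridis",
    vmin: float | None = None,
    vmax: float | None = None,
    unit_label: str | None = None,
):
    """Heatmap of a surface field; masked cells are blanked.

    ``overlay_angle`` draws a constant-angle attack trajectory (a straight
    line through the carbonyl carbon in the Cartesian view, a vertical line
    in the rectangular view).  Returns the matplotlib figure; saves to
    ``out`` when given.
    """
    if sf.n_valid == 0:
        raise SurfaceError("cannot plot a fully masked surface")
    X, Y, V, mask = to_view(sf, view)
    Vm = np.ma.masked_array(V, mask=~mask)
    if vmin is None:
        vmin = float(V[mask].min())
    if vmax is None:
        vmax = float(V[mask].max())
    fig, ax = plt.subplots(figsize=(6.0, 4.8))
    pc = ax.pcolormesh(X, Y, Vm, shading="nearest", cmap=cmap,
                       vmin=vmin, vmax=vmax)
    unit = unit_label or _UNITS.get(sf.name, "kcal/mol")
    fig.colorbar(pc, ax=ax, label=f"{sf.name} ({unit})")
    if view == "cartesian":
        ax.set_xlabel("x = r cos(theta) (A)")
        ax.set_ylabel("y = r sin(theta) (A)")
        ax.set_aspect("equal")
        if overlay_angle is not None:
            t = math.radians(overlay_angle)
            rmax = sf.gridspec.r_max
            ax.plot([0.0, rmax * math.cos(t)], [0.0, rmax * math.sin(t)],
                    color="lightblue", lw=2.0)
    else:
        ax.set_xlabel("theta (deg)")
        ax.set_ylabel("r (A)")
        if overlay_angle is not None:
            ax.axvline(overlay_angle, color="lightblue", lw=2.0)
    ax.set_title(sf.name)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig


def plot_cross_section(sections, out=None):
    """Overlayed angular cross-sections (list of CrossSection)."""
    fig, ax = plt.subplots(figsize=(6.0, 4.2))
    for cs in sections:
        ax.plot(cs.thetas[cs.mask], cs.values[cs.mask], marker="o",
                label=cs.field)
    ax.set_xlabel("theta (deg)")
    ax.set_ylabel("energy (kcal/mol)")
    ax.legend()
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
        plt.close(fig)
    return fig
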