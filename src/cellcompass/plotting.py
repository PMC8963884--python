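"""Matplotlib rendering of maps and phase diagrams."""

from __future__ import annotations

import numpy as np

from .compass import ParameterEstimate, PhaseDiagram
from .morphomap import MorphodynamicMap


def plot_morphomap(mmap, ax=None, vmax=None, cmap="RdBu_r", time_unit="frames"):
    """Render a morphodynamic (or trafficking) map as a kymograph.

    Red = protrusion, blue = retraction, x = time, y = contour marker;
    the colour scale is symmetric about zero.
    """
    import matplotlib.pyplot as plt

    values = mmap.values if isinstance(mmap, MorphodynamicMap) else np.asarray(mmap)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    if vmax is None:
        vmax = np.nanpercentile(np.abs(values), 99) or 1.0
    im = ax.imshow(values, aspect="auto", cmap=cmap, vmin=-vmax, vmax=vmax,
                   origin="lower", interpolation="nearest")
    ax.set_xlabel(f"time ({time_unit})")
    ax.set_ylabel("contour marker")
    ax.figure.colorbar(im, ax=ax, label="edge speed")
    return ax


def plot_phase_diagrams(
    diagram: PhaseDiagram,
    measured: dict | None = None,
    estimate: ParameterEstimate | None = None,
):
    """Three-panel phase diagram with optional measured iso-contours.

    ``measured`` maps observable names (``tau_hours``, ``unicity``,
    ``alignment``) to their measured values; each panel then draws the
    corresponding iso-line, and ``estimate`` marks the best-fit point
    where the lines cross.
    """
    import matplotlib.pyplot as plt

    fields = [
        ("tau_hours", diagram.tau_hours, "persistence time (h)"),
        ("unicity", diagram.unicity, "protrusive unicity"),
        ("alignment", diagram.alignment, "alignment index"),
    ]
    fig, axes = plt.subplots(1, 3, figsize=(13, 3.6), constrained_layout=True)
    extent = [
        diagram.kappa_values[0], diagram.kappa_values[-1],
        diagram.p_values[0], diagram.p_values[-1],
    ]
    for ax, (name, grid, label) in zip(axes, fields):
        shown = np.log10(grid) if name == "tau_hours" else grid
        im = ax.imshow(shown, origin="lower", aspect="auto", extent=extent, cmap="viridis")
        fig.colorbar(im, ax=ax, label=("log10 " + label) if name == "tau_hours" else label)
        if measured and measured.get(name) is not None:
            K, P = np.meshgrid(diagram.kappa_values, diagram.p_values)
            ax.contour(K, P, grid, levels=[measured[name]], colors="k", linewidths=1.5)
        if estimate is not None:
            ax.plot(estimate.kappa, estimate.p_polarized, "o", color="tab:red", ms=7)
        ax.set_xlabel(r"$\kappa$")
        ax.set_ylabel(r"$P_{polarized}$")
        ax.set_title(label)
    return fig
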