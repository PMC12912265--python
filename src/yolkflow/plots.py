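"""Rose-plot and quiver-overlay figures for PIV summaries."""

from __future__ import annotations

import numpy as np

from .piv import DirectionalSummary, VectorField


def rose_plot(summary: DirectionalSummary, path) -> None:
    """Circular histogram of pooled vector directions."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.radians(summary.rose_bin_edges_deg)
    widths = np.diff(edges)
    fig = plt.figure(figsize=(4, 4))
    ax = fig.add_subplot(projection="polar")
    ax.bar(edges[:-1], summary.rose_counts, width=widths, align="edge",
           color="#4878a8", edgecolor="k", linewidth=0.3)
    ax.set_title(f"n={summary.n_valid}, mean speed {summary.mean_speed_um_min:.2f} µm/min",
                 fontsize=9)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def quiver_overlay(frame: np.ndarray, fld: VectorField, path, scale: float = 20.0) -> None:
    """Valid vectors drawn over the first frame of the pair."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 5))
    ax.imshow(frame, cmap="gray")
    v = fld.valid
    ax.quiver(fld.cols[v], fld.rows[v], fld.dx[v], -fld.dy[v],
              color="yellow", angles="xy", scale_units="xy", scale=1.0 / scale)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
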