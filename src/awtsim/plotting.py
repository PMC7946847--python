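"""Optional window plots (requires matplotlib)."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .scoring import AttentionWindow


def plot_attention_window(window: AttentionWindow, path: str | Path | None = None, ax=None):
    """Draw the endpoint polygon of an attention window.

    Returns the matplotlib axes; saves to ``path`` (SVG/PNG by extension)
    when given.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    pts = np.array(window.vertices + (window.vertices[0],))
    ax.plot(pts[:, 0], pts[:, 1], "o-", color="tab:blue")
    ax.fill(pts[:, 0], pts[:, 1], alpha=0.15, color="tab:blue")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.set_aspect("equal")
    ax.set_xlabel("deg visual angle")
    ax.set_ylabel("deg visual angle")
    ax.set_title(
        f"AW polygon {window.polygon_area_deg2:.0f} deg$^2$, "
        f"aspect H/V = {window.aspect_ratio:.2f}"
    )
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight")
    return ax
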