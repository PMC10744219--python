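"""Polar AHA bullseye plot of segmental InD."""

from __future__ import annotations

import numpy as np

from .bullseye import Bullseye17


def plot_bullseye(b: Bullseye17, path=None, title: str = "Inward displacement (%)"):
    """Draw the standard 17-segment bullseye (outer ring basal 1-6, then
    mid 7-12, apical 13-16, centre cap 17). Saves to ``path`` if given and
    returns the matplotlib figure."""
    import matplotlib

    if path is not None:
        matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib import cm, colors

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(6, 6))
    finite = b.seg_pct[np.isfinite(b.seg_pct)]
    vmin, vmax = (0.0, 50.0) if finite.size == 0 else (min(0.0, finite.min()), max(50.0, finite.max()))
    norm = colors.Normalize(vmin=vmin, vmax=vmax)
    cmap = cm.viridis

    rings = [  # (segment ids outward->inward, inner radius, outer radius, rotation deg)
        (range(1, 7), 0.75, 1.0, 60.0),
        (range(7, 13), 0.5, 0.75, 60.0),
        (range(13, 17), 0.25, 0.5, 45.0),
    ]
    for ids, r0, r1, rot in rings:
        ids = list(ids)
        width = 2 * np.pi / len(ids)
        for k, sid in enumerate(ids):
            theta0 = np.deg2rad(rot) + k * width
            value = b[sid]
            color = cmap(norm(value)) if np.isfinite(value) else "lightgray"
            ax.bar(theta0 + width / 2, r1 - r0, width=width, bottom=r0,
                   color=color, edgecolor="white", linewidth=1.5)
            label = f"{sid}\n{value:.0f}" if np.isfinite(value) else f"{sid}\n--"
            ax.text(theta0 + width / 2, (r0 + r1) / 2, label,
                    ha="center", va="center", fontsize=8)
    cap = b[17]
    ax.bar(0, 0.25, width=2 * np.pi, bottom=0,
           color=cmap(norm(cap)) if np.isfinite(cap) else "lightgray",
           edgecolor="white", linewidth=1.5)
    ax.text(0, 0, f"17\n{cap:.0f}" if np.isfinite(cap) else "17\n--",
            ha="center", va="center", fontsize=8)

    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(title)
    fig.colorbar(cm.ScalarMappable(norm=norm, cmap=cmap), ax=ax, shrink=0.7, label="%")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
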