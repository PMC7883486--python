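"""Optional UpSet-style rendering of combination counts (matplotlib).

Bars show per-subset counts; the dot matrix beneath marks which classes each
bar's subset contains. Plots are convenience artifacts only — every
quantitative surface of the pipeline is tabular.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .coexpression import CombinationCounts, subset_label

__all__ = ["plot_upset"]


def plot_upset(
    counts: CombinationCounts,
    path: str | Path | None = None,
    which: str = "exclusive",
    include_empty: bool = True,
):
    """Render an UpSet-style figure; writes to ``path`` if given, returns the Figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    source = counts.exclusive if which == "exclusive" else counts.inclusive
    items = [(s, v) for s, v in source.items() if include_empty or s]
    items.sort(key=lambda kv: (-kv[1], subset_label(kv[0], counts.class_names)))
    labels = [subset_label(s, counts.class_names) for s, _ in items]
    values = [v for _, v in items]
    k = len(counts.class_names)

    fig, (ax_bar, ax_dot) = plt.subplots(
        2, 1, figsize=(max(4, 0.6 * len(items) + 2), 4 + 0.3 * k),
        sharex=True, height_ratios=[3, max(1, k)],
    )
    x = np.arange(len(items))
    ax_bar.bar(x, values, color="0.25")
    for xi, v in zip(x, values):
        ax_bar.text(xi, v, str(v), ha="center", va="bottom", fontsize=8)
    ax_bar.set_ylabel(f"{which} cells")
    ax_bar.spines[["top", "right"]].set_visible(False)

    for j, cls in enumerate(counts.class_names):
        member = [cls in s for s, _ in items]
        ax_dot.scatter(x[member], [j] * sum(member), s=60, color="0.15", zorder=3)
        ax_dot.scatter(x[[not m for m in member]], [j] * (len(items) - sum(member)),
                       s=60, facecolors="0.9", edgecolors="0.7", zorder=2)
    for xi, (s, _) in enumerate(items):
        rows = [counts.class_names.index(c) for c in s]
        if len(rows) > 1:
            ax_dot.plot([xi, xi], [min(rows), max(rows)], color="0.15", lw=2, zorder=1)
    ax_dot.set_yticks(range(k), counts.class_names)
    ax_dot.set_ylim(-0.5, k - 0.5)
    ax_dot.invert_yaxis()
    ax_dot.set_xticks(x, labels, rotation=90, fontsize=7)
    ax_dot.spines[["top", "right", "bottom", "left"]].set_visible(False)
    ax_dot.tick_params(length=0)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
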