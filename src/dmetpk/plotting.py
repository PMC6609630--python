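"""Forest-plot rendering for meta-analysis results."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .meta import MetaResult

__all__ = ["plot_forest"]

_MARKERS = {"I": "o", "II": "^", "III": "D"}


def plot_forest(result: MetaResult, path: str | Path | None = None):
    """Draw a forest plot: per-study means ± interval plus one summary row
    per %CV method, with a vertical line at the weighted mean.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    rows = result.forest_rows
    fig, ax = plt.subplots(figsize=(6, 0.45 * len(rows) + 1.2))
    y = len(rows)
    for fr in rows:
        y -= 1
        if fr.row_kind == "study":
            marker, color = "s", "0.25"
        else:
            marker = _MARKERS.get(fr.label.split()[-1], "o")
            color = "C0"
        ax.plot([fr.ci_low, fr.ci_high], [y, y], "-", color=color, lw=1.2)
        ax.plot(fr.mean, y, marker, color=color, ms=5)
    ax.axvline(result.pooled.WM, color="0.5", ls=":", lw=1)
    ax.set_yticks(range(len(rows)))
    ax.set_yticklabels([fr.label for fr in reversed(rows)], fontsize=8)
    ax.set_xlabel("abundance (pmol/mg microsomal protein)")
    ax.set_title(f"{result.protein} ({result.tissue}), k={result.k}")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
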