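"""Optional dot-matrix rendering of a concordance result table.

Circle size and color intensity are proportional to the Pearson
coefficient; a black frame marks cells flagged significant. Blue encodes
positive, red negative correlations. TSV tables remain the contract — the
plot is a convenience view.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["dot_matrix"]


def dot_matrix(result: pd.DataFrame, path: str | Path, title: str = "") -> Path:
    """Render a flagged long-format concordance table to ``path``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    factors = list(result["factor"].unique())
    targets = list(result["target"].unique())
    fig_w = max(4.0, 0.45 * len(targets) + 2)
    fig_h = max(3.0, 0.35 * len(factors) + 1.5)
    fig, ax = plt.subplots(figsize=(fig_w, fig_h))
    for _, row in result.iterrows():
        if not np.isfinite(row["r"]):
            continue
        x = targets.index(row["target"])
        y = factors.index(row["factor"])
        color = plt.cm.RdBu(0.5 + row["r"] / 2)  # blue positive, red negative
        edge = "black" if row.get("sig", "none") != "none" else "none"
        ax.scatter(
            x, y, s=40 + 360 * abs(row["r"]), c=[color],
            edgecolors=edge, linewidths=1.2, zorder=3,
        )
    ax.set_xticks(range(len(targets)), targets, rotation=90, fontsize=7)
    ax.set_yticks(range(len(factors)), factors, fontsize=8)
    ax.set_xlim(-0.5, len(targets) - 0.5)
    ax.set_ylim(len(factors) - 0.5, -0.5)
    ax.set_title(title)
    ax.grid(True, color="0.9", zorder=0)
    fig.tight_layout()
    path = Path(path)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
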