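"""Diagnostic figures: cell-mean histograms and prediction-vs-data scatters."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd

from .design import ABSOLUTE_LEVELS, RELATIVE_LEVELS
from .comparison import _pair


def cell_means_histogram(cell_summary: pd.DataFrame, title: str = "",
                         path: str | Path | None = None):
    """Bar chart of the 18 condition means with CI error bars, grouped like
    the prediction-pattern figures (absolute level x relative level panels,
    split by dangerousness)."""
    fig, axes = plt.subplots(1, 3, figsize=(10, 3.2), sharey=True)
    for ax, abs_level in zip(axes, ABSOLUTE_LEVELS):
        sub = cell_summary[cell_summary["abs_level"] == abs_level]
        for shift, danger in ((-0.18, 0), (0.18, 1)):
            rows = sub[sub["dangerous"] == danger].set_index("rel_level").reindex(
                list(RELATIVE_LEVELS))
            x = [i + shift for i in range(len(rows))]
            err = [(rows["mean"] - rows["ci_low"]).to_numpy(),
                   (rows["ci_high"] - rows["mean"]).to_numpy()]
            ax.bar(x, rows["mean"], width=0.34, yerr=err, capsize=2,
                   label="dangerous" if danger else "non-dangerous")
        ax.set_xticks(range(3), RELATIVE_LEVELS)
        ax.set_title(f"absolute: {abs_level}")
        ax.set_ylim(-3.2, 3.2)
        ax.axhline(0, color="k", lw=0.5)
    axes[0].set_ylabel("justifiability rating")
    axes[-1].legend(fontsize=8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def prediction_scatter(predictions: pd.DataFrame, trials: pd.DataFrame,
                       granularity: str = "cell",
                       path: str | Path | None = None):
    """Observed ratings against one model's normalized predictions."""
    p, obs = _pair(predictions, trials, granularity)
    fig, ax = plt.subplots(figsize=(3.4, 3.4))
    ax.scatter(p, obs, s=12, alpha=0.6)
    ax.plot([-3, 3], [-3, 3], "k--", lw=0.8)
    ax.set_xlabel(f"{predictions.attrs.get('model', 'model')} prediction")
    ax.set_ylabel("observed rating")
    ax.set_xlim(-3.2, 3.2)
    ax.set_ylim(-3.2, 3.2)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
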