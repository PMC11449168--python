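"""Simple publication-style summaries: caterpillar and forest plots."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import pandas as pd


def caterpillar_plot(
    realized: pd.DataFrame,
    value_col: str,
    path: str | Path,
    title: str = "",
    population_mean: float | None = None,
) -> None:
    """Sorted per-individual estimates with 95% HPD bars."""
    df = realized.sort_values(value_col).reset_index(drop=True)
    fig, ax = plt.subplots(figsize=(7, 3.5))
    x = range(len(df))
    ax.errorbar(
        x, df[value_col],
        yerr=[df[value_col] - df["hpd_low"], df["hpd_high"] - df[value_col]],
        fmt="o", ms=2.5, lw=0.6, color="steelblue", ecolor="lightsteelblue",
    )
    if population_mean is not None:
        ax.axhline(population_mean, ls="--", color="grey", lw=1)
    ax.set_xlabel("individual (sorted)")
    ax.set_ylabel(value_col.replace("_", " "))
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def correlation_forest_plot(correlations: pd.DataFrame, path: str | Path) -> None:
    """Posterior correlations with HPD bars; filled markers exclude zero."""
    fig, ax = plt.subplots(figsize=(6, 0.5 * len(correlations) + 1.2))
    ypos = range(len(correlations))
    for y, (_, row) in zip(ypos, correlations.iterrows()):
        filled = row.get("significant", False)
        ax.plot(
            [row["hpd_low"], row["hpd_high"]], [y, y], color="steelblue", lw=1.5
        )
        ax.plot(
            row["mean"], y, "o",
            color="steelblue" if filled else "white",
            mec="steelblue", ms=6,
        )
    ax.axvline(0, color="grey", ls="--", lw=1)
    ax.set_yticks(list(ypos))
    ax.set_yticklabels(correlations["label"])
    ax.set_xlabel("among-individual correlation")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
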