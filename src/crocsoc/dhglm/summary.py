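"""Posterior summaries: means and highest-posterior-density intervals."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .model import BEHAVIOURS
from .sampler import PosteriorDraws, _reported_matrix

logger = logging.getLogger(__name__)


def hpd_interval(draws: np.ndarray, prob: float = 0.95) -> tuple[float, float]:
    """Narrowest interval containing ``prob`` of the draws.

    For a unimodal sample this is the highest-posterior-density interval;
    it is never wider than the equal-tailed interval.
    """
    x = np.sort(np.asarray(draws, dtype=float).ravel())
    n = len(x)
    if n == 0:
        raise ValueError("empty draws")
    m = max(1, int(np.ceil(prob * n)))
    if m >= n:
        return float(x[0]), float(x[-1])
    widths = x[m:] - x[: n - m]
    j = int(np.argmin(widths))
    return float(x[j]), float(x[j + m])


def summarize_fit(
    draws: PosteriorDraws, prob: float = 0.95, include_levels: bool = True
) -> pd.DataFrame:
    """Per-parameter posterior mean and HPD interval, with diagnostics.

    Fixed effects, SDs and correlations carry their split-R-hat and ESS;
    random-effect levels (individual and year intercepts) are appended when
    ``include_levels``. Cases where the posterior mean falls outside its
    own HPD interval (possible for strongly multimodal samples) are logged,
    not raised.
    """
    names, mat = _reported_matrix(draws.arrays)
    flat = mat.reshape(-1, mat.shape[-1])
    rows = []
    for j, name in enumerate(names):
        lo, hi = hpd_interval(flat[:, j], prob)
        rows.append((name, float(flat[:, j].mean()), lo, hi))
    summary = pd.DataFrame(rows, columns=["parameter", "mean", "hpd_low", "hpd_high"])
    summary = summary.merge(draws.diagnostics, on="parameter", how="left")

    if include_levels:
        extra = []
        for block, labels in (
            ("a", draws.coords["individual"]),
            ("b", draws.coords["individual"]),
            ("u", draws.coords["year"]),
            ("v", draws.coords["year"]),
        ):
            arr = draws.get(block)  # (s, n_lev, 3)
            for li, lab in enumerate(labels):
                for k, beh in enumerate(BEHAVIOURS):
                    lo, hi = hpd_interval(arr[:, li, k], prob)
                    extra.append(
                        (f"{block}[{lab},{beh}]", float(arr[:, li, k].mean()), lo, hi,
                         np.nan, np.nan)
                    )
        summary = pd.concat(
            [summary, pd.DataFrame(extra, columns=summary.columns)],
            ignore_index=True,
        )

    outside = (summary["mean"] < summary["hpd_low"]) | (
        summary["mean"] > summary["hpd_high"]
    )
    if outside.any():
        logger.warning(
            "posterior mean outside its HPD interval for %s",
            summary.loc[outside, "parameter"].tolist(),
        )
    return summary
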