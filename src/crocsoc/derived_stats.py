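"""Derived personality and predictability statistics.

Everything here is computed per posterior draw and then summarized
(posterior mean + 95% HPD), propagating the full uncertainty; plug-in
``*_point`` variants evaluate the same formulas on point estimates, which
is how worked examples from printed tables are checked.

Definitions, for behaviour k:

* repeatability ``R = V_ID / (V_ID + V_year + V_res)`` with
  ``V_ID = sd_ID^2``, ``V_year = sd_year^2`` and — because the dispersion
  model works on the log scale — ``V_res = (exp(gamma0))^2`` using only the
  dispersion intercept;
* coefficient of predictability ``CV_p = sqrt(exp(omega^2) - 1)`` where
  omega is the among-individual SD of dispersion intercepts (the
  lognormal-CV form of its cited source; see the methods note on the
  square root);
* realized phenotype of individual i: ``beta0 + a_i`` back-transformed to
  original units; realized rIIV: ``exp(gamma0 + b_i)`` rescaled by the
  response's standardization SD (approximate in original units for
  cube-root transformed responses — the power transform has no exact SD
  mapping).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dhglm.model import BEHAVIOURS, RE_NAMES
from .dhglm.sampler import PosteriorDraws
from .dhglm.summary import hpd_interval


@dataclass(frozen=True)
class PosteriorQuantity:
    """A scalar derived quantity with its posterior draws and summary."""

    name: str
    draws: np.ndarray
    mean: float
    hpd_low: float
    hpd_high: float

    @classmethod
    def from_draws(cls, name: str, draws: np.ndarray) -> "PosteriorQuantity":
        lo, hi = hpd_interval(draws)
        return cls(name, draws, float(np.mean(draws)), lo, hi)

    @property
    def significant(self) -> bool:
        """True when the 95% HPD excludes zero."""
        return not (self.hpd_low <= 0.0 <= self.hpd_high)


def _k(behaviour: str) -> int:
    try:
        return BEHAVIOURS.index(behaviour)
    except ValueError:
        raise KeyError(f"unknown behaviour {behaviour!r}") from None


def repeatability_point(sd_id: float, sd_year: float, gamma0: float) -> float:
    """Variance-partitioning repeatability from point estimates."""
    v_id, v_year, v_res = sd_id**2, sd_year**2, np.exp(gamma0) ** 2
    return v_id / (v_id + v_year + v_res)


def repeatability(draws: PosteriorDraws, behaviour: str) -> PosteriorQuantity:
    """Posterior of the repeatability of one behaviour (per-draw)."""
    k = _k(behaviour)
    sd_id = draws.get("sd_id")[:, k]
    sd_year = draws.get("sd_year")[:, k]
    gamma0 = draws.get("gamma")[:, k, 0]
    r = sd_id**2 / (sd_id**2 + sd_year**2 + np.exp(gamma0) ** 2)
    return PosteriorQuantity.from_draws(f"repeatability[{behaviour}]", r)


def cv_p_point(omega: float) -> float:
    """Coefficient of predictability from a point estimate of omega."""
    return float(np.sqrt(np.expm1(omega**2)))


def coefficient_of_predictability(
    draws: PosteriorDraws, behaviour: str
) -> PosteriorQuantity:
    """Posterior of CV_p for one behaviour (per-draw)."""
    k = _k(behaviour)
    omega = draws.get("sd_id")[:, 3 + k]
    cv = np.sqrt(np.expm1(omega**2))
    return PosteriorQuantity.from_draws(f"cv_p[{behaviour}]", cv)


def realized_phenotypes(draws: PosteriorDraws, behaviour: str) -> pd.DataFrame:
    """Per-individual behavioural phenotypes in original units.

    Per draw and individual: population intercept plus the individual's
    random intercept, destandardized and (where a cube root was applied)
    cubed back to the original scale. Ordering of individuals follows their
    random intercepts because the back-transform is monotone.
    """
    k = _k(behaviour)
    tr = draws.data.transforms[behaviour]
    z = draws.get("beta")[:, k, 0][:, None] + draws.get("a")[:, :, k]  # (s, n_i)
    raw = tr.to_raw(z)
    rows = []
    for i, ind in enumerate(draws.coords["individual"]):
        lo, hi = hpd_interval(raw[:, i])
        rows.append((ind, float(raw[:, i].mean()), lo, hi))
    return pd.DataFrame(
        rows, columns=["individual_id", "realized_phenotype", "hpd_low", "hpd_high"]
    )


def realized_riiv(draws: PosteriorDraws, behaviour: str) -> pd.DataFrame:
    """Per-individual residual SDs (rIIV) in original units.

    ``exp(gamma0 + b_i)`` rescaled by the response's standardization SD.
    For cube-root transformed responses the original-unit value is
    approximate (flagged in the ``approximate`` column): the cube maps
    means, not SDs, so only the standardization is inverted.
    """
    k = _k(behaviour)
    tr = draws.data.transforms[behaviour]
    sig = np.exp(draws.get("gamma")[:, k, 0][:, None] + draws.get("b")[:, :, k])
    sig_raw = sig * tr.sd
    rows = []
    for i, ind in enumerate(draws.coords["individual"]):
        lo, hi = hpd_interval(sig_raw[:, i])
        rows.append((ind, float(sig_raw[:, i].mean()), lo, hi, tr.power != 1))
    return pd.DataFrame(
        rows,
        columns=["individual_id", "realized_riiv", "hpd_low", "hpd_high", "approximate"],
    )


MEAN_RIIV_PAIRS = {beh: (i, 3 + i) for i, beh in enumerate(BEHAVIOURS)}
SYNDROME_PAIRS = {
    (BEHAVIOURS[i], BEHAVIOURS[j]): (i, j) for i in range(3) for j in range(i + 1, 3)
}


def random_effect_correlations(draws: PosteriorDraws) -> pd.DataFrame:
    """Mean-rIIV correlations and behavioural syndromes from Sigma_ID.

    One row per reported correlation with posterior mean, 95% HPD and a
    significance flag (HPD excludes zero).
    """
    corr = draws.get("corr_id")  # (s, 6, 6)
    rows = []
    for beh, (i, j) in MEAN_RIIV_PAIRS.items():
        q = PosteriorQuantity.from_draws(f"r_mean_riiv[{beh}]", corr[:, i, j])
        rows.append(("mean_riiv", beh, q))
    for (b1, b2), (i, j) in SYNDROME_PAIRS.items():
        q = PosteriorQuantity.from_draws(f"syndrome[{b1},{b2}]", corr[:, i, j])
        rows.append(("syndrome", f"{b1}~{b2}", q))
    return pd.DataFrame(
        [
            (kind, label, q.mean, q.hpd_low, q.hpd_high, q.significant)
            for kind, label, q in rows
        ],
        columns=["kind", "label", "mean", "hpd_low", "hpd_high", "significant"],
    )


def correlation_matrix_summary(draws: PosteriorDraws) -> pd.DataFrame:
    """Posterior summary of every entry of the 6x6 individual-level matrix."""
    corr = draws.get("corr_id")
    rows = []
    for i in range(6):
        for j in range(i + 1, 6):
            lo, hi = hpd_interval(corr[:, i, j])
            rows.append(
                (RE_NAMES[i], RE_NAMES[j], float(corr[:, i, j].mean()), lo, hi)
            )
    return pd.DataFrame(rows, columns=["re_1", "re_2", "mean", "hpd_low", "hpd_high"])


# ---------------------------------------------------------------------------
# Associates model: does home-range size drive encounter counts?
# ---------------------------------------------------------------------------


@dataclass
class AssociatesModelResult:
    """Bayesian Poisson mixed model of monthly associate counts.

    log rate = intercept + hr_size_z * b_hr + observed * b_type
               + hr_size_z * observed * b_interaction + ID + year intercepts.
    """

    summary: pd.DataFrame
    draws: dict[str, np.ndarray]
    hr_scale: tuple[float, float]

    def coefficient(self, name: str) -> PosteriorQuantity:
        return PosteriorQuantity.from_draws(name, self.draws[name])

    def predicted_rates(self, counts: pd.DataFrame) -> np.ndarray:
        hr_z = (counts["hr_size"].to_numpy() - self.hr_scale[0]) / self.hr_scale[1]
        obs = (counts["type"].to_numpy() == "observed").astype(float)
        lp = (
            self.draws["intercept"].mean()
            + self.draws["hr_size"].mean() * hr_z
            + self.draws["type_observed"].mean() * obs
            + self.draws["hr_size:type_observed"].mean() * hr_z * obs
        )
        return np.exp(lp)


def fit_associates_glmm(
    counts: pd.DataFrame,
    iterations: int = 3000,
    warmup: int = 1000,
    seed: int = 0,
) -> AssociatesModelResult:
    """Fit the Poisson GLMM for associate counts by slice-within-Gibbs.

    ``counts`` must carry individual_id, year, hr_size, type
    ('potential'/'observed') and count. Home-range size is standardized
    internally. Priors: Normal(0, 5) on fixed effects, half-Normal(0, 1)
    on the two random-intercept SDs.
    """
    from .dhglm.sampler import _slice_update

    y = counts["count"].to_numpy(dtype=float)
    if np.all(y == 0):
        raise ValueError("all counts are zero; the associates model is degenerate")
    hr_m = float(counts["hr_size"].mean())
    hr_s = float(counts["hr_size"].std(ddof=0)) or 1.0
    hr_z = (counts["hr_size"].to_numpy(dtype=float) - hr_m) / hr_s
    obs = (counts["type"].to_numpy() == "observed").astype(float)
    X = np.column_stack([np.ones_like(hr_z), hr_z, obs, hr_z * obs])
    fixed_names = ["intercept", "hr_size", "type_observed", "hr_size:type_observed"]

    ind_cat = pd.Categorical(counts["individual_id"])
    yr_cat = pd.Categorical(counts["year"])
    ind_idx = ind_cat.codes.astype(int)
    yr_idx = yr_cat.codes.astype(int)
    n_ind, n_yr = len(ind_cat.categories), len(yr_cat.categories)

    rng = np.random.default_rng(seed)
    beta = np.zeros(4)
    beta[0] = np.log(max(y.mean(), 0.1))
    re_i = np.zeros(n_ind)
    re_y = np.zeros(n_yr)
    log_sd = np.log(np.array([0.3, 0.2]))

    def lp_vec() -> np.ndarray:
        return X @ beta + re_i[ind_idx] + re_y[yr_idx]

    kept = {
        name: np.empty(iterations - warmup)
        for name in fixed_names + ["sd_individual", "sd_year"]
    }
    sum_y_i = np.bincount(ind_idx, weights=y, minlength=n_ind)
    sum_y_yr = np.bincount(yr_idx, weights=y, minlength=n_yr)

    for it in range(iterations):
        # fixed effects
        for j in range(4):
            xj = X[:, j]
            lp0 = lp_vec() - xj * beta[j]

            def logf(t: float) -> float:
                lam = lp0 + xj * t
                return float(np.sum(y * lam) - np.sum(np.exp(lam)) - t * t / 50.0)

            beta[j] = _slice_update(float(beta[j]), logf, rng, w=0.3)

        # individual intercepts (partial evaluation through per-level sums)
        lp0 = lp_vec() - re_i[ind_idx]
        e_i = np.bincount(ind_idx, weights=np.exp(lp0), minlength=n_ind)
        s2 = np.exp(2.0 * log_sd[0])
        for i in range(n_ind):

            def logf(t: float) -> float:
                return float(sum_y_i[i] * t - e_i[i] * np.exp(t) - t * t / (2 * s2))

            re_i[i] = _slice_update(float(re_i[i]), logf, rng, w=0.4)

        lp0 = lp_vec() - re_y[yr_idx]
        e_y = np.bincount(yr_idx, weights=np.exp(lp0), minlength=n_yr)
        s2 = np.exp(2.0 * log_sd[1])
        for i in range(n_yr):

            def logf(t: float) -> float:
                return float(sum_y_yr[i] * t - e_y[i] * np.exp(t) - t * t / (2 * s2))

            re_y[i] = _slice_update(float(re_y[i]), logf, rng, w=0.4)

        # random-effect SDs on the log scale, half-Normal(0, 1) prior
        for j, re in ((0, re_i), (1, re_y)):

            def logf(ls: float) -> float:
                s = np.exp(ls)
                return float(
                    -len(re) * ls
                    - 0.5 * np.sum(re**2) / s**2
                    - 0.5 * s**2
                    + ls
                )

            log_sd[j] = _slice_update(float(log_sd[j]), logf, rng, w=0.4)

        if it >= warmup:
            t = it - warmup
            for j, name in enumerate(fixed_names):
                kept[name][t] = beta[j]
            kept["sd_individual"][t] = np.exp(log_sd[0])
            kept["sd_year"][t] = np.exp(log_sd[1])

    rows = []
    for name, arr in kept.items():
        lo, hi = hpd_interval(arr)
        rows.append((name, float(arr.mean()), lo, hi))
    summary = pd.DataFrame(rows, columns=["parameter", "mean", "hpd_low", "hpd_high"])
    return AssociatesModelResult(summary=summary, draws=kept, hr_scale=(hr_m, hr_s))
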