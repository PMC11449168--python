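"""Blocked MCMC for the double-hierarchical Gaussian model.

The sampler is a Metropolis-within-Gibbs scheme built around the model's
conditional structure rather than a generic black-box algorithm:

* mean-model fixed effects and mean random intercepts (individual and
  year) have exact Gaussian full conditionals given the cell SDs — drawn
  by conjugate Gibbs updates (batched 3x3 linear algebra across levels);
* dispersion fixed effects, year dispersion intercepts, random-effect SDs
  (sampled on the log scale) and correlation-matrix entries are updated by
  univariate stepping-out slice sampling (Neal 2003), which is tuning-free
  and respects bounded/constrained supports (a non-PSD correlation
  proposal simply falls below the slice);
* individual dispersion intercepts, the highest-dimensional awkward block,
  use a vectorized random-walk Metropolis step per individual with
  per-individual scale adaptation during warm-up.

Random effects are sampled on the centred scale: the conjugate updates are
exact there, and at the panel sizes this package targets the data dominate
the hierarchy, so the small-SD funnel that motivates non-centring is not
binding.

Determinism: all randomness flows from one integer seed through
``numpy.random.SeedSequence``; identical data + config + seed reproduce
identical draws.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.linalg import cho_factor, cho_solve, solve_triangular

from .model import (
    BEHAVIOURS,
    DESIGN_COLUMNS,
    RE_NAMES,
    DHGLMParams,
    ModelData,
    PriorSpec,
)


@dataclass
class SamplerConfig:
    """Chain settings; defaults mirror the study protocol.

    Four chains of 8000 iterations with 6000 warm-up and thinning 2 retain
    1000 draws per chain. ``fit_dhglm`` reports the actual retained count.
    """

    chains: int = 4
    iterations: int = 8000
    warmup: int = 6000
    thin: int = 2
    b_mh_steps: int = 4
    rhat_threshold: float = 1.01
    ess_threshold: float = 1000.0

    @property
    def n_keep_per_chain(self) -> int:
        return len(range(self.warmup, self.iterations, self.thin))


@dataclass
class PosteriorDraws:
    """Retained draws plus coordinates and sampler diagnostics.

    Arrays are keyed by block name with shape (chain, draw, ...); see
    ``coords`` for the meaning of trailing axes. ``diagnostics`` holds
    split-R-hat and bulk effective sample size per reported scalar
    parameter (fixed effects, SDs, correlations).
    """

    arrays: dict[str, np.ndarray]
    coords: dict[str, list]
    diagnostics: "object"  # pandas.DataFrame
    converged: bool
    config: SamplerConfig
    data: ModelData

    @property
    def n_chains(self) -> int:
        return next(iter(self.arrays.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.arrays.values())).shape[1]

    def get(self, name: str) -> np.ndarray:
        """Draws stacked over chains: shape (chain*draw, ...)."""
        arr = self.arrays[name]
        return arr.reshape(-1, *arr.shape[2:])

    def to_inference_data(self):
        import arviz as az

        dims = {
            "beta": ["behaviour", "design"],
            "gamma": ["behaviour", "design"],
            "a": ["individual", "behaviour"],
            "b": ["individual", "behaviour"],
            "u": ["year", "behaviour"],
            "v": ["year", "behaviour"],
            "sd_id": ["re"],
            "sd_year": ["re"],
            "corr_id": ["re", "re2"],
            "corr_year": ["re", "re2"],
        }
        coords = {
            "behaviour": list(BEHAVIOURS),
            "design": list(DESIGN_COLUMNS),
            "individual": self.coords["individual"],
            "year": [str(y) for y in self.coords["year"]],
            "re": list(RE_NAMES),
            "re2": list(RE_NAMES),
        }
        return az.from_dict(posterior=self.arrays, dims=dims, coords=coords)


def _slice_update(
    x0: float,
    logf: Callable[[float], float],
    rng: np.random.Generator,
    w: float = 0.5,
    max_step_out: int = 30,
    max_shrink: int = 60,
) -> float:
    """One univariate stepping-out slice-sampling update."""
    f0 = logf(x0)
    if not np.isfinite(f0):
        raise FloatingPointError("slice sampler started outside the support")
    level = f0 - rng.exponential()
    left = x0 - w * rng.random()
    right = left + w
    k = max_step_out
    while k > 0 and logf(left) > level:
        left -= w
        k -= 1
    k = max_step_out
    while k > 0 and logf(right) > level:
        right += w
        k -= 1
    for _ in range(max_shrink):
        x1 = rng.uniform(left, right)
        if logf(x1) > level:
            return x1
        if x1 < x0:
            left = x1
        else:
            right = x1
    return x0


def _conditional_blocks(sd: np.ndarray, corr: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """For eta = (a, b) ~ MVN(0, D corr D): conditional of a given b.

    Returns (M, V) with a | b ~ MVN(M b, V).
    """
    sigma = (sd[:, None] * corr) * sd[None, :]
    s_aa, s_ab, s_bb = sigma[:3, :3], sigma[:3, 3:], sigma[3:, 3:]
    m = s_ab @ np.linalg.inv(s_bb)
    v = s_aa - m @ s_ab.T
    return m, v


class _ChainState:
    """Mutable state of one chain plus cached per-behaviour index arrays."""

    def __init__(self, data: ModelData, priors: PriorSpec, rng: np.random.Generator):
        self.data = data
        self.priors = priors
        self.rng = rng
        self.n_i = data.n_individuals
        self.n_y = data.n_years
        self.p = data.X.shape[1]

        mask = data.mask
        self.idx = [np.flatnonzero(mask[:, k]) for k in range(3)]
        self.yk = [data.y[self.idx[k], k] for k in range(3)]
        self.Xk = [np.ascontiguousarray(data.X[self.idx[k]]) for k in range(3)]
        self.ik = [data.ind_idx[self.idx[k]] for k in range(3)]
        self.yrk = [data.year_idx[self.idx[k]] for k in range(3)]

        p = self.p
        self.beta = np.zeros((3, p))
        self.gamma = np.zeros((3, p))
        for k in range(3):
            X, y = self.Xk[k], self.yk[k]
            self.beta[k] = np.linalg.solve(X.T @ X + np.eye(p), X.T @ y)
            resid = y - X @ self.beta[k]
            self.gamma[k, 0] = float(np.log(max(np.std(resid), 1e-3)))
        self.a = np.zeros((self.n_i, 3))
        self.b = np.zeros((self.n_i, 3))
        self.u = np.zeros((self.n_y, 3))
        self.v = np.zeros((self.n_y, 3))
        self.sd_id = np.full(6, 0.3)
        self.corr_id = np.eye(6)
        self.sd_year = np.full(6, 0.15)
        self.corr_year = np.eye(6)
        self.b_scales = np.full(self.n_i, 0.25)
        self.b_mh_steps = 4
        # per-individual total length (constant within individual), used by
        # the recentering moves
        tl_col = data.X[:, self.p - 2]
        sums = np.zeros(self.n_i)
        cnts = np.zeros(self.n_i)
        np.add.at(sums, data.ind_idx, tl_col)
        np.add.at(cnts, data.ind_idx, 1.0)
        self.tl_i = sums / np.maximum(cnts, 1.0)

    # -- cached quantities -------------------------------------------------
    def disp_lp(self, k: int) -> np.ndarray:
        return self.Xk[k] @ self.gamma[k] + self.b[self.ik[k], k] + self.v[self.yrk[k], k]

    def mean_resid(self, k: int) -> np.ndarray:
        return (
            self.yk[k]
            - self.Xk[k] @ self.beta[k]
            - self.a[self.ik[k], k]
            - self.u[self.yrk[k], k]
        )

    # -- conjugate Gaussian blocks ----------------------------------------
    def update_beta(self) -> None:
        prec0 = 1.0 / self.priors.beta_sd**2
        for k in range(3):
            w = np.exp(-2.0 * self.disp_lp(k))
            target = self.yk[k] - self.a[self.ik[k], k] - self.u[self.yrk[k], k]
            X = self.Xk[k]
            A = X.T @ (X * w[:, None])
            A[np.diag_indices_from(A)] += prec0
            rhs = X.T @ (w * target)
            c, low = cho_factor(A, lower=True)
            mean = cho_solve((c, low), rhs)
            z = self.rng.standard_normal(self.p)
            self.beta[k] = mean + solve_triangular(c, z, lower=low, trans="T")

    def _update_gaussian_levels(
        self, which: str
    ) -> None:
        """Conjugate draw of a (individual) or u (year) mean intercepts."""
        if which == "a":
            n_lev, lev_idx = self.n_i, self.ik
            other, sd, corr = self.b, self.sd_id, self.corr_id
        else:
            n_lev, lev_idx = self.n_y, self.yrk
            other, sd, corr = self.v, self.sd_year, self.corr_year
        m_op, v_cond = _conditional_blocks(sd, corr)
        v_inv = np.linalg.inv(v_cond)
        prior_mean = other @ m_op.T  # (n_lev, 3)

        prec = np.zeros((n_lev, 3))
        lin = np.zeros((n_lev, 3))
        for k in range(3):
            w = np.exp(-2.0 * self.disp_lp(k))
            if which == "a":
                target = (
                    self.yk[k] - self.Xk[k] @ self.beta[k] - self.u[self.yrk[k], k]
                )
            else:
                target = (
                    self.yk[k] - self.Xk[k] @ self.beta[k] - self.a[self.ik[k], k]
                )
            prec[:, k] = np.bincount(lev_idx[k], weights=w, minlength=n_lev)
            lin[:, k] = np.bincount(lev_idx[k], weights=w * target, minlength=n_lev)

        P = np.broadcast_to(v_inv, (n_lev, 3, 3)).copy()
        P[:, np.arange(3), np.arange(3)] += prec
        h = prior_mean @ v_inv.T + lin
        cov = np.linalg.inv(P)
        mean = np.einsum("nij,nj->ni", cov, h)
        L = np.linalg.cholesky(cov)
        z = self.rng.standard_normal((n_lev, 3))
        draw = mean + np.einsum("nij,nj->ni", L, z)
        if which == "a":
            self.a = draw
        else:
            self.u = draw

    # -- dispersion blocks -------------------------------------------------
    def update_gamma(self) -> None:
        prec0 = 1.0 / self.priors.gamma_sd**2
        for k in range(3):
            r2 = self.mean_resid(k) ** 2
            lp = self.disp_lp(k)
            X = self.Xk[k]
            for j in range(self.p):
                xj = X[:, j]
                lp0 = lp - xj * self.gamma[k, j]

                def logf(g: float) -> float:
                    full = lp0 + xj * g
                    return float(
                        -np.sum(full)
                        - 0.5 * np.sum(r2 * np.exp(-2.0 * full))
                        - 0.5 * prec0 * g * g
                    )

                self.gamma[k, j] = _slice_update(
                    float(self.gamma[k, j]), logf, self.rng, w=0.2
                )
                lp = lp0 + xj * self.gamma[k, j]

    def update_v(self) -> None:
        sigma_inv = np.linalg.inv(
            (self.sd_year[:, None] * self.corr_year) * self.sd_year[None, :]
        )
        for k in range(3):
            r2 = self.mean_resid(k) ** 2
            lp0 = (
                self.Xk[k] @ self.gamma[k] + self.b[self.ik[k], k]
            )  # excludes v
            e_y = np.bincount(
                self.yrk[k], weights=0.5 * r2 * np.exp(-2.0 * lp0), minlength=self.n_y
            )
            n_y = np.bincount(self.yrk[k], minlength=self.n_y).astype(float)
            for y in range(self.n_y):
                zeta = np.concatenate([self.u[y], self.v[y]])
                d = 3 + k

                def logf(val: float) -> float:
                    zeta[d] = val
                    prior = -0.5 * float(zeta @ sigma_inv @ zeta)
                    return prior - n_y[y] * val - e_y[y] * np.exp(-2.0 * val)

                self.v[y, k] = _slice_update(
                    float(self.v[y, k]), logf, self.rng, w=0.3
                )

    def update_b(self, adapt: bool) -> None:
        counts = np.zeros((self.n_i, 3))
        e_ik = np.zeros((self.n_i, 3))
        for k in range(3):
            r2 = self.mean_resid(k) ** 2
            lp0 = self.Xk[k] @ self.gamma[k] + self.v[self.yrk[k], k]  # excludes b
            counts[:, k] = np.bincount(self.ik[k], minlength=self.n_i)
            e_ik[:, k] = np.bincount(
                self.ik[k], weights=0.5 * r2 * np.exp(-2.0 * lp0), minlength=self.n_i
            )
        sigma_inv = np.linalg.inv(
            (self.sd_id[:, None] * self.corr_id) * self.sd_id[None, :]
        )

        def joint(bmat: np.ndarray) -> np.ndarray:
            eta = np.concatenate([self.a, bmat], axis=1)
            prior = -0.5 * np.einsum("ni,ij,nj->n", eta, sigma_inv, eta)
            lik = np.sum(-counts * bmat - e_ik * np.exp(-2.0 * bmat), axis=1)
            return prior + lik

        cur = joint(self.b)
        for _step in range(self.b_mh_steps):
            prop = self.b + self.b_scales[:, None] * self.rng.standard_normal(
                (self.n_i, 3)
            )
            new = joint(prop)
            accept = np.log(self.rng.random(self.n_i)) < new - cur
            self.b[accept] = prop[accept]
            cur = np.where(accept, new, cur)
            if adapt:
                self.b_scales *= np.exp(0.05 * (accept.astype(float) - 0.35))
                np.clip(self.b_scales, 1e-3, 2.0, out=self.b_scales)

    # -- hyperparameters ---------------------------------------------------
    def _update_cov(self, level: str) -> None:
        if level == "id":
            x = np.concatenate([self.a, self.b], axis=1)
            sd, corr = self.sd_id, self.corr_id
        else:
            x = np.concatenate([self.u, self.v], axis=1)
            sd, corr = self.sd_year, self.corr_year
        n = x.shape[0]
        scale = self.priors.sd_scale
        eta_lkj = self.priors.lkj_eta
        # the MVN quadratic form enters only through the 6x6 scatter matrix,
        # so each slice evaluation is O(1) in the number of levels
        scatter = x.T @ x

        # SDs on the log scale; correlation matrix fixed within this block
        L_corr = np.linalg.cholesky(corr)
        logdet_corr = 2.0 * float(np.sum(np.log(np.diag(L_corr))))
        half = solve_triangular(L_corr, np.eye(6), lower=True)
        corr_inv = half.T @ half
        for j in range(6):

            def logf(ls: float) -> float:
                s = sd.copy()
                s[j] = np.exp(ls)
                quad = float(np.sum(corr_inv * (scatter / np.outer(s, s))))
                logdet = 2.0 * float(np.sum(np.log(s))) + logdet_corr
                lp = -0.5 * (quad + n * logdet)
                lp += -0.5 * (s[j] / scale) ** 2  # half-normal kernel
                lp += ls  # log-scale Jacobian
                return lp

            sd[j] = np.exp(
                _slice_update(float(np.log(sd[j])), logf, self.rng, w=0.4)
            )

        # correlation entries, one at a time, slice within the PSD region
        scatter_z = scatter / np.outer(sd, sd)
        eye6 = np.eye(6)
        for j in range(6):
            for l in range(j + 1, 6):

                def logf(c: float) -> float:
                    if abs(c) >= 1.0:
                        return -np.inf
                    cc = corr.copy()
                    cc[j, l] = cc[l, j] = c
                    try:
                        L = np.linalg.cholesky(cc)
                    except np.linalg.LinAlgError:
                        return -np.inf
                    half = solve_triangular(L, eye6, lower=True, check_finite=False)
                    quad = float(np.sum((half.T @ half) * scatter_z))
                    logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
                    lp = -0.5 * (quad + n * logdet)
                    if eta_lkj != 1.0:
                        lp += (eta_lkj - 1.0) * logdet
                    return lp

                corr[j, l] = corr[l, j] = _slice_update(
                    float(corr[j, l]), logf, self.rng, w=0.3
                )

    def _recenter(self) -> None:
        """Gibbs moves along the intercept/random-effect translation axes.

        The likelihood is invariant to shifting mass between a fixed
        effect of an individual-constant covariate and the matching
        projection of its random-effect block (the intercept for both
        levels; total length for the individual level), so the conditional
        of the shift is Gaussian in the priors alone; sampling it directly
        removes the slow random-walk drift this confounding otherwise
        causes (worst for the few-level year block).
        """
        p = self.p
        for level in ("id", "year"):
            if level == "id":
                eta = np.concatenate([self.a, self.b], axis=1)
                sd, corr = self.sd_id, self.corr_id
                directions = [(np.ones(eta.shape[0]), 0), (self.tl_i, p - 2)]
            else:
                eta = np.concatenate([self.u, self.v], axis=1)
                sd, corr = self.sd_year, self.corr_year
                directions = [(np.ones(eta.shape[0]), 0)]
            omega = np.linalg.inv((sd[:, None] * corr) * sd[None, :])
            for weights, col in directions:
                wsq = float(np.sum(weights**2))
                if wsq <= 0:
                    continue
                for d in range(6):
                    k = d % 3
                    if d < 3:
                        c0, prior_sd = self.beta[k, col], self.priors.beta_sd
                    else:
                        c0, prior_sd = self.gamma[k, col], self.priors.gamma_sd
                    prec = wsq * omega[d, d] + 1.0 / prior_sd**2
                    lin = float(weights @ (eta @ omega[:, d])) - c0 / prior_sd**2
                    delta = lin / prec + self.rng.standard_normal() / np.sqrt(prec)
                    eta[:, d] -= delta * weights
                    if d < 3:
                        self.beta[k, col] += delta
                    else:
                        self.gamma[k, col] += delta
            if level == "id":
                self.a, self.b = eta[:, :3].copy(), eta[:, 3:].copy()
            else:
                self.u, self.v = eta[:, :3].copy(), eta[:, 3:].copy()

    def sweep(self, adapt: bool) -> None:
        self.update_beta()
        self._update_gaussian_levels("a")
        self._update_gaussian_levels("u")
        self.update_gamma()
        self.update_v()
        self.update_b(adapt)
        self._recenter()
        self._update_cov("id")
        self._update_cov("year")

    def params(self) -> DHGLMParams:
        return DHGLMParams(
            beta=self.beta.copy(), gamma=self.gamma.copy(),
            a=self.a.copy(), b=self.b.copy(),
            u=self.u.copy(), v=self.v.copy(),
            sd_id=self.sd_id.copy(), corr_id=self.corr_id.copy(),
            sd_year=self.sd_year.copy(), corr_year=self.corr_year.copy(),
        )


_TRIU = [(j, l) for j in range(6) for l in range(j + 1, 6)]


def reported_parameter_names() -> list[str]:
    names = []
    for k, beh in enumerate(BEHAVIOURS):
        for j, col in enumerate(DESIGN_COLUMNS):
            names.append(f"beta[{beh},{col}]")
    for k, beh in enumerate(BEHAVIOURS):
        for j, col in enumerate(DESIGN_COLUMNS):
            names.append(f"gamma[{beh},{col}]")
    names += [f"sd_id[{r}]" for r in RE_NAMES]
    names += [f"sd_year[{r}]" for r in RE_NAMES]
    names += [f"corr_id[{RE_NAMES[j]},{RE_NAMES[l]}]" for j, l in _TRIU]
    names += [f"corr_year[{RE_NAMES[j]},{RE_NAMES[l]}]" for j, l in _TRIU]
    return names


def _reported_matrix(arrays: dict[str, np.ndarray]) -> tuple[list[str], np.ndarray]:
    """Stack reported scalar parameters as (chain, draw, n_param)."""
    cols = []
    beta, gamma = arrays["beta"], arrays["gamma"]
    for k in range(3):
        for j in range(beta.shape[-1]):
            cols.append(beta[:, :, k, j])
    for k in range(3):
        for j in range(gamma.shape[-1]):
            cols.append(gamma[:, :, k, j])
    for j in range(6):
        cols.append(arrays["sd_id"][:, :, j])
    for j in range(6):
        cols.append(arrays["sd_year"][:, :, j])
    for j, l in _TRIU:
        cols.append(arrays["corr_id"][:, :, j, l])
    for j, l in _TRIU:
        cols.append(arrays["corr_year"][:, :, j, l])
    return reported_parameter_names(), np.stack(cols, axis=-1)


def fit_dhglm(
    data: ModelData,
    priors: PriorSpec | None = None,
    sampler: SamplerConfig | None = None,
    seed: int = 0,
) -> PosteriorDraws:
    """Sample the DHGLM posterior.

    Runs ``sampler.chains`` independent chains; retains every ``thin``-th
    iteration after ``warmup``. Split-R-hat and bulk ESS are computed (via
    arviz) for all fixed effects, SDs and correlations; if any reported
    parameter misses the convergence contract (R-hat < 1.01, ESS > 1000 by
    default) a warning is raised and the result is returned with
    ``converged=False`` — the caller decides.
    """
    import arviz as az
    import pandas as pd

    priors = priors or PriorSpec()
    cfg = sampler or SamplerConfig()
    seeds = np.random.SeedSequence(seed).spawn(cfg.chains)

    n_keep = cfg.n_keep_per_chain
    p = data.X.shape[1]
    shapes = {
        "beta": (3, p), "gamma": (3, p),
        "a": (data.n_individuals, 3), "b": (data.n_individuals, 3),
        "u": (data.n_years, 3), "v": (data.n_years, 3),
        "sd_id": (6,), "corr_id": (6, 6),
        "sd_year": (6,), "corr_year": (6, 6),
    }
    arrays = {
        name: np.empty((cfg.chains, n_keep) + shp) for name, shp in shapes.items()
    }

    for c in range(cfg.chains):
        rng = np.random.default_rng(seeds[c])
        state = _ChainState(data, priors, rng)
        state.b_mh_steps = cfg.b_mh_steps
        kept = 0
        for it in range(cfg.iterations):
            state.sweep(adapt=it < cfg.warmup)
            if it >= cfg.warmup and (it - cfg.warmup) % cfg.thin == 0:
                par = state.params()
                for name in shapes:
                    arrays[name][c, kept] = getattr(par, name)
                kept += 1

    names, mat = _reported_matrix(arrays)
    # degenerate columns (e.g. a month level absent from the data) carry no
    # information; diagnostics are computed where the draws actually vary
    rhat = np.full(len(names), np.nan)
    ess = np.full(len(names), np.nan)
    varying = mat.std(axis=(0, 1)) > 1e-12
    idata = az.convert_to_dataset(mat[:, :, varying])
    import logging as _logging

    az_logger = _logging.getLogger("arviz")
    old_level = az_logger.level
    az_logger.setLevel(_logging.ERROR)  # single-chain shape notices are expected
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rhat[varying] = az.rhat(idata)["x"].to_numpy()
            ess[varying] = az.ess(idata)["x"].to_numpy()
    finally:
        az_logger.setLevel(old_level)
    diagnostics = pd.DataFrame({"parameter": names, "rhat": rhat, "ess": ess})

    ok = bool(
        np.all(rhat[varying] < cfg.rhat_threshold)
        and np.all(ess[varying] > cfg.ess_threshold)
    )
    if not ok:
        worst = np.nanmax(rhat) if np.isfinite(rhat).any() else np.nan
        low = np.nanmin(ess) if np.isfinite(ess).any() else np.nan
        warnings.warn(
            f"sampler convergence contract not met (max R-hat {worst:.3f}, "
            f"min ESS {low:.0f}); inspect diagnostics",
            RuntimeWarning,
            stacklevel=2,
        )

    return PosteriorDraws(
        arrays=arrays,
        coords={"individual": data.ind_ids, "year": data.year_labels},
        diagnostics=diagnostics,
        converged=ok,
        config=cfg,
        data=data,
    )
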