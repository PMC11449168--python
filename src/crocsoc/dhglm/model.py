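"""The trivariate double-hierarchical Gaussian model.

Three behavioural responses (sociability, activity, site fidelity on a
transformed, standardized scale) are modelled jointly. Each response k has

* a mean submodel:
  ``mu = X beta_k + a_ik + u_{y,k}``
* a dispersion submodel on the log residual SD:
  ``log sigma = X gamma_k + b_ik + v_{y,k}``

with one shared design X (intercept, month factor with January reference,
standardized total length, standardized log monthly detections). The six
individual-level random intercepts (three mean, three dispersion) are
jointly multivariate normal with an unstructured 6x6 covariance
``Sigma_ID`` parameterized as SDs plus a full correlation matrix; year
intercepts likewise under ``Sigma_year``. Cells are observed y ~
Normal(mu, sigma); missing cells contribute nothing (one joint model with
per-cell masks rather than per-behaviour subset fits).

Priors (all configurable): Normal(0, 5) on fixed effects, half-Normal(0, 1)
on all SDs, LKJ(eta=1) — uniform — on correlation matrices. The log
posterior is reported up to the additive constant of the LKJ normalization.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

BEHAVIOURS = ("sociability", "activity", "site_fidelity")
MONTH_LEVELS = (
    "February", "March", "April", "May", "June", "July",
    "August", "September", "October", "November", "December",
)
DESIGN_COLUMNS = ("intercept",) + MONTH_LEVELS + ("total_length", "detections")

RE_NAMES = tuple(f"a_{b}" for b in BEHAVIOURS) + tuple(f"b_{b}" for b in BEHAVIOURS)

_LOG_2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class ResponseTransform:
    """Mapping between raw and model scale for one response.

    model = (raw ** (1/power) - mean) / sd ;  raw = (model * sd + mean) ** power
    """

    mean: float = 0.0
    sd: float = 1.0
    power: int = 1

    def to_model(self, raw: np.ndarray) -> np.ndarray:
        root = np.sign(raw) * np.abs(raw) ** (1.0 / self.power) if self.power != 1 else raw
        return (root - self.mean) / self.sd

    def to_raw(self, model: np.ndarray) -> np.ndarray:
        z = model * self.sd + self.mean
        return z**self.power if self.power != 1 else z


@dataclass
class ModelData:
    """Model-ready arrays plus the bookkeeping to map back to raw units."""

    y: np.ndarray          # (n_rows, 3), NaN for missing cells
    X: np.ndarray          # (n_rows, p) shared design
    ind_idx: np.ndarray    # (n_rows,) individual codes
    year_idx: np.ndarray   # (n_rows,) year codes
    ind_ids: list[str]
    year_labels: list
    transforms: dict[str, ResponseTransform]
    covariate_scales: dict[str, tuple[float, float]] = field(default_factory=dict)

    @property
    def n_rows(self) -> int:
        return self.y.shape[0]

    @property
    def n_individuals(self) -> int:
        return len(self.ind_ids)

    @property
    def n_years(self) -> int:
        return len(self.year_labels)

    @property
    def mask(self) -> np.ndarray:
        return ~np.isnan(self.y)

    def validate(self) -> None:
        if not self.mask.any(axis=1).all():
            raise ValueError("every retained row must have >= 1 observed response")


def _standardize(x: np.ndarray) -> tuple[np.ndarray, float, float]:
    m = float(np.nanmean(x))
    s = float(np.nanstd(x, ddof=0))
    return (x - m) / s, m, s


def prepare_model_data(
    panel: pd.DataFrame,
    individuals: Optional[pd.DataFrame] = None,
    min_months: int = 2,
    transform: bool = True,
) -> ModelData:
    """Turn a monthly behaviour panel into model-ready arrays.

    With ``transform=True`` (raw metric panels) sociability and activity are
    cube-root transformed, all three responses standardized to mean 0 / SD 1
    over their available values, total length standardized, and monthly
    detection counts log-then-standardized; the transform parameters are
    stored for back-transformation of realized phenotypes. With
    ``transform=False`` the panel is taken to be on the model scale already
    (columns ``tl_z`` and ``det_z`` present) and passes through unchanged
    with identity transforms.

    Rows with all three responses missing are dropped; individuals observed
    in fewer than ``min_months`` retained rows are dropped.
    """
    panel = panel.copy()
    powers = {"sociability": 3, "activity": 3, "site_fidelity": 1}

    if transform:
        if individuals is not None:
            panel = panel.merge(
                individuals[["individual_id", "total_length_m"]],
                on="individual_id", how="left",
            )
        tl_raw = panel["total_length_m"].to_numpy(dtype=float)
        det_raw = np.log(panel["n_detections"].to_numpy(dtype=float))
        tl_z, tl_m, tl_s = _standardize(tl_raw)
        det_z, det_m, det_s = _standardize(det_raw)
        panel["tl_z"], panel["det_z"] = tl_z, det_z
        cov_scales = {"total_length": (tl_m, tl_s), "log_detections": (det_m, det_s)}
        transforms = {}
        for beh in BEHAVIOURS:
            raw = panel[beh].to_numpy(dtype=float)
            p = powers[beh]
            root = np.abs(raw) ** (1.0 / p) * np.sign(raw) if p != 1 else raw
            sd = float(np.nanstd(root, ddof=0))
            if not sd > 0:
                raise ValueError(f"response {beh!r} has zero variance")
            mean = float(np.nanmean(root))
            panel[beh] = (root - mean) / sd
            transforms[beh] = ResponseTransform(mean=mean, sd=sd, power=p)
    else:
        transforms = {beh: ResponseTransform() for beh in BEHAVIOURS}
        cov_scales = {}
        for beh in BEHAVIOURS:
            vals = panel[beh].to_numpy(dtype=float)
            if np.isnan(vals).all():
                continue  # an entirely-missing response contributes no cells
            if not np.nanstd(vals) > 0:
                raise ValueError(f"response {beh!r} has zero variance")

    y = panel[list(BEHAVIOURS)].to_numpy(dtype=float)
    keep = ~np.isnan(y).all(axis=1)
    panel, y = panel[keep], y[keep]

    months_per_ind = panel.groupby("individual_id")["month"].size()
    keep_ids = set(months_per_ind[months_per_ind >= min_months].index)
    keep = panel["individual_id"].isin(keep_ids).to_numpy()
    panel, y = panel[keep], y[keep]
    if panel.empty:
        raise ValueError("no rows survive the minimum-months filter")

    month = panel["month"].to_numpy(dtype=int)
    X = np.zeros((len(panel), len(DESIGN_COLUMNS)))
    X[:, 0] = 1.0
    for j, _name in enumerate(MONTH_LEVELS, start=1):
        X[:, j] = (month == j + 1).astype(float)  # February is month 2
    X[:, -2] = panel["tl_z"].to_numpy(dtype=float)
    X[:, -1] = panel["det_z"].to_numpy(dtype=float)

    ind_cat = pd.Categorical(panel["individual_id"])
    year_cat = pd.Categorical(panel["year"])
    data = ModelData(
        y=np.ascontiguousarray(y),
        X=X,
        ind_idx=ind_cat.codes.astype(np.int64),
        year_idx=year_cat.codes.astype(np.int64),
        ind_ids=[str(c) for c in ind_cat.categories],
        year_labels=list(year_cat.categories),
        transforms=transforms,
        covariate_scales=cov_scales,
    )
    data.validate()
    return data


@dataclass
class PriorSpec:
    """Prior hyperparameters; defaults are weakly informative."""

    beta_sd: float = 5.0
    gamma_sd: float = 5.0
    sd_scale: float = 1.0
    lkj_eta: float = 1.0


@dataclass
class DHGLMParams:
    """One full parameter configuration of the model."""

    beta: np.ndarray       # (3, p) mean fixed effects
    gamma: np.ndarray      # (3, p) dispersion fixed effects
    a: np.ndarray          # (n_ind, 3) individual mean intercepts
    b: np.ndarray          # (n_ind, 3) individual dispersion intercepts
    u: np.ndarray          # (n_year, 3)
    v: np.ndarray          # (n_year, 3)
    sd_id: np.ndarray      # (6,)
    corr_id: np.ndarray    # (6, 6)
    sd_year: np.ndarray    # (6,)
    corr_year: np.ndarray  # (6, 6)

    @classmethod
    def zeros(cls, n_ind: int, n_year: int, p: int = len(DESIGN_COLUMNS)) -> "DHGLMParams":
        return cls(
            beta=np.zeros((3, p)), gamma=np.zeros((3, p)),
            a=np.zeros((n_ind, 3)), b=np.zeros((n_ind, 3)),
            u=np.zeros((n_year, 3)), v=np.zeros((n_year, 3)),
            sd_id=np.full(6, 0.3), corr_id=np.eye(6),
            sd_year=np.full(6, 0.2), corr_year=np.eye(6),
        )


def _mvn_logpdf_rows(x: np.ndarray, sd: np.ndarray, corr: np.ndarray) -> float:
    """Sum of MVN(0, diag(sd) corr diag(sd)) log densities over rows of x.

    Returns -inf (rather than raising) for a non-PSD correlation proposal.
    """
    if np.any(sd <= 0):
        return -np.inf
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        return -np.inf
    w = np.linalg.solve(L, (x / sd).T)  # (6, n)
    quad = float(np.sum(w * w))
    logdet = 2.0 * float(np.sum(np.log(np.diag(L)))) + 2.0 * float(np.sum(np.log(sd)))
    n, k = x.shape
    return -0.5 * (quad + n * (k * _LOG_2PI + logdet))


def _halfnormal_logpdf(x: np.ndarray, scale: float) -> float:
    x = np.asarray(x, dtype=float)
    if np.any(x < 0):
        return -np.inf
    return float(
        np.sum(0.5 * np.log(2.0 / np.pi) - np.log(scale) - 0.5 * (x / scale) ** 2)
    )


def _lkj_logpdf(corr: np.ndarray, eta: float) -> float:
    """LKJ density up to its normalization constant; -inf if not PSD."""
    try:
        L = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError:
        return -np.inf
    if eta == 1.0:
        return 0.0
    return float((eta - 1.0) * 2.0 * np.sum(np.log(np.diag(L))))


def dhglm_log_density(
    params: DHGLMParams, data: ModelData, priors: PriorSpec | None = None
) -> float:
    """Joint log posterior density (up to the LKJ normalizing constant).

    Sums, over observed cells only, the Normal log likelihood with
    cell-specific mean and SD; adds the multivariate-normal log densities of
    the individual and year random-effect rows and the prior terms. A
    non-PSD correlation matrix yields -inf rather than an exception.
    """
    priors = priors or PriorSpec()
    mask = data.mask

    mu = data.X @ params.beta.T + params.a[data.ind_idx] + params.u[data.year_idx]
    log_sigma = (
        data.X @ params.gamma.T + params.b[data.ind_idx] + params.v[data.year_idx]
    )
    resid = data.y - mu
    cell_ll = -0.5 * _LOG_2PI - log_sigma - 0.5 * (resid * np.exp(-log_sigma)) ** 2
    ll = float(np.sum(cell_ll[mask]))

    eta = np.concatenate([params.a, params.b], axis=1)
    zeta = np.concatenate([params.u, params.v], axis=1)
    lp_re = _mvn_logpdf_rows(eta, params.sd_id, params.corr_id)
    lp_re += _mvn_logpdf_rows(zeta, params.sd_year, params.corr_year)
    if not np.isfinite(lp_re):
        return -np.inf

    def _normal_prior(x: np.ndarray, sd: float) -> float:
        return float(np.sum(-0.5 * _LOG_2PI - np.log(sd) - 0.5 * (x / sd) ** 2))

    lp = _normal_prior(params.beta, priors.beta_sd)
    lp += _normal_prior(params.gamma, priors.gamma_sd)
    lp += _halfnormal_logpdf(params.sd_id, priors.sd_scale)
    lp += _halfnormal_logpdf(params.sd_year, priors.sd_scale)
    lp += _lkj_logpdf(params.corr_id, priors.lkj_eta)
    lp += _lkj_logpdf(params.corr_year, priors.lkj_eta)
    if not np.isfinite(lp):
        return -np.inf
    return ll + lp_re + lp
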