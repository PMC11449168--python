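"""Model data preparation, the joint log density, fitting and summaries."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crocsoc.dhglm import (
    DHGLMParams,
    PriorSpec,
    SamplerConfig,
    dhglm_log_density,
    fit_dhglm,
    prepare_model_data,
    summarize_fit,
)
from crocsoc.dhglm.model import DESIGN_COLUMNS, ResponseTransform
from crocsoc.dhglm.summary import hpd_interval
from crocsoc.synthetic_data import SyntheticTruth, simulate_behaviour_panel


def _raw_panel(n_ind=6, n_months=8, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n_ind):
        for t in range(n_months):
            rows.append(
                {
                    "individual_id": f"C{i}",
                    "year": 2019 + t // 12,
                    "month": t % 12 + 1,
                    "sociability": rng.uniform(0.01, 0.5),
                    "activity": rng.uniform(0.5, 8.0),
                    "site_fidelity": rng.uniform(0.1, 0.9),
                    "n_detections": int(rng.integers(10, 500)),
                    "total_length_m": 1.0 + 0.5 * i,
                }
            )
    return pd.DataFrame(rows)


class TestPrepareModelData:
    def test_cube_root_before_standardization(self):
        panel = _raw_panel()
        panel.loc[0, "sociability"] = 0.064
        data = prepare_model_data(panel, min_months=1)
        tr = data.transforms["sociability"]
        # 0.064 ** (1/3) = 0.4 on the pre-standardization scale
        assert data.y[0, 0] * tr.sd + tr.mean == pytest.approx(0.4)
        assert tr.power == 3

    def test_standardization_round_trip(self):
        panel = _raw_panel()
        data = prepare_model_data(panel, min_months=1)
        for beh_idx, beh in enumerate(
            ("sociability", "activity", "site_fidelity")
        ):
            tr = data.transforms[beh]
            raw = panel[beh].to_numpy()
            np.testing.assert_allclose(tr.to_raw(tr.to_model(raw)), raw)
            np.testing.assert_allclose(tr.to_model(raw), data.y[:, beh_idx])

    def test_responses_standardized_and_design_shape(self):
        data = prepare_model_data(_raw_panel(), min_months=1)
        assert np.allclose(np.nanmean(data.y, axis=0), 0.0, atol=1e-9)
        assert np.allclose(np.nanstd(data.y, axis=0), 1.0, atol=1e-9)
        assert data.X.shape[1] == len(DESIGN_COLUMNS)
        assert set(np.unique(data.X[:, 0])) == {1.0}

    def test_synthetic_panel_passes_through_unchanged(self, small_panel):
        panel, _, _ = small_panel
        data = prepare_model_data(panel, transform=False)
        obs = ~panel["site_fidelity"].isna()
        kept = panel[panel.groupby("individual_id")["month"].transform("size") >= 2]
        np.testing.assert_array_equal(
            data.y[:, 0], kept["sociability"].to_numpy()
        )
        assert data.transforms["activity"] == ResponseTransform()

    def test_zero_variance_response_named(self):
        panel = _raw_panel()
        panel["activity"] = 2.0
        with pytest.raises(ValueError, match="activity"):
            prepare_model_data(panel, min_months=1)

    def test_min_months_filter_drops_sparse_individuals(self):
        panel = _raw_panel(n_ind=4, n_months=6)
        panel = panel[~((panel["individual_id"] == "C0") & (panel["month"] > 1))]
        data = prepare_model_data(panel, min_months=2)
        assert "C0" not in data.ind_ids
        assert len(data.ind_ids) == 3


def brute_force_log_density(params, data, priors):
    """Independent evaluation: explicit loops, scipy distributions and a
    naive MVN via determinant/solve."""
    total = 0.0
    n, _ = data.y.shape
    for r in range(n):
        for k in range(3):
            if np.isnan(data.y[r, k]):
                continue
            mu = (
                float(data.X[r] @ params.beta[k])
                + params.a[data.ind_idx[r], k]
                + params.u[data.year_idx[r], k]
            )
            log_sig = (
                float(data.X[r] @ params.gamma[k])
                + params.b[data.ind_idx[r], k]
                + params.v[data.year_idx[r], k]
            )
            total += stats.norm.logpdf(data.y[r, k], mu, np.exp(log_sig))

    def mvn_block(rows, sd, corr):
        cov = np.diag(sd) @ corr @ np.diag(sd)
        out = 0.0
        for row in rows:
            out += stats.multivariate_normal.logpdf(row, mean=np.zeros(6), cov=cov)
        return out

    total += mvn_block(np.hstack([params.a, params.b]), params.sd_id, params.corr_id)
    total += mvn_block(np.hstack([params.u, params.v]), params.sd_year, params.corr_year)
    for block, sd in ((params.beta, priors.beta_sd), (params.gamma, priors.gamma_sd)):
        total += stats.norm.logpdf(block.ravel(), 0, sd).sum()
    total += stats.halfnorm.logpdf(params.sd_id, scale=priors.sd_scale).sum()
    total += stats.halfnorm.logpdf(params.sd_year, scale=priors.sd_scale).sum()
    for corr in (params.corr_id, params.corr_year):
        total += (priors.lkj_eta - 1.0) * np.linalg.slogdet(corr)[1]
    return total


def _random_params(data, seed, corr_scale=0.3):
    rng = np.random.default_rng(seed)
    p = data.X.shape[1]

    def rand_corr():
        A = rng.normal(0, corr_scale, (6, 6))
        S = A @ A.T + np.eye(6)
        d = 1 / np.sqrt(np.diag(S))
        return d[:, None] * S * d[None, :]

    return DHGLMParams(
        beta=rng.normal(0, 0.5, (3, p)), gamma=rng.normal(0, 0.3, (3, p)),
        a=rng.normal(0, 0.3, (data.n_individuals, 3)),
        b=rng.normal(0, 0.3, (data.n_individuals, 3)),
        u=rng.normal(0, 0.2, (data.n_years, 3)),
        v=rng.normal(0, 0.2, (data.n_years, 3)),
        sd_id=rng.uniform(0.1, 0.8, 6), corr_id=rand_corr(),
        sd_year=rng.uniform(0.05, 0.4, 6), corr_year=rand_corr(),
    )


class TestLogDensity:
    def test_matches_brute_force_on_five_individual_toy(self):
        truth = SyntheticTruth().with_(n_individuals=5, n_months=6)
        panel, _, _ = simulate_behaviour_panel(truth, seed=0)
        data = prepare_model_data(panel, transform=False)
        priors = PriorSpec()
        for seed in range(3):
            params = _random_params(data, seed)
            fast = dhglm_log_density(params, data, priors)
            slow = brute_force_log_density(params, data, priors)
            assert fast == pytest.approx(slow, rel=1e-8)

    def test_toy_closed_form_residuals(self):
        """REs zero, gamma zero: likelihood is standard-normal at residuals."""
        panel = pd.DataFrame(
            {
                "individual_id": ["C0", "C0", "C1"],
                "year": [2019] * 3,
                "month": [1, 1, 1],
                "tl_z": [0.0] * 3,
                "det_z": [0.0] * 3,
                "sociability": [0.5, -0.3, 1.2],
                "activity": [np.nan] * 3,
                "site_fidelity": [np.nan] * 3,
            }
        )
        data = prepare_model_data(panel, transform=False, min_months=1)
        params = DHGLMParams.zeros(data.n_individuals, data.n_years)
        params.sd_id[:] = 0.4
        params.sd_year[:] = 0.2
        priors = PriorSpec()
        expected_lik = stats.norm.logpdf([0.5, -0.3, 1.2]).sum()
        # the prior/RE terms for zeroed parameters, via the oracle
        zero_terms = brute_force_log_density(params, data, priors) - expected_lik
        assert dhglm_log_density(params, data, priors) == pytest.approx(
            expected_lik + zero_terms
        )

    def test_masking_one_cell_changes_by_its_normal_logpdf(self):
        truth = SyntheticTruth().with_(n_individuals=5, n_months=6)
        panel, _, _ = simulate_behaviour_panel(truth, seed=1)
        data = prepare_model_data(panel, transform=False)
        params = _random_params(data, 7)
        full = dhglm_log_density(params, data)
        r = int(np.flatnonzero(data.mask[:, 1])[0])
        mu = (
            data.X[r] @ params.beta[1]
            + params.a[data.ind_idx[r], 1]
            + params.u[data.year_idx[r], 1]
        )
        sg = np.exp(
            data.X[r] @ params.gamma[1]
            + params.b[data.ind_idx[r], 1]
            + params.v[data.year_idx[r], 1]
        )
        cell = stats.norm.logpdf(data.y[r, 1], mu, sg)
        data_masked = data
        y2 = data.y.copy()
        y2[r, 1] = np.nan
        import dataclasses

        data_masked = dataclasses.replace(data, y=y2)
        assert dhglm_log_density(params, data_masked) == pytest.approx(
            full - cell, rel=1e-10
        )

    def test_non_psd_correlation_gives_neg_inf(self):
        truth = SyntheticTruth().with_(n_individuals=4, n_months=4)
        panel, _, _ = simulate_behaviour_panel(truth, seed=2)
        data = prepare_model_data(panel, transform=False)
        params = _random_params(data, 3)
        bad = np.eye(6)
        bad[0, 1] = bad[1, 0] = 0.95
        bad[1, 2] = bad[2, 1] = 0.95
        bad[0, 2] = bad[2, 0] = -0.95
        params.corr_id = bad
        assert dhglm_log_density(params, data) == -np.inf


class TestFit:
    def test_same_seed_identical_draws(self):
        truth = SyntheticTruth().with_(n_individuals=8, n_months=8)
        panel, _, _ = simulate_behaviour_panel(truth, seed=3)
        data = prepare_model_data(panel, transform=False)
        cfg = SamplerConfig(chains=1, iterations=60, warmup=30, thin=2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            d1 = fit_dhglm(data, sampler=cfg, seed=99)
            d2 = fit_dhglm(data, sampler=cfg, seed=99)
        for name in d1.arrays:
            np.testing.assert_array_equal(d1.arrays[name], d2.arrays[name])
        assert d1.n_draws == cfg.n_keep_per_chain

    def test_null_individual_variance_shrinks_sd_posterior(self):
        """A panel generated without individual effects concentrates the
        among-individual SD posterior near zero."""
        truth = SyntheticTruth().with_(
            n_individuals=100, n_months=36,
            sd_id=np.zeros(6), corr_id=np.eye(6),
            missingness=np.zeros(3),
        )
        panel, _, _ = simulate_behaviour_panel(truth, seed=4)
        data = prepare_model_data(panel, transform=False)
        cfg = SamplerConfig(chains=1, iterations=600, warmup=300, thin=1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            draws = fit_dhglm(data, sampler=cfg, seed=5)
        post_mean = draws.get("sd_id").mean(axis=0)
        assert np.all(post_mean[:3] < 0.15)

    def test_convergence_warning_on_short_run(self):
        truth = SyntheticTruth().with_(n_individuals=6, n_months=6)
        panel, _, _ = simulate_behaviour_panel(truth, seed=6)
        data = prepare_model_data(panel, transform=False)
        cfg = SamplerConfig(chains=2, iterations=40, warmup=20, thin=1)
        with pytest.warns(RuntimeWarning, match="convergence contract"):
            draws = fit_dhglm(data, sampler=cfg, seed=7)
        assert not draws.converged


class TestSummaries:
    def test_constant_draws_degenerate_hpd(self):
        lo, hi = hpd_interval(np.full(500, 3.25))
        assert (lo, hi) == (3.25, 3.25)

    def test_standard_normal_hpd_matches_quantiles(self, rng):
        draws = rng.standard_normal(100_000)
        lo, hi = hpd_interval(draws)
        assert lo == pytest.approx(-1.96, abs=0.05)
        assert hi == pytest.approx(1.96, abs=0.05)

    def test_hpd_shorter_than_equal_tailed_on_skewed_sample(self, rng):
        draws = rng.lognormal(0.0, 1.0, 50_000)
        lo, hi = hpd_interval(draws)
        eq_lo, eq_hi = np.quantile(draws, [0.025, 0.975])
        assert (hi - lo) < (eq_hi - eq_lo)

    def test_summarize_fit_table(self, small_fit):
        draws, _ = small_fit
        summary = summarize_fit(draws)
        assert {"parameter", "mean", "hpd_low", "hpd_high", "rhat", "ess"} <= set(
            summary.columns
        )
        assert (summary["hpd_low"] <= summary["hpd_high"]).all()
        some = summary.set_index("parameter")
        assert "beta[sociability,intercept]" in some.index
        assert "corr_id[a_sociability,b_sociability]" in some.index
        # individual levels included
        assert any(p.startswith("a[") for p in summary["parameter"])
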