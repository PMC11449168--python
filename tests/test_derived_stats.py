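"""Repeatability, predictability, realized phenotypes and correlations."""

import numpy as np
import pandas as pd
import pytest

from crocsoc import derived_stats as ds
from crocsoc.dhglm.model import ModelData, ResponseTransform
from crocsoc.dhglm.sampler import PosteriorDraws, SamplerConfig


def make_draws(
    n_draws=200,
    n_ind=3,
    n_year=2,
    transforms=None,
    seed=0,
    **overrides,
):
    """A hand-built PosteriorDraws with controllable arrays."""
    rng = np.random.default_rng(seed)
    p = 14
    arrays = {
        "beta": np.zeros((1, n_draws, 3, p)),
        "gamma": np.zeros((1, n_draws, 3, p)),
        "a": np.zeros((1, n_draws, n_ind, 3)),
        "b": np.zeros((1, n_draws, n_ind, 3)),
        "u": np.zeros((1, n_draws, n_year, 3)),
        "v": np.zeros((1, n_draws, n_year, 3)),
        "sd_id": np.full((1, n_draws, 6), 0.3),
        "corr_id": np.tile(np.eye(6), (1, n_draws, 1, 1)),
        "sd_year": np.full((1, n_draws, 6), 0.1),
        "corr_year": np.tile(np.eye(6), (1, n_draws, 1, 1)),
    }
    for name, value in overrides.items():
        arrays[name][...] = value
    transforms = transforms or {
        beh: ResponseTransform() for beh in ("sociability", "activity", "site_fidelity")
    }
    data = ModelData(
        y=np.zeros((n_ind, 3)), X=np.zeros((n_ind, p)),
        ind_idx=np.arange(n_ind), year_idx=np.zeros(n_ind, dtype=int),
        ind_ids=[f"C{i}" for i in range(n_ind)],
        year_labels=list(range(n_year)), transforms=transforms,
    )
    return PosteriorDraws(
        arrays=arrays, coords={"individual": data.ind_ids, "year": data.year_labels},
        diagnostics=pd.DataFrame(columns=["parameter", "rhat", "ess"]),
        converged=True, config=SamplerConfig(), data=data,
    )


class TestRepeatability:
    @pytest.mark.parametrize(
        "sd_id, sd_year, gamma0, expected",
        [
            (0.58, 0.11, -0.28, 0.37),  # daily activity
            (0.27, 0.04, -0.38, 0.13),  # sociability
        ],
    )
    def test_point_worked_examples(self, sd_id, sd_year, gamma0, expected):
        assert round(ds.repeatability_point(sd_id, sd_year, gamma0), 2) == expected

    def test_vanishing_residual_limit(self):
        assert ds.repeatability_point(0.5, 0.0, -40.0) == pytest.approx(1.0)

    def test_per_draw_posterior_bounded_and_consistent(self):
        draws = make_draws()
        draws.arrays["sd_id"][..., 1] = 0.58
        draws.arrays["sd_year"][..., 1] = 0.11
        draws.arrays["gamma"][..., 1, 0] = -0.28
        q = ds.repeatability(draws, "activity")
        assert q.mean == pytest.approx(
            ds.repeatability_point(0.58, 0.11, -0.28)
        )
        assert 0.0 <= q.hpd_low <= q.hpd_high <= 1.0

    def test_per_draw_vs_plug_in_both_valid(self, small_fit):
        draws, _ = small_fit
        for beh in ("sociability", "activity", "site_fidelity"):
            per_draw = ds.repeatability(draws, beh)
            k = ("sociability", "activity", "site_fidelity").index(beh)
            plug_in = ds.repeatability_point(
                draws.get("sd_id")[:, k].mean(),
                draws.get("sd_year")[:, k].mean(),
                draws.get("gamma")[:, k, 0].mean(),
            )
            assert 0.0 <= per_draw.mean <= 1.0
            assert 0.0 <= plug_in <= 1.0


class TestCVp:
    @pytest.mark.parametrize(
        "omega, expected", [(0.29, 0.30), (0.31, 0.32), (0.0, 0.0)]
    )
    def test_point_worked_examples(self, omega, expected):
        assert round(ds.cv_p_point(omega), 2) == expected

    def test_monotone_in_omega_per_draw(self, rng):
        omegas = np.sort(rng.uniform(0.0, 1.0, 50))
        cvs = np.array([ds.cv_p_point(w) for w in omegas])
        assert np.all(np.diff(cvs) >= 0)

    def test_posterior_uses_dispersion_sd(self):
        draws = make_draws()
        draws.arrays["sd_id"][..., 3] = 0.29  # omega for sociability
        q = ds.coefficient_of_predictability(draws, "sociability")
        assert q.mean == pytest.approx(ds.cv_p_point(0.29))


class TestRealized:
    def test_phenotype_hand_arithmetic(self):
        transforms = {
            "sociability": ResponseTransform(mean=0.42, sd=0.12, power=3),
            "activity": ResponseTransform(),
            "site_fidelity": ResponseTransform(),
        }
        draws = make_draws(transforms=transforms)
        draws.arrays["beta"][..., 0, 0] = -0.20
        out = ds.realized_phenotypes(draws, "sociability")
        assert out["realized_phenotype"].iloc[0] == pytest.approx(0.396**3)

    def test_identity_transform_is_sum(self):
        draws = make_draws()
        draws.arrays["beta"][..., 1, 0] = 0.5
        draws.arrays["a"][..., 0, 1] = 0.25
        out = ds.realized_phenotypes(draws, "activity")
        assert out["realized_phenotype"].iloc[0] == pytest.approx(0.75)

    def test_phenotype_ordering_follows_random_intercepts(self):
        transforms = {
            "sociability": ResponseTransform(mean=0.4, sd=0.1, power=3),
            "activity": ResponseTransform(),
            "site_fidelity": ResponseTransform(),
        }
        draws = make_draws(n_ind=5, transforms=transforms)
        a_vals = np.array([0.3, -0.5, 0.0, 0.9, -0.1])
        draws.arrays["a"][..., 0] = a_vals  # behaviour 0 = sociability
        out = ds.realized_phenotypes(draws, "sociability")
        assert list(np.argsort(out["realized_phenotype"])) == list(np.argsort(a_vals))

    def test_riiv_identity_baseline_and_doubling(self):
        draws = make_draws()
        out = ds.realized_riiv(draws, "activity")
        assert out["realized_riiv"].iloc[0] == pytest.approx(1.0)
        draws.arrays["b"][..., 0, 1] = np.log(2.0)
        out2 = ds.realized_riiv(draws, "activity")
        assert out2["realized_riiv"].iloc[0] == pytest.approx(2.0)
        assert not out2["approximate"].iloc[0]

    def test_riiv_flags_cube_root_responses_as_approximate(self):
        transforms = {
            "sociability": ResponseTransform(mean=0.4, sd=0.1, power=3),
            "activity": ResponseTransform(),
            "site_fidelity": ResponseTransform(),
        }
        draws = make_draws(transforms=transforms)
        out = ds.realized_riiv(draws, "sociability")
        assert out["approximate"].all()
        # scaled by the standardization SD
        assert out["realized_riiv"].iloc[0] == pytest.approx(0.1)


class TestCorrelations:
    def test_extraction_matches_injected_matrix(self):
        corr = np.eye(6)
        corr[0, 3] = corr[3, 0] = -0.56
        corr[0, 1] = corr[1, 0] = -0.33
        draws = make_draws(corr_id=corr)
        out = ds.random_effect_correlations(draws)
        soc = out[(out["kind"] == "mean_riiv") & (out["label"] == "sociability")]
        assert soc["mean"].iloc[0] == pytest.approx(-0.56)
        assert soc["significant"].iloc[0]
        syn = out[out["label"] == "sociability~activity"]
        assert syn["mean"].iloc[0] == pytest.approx(-0.33)

    def test_matrix_symmetric_unit_diagonal_per_draw(self, small_fit):
        draws, _ = small_fit
        corr = draws.get("corr_id")
        np.testing.assert_allclose(corr, np.swapaxes(corr, 1, 2), atol=1e-12)
        np.testing.assert_allclose(
            corr[:, np.arange(6), np.arange(6)], 1.0, atol=1e-12
        )


def simulate_counts(
    n_ind=40, n_months=10, slope_potential=0.3, slope_observed=-0.2, seed=0
):
    """Poisson counts with log-linear dependence on home-range size."""
    rng = np.random.default_rng(seed)
    hr = rng.lognormal(1.0, 0.5, (n_ind, n_months))
    hr_z = (hr - hr.mean()) / hr.std()
    re_i = rng.normal(0, 0.2, n_ind)
    rows = []
    for i in range(n_ind):
        for m in range(n_months):
            lam_p = np.exp(1.0 + slope_potential * hr_z[i, m] + re_i[i])
            lam_o = np.exp(0.3 + slope_observed * hr_z[i, m] + re_i[i])
            rows.append((f"C{i}", 2019, m + 1, hr[i, m], "potential",
                         rng.poisson(lam_p)))
            rows.append((f"C{i}", 2019, m + 1, hr[i, m], "observed",
                         rng.poisson(lam_o)))
    return pd.DataFrame(
        rows, columns=["individual_id", "year", "month", "hr_size", "type", "count"]
    )


class TestAssociatesGLMM:
    def test_interaction_recovery(self):
        counts = simulate_counts(slope_potential=0.3, slope_observed=-0.2, seed=1)
        res = ds.fit_associates_glmm(counts, iterations=1500, warmup=500, seed=0)
        q = res.coefficient("hr_size:type_observed")
        assert q.mean < 0
        assert q.significant  # HPD excludes zero

    def test_null_interaction_calibration(self):
        """Equal slopes for both types: the interaction HPD should include
        zero in nearly all replicates."""
        hits = 0
        n_rep = 12
        for rep in range(n_rep):
            counts = simulate_counts(
                n_ind=25, n_months=8, slope_potential=0.2, slope_observed=0.2,
                seed=100 + rep,
            )
            res = ds.fit_associates_glmm(counts, iterations=800, warmup=300, seed=rep)
            if not res.coefficient("hr_size:type_observed").significant:
                hits += 1
        assert hits >= int(0.9 * n_rep)

    def test_predicted_rates_positive(self):
        counts = simulate_counts(seed=2)
        res = ds.fit_associates_glmm(counts, iterations=600, warmup=200, seed=3)
        assert (res.predicted_rates(counts) > 0).all()

    def test_all_zero_counts_rejected(self):
        counts = simulate_counts(seed=3)
        counts["count"] = 0
        with pytest.raises(ValueError, match="zero"):
            ds.fit_associates_glmm(counts)
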