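"""NB GLM machinery versus closed forms and independent library oracles."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from seromir.nbglm import (
    ALPHA_FLOOR,
    DesignError,
    bh_adjust,
    build_design,
    differential_expression,
    estimate_dispersion,
    fit_nb_glm,
    lrt_test,
    nb_loglik,
)
from seromir.synthdata import SynthConfig, simulate_counts


def brute_force_bh(p):
    """Step-up definition evaluated literally."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [None] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return np.array(q)


class TestBuildDesign:
    def test_toy_sheet_matches_hand_written_matrix(self, toy_meta):
        d = build_design(toy_meta, "condition")
        expected = np.array(
            [
                [1, 1.0, 1, 0, 0],
                [1, 2.0, 0, 1, 0],
                [1, 0.8, 0, 0, 0],
                [1, 3.0, 1, 0, 1],
                [1, 1.5, 0, 1, 1],
                [1, 0.6, 0, 0, 1],
            ],
            dtype=float,
        )
        np.testing.assert_allclose(d.matrix, expected)
        assert list(d.frame.columns) == [
            "intercept", "absorbance", "family1", "family2", "condition",
        ]

    def test_constant_family_column_dropped_with_warning(self, toy_meta):
        meta = toy_meta.copy()
        meta["family1"] = 0
        with pytest.warns(UserWarning, match="family1"):
            d = build_design(meta, "condition")
        assert "family1" not in d.frame.columns
        assert "family1" in d.dropped

    def test_condition_confounded_with_family_rejected(self, toy_meta):
        meta = toy_meta.copy()
        meta["family1"] = [0, 0, 0, 1, 1, 1]  # identical to condition coding
        meta["family2"] = 0
        with pytest.raises(DesignError, match="confounded"):
            build_design(meta, "condition")

    def test_single_condition_rejected(self, toy_meta):
        meta = toy_meta.copy()
        meta["condition"] = "case"
        with pytest.raises(DesignError, match="control"):
            build_design(meta, "condition")

    def test_absorbance_cannot_be_tested_and_excluded(self, toy_meta):
        with pytest.raises(ValueError, match="exclude"):
            build_design(toy_meta, "absorbance", include_absorbance=False)

    def test_offset_is_log_size_factor(self, toy_meta):
        sf = pd.Series([1.0, 2.0, 4.0, 0.5, 1.5, 3.0], index=toy_meta.index)
        d = build_design(toy_meta, "condition", size_factors=sf)
        np.testing.assert_allclose(d.offset, np.log(sf.to_numpy()))


class TestFitNBGLM:
    def test_intercept_only_recovers_log_mean(self):
        y = np.full(12, 7.0)
        fit = fit_nb_glm(y, np.ones((12, 1)), alpha=0.0)
        assert fit.converged
        assert fit.beta[0] == pytest.approx(np.log(7.0), abs=1e-8)

    def test_two_group_poisson_closed_form(self, rng):
        m0, m1 = 9.0, 21.0
        y = np.concatenate([np.full(30, m0), np.full(30, m1)])
        X = np.column_stack([np.ones(60), np.repeat([0.0, 1.0], 30)])
        fit = fit_nb_glm(y, X, alpha=0.0)
        assert fit.beta[0] == pytest.approx(np.log(m0), abs=1e-7)
        assert fit.beta[1] == pytest.approx(np.log(m1 / m0), abs=1e-7)

    @pytest.mark.parametrize("seed", range(10))
    def test_poisson_case_matches_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        n, p = 40, 3
        X = np.column_stack([np.ones(n), rng.normal(size=(n, p - 1))])
        beta = rng.normal(0, 0.4, p) + [2.0, 0, 0]
        y = rng.poisson(np.exp(X @ beta))
        ours = fit_nb_glm(y, X, alpha=0.0)
        ref = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-6)
        assert ours.loglik == pytest.approx(ref.llf, abs=1e-6)

    def test_nb_case_matches_statsmodels(self, rng):
        n = 80
        X = np.column_stack([np.ones(n), rng.normal(size=n)])
        mu = np.exp(2.5 + 0.4 * X[:, 1])
        alpha = 0.3
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
        ours = fit_nb_glm(y, X, alpha=alpha)
        ref = sm.GLM(
            y, X, family=sm.families.NegativeBinomial(alpha=alpha)
        ).fit()
        np.testing.assert_allclose(ours.beta, ref.params, atol=1e-5)

    def test_offset_shifts_intercept(self):
        y = np.full(10, 8.0)
        off = np.full(10, np.log(2.0))
        fit = fit_nb_glm(y, np.ones((10, 1)), alpha=0.0, offset=off)
        assert fit.beta[0] == pytest.approx(np.log(4.0), abs=1e-8)

    def test_coefficient_recovery_at_large_n(self):
        rng = np.random.default_rng(0)
        n, alpha = 2000, 0.1
        X = np.column_stack([np.ones(n), rng.normal(size=n), rng.binomial(1, 0.5, n)])
        beta = np.array([3.0, 0.25, -0.4])
        mu = np.exp(X @ beta)
        y = rng.poisson(rng.gamma(1 / alpha, alpha * mu))
        fit = fit_nb_glm(y, X, alpha=alpha)
        W = (mu / (1 + alpha * mu))[:, None]
        cov = np.linalg.inv(X.T @ (W * X))
        se = np.sqrt(np.diag(cov))
        assert np.all(np.abs(fit.beta - beta) < 3 * se)

    def test_all_zero_response_flagged_not_raised(self):
        fit = fit_nb_glm(np.zeros(8), np.ones((8, 1)), alpha=0.1)
        assert "all_zero" in fit.flags
        assert not fit.converged


class TestEstimateDispersion:
    def test_poisson_data_hits_the_floor(self, rng):
        y = rng.poisson(50.0, size=500)
        a = estimate_dispersion(y, np.ones((500, 1)))
        assert a < 1e-3

    def test_nb_dispersion_recovered(self):
        rng = np.random.default_rng(3)
        alpha = 0.2
        y = rng.poisson(rng.gamma(1 / alpha, alpha * 100.0, size=2000))
        a = estimate_dispersion(y, np.ones((2000, 1)))
        assert 0.15 <= a <= 0.25

    def test_no_residual_dof_rejected(self):
        with pytest.raises(ValueError, match="degree"):
            estimate_dispersion(np.array([1.0, 2.0]), np.eye(2))

    def test_clamped_to_bracket(self, rng):
        y = np.array([1.0, 1.0, 1.0, 1.0, 1.0])
        a = estimate_dispersion(y, np.ones((5, 1)))
        assert ALPHA_FLOOR <= a <= 10.0


class TestLRT:
    def test_equal_likelihoods_give_unit_p(self):
        assert lrt_test(-10.0, -10.0) == 1.0

    def test_chi2_reference_values(self):
        assert lrt_test(-8.0, -8.0 - 3.8415 / 2) == pytest.approx(0.0500, abs=2e-4)
        assert lrt_test(0.0, -5.0) == pytest.approx(0.00157, abs=2e-5)

    def test_negative_statistic_clipped(self):
        assert lrt_test(-10.0, -9.999) == 1.0


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_textbook_examples(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )
        np.testing.assert_allclose(bh_adjust(np.array([0.005, 0.5])), [0.01, 0.5])

    def test_matches_brute_force_and_statsmodels(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(1, 40))
            ours = bh_adjust(p)
            np.testing.assert_allclose(ours, brute_force_bh(p), atol=1e-12)
            np.testing.assert_allclose(
                ours, multipletests(p, method="fdr_bh")[1], atol=1e-12
            )

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError, match="0, 1"):
            bh_adjust(np.array([0.5, 1.2]))

    @settings(deadline=None, max_examples=100)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=50)
    )
    def test_adjusted_never_below_raw_and_order_preserved(self, p):
        p = np.array(p)
        q = bh_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)


@pytest.fixture(scope="module")
def planted():
    cfg = SynthConfig(
        seed=21,
        n_features=120,
        phase_fractions=(0.0, 0.9, 0.1),
        de_fraction=0.1,
        de_log2fc_range=(0.47, 0.47),
        hemo_fraction=0.2,
        latent_factor_sd=0.0,
    )
    return simulate_counts(cfg)


class TestDifferentialExpression:
    def test_planted_condition_effects_recovered(self, planted):
        counts, meta, truth = planted
        tab = differential_expression(counts, meta, "condition")
        for fid, lfc in truth.true_de.items():
            assert np.sign(tab.loc[fid, "log2fc"]) == np.sign(lfc)
            assert abs(tab.loc[fid, "log2fc"] - lfc) < 0.35

    def test_hemolysis_screen_targets_planted_features(self):
        cfg = SynthConfig(
            seed=8,
            n_features=100,
            phase_fractions=(0.0, 0.9, 0.1),
            de_fraction=0.0,
            hemo_fraction=0.15,
            hemo_beta_range=(0.8, 1.2),
            family_shift_sd=0.0,
            latent_factor_sd=0.0,
        )
        counts, meta, truth = simulate_counts(cfg)
        tab = differential_expression(counts, meta, "absorbance")
        # at FDR 0.05 an occasional null feature slips in by design; the
        # confidently-called set must consist of planted features only
        strong = set(tab[tab["p_adj"] < 1e-4].index)
        assert strong  # strong effects must be detectable
        assert strong <= set(truth.true_hemo)
        hits = set(tab[tab["significant"]].index) & set(truth.true_hemo)
        assert len(hits) >= 0.8 * len(truth.true_hemo)

    def test_p_adj_at_least_p_raw(self, planted):
        counts, meta, _ = planted
        tab = differential_expression(counts, meta, "condition")
        assert (tab["p_adj"] >= tab["p_raw"] - 1e-12).all()
        assert tab["p_raw"].between(0, 1).all()

    def test_invariant_to_condition_recoding(self, planted):
        counts, meta, _ = planted
        flipped = meta.copy()
        flipped["condition"] = np.where(
            meta["condition"] == "case", "control", "case"
        )
        t1 = differential_expression(counts, meta, "condition")
        t2 = differential_expression(counts, flipped, "condition")
        np.testing.assert_allclose(t1["p_raw"], t2["p_raw"], atol=1e-6)
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"], atol=1e-5)

    def test_all_zero_feature_reported_with_unit_p(self, planted):
        counts, meta, _ = planted
        counts = counts.copy()
        counts.iloc[0] = 0
        tab = differential_expression(counts, meta, "condition")
        row = tab.iloc[0]
        assert row["p_raw"] == 1.0
        assert row["log2fc"] == 0.0
        assert "all_zero" in row["fit_flags"]


def test_nb_loglik_matches_scipy_pmf(rng):
    from scipy.stats import nbinom, poisson

    y = rng.integers(0, 30, 20).astype(float)
    mu = rng.uniform(1, 20, 20)
    alpha = 0.4
    r = 1 / alpha
    ref = nbinom.logpmf(y, r, r / (r + mu)).sum()
    assert nb_loglik(y, mu, alpha) == pytest.approx(ref, abs=1e-9)
    assert nb_loglik(y, mu, 0.0) == pytest.approx(
        poisson.logpmf(y, mu).sum(), abs=1e-9
    )
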