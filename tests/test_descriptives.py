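import numpy as np
import pytest

import emascale as e
from emascale.descriptives import (
    corr_structure_similarity,
    count_modes,
    group_corr_summary,
    initial_elevation,
    mean_abs_corr,
    missing_proportion,
    wp_ar1,
    wp_corr_matrix,
    wp_moments,
    wp_rmssd,
)
import oracles as bf


class TestMoments:
    def test_constant_series(self):
        out = wp_moments([0.5] * 30)
        assert out["mean"] == 0.5 and out["sd"] == 0.0 and np.isnan(out["skew"])

    def test_small_example(self):
        assert wp_moments([0.0, 0.0, 1.0])["mean"] == pytest.approx(1 / 3)

    def test_empty_series_undefined(self):
        out = wp_moments([np.nan] * 5)
        assert out["n"] == 0 and np.isnan(out["mean"])

    def test_matches_brute_force(self, rng):
        vals = rng.random(200)
        out = wp_moments(vals)
        assert out["mean"] == pytest.approx(bf.bf_mean(vals), abs=1e-12)
        assert out["sd"] == pytest.approx(bf.bf_sd(vals), abs=1e-12)
        assert out["skew"] == pytest.approx(bf.bf_skew(vals), abs=1e-12)


class TestLagged:
    def test_constant_series_rmssd_zero(self):
        assert wp_rmssd([0.3] * 10)["rmssd"] == 0.0

    def test_alternating_series(self):
        s = [0.0, 1.0] * 20
        assert wp_rmssd(s)["rmssd"] == pytest.approx(1.0)
        assert wp_ar1(s)["ar1"] == pytest.approx(-1.0)

    def test_missing_breaks_pairs(self):
        out = wp_rmssd([0.2, np.nan, 0.4, 0.6])
        assert out["n_pairs"] == 1
        assert out["rmssd"] == pytest.approx(0.2)

    def test_constant_ar1_undefined(self):
        assert np.isnan(wp_ar1([0.3] * 10)["ar1"])

    def test_ar1_consistency_on_simulated_ar_process(self, rng):
        phi = 0.5
        x = np.empty(5000)
        x[0] = rng.normal(0, 1 / np.sqrt(1 - phi**2))
        for t in range(1, 5000):
            x[t] = phi * x[t - 1] + rng.normal()
        assert wp_ar1(x)["ar1"] == pytest.approx(phi, abs=0.05)

    def test_rmssd_squared_limit(self, rng):
        # for AR(1): E[(x_{t+1}-x_t)^2] = 2 * var * (1 - phi)
        phi = 0.4
        x = np.empty(20000)
        x[0] = rng.normal(0, 1 / np.sqrt(1 - phi**2))
        for t in range(1, 20000):
            x[t] = phi * x[t - 1] + rng.normal()
        expected = 2 * (1 / (1 - phi**2)) * (1 - phi)
        assert wp_rmssd(x)["rmssd"] ** 2 == pytest.approx(expected, rel=0.05)

    def test_lag_stats_invariant_to_pairless_missing(self, rng):
        # dropping a slot whose two neighbours are already missing removes
        # no valid pair, so rmssd and ar1 are unchanged
        s = rng.random(84)
        s[10] = s[12] = np.nan
        s2 = s.copy()
        s2[11] = np.nan
        assert wp_rmssd(s2)["rmssd"] == pytest.approx(wp_rmssd(s)["rmssd"], abs=1e-15)
        assert wp_ar1(s2)["ar1"] == pytest.approx(wp_ar1(s)["ar1"], abs=1e-15)

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(200):
            s = bf.random_series(rng)
            assert np.allclose(wp_rmssd(s)["rmssd"], bf.bf_rmssd(s), atol=1e-12, equal_nan=True)
            assert np.allclose(wp_ar1(s)["ar1"], bf.bf_ar1(s), atol=1e-12, equal_nan=True)


class TestModes:
    def test_unimodal_bump(self, rng):
        vals = np.clip(rng.normal(0.5, 0.08, 80), 0, 1)
        assert count_modes(vals, rng_seed=1) == 1

    def test_bimodal_bumps(self, rng):
        vals = np.clip(np.concatenate([rng.normal(0.15, 0.05, 40), rng.normal(0.85, 0.05, 40)]), 0, 1)
        assert count_modes(vals, rng_seed=1) == 2

    def test_constant_series_is_unimodal(self):
        assert count_modes([0.4] * 30, rng_seed=0) == 1

    def test_reflection_invariance(self, rng):
        vals = np.clip(np.concatenate([rng.normal(0.2, 0.05, 40), rng.normal(0.7, 0.05, 40)]), 0, 1)
        assert count_modes(vals, rng_seed=5) == count_modes(1 - vals, rng_seed=5)


class TestCorrelations:
    def test_identical_series_r_one(self, rng):
        s = rng.random(84)
        cm = wp_corr_matrix(np.stack([s, s]))
        assert cm.values[0, 1] == pytest.approx(1.0)

    def test_independent_series_near_zero(self, rng):
        mat = rng.random((2, 5000))
        cm = wp_corr_matrix(mat)
        assert abs(cm.values[0, 1]) < 0.05

    def test_symmetric_unit_diagonal(self, rng):
        mat = rng.random((5, 84))
        cm = wp_corr_matrix(mat)
        assert np.allclose(cm.values, cm.values.T, equal_nan=True)
        assert np.allclose(np.diag(cm.values), 1.0)

    def test_zero_variance_item_undefined(self, rng):
        mat = np.vstack([np.full(84, 0.5), rng.random((2, 84))])
        cm = wp_corr_matrix(mat)
        assert np.isnan(cm.values[0, 1]) and np.isnan(cm.values[0, 2])

    def test_pairwise_complete_matches_brute_force(self, rng):
        for _ in range(100):
            mat = np.stack([bf.random_series(rng, 40), bf.random_series(rng, 40)])
            cm = wp_corr_matrix(mat)
            assert np.allclose(cm.values[0, 1], bf.bf_pearson(mat[0], mat[1]), atol=1e-12, equal_nan=True)

    def test_mean_abs_corr_examples(self):
        vals = np.array([[1.0, 0.3, 0.3], [0.3, 1.0, 0.3], [0.3, 0.3, 1.0]])
        cm = e.CorrMatrix(vals, np.full((3, 3), 50), ["a", "b", "c"])
        assert mean_abs_corr(cm, 0) == pytest.approx(0.3)
        vals2 = np.full((4, 4), np.nan)
        np.fill_diagonal(vals2, 1.0)
        vals2[0, 1] = vals2[1, 0] = -0.4
        vals2[0, 2] = vals2[2, 0] = 0.2
        cm2 = e.CorrMatrix(vals2, np.full((4, 4), 50), list("abcd"))
        assert mean_abs_corr(cm2, 0) == pytest.approx(0.3)  # mean(|-0.4|, |0.2|)
        with np.errstate(invalid="ignore"):
            assert np.isnan(mean_abs_corr(cm2, 3))


class TestGroupSummary:
    def test_single_participant_identity(self, rng):
        mat = rng.random((4, 84))
        cm = wp_corr_matrix(mat)
        out = group_corr_summary([cm])
        assert np.allclose(out["mean_matrix"], cm.values)

    def test_identity_matrix_eigenvalues(self):
        cm = e.CorrMatrix(np.eye(5), np.full((5, 5), 50), list("abcde"))
        out = group_corr_summary([cm])
        assert np.allclose(out["eigenvalues"], 1.0)

    def test_same_process_groups_highly_similar(self, rng):
        # two groups of participants from one generator: cell-wise mean
        # matrices correlate strongly across groups
        cfg = e.SyntheticConfig(n_likert=20, n_vas=20, seed=11)
        u, _, _ = e.simulate_latent(cfg, 40, np.random.default_rng(11))
        mats = [wp_corr_matrix(u[i]) for i in range(40)]
        a = group_corr_summary(mats[:20])["mean_matrix"]
        b = group_corr_summary(mats[20:])["mean_matrix"]
        assert corr_structure_similarity(a, b) > 0.8


class TestElevationAndMissing:
    def test_flat_series_zero(self):
        assert initial_elevation([0.4] * 84) == pytest.approx(0.0)

    def test_constructed_day_one_shift(self):
        s = np.full(84, 0.3)
        s[:6] += 0.2
        assert initial_elevation(s) == pytest.approx(0.2)

    def test_day_one_missing_undefined(self):
        s = np.full(84, 0.3)
        s[:6] = np.nan
        assert np.isnan(initial_elevation(s))

    @pytest.mark.parametrize("n, expected", [(84, 0.0), (42, 0.5), (20, 64 / 84)])
    def test_missing_proportion(self, n, expected):
        assert missing_proportion(n) == pytest.approx(expected)


def test_stat_table_has_expected_shape_and_bounds(small_stat_table):
    tab = small_stat_table
    assert {"wp_mean", "wp_sd", "wp_skew", "rmssd", "ar1", "mean_abs_corr", "missing_prop"} <= set(tab.columns)
    assert tab["wp_mean"].dropna().between(0, 1).all()
    assert tab["ar1"].dropna().between(-1, 1).all()
    assert (tab["n_pairs"] <= tab["n_obs"] - 1).all()
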