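import numpy as np
import pandas as pd
import pytest
from scipy import integrate
from scipy.special import expit

import emascale as e
from emascale.models import ModelSpec, PosteriorDraws, emm_draws, hdi, zoib_logpdf
import oracles as bf


class TestZoibDensity:
    def test_point_mass_branches(self):
        assert zoib_logpdf(0.0, 0.5, 2.0, pi0=0.2) == pytest.approx(np.log(0.2))
        assert zoib_logpdf(1.0, 0.5, 2.0, pi0=0.2, pi1=0.0) == -np.inf

    def test_uniform_interior(self):
        # Beta(1, 1) with no inflation is the uniform density
        assert zoib_logpdf(0.5, 0.5, 2.0) == pytest.approx(0.0)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            zoib_logpdf(1.2, 0.5, 2.0)
        with pytest.raises(ValueError):
            zoib_logpdf(0.5, 0.5, 2.0, pi0=0.6, pi1=0.5)

    @pytest.mark.parametrize("mu, phi, pi0, pi1", [
        (0.5, 2.0, 0.0, 0.0),
        (0.3, 8.0, 0.2, 0.0),
        (0.7, 5.0, 0.1, 0.15),
        (0.15, 20.0, 0.4, 0.05),
    ])
    def test_total_mass_is_one(self, mu, phi, pi0, pi1):
        interior, _ = integrate.quad(
            lambda y: np.exp(zoib_logpdf(y, mu, phi, pi0, pi1)), 1e-12, 1 - 1e-12, limit=200
        )
        assert interior + pi0 + pi1 == pytest.approx(1.0, abs=1e-8)


class TestHDI:
    def test_degenerate_draws(self):
        lo, hi = hdi(np.full(500, 3.2))
        assert lo == hi == 3.2

    def test_skewed_hdi_shorter_than_central(self, rng):
        d = rng.exponential(1.0, 50_000)
        lo, hi = hdi(d, mass=0.9)
        q = np.quantile(d, [0.05, 0.95])
        assert (hi - lo) < (q[1] - q[0])
        assert lo == pytest.approx(0.0, abs=0.01)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            hdi(np.arange(50))


def _draws_from_constants(n=500, **eta):
    """PosteriorDraws with every coefficient fixed (link scale)."""
    spec = ModelSpec("zoib", zero_inflation="b_pi0[intercept]" in eta, one_inflation="b_pi1[intercept]" in eta)
    names = ["intercept", "scale_vas"]
    draws = {}
    for block in spec.param_blocks:
        for nm in names:
            draws[f"b_{block}[{nm}]"] = np.full(n, eta.get(f"b_{block}[{nm}]", 0.0))
    return PosteriorDraws(draws, "test", spec, names)


class TestEMM:
    def test_zoib_closed_form(self):
        from scipy.special import logit
        post = _draws_from_constants(**{
            "b_mu[intercept]": logit(0.5),
            "b_disp[intercept]": np.log(2.0),
            "b_pi0[intercept]": logit(0.2),
        })
        emm = emm_draws(post, "likert")
        assert np.allclose(emm, (1 - 0.2) * 0.5)

    def test_no_inflation_emm_equals_mu(self):
        from scipy.special import logit
        post = _draws_from_constants(**{"b_mu[intercept]": logit(0.3)})
        assert np.allclose(emm_draws(post, "likert"), 0.3)

    def test_identical_groups_difference_straddles_zero(self, rng):
        spec = ModelSpec("gaussian")
        names = ["intercept", "scale_vas"]
        draws = {
            "b_mu[intercept]": rng.normal(0.5, 0.05, 1000),
            "b_mu[scale_vas]": rng.normal(0.0, 0.05, 1000),
            "b_disp[intercept]": np.full(1000, -2.0),
            "b_disp[scale_vas]": np.zeros(1000),
        }
        post = PosteriorDraws(draws, "test", spec, names)
        emm = e.emm_summary(post)
        lo, hi = emm.table.loc["difference", ["hdi_low", "hdi_high"]]
        assert lo < 0 < hi

    def test_monotone_in_mu_and_pi0(self):
        from scipy.special import logit
        base = dict({"b_disp[intercept]": np.log(5.0), "b_pi0[intercept]": logit(0.2)})
        e1 = emm_draws(_draws_from_constants(**base, **{"b_mu[intercept]": logit(0.3)}), "likert")[0]
        e2 = emm_draws(_draws_from_constants(**base, **{"b_mu[intercept]": logit(0.5)}), "likert")[0]
        assert e2 > e1
        f1 = emm_draws(_draws_from_constants(**{"b_mu[intercept]": logit(0.4), "b_disp[intercept]": 1.0, "b_pi0[intercept]": logit(0.1)}), "likert")[0]
        f2 = emm_draws(_draws_from_constants(**{"b_mu[intercept]": logit(0.4), "b_disp[intercept]": 1.0, "b_pi0[intercept]": logit(0.3)}), "likert")[0]
        assert f2 < f1

    def test_missing_parameter_rejected(self):
        post = _draws_from_constants(**{"b_mu[intercept]": 0.0})
        del post.draws["b_disp[intercept]"]
        with pytest.raises(ValueError, match="missing"):
            emm_draws(post, "vas")


class TestFitting:
    def test_laplace_recovers_scale_effect(self):
        tab = bf.simulate_zoib_stat_table(seed=5, n_per=80, scale_eff=0.6)
        post = e.fit_group_model(tab, "wp_mean", backend="map_laplace", seed=1)
        lo, hi = hdi(post.draws["b_mu[scale_vas]"], 0.90)
        assert lo < 0.6 < hi or abs(np.median(post.draws["b_mu[scale_vas]"]) - 0.6) < 0.15

    def test_no_zeros_concentrates_pi0_near_zero(self):
        tab = bf.simulate_zoib_stat_table(seed=5, n_per=40, pi0=0.0)
        post = e.fit_group_model(tab, "wp_mean", backend="map_laplace", seed=1)
        assert np.median(expit(post.draws["b_pi0[intercept]"])) < 0.02

    def test_zoib_without_zeros_reduces_to_beta_regression(self):
        tab = bf.simulate_zoib_stat_table(seed=8, n_per=40, pi0=0.0)
        with_zi = e.fit_group_model(tab, "wp_mean", ModelSpec("zoib", zero_inflation=True), backend="map_laplace")
        no_zi = e.fit_group_model(tab, "wp_mean", ModelSpec("zoib", zero_inflation=False), backend="map_laplace")
        for nm in ("intercept", "scale_vas", "valence", "scale_x_valence"):
            a = np.median(with_zi.draws[f"b_mu[{nm}]"])
            b = np.median(no_zi.draws[f"b_mu[{nm}]"])
            assert a == pytest.approx(b, abs=0.02)

    def test_duplicating_participants_keeps_point_shrinks_interval(self):
        tab = bf.simulate_zoib_stat_table(seed=3, n_per=25)
        dup = tab.copy()
        dup["participant_id"] = dup["participant_id"] + "_copy"
        doubled = pd.concat([tab, dup], ignore_index=True)
        a = e.fit_group_model(tab, "wp_mean", backend="cluster_bootstrap", seed=2, B=150)
        b = e.fit_group_model(doubled, "wp_mean", backend="cluster_bootstrap", seed=2, B=150)
        # the weak stabilizing ridge does not rescale with the data, so the
        # point estimates agree only up to its (tiny) influence
        assert a.meta["point"][1] == pytest.approx(b.meta["point"][1], abs=1e-3)
        wa = np.subtract(*hdi(a.draws["b_mu[scale_vas]"], 0.90)[::-1])
        wb = np.subtract(*hdi(b.draws["b_mu[scale_vas]"], 0.90)[::-1])
        assert wb < wa

    def test_backends_agree_on_well_separated_effect(self):
        tab = bf.simulate_zoib_stat_table(seed=4, n_per=50, scale_eff=1.0)
        boot = e.fit_group_model(tab, "wp_mean", backend="cluster_bootstrap", seed=1, B=150)
        mcmc = e.fit_group_model(tab, "wp_mean", backend="mcmc", seed=1, chains=2, warmup=250, draws=250, thin=1)
        db, dm = boot.draws["b_mu[scale_vas]"], mcmc.draws["b_mu[scale_vas]"]
        assert np.sign(np.median(db)) == np.sign(np.median(dm)) == 1
        lob, hib = hdi(db, 0.90)
        lom, him = hdi(dm, 0.90)
        assert max(lob, lom) < min(hib, him)  # intervals overlap

    def test_mcmc_reports_diagnostics(self):
        tab = bf.simulate_zoib_stat_table(seed=4, n_per=20)
        post = e.fit_group_model(tab, "wp_mean", backend="mcmc", seed=1, chains=2, warmup=150, draws=150, thin=1)
        assert {"rhat", "ess_bulk", "ess_tail"} <= set(post.diagnostics.columns)
        assert post.diagnostics["rhat"].notna().all()

    def test_too_few_participants_rejected(self):
        tab = bf.simulate_zoib_stat_table(seed=1, n_per=1)
        with pytest.raises(ValueError):
            e.fit_group_model(tab, "wp_mean", backend="map_laplace")


class TestCriterionCorrelations:
    def _setup(self, rng, n=40, loading=0.0):
        pids = [f"L{i}" for i in range(n)] + [f"V{i}" for i in range(n)]
        groups = pd.Series(["likert"] * n + ["vas"] * n, index=pids)
        latent = rng.standard_normal(2 * n)
        items = pd.DataFrame(
            rng.standard_normal((2 * n, 14)) + loading * latent[:, None],
            index=pids, columns=[f"item{j}" for j in range(14)],
        )
        crit = pd.Series(latent + rng.standard_normal(2 * n), index=pids)
        return items, crit, groups

    def test_criterion_identical_to_item_gives_r_one(self, rng):
        items, crit, groups = self._setup(rng)
        crit = items["item0"]
        res = e.criterion_correlations(items, crit, groups, B=150, seed=0)
        assert res.per_item.loc["item0", "likert"] == pytest.approx(1.0)
        assert res.per_item.loc["item0", "vas"] == pytest.approx(1.0)

    def test_null_criterion_difference_straddles_zero(self, rng):
        items, crit, groups = self._setup(rng, n=200, loading=0.0)
        res = e.criterion_correlations(items, crit, groups, B=300, seed=1)
        lo, hi = res.difference.loc["vas_minus_likert", ["hdi_low", "hdi_high"]]
        assert lo < 0 < hi

    def test_generator_sign_pattern(self):
        ds = e.generate_study(e.SyntheticConfig(n_likert=120, n_vas=120, criterion_loading=0.8, seed=6))
        tab = e.compute_stat_table(ds)
        item_means = tab.pivot(index="participant_id", columns="item", values="wp_mean")
        res = e.criterion_correlations(item_means, ds.criteria["dass_dep"], ds.group_of(), B=120, seed=0)
        valence = {it.name: it.valence for it in ds.items}
        for item, row in res.per_item.iterrows():
            expected_sign = 1 if valence[item] == "negative" else -1
            assert np.sign(row["vas"]) == expected_sign

    def test_zero_variance_criterion_rejected(self, rng):
        items, crit, groups = self._setup(rng, n=10)
        crit[:] = 1.0
        res = e.criterion_correlations(items, crit, groups, B=120, seed=0)
        assert res.per_item.isna().all().all()
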