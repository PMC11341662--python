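import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridgs import mm, simcross as sc

from _oracles import balanced_oneway_reml


def _oneway(q, r, sigma_u, sigma_e, seed):
    rng = np.random.default_rng(seed)
    groups = np.repeat(np.arange(q), r)
    u = rng.normal(0, sigma_u, q)
    y = 5.0 + u[groups] + rng.normal(0, sigma_e, q * r)
    return y, groups


class TestRemlFit:
    def test_balanced_oneway_closed_form(self):
        y, groups = _oneway(q=10, r=6, sigma_u=1.5, sigma_e=1.0, seed=11)
        Z, levels = mm.incidence(groups)
        fit = mm.reml_fit(y, np.ones((y.size, 1)),
                          [mm.RandomTerm("u", Z, None, levels)],
                          tol_loglik=1e-12, tol_param=1e-10)
        s_u, s_e = balanced_oneway_reml(y, groups)
        assert fit.varcomp["u"] == pytest.approx(s_u, abs=1e-6)
        assert fit.varcomp["residual"] == pytest.approx(s_e, abs=1e-6)

    def test_loglik_invariant_to_fixed_reparameterization(self):
        y, groups = _oneway(q=8, r=4, sigma_u=1.0, sigma_e=0.8, seed=12)
        Z, levels = mm.incidence(groups)
        blocks = np.tile([0, 0, 1, 1], 8)
        B, _ = mm.incidence(blocks)
        X_treat = np.column_stack([np.ones(y.size), B[:, 1:]])
        X_sum = np.column_stack([np.ones(y.size), B[:, 0] - B[:, 1]])
        fits = [
            mm.reml_fit(y, X, [mm.RandomTerm("u", Z, None, levels)],
                        tol_loglik=1e-12, tol_param=1e-10)
            for X in (X_treat, X_sum)
        ]
        assert fits[0].loglik == pytest.approx(fits[1].loglik, abs=1e-6)
        assert fits[0].varcomp["u"] == pytest.approx(fits[1].varcomp["u"],
                                                     abs=1e-6)

    def test_blups_match_shrinkage_formula(self):
        y, groups = _oneway(q=12, r=5, sigma_u=2.0, sigma_e=1.0, seed=13)
        Z, levels = mm.incidence(groups)
        fit = mm.reml_fit(y, np.ones((y.size, 1)),
                          [mm.RandomTerm("u", Z, None, levels)],
                          tol_loglik=1e-12, tol_param=1e-10)
        # balanced case: u_hat = r s_u / (r s_u + s_e) * (group mean - GLS mean)
        r = 5
        s_u, s_e = fit.varcomp["u"], fit.varcomp["residual"]
        gm = np.array([y[groups == int(g)].mean() for g in levels])
        shrink = r * s_u / (r * s_u + s_e)
        np.testing.assert_allclose(
            fit.blups["u"], shrink * (gm - float(fit.beta[0])), atol=1e-6
        )

    def test_residual_groups_recover_heterogeneous_noise(self):
        rng = np.random.default_rng(14)
        n = 400
        grp = np.repeat(["a", "b"], n // 2)
        y = np.where(grp == "a", rng.normal(0, 1.0, n), rng.normal(0, 3.0, n))
        fit = mm.reml_fit(y, np.ones((n, 1)), [], residual_groups=grp)
        assert fit.varcomp["residual:a"] == pytest.approx(1.0, rel=0.3)
        assert fit.varcomp["residual:b"] == pytest.approx(9.0, rel=0.3)

    def test_component_pinned_at_zero_when_absent(self):
        rng = np.random.default_rng(15)
        n = 120
        groups = np.repeat(np.arange(12), 10)
        y = rng.normal(0, 1.0, n)  # no group signal at all
        Z, levels = mm.incidence(groups)
        fit = mm.reml_fit(y, np.ones((n, 1)),
                          [mm.RandomTerm("u", Z, None, levels)])
        assert fit.varcomp["u"] < 0.05
        assert fit.varcomp["residual"] == pytest.approx(1.0, rel=0.2)

    def test_rank_deficient_design_raises_with_columns(self):
        y = np.arange(6.0)
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(mm.NotEstimableError, match="rank deficient"):
            mm.reml_fit(y, X, [], fixed_names=["intercept", "dup"])

    def test_duplicate_term_labels_rejected(self):
        y = np.arange(4.0)
        Z = np.eye(4)
        with pytest.raises(ValueError, match="unique"):
            mm.reml_fit(y, np.ones((4, 1)),
                        [mm.RandomTerm("u", Z), mm.RandomTerm("u", Z)])

    @given(st.integers(0, 10**6))
    @settings(max_examples=10)
    def test_estimates_nonnegative_and_converged(self, seed):
        y, groups = _oneway(q=6, r=4, sigma_u=1.0, sigma_e=1.0, seed=seed)
        Z, levels = mm.incidence(groups)
        fit = mm.reml_fit(y, np.ones((y.size, 1)),
                          [mm.RandomTerm("u", Z, None, levels)])
        assert fit.converged
        assert all(v >= 0.0 for v in fit.varcomp.values())


class TestSummaries:
    def test_percent_sca_formula_and_errors(self):
        assert mm.percent_sca(3.0, 1.0, 1.0) == pytest.approx(20.0)
        with pytest.raises(ValueError, match="non-negative"):
            mm.percent_sca(-0.1, 1.0, 0.0)
        with pytest.raises(ValueError, match="undefined"):
            mm.percent_sca(0.0, 0.0, 0.0)

    def test_heritability_formula(self):
        # H2 = s_H / (s_H + s_HxE/n_site + s_E/(n_rep n_site))
        assert mm.heritability(2.0, 1.0, 1.0, 4, 2) == pytest.approx(
            2.0 / (2.0 + 0.25 + 0.125)
        )
        with pytest.raises(ValueError, match="positive"):
            mm.heritability(1.0, 1.0, 1.0, 0, 1)


class TestDecomposeVariance:
    def test_interaction_terms_not_aliased(self, genome, panels):
        # asymmetric truth: flint-by-trial noise only
        flint, dent = panels
        t = sc.TraitModel.sample(genome.n_markers, 25,
                                 np.random.default_rng(21))
        t = t.calibrate(flint, dent, 0.5, 0.3, 0.0)
        t.trial_structure = {"gcaf_e": 0.8, "gcad_e": 0.0, "sca_e": 0.0,
                             "residual": 0.3}
        des = sc.make_factorial(flint.ids, dent.ids, 3.0, seed=22)
        plots = sc.simulate_phenotypes(des, t, flint, dent, n_trials=4, seed=23)
        tab, _ = mm.decompose_variance(plots, des)
        est = tab.set_index("component")["estimate"]
        assert est["GCAfxE"] > est["GCAdxE"] + 0.1
        assert est["GCAfxE"] == pytest.approx(0.8, abs=0.4)

    def test_per_trial_residuals_reported(self, plots, factorial):
        tab, summary = mm.decompose_variance(plots, factorial)
        res = tab[tab["component"].str.startswith("residual")]
        assert len(res) == 3  # one per trial
        g = summary["G0R"]
        assert 0.0 <= g["H2"] <= 1.0
        assert g["n_site"] == pytest.approx(3.0)
        assert g["n_rep"] >= 1.0

    def test_single_trial_warns_and_drops_interactions(self, factorial, trait,
                                                       panels):
        flint, dent = panels
        plots1 = sc.simulate_phenotypes(factorial, trait, flint, dent,
                                        n_trials=1, seed=24)
        with pytest.warns(UserWarning, match="single trial"):
            tab, _ = mm.decompose_variance(plots1, factorial)
        est = tab.set_index("component")["estimate"]
        assert est["GCAfxE"] == 0.0 and est["SCAxE"] == 0.0

    def test_missing_columns_rejected(self, factorial):
        with pytest.raises(ValueError, match="misses columns"):
            mm.decompose_variance(pd.DataFrame({"value": [1.0]}), factorial)


class TestLsMeans:
    def test_balanced_equals_plain_means(self, factorial, trait, panels):
        flint, dent = panels
        plots = sc.simulate_phenotypes(factorial, trait, flint, dent,
                                       n_trials=3, prep_fraction=0.0, seed=31,
                                       trial_effect_sd=0.0)
        lsm = mm.ls_means(plots)
        raw = plots.groupby("hybrid_id")["value"].mean()
        np.testing.assert_allclose(lsm["ls_mean"],
                                   raw.loc[lsm.index].to_numpy(), atol=1e-8)

    def test_unbalanced_matches_ols_package(self, plots):
        import statsmodels.formula.api as smf

        d = plots.copy()
        # unbalance: drop some hybrid-by-trial cells
        d = d[~((d["trial_id"] == "trial0")
                & (d["hybrid_id"].isin(d["hybrid_id"].unique()[:10])))]
        lsm = mm.ls_means(d)
        fit = smf.ols("value ~ C(hybrid_id) + C(trial_id)", data=d).fit()
        grid = pd.MultiIndex.from_product(
            [lsm.index, sorted(d["trial_id"].unique())],
            names=["hybrid_id", "trial_id"],
        ).to_frame(index=False)
        pred = fit.predict(grid)
        oracle = grid.assign(p=pred).groupby("hybrid_id")["p"].mean()
        np.testing.assert_allclose(lsm["ls_mean"],
                                   oracle.loc[lsm.index].to_numpy(), atol=1e-8)

    def test_disconnected_design_raises(self):
        d = pd.DataFrame(
            {
                "hybrid_id": ["h1", "h2", "h3", "h4"],
                "trial_id": ["t1", "t1", "t2", "t2"],
                "is_control": False,
                "generation": "G0R",
                "value": [1.0, 2.0, 3.0, 4.0],
            }
        )
        with pytest.raises(mm.NotEstimableError, match="disconnected"):
            mm.ls_means(d)

    def test_include_warns_on_absent(self, plots):
        with pytest.warns(UserWarning, match="absent"):
            lsm = mm.ls_means(plots, include=[plots["hybrid_id"].iloc[0],
                                             "no_such_hybrid"])
        assert list(lsm.index) == [plots["hybrid_id"].iloc[0]]


class TestCorrectSpatial:
    def test_block_blup_reduces_block_signal(self, factorial, trait, panels):
        flint, dent = panels
        noisy = sc.simulate_phenotypes(factorial, trait, flint, dent,
                                       n_trials=2, seed=41, block_sigma2=4.0,
                                       plots_per_block=10)
        corr = mm.correct_spatial(noisy, mode="block_blup")
        def block_var(df):
            blk = df.groupby(["trial_id", "block_id"])["value"].mean()
            return blk.groupby("trial_id").var().mean()
        assert block_var(corr) < 0.5 * block_var(noisy)
        same = mm.correct_spatial(noisy, mode="none")
        pd.testing.assert_frame_equal(same, noisy)

    def test_requires_blocks_and_valid_mode(self, plots):
        with pytest.raises(ValueError, match="mode"):
            mm.correct_spatial(plots, mode="fancy")
        d = plots.drop(columns=["block_id"])
        with pytest.raises(ValueError, match="block ids"):
            mm.correct_spatial(d, mode="block_blup")
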