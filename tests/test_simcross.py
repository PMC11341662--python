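import numpy as np
import pandas as pd
import pytest

from hybridgs import simcross as sc


class TestGenomeSpec:
    def test_uniform_layout(self, genome):
        assert genome.n_markers == 200
        assert len(genome.marker_ids) == 200
        for pos, length in zip(genome.marker_positions,
                               genome.chrom_length_morgans):
            assert np.all(np.diff(pos) > 0)
            assert pos[0] >= 0 and pos[-1] <= length

    def test_validation(self):
        with pytest.raises(ValueError, match="one length per chromosome"):
            sc.GenomeSpec(2, [1.0])
        with pytest.raises(ValueError, match="strictly increasing"):
            sc.GenomeSpec(1, [1.0], [np.array([0.5, 0.5])])
        with pytest.raises(ValueError, match="outside chr"):
            sc.GenomeSpec(1, [1.0], [np.array([0.5, 1.5])])


class TestFoundersAndDh:
    def test_founder_validation(self, genome):
        with pytest.raises(ValueError, match=r"\[0,1\]"):
            sc.simulate_founders(genome, 4, divergence=1.5)
        with pytest.raises(ValueError, match="at least 2 founders"):
            sc.simulate_founders(genome, 1)

    def test_fst_monotone_in_divergence(self, genome):
        fsts = []
        for div in (0.0, 0.3, 0.8):
            a, b = sc.simulate_founders(genome, 30, div, seed=201)
            fsts.append(sc.fst_hudson(a, b))
        assert fsts[0] < fsts[1] < fsts[2]
        assert fsts[2] > 0.4

    def test_dh_lines_fully_homozygous_dosage(self, genome, panels):
        flint, _ = panels
        g = flint.to_genotype_matrix(genome.marker_ids)
        assert np.isin(g.dosage, (0.0, 2.0)).all()
        assert len(flint.family) == flint.n_lines

    def test_crossover_rate_matches_haldane(self, genome):
        # two fully opposed parents: the DH allele vector IS the gamete
        # phase, so adjacent-marker switches count crossovers directly.
        m = genome.n_markers
        parents = sc.LinePanel(
            ["a", "b"], np.vstack([np.zeros(m), np.ones(m)]), "flint"
        )
        lines = sc.derive_dh_lines(parents, [("a", "b")], 4000, genome,
                                   seed=202)
        switches = 0.0
        expected = 0.0
        for sl, pos in zip(genome.chrom_slices, genome.marker_positions):
            block = lines.alleles[:, sl]
            switches += np.abs(np.diff(block, axis=1)).sum() / lines.n_lines
            delta = np.diff(pos)
            expected += np.sum((1.0 - np.exp(-2.0 * delta)) / 2.0)
        assert switches == pytest.approx(expected, abs=0.15)

    def test_dh_errors(self, genome, panels):
        flint, _ = panels
        with pytest.raises(ValueError, match="outside group"):
            sc.derive_dh_lines(flint, [("nope", flint.ids[0])], 2, genome)
        with pytest.raises(ValueError, match="distinct parents"):
            sc.derive_dh_lines(flint, [(flint.ids[0], flint.ids[0])], 2, genome)


class TestDesigns:
    def test_factorial_counts_and_uniqueness(self, panels):
        flint, dent = panels
        des = sc.make_factorial(flint.ids, dent.ids, 1.5, seed=203)
        n_h = round(1.5 * (flint.n_lines + dent.n_lines) / 2)
        assert len(des) == n_h
        pairs = list(zip(des.table["flint_parent"], des.table["dent_parent"]))
        assert len(set(pairs)) == n_h

    def test_factorial_uses_every_line_when_possible(self, panels):
        flint, dent = panels
        des = sc.make_factorial(flint.ids, dent.ids, 2.0, seed=204)
        assert set(des.table["flint_parent"]) == set(flint.ids)
        assert set(des.table["dent_parent"]) == set(dent.ids)

    def test_factorial_deterministic(self, panels):
        flint, dent = panels
        a = sc.make_factorial(flint.ids, dent.ids, 1.2, seed=205)
        b = sc.make_factorial(flint.ids, dent.ids, 1.2, seed=205)
        pd.testing.assert_frame_equal(a.table, b.table)

    def test_factorial_errors(self):
        with pytest.raises(ValueError, match=">= 1"):
            sc.make_factorial(["f1", "f2"], ["d1", "d2"], 0.5)
        with pytest.raises(ValueError, match="distinct parent pairs"):
            sc.make_factorial(["f1"], ["d1"], 2.0)

    def test_tester_allocations(self):
        lines = [f"l{i}" for i in range(6)]
        one = sc.make_tester_design(lines, ["t1", "t2"], "one-tester")
        assert set(one.table["dent_parent"]) == {"t1"}
        assert len(one) == 6
        both = sc.make_tester_design(lines, ["t1", "t2"], "both-testers")
        assert len(both) == 12
        split = sc.make_tester_design(lines, ["t1", "t2"], "split")
        assert len(split) == 6
        counts = split.table["dent_parent"].value_counts()
        assert counts["t1"] == 3 and counts["t2"] == 3
        dent_side = sc.make_tester_design(lines, ["t1"], "one-tester",
                                          lines_group="dent")
        assert set(dent_side.table["flint_parent"]) == {"t1"}
        assert set(dent_side.table["dent_parent"]) == set(lines)

    def test_tester_errors(self):
        with pytest.raises(ValueError, match="at least one tester"):
            sc.make_tester_design(["l1"], [])
        with pytest.raises(ValueError, match="divisible"):
            sc.make_tester_design(["l1", "l2", "l3"], ["t1", "t2"], "split")
        with pytest.raises(ValueError, match="allocation"):
            sc.make_tester_design(["l1"], ["t1"], "bogus")


def _full_grid(flint, dent):
    rows = [
        [f"G{i}_{j}", f_id, d_id, "G0R", "grid"]
        for i, f_id in enumerate(flint.ids)
        for j, d_id in enumerate(dent.ids)
    ]
    from hybridgs import genio

    return genio.CrossingDesign(
        pd.DataFrame(rows, columns=["hybrid_id", "flint_parent", "dent_parent",
                                    "generation", "design"])
    )


class TestTraitModel:
    def test_calibration_hits_targets_exactly(self, trait, panels):
        flint, dent = panels
        gv = sc.genetic_values(_full_grid(flint, dent), trait, flint, dent)
        des = _full_grid(flint, dent).table
        gca_f = gv.assign(fp=des["flint_parent"].to_numpy()).groupby(
            "fp")["true_gca_f"].first()
        gca_d = gv.assign(dp=des["dent_parent"].to_numpy()).groupby(
            "dp")["true_gca_d"].first()
        assert np.var(gca_f.to_numpy()) == pytest.approx(0.44, abs=1e-8)
        assert np.var(gca_d.to_numpy()) == pytest.approx(0.25, abs=1e-8)
        assert np.var(gv["true_sca"].to_numpy()) == pytest.approx(0.19,
                                                                  abs=1e-8)

    def test_decomposition_identity(self, trait, panels, factorial):
        flint, dent = panels
        gv = sc.genetic_values(factorial, trait, flint, dent)
        np.testing.assert_allclose(gv["check"], gv["true_value"], atol=1e-10)

    def test_zero_sca_target_zeroes_dominance(self, genome, panels):
        flint, dent = panels
        t = sc.TraitModel.sample(genome.n_markers, 20,
                                 np.random.default_rng(206))
        t0 = t.calibrate(flint, dent, 0.4, 0.4, 0.0)
        assert np.all(t0.dominance_effects == 0.0)
        gv = sc.genetic_values(_full_grid(flint, dent), t0, flint, dent)
        assert np.var(gv["true_sca"].to_numpy()) == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_negative_targets_rejected(self, genome, panels):
        flint, dent = panels
        t = sc.TraitModel.sample(genome.n_markers, 20,
                                 np.random.default_rng(207))
        with pytest.raises(ValueError, match=">= 0"):
            t.calibrate(flint, dent, -1.0, 0.1, 0.1)

    def test_qtl_outside_markers_rejected(self, panels, factorial):
        flint, dent = panels
        bad = sc.TraitModel(
            qtl_indices=np.array([10**6]),
            additive_effects_flint=np.array([1.0]),
            additive_effects_dent=np.array([1.0]),
            dominance_effects=np.array([0.0]),
        )
        with pytest.raises(ValueError, match="outside genotyped markers"):
            sc.genetic_values(factorial, bad, flint, dent)


class TestSimulatePhenotypes:
    def test_layout_counts(self, factorial, trait, panels):
        flint, dent = panels
        controls = factorial.hybrid_ids[:3]
        plots = sc.simulate_phenotypes(
            factorial, trait, flint, dent, n_trials=4, controls=controls,
            prep_fraction=0.15, seed=208,
        )
        n_h = len(factorial)
        n_exp = n_h - len(controls)
        n_rep = round(0.15 * n_exp)
        per_trial = plots.groupby("trial_id").size()
        assert (per_trial == n_h + len(controls) + n_rep).all()
        for t, sub in plots.groupby("trial_id"):
            counts = sub["hybrid_id"].value_counts()
            assert (counts.loc[controls] == 2).all()
            assert (counts.drop(controls).isin([1, 2])).all()
            assert (counts.drop(controls) == 2).sum() == n_rep
        assert plots.loc[plots["hybrid_id"].isin(controls),
                         "is_control"].all()

    def test_deterministic(self, factorial, trait, panels):
        flint, dent = panels
        a = sc.simulate_phenotypes(factorial, trait, flint, dent, n_trials=2,
                                   seed=209)
        b = sc.simulate_phenotypes(factorial, trait, flint, dent, n_trials=2,
                                   seed=209)
        pd.testing.assert_frame_equal(a, b)

    def test_validation(self, factorial, trait, panels):
        flint, dent = panels
        with pytest.raises(ValueError, match="n_trials"):
            sc.simulate_phenotypes(factorial, trait, flint, dent, n_trials=0)
        with pytest.raises(ValueError, match="prep_fraction"):
            sc.simulate_phenotypes(factorial, trait, flint, dent,
                                   prep_fraction=2.0)


class TestTwoCycleScheme:
    def test_structure(self, small_scheme):
        s = small_scheme
        assert len(s.selected_flint) == 12 and len(s.selected_dent) == 12
        assert set(s.selected_flint) <= set(s.flint_g0.ids)
        gens = set(s.g1_design.table["generation"])
        assert gens == {"G1", "G0S"}
        g0s = s.g1_design.table.query("generation == 'G0S'")
        assert set(g0s["flint_parent"]) <= set(s.selected_flint)
        assert set(g0s["dent_parent"]) <= set(s.selected_dent)
        # every phenotyped hybrid is covered by the combined panels
        flint_all, dent_all = s.panels_for(s.g1_design)
        assert set(s.g1_design.table["flint_parent"]) <= set(flint_all.ids)
        ped = s.pedigree()
        assert not ped["id"].duplicated().any()
        from hybridgs import kinship

        A = kinship.pedigree_A(ped)
        d = np.diag(A.values)
        assert np.all(d >= 1.0 - 1e-9) and np.all(d <= 2.0 + 1e-9)

    def test_selection_raises_true_gca_mean(self, small_scheme):
        s = small_scheme
        gf, gd = sc._true_line_gcas(s.trait, s.flint_g0, s.dent_g0)
        sel = pd.Series(gf, index=s.flint_g0.ids).loc[s.selected_flint]
        assert sel.mean() > 0.0

    def test_deterministic_replay(self):
        kwargs = dict(
            genome=sc.GenomeSpec.uniform(2, 0.5, 10),
            lines_per_group_g0=16,
            hybrids_per_line_g0=1.2,
            n_qtl=10,
            n_trials_g0=2,
            n_trials_g1=2,
            n_selected=6,
            n_intragroup_crosses=4,
            lines_per_group_g1=12,
            hybrids_per_line_g1=1.5,
            n_g0s_hybrids=6,
            select_on="true_gca",
            seed=210,
        )
        a = sc.simulate_two_cycle_scheme(**kwargs)
        b = sc.simulate_two_cycle_scheme(**kwargs)
        pd.testing.assert_frame_equal(a.g0_plots, b.g0_plots)
        pd.testing.assert_frame_equal(a.g1_plots, b.g1_plots)
        assert a.selected_flint == b.selected_flint
        np.testing.assert_array_equal(a.flint_g1.alleles, b.flint_g1.alleles)

    def test_select_on_validation(self):
        with pytest.raises(ValueError, match="select_on"):
            sc.simulate_two_cycle_scheme(
                genome=sc.GenomeSpec.uniform(1, 0.5, 5),
                lines_per_group_g0=6, n_qtl=3, select_on="bogus", seed=211,
            )
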