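"""Generators: determinism, planted structure, and the truth ledger."""

import numpy as np
import pandas as pd
import pytest

from rootqtl import read_qc, root_traits as rt, synthetic_data as sd


class TestMakeGenome:
    def test_construction_and_determinism(self):
        g1 = sd.make_genome(1, 10, 500, seed=1)
        g2 = sd.make_genome(1, 10, 500, seed=1)
        assert len(g1.genes) == 10
        assert g1.recurrent_seqs == g2.recurrent_seqs
        assert g1.donor_seqs == g2.donor_seqs
        starts = [g.start for g in g1.genes]
        assert starts == sorted(starts)

    def test_alleles_differ_only_at_planted_snps(self):
        g = sd.make_genome(2, 50, 500, seed=7)
        assert len(g.genes) == 100
        for gid in g.gene_ids:
            rec, don = g.recurrent_seqs[gid], g.donor_seqs[gid]
            diffs = tuple(i for i, (a, b) in enumerate(zip(rec, don)) if a != b)
            assert diffs == g.snp_positions[gid]

    def test_bad_sizes(self):
        with pytest.raises(ValueError):
            sd.make_genome(0, 10, 500)
        with pytest.raises(ValueError):
            sd.make_genome(1, 1, 500)


class TestMakeIlPanel:
    def test_two_overlapping_ils_give_three_signatures(self, small_genome):
        genome = sd.make_genome(1, 20, 500, seed=2)
        panel = sd.make_il_panel(genome, 2, overlap_frac=0.5, seed=2)
        (c1, s1, e1), = panel[0].intervals
        (c2, s2, e2), = panel[1].intervals
        assert s1 < s2 < e1 < e2      # proper overlap → 3 coverage signatures

    def test_subils_contained_in_parent(self, small_genome, small_panel):
        parents = {il.il_id: il for il in small_panel if il.il_id.count("-") == 1}
        subs = [il for il in small_panel if il.il_id.count("-") == 2]
        assert subs
        for sub in subs:
            parent_id = sub.il_id.rsplit("-", 1)[0]
            (pc, ps, pe), = parents[parent_id].intervals
            (sc, ss, se), = sub.intervals
            assert sc == pc
            assert ps <= ss and se < pe   # strict sub-interval

    def test_invalid_overlap(self, small_genome):
        with pytest.raises(ValueError):
            sd.make_il_panel(small_genome, 4, overlap_frac=1.0)
        with pytest.raises(ValueError):
            sd.make_il_panel(small_genome, 1)


class TestSimulateExpression:
    def test_determinism(self, small_genome, small_panel, small_truth):
        m1 = sd.simulate_expression(small_panel, small_genome, small_truth, seed=4)
        m2 = sd.simulate_expression(small_panel, small_genome, small_truth, seed=4)
        pd.testing.assert_frame_equal(m1.counts, m2.counts)

    def test_poisson_limit_variance(self):
        genome = sd.make_genome(1, 5, 200, seed=3)
        truth = sd.SimTruth(dispersions={g: 1e-9 for g in genome.gene_ids})
        panel = sd.make_il_panel(genome, 2, seed=3)
        m = sd.simulate_expression(panel, genome, truth, n_reps=1000,
                                   lib_size_cv=0.0, seed=3)
        arr = m.counts.to_numpy(dtype=float)   # 3000 draws per gene
        ratio = arr.var(axis=1) / arr.mean(axis=1)
        assert np.all(np.abs(ratio - 1.0) < 0.10)

    def test_nb_mean_variance_law(self):
        genome = sd.make_genome(1, 4, 200, seed=5)
        phi = 0.2
        truth = sd.SimTruth(dispersions={g: phi for g in genome.gene_ids})
        rng = np.random.default_rng(5)
        draws = sd._nb_draw(rng, np.full(10_000, 100.0), np.full(10_000, phi))
        expected_var = 100.0 + phi * 100.0 ** 2
        assert draws.var() == pytest.approx(expected_var, rel=0.1)
        assert draws.mean() == pytest.approx(100.0, rel=0.02)

    def test_cis_effect_doubles_mean_inside_introgression(self):
        genome = sd.make_genome(1, 10, 300, seed=6)
        panel = sd.make_il_panel(genome, 2, overlap_frac=0.0, seed=6)
        il = panel[0]
        gene = next(g for g in genome.genes if il.contains_gene(g))
        truth = sd.SimTruth(cis_effects={gene.gene_id: 1.0},
                            dispersions={g: 1e-9 for g in genome.gene_ids})
        m = sd.simulate_expression(panel, genome, truth, n_reps=200,
                                   lib_size_cv=0.0, seed=6)
        geno = m.samples["genotype"]
        mean_il = m.counts.loc[gene.gene_id, (geno == il.il_id).to_numpy()].mean()
        mean_ref = m.counts.loc[gene.gene_id, (geno == "M82").to_numpy()].mean()
        assert mean_il / mean_ref == pytest.approx(2.0, rel=0.1)


class TestSimulateTrait:
    def test_zero_variance_reduces_to_baseline(self, small_genome, small_panel):
        truth = sd.SimTruth(dispersions={})
        rec = sd.simulate_trait(small_panel, small_genome, truth, n_seedlings=4,
                                sd_germ_age=0, sd_plate_date=0, sd_resid=0,
                                collide_shift=0, baseline=25.0, seed=1)
        assert np.allclose(rec["trait"], 25.0)

    def test_planted_effect_shifts_group_mean(self, small_genome, small_panel,
                                              small_truth):
        rec = sd.simulate_trait(small_panel, small_genome, small_truth,
                                n_seedlings=400, seed=2)
        carrier = next(il.il_id for il in small_panel
                       if sd.genotype_trait_shift(il, small_genome, small_truth) > 0)
        diff = (rec.loc[rec.genotype == carrier, "trait"].mean()
                - rec.loc[rec.genotype == "M82", "trait"].mean())
        assert diff == pytest.approx(8.0, abs=1.5)

    def test_metadata_columns_present(self, small_genome, small_panel, small_truth):
        rec = sd.simulate_trait(small_panel, small_genome, small_truth,
                                n_seedlings=3, seed=3)
        assert {"germAge", "plateDate", "collide", "along"} <= set(rec.columns)
        with pytest.raises(ValueError):
            sd.simulate_trait(small_panel, small_genome, small_truth, n_seedlings=1)


class TestSimulateTipAngles:
    def test_flat_series_without_response_or_noise(self):
        out = sd.simulate_tip_angle_series({"M82": (0.0, 0.0, 0.0)}, n_roots=3,
                                           noise_sd=0.0, a0_sd=5.0, seed=1)
        for s in out:
            assert np.allclose(s.angles, s.angles[0])

    def test_noise_free_swing_rate_matches_closed_form(self):
        rate, amp, lag = 0.05, 30.0, 7.5   # lag on the sampling grid
        out = sd.simulate_tip_angle_series({"g": (rate, amp, lag)}, n_roots=1,
                                           noise_sd=0.0, a0_sd=0.0, seed=2)
        s = out[0]
        r = rt.swing_rate(s)
        dt = s.dt
        k = int(lag / dt)              # first step after the lag
        expected = amp * (1 - np.exp(-rate * dt)) / dt   # closed-form difference
        assert r.rates[k] == pytest.approx(expected, rel=1e-9)
        # for small rate·dt the discrete rate approximates amplitude·rate
        assert r.rates[k] == pytest.approx(amp * rate, rel=rate * dt)

    def test_rotation_classes_both_occur(self):
        out = sd.simulate_tip_angle_series({"g": (0.05, 30, 0)}, n_roots=50,
                                           noise_sd=0.5, a0_sd=8.0, seed=3)
        classes = {s.rotation_class for s in out}
        assert classes == {"through", "away"}

    def test_negative_params_rejected(self):
        with pytest.raises(ValueError):
            sd.simulate_tip_angle_series({"g": (-0.1, 30, 0)}, n_roots=1)


class TestSimulateReads:
    def test_clean_reads_all_kept(self, small_genome):
        recs, truth = sd.simulate_reads(small_genome, None, "ACGTAC", 200, seed=1)
        assert (truth["expected_fate"] == "kept").all()
        assert all(seq.startswith("ACGTAC") for _, seq, _ in recs)

    def test_planted_polyn_and_short_fates(self, small_genome):
        cfg = sd.ContaminationConfig(polyn_rate=0.5, short_rate=0.5)
        recs, truth = sd.simulate_reads(small_genome, None, "ACGTAC", 100, cfg, seed=2)
        assert set(truth["reason"]) <= {"polyN", "short"}
        polyn = truth[truth.reason == "polyN"]
        assert (polyn["expected_fate"] == "discarded").all()
        for rid in polyn["read_id"]:
            seq = next(s for i, s, _ in recs if i == rid)
            assert "N" * 15 in seq

    def test_empty_barcode_rejected(self, small_genome):
        with pytest.raises(ValueError):
            sd.simulate_reads(small_genome, None, "", 10)

    def test_donor_allele_inside_introgression(self, small_genome, small_panel):
        il = small_panel[0]
        recs, truth = sd.simulate_reads(small_genome, il, "ACGTAC", 300, seed=4)
        genes = {g.gene_id: g for g in small_genome.genes}
        for _, row in truth.iterrows():
            inside = il.contains_gene(genes[row.source_gene])
            assert row.source_allele == ("donor" if inside else "recurrent")


class TestPlateLayout:
    def test_study_design_arithmetic(self):
        genotypes = [f"IL{i}" for i in range(77)] + ["M82", "PENN"]
        layout = sd.make_plate_layout(genotypes, ("M82", "PENN"), seed=9)
        assert layout.n_plates == 162
        assert layout.empty_positions == 6

    def test_conservation_and_determinism(self):
        genotypes = [f"IL{i}" for i in range(40)] + ["M82", "PENN"]
        l1 = sd.make_plate_layout(genotypes, ("M82", "PENN"), seed=5)
        l2 = sd.make_plate_layout(genotypes, ("M82", "PENN"), seed=5)
        assert l1.assignments == l2.assignments
        assert l1.n_plates + l1.empty_positions == sd.PLATE_CAPACITY
        # each non-parent genotype's 2 plates share one pair-slot
        frame = l1.to_frame()
        for geno, grp in frame[~frame.genotype.isin(["M82", "PENN"])].groupby("genotype"):
            assert len(grp) == 2
            assert grp[["holder", "slot"]].drop_duplicates().shape[0] == 1

    def test_capacity_error(self):
        with pytest.raises(ValueError):
            sd.make_plate_layout([f"g{i}" for i in range(90)], ("a", "b"))


class TestTruthLedger:
    def test_roundtrip(self, tmp_path, small_truth):
        p = tmp_path / "truth.json"
        small_truth.to_json(p)
        back = sd.SimTruth.from_json(p)
        assert back.cis_effects == small_truth.cis_effects
        assert back.trans_effects == small_truth.trans_effects
        assert back.causal_gene == small_truth.causal_gene

    def test_invariants(self):
        with pytest.raises(ValueError):
            sd.SimTruth(dispersions={"g": -1.0})
        with pytest.raises(ValueError):
            sd.SimTruth(causal_gene="g", cis_effects={})
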