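"""FDR machinery, the angle mixed model, per-timepoint tests, and runs."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from rootqtl import synthetic_data as sd, trait_qtl as tq


def bh_oracle(p):
    """Definitional step-up: q_i = min over k with p(k) ≥ p(i) of p(k)·m/k."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q[i] = min(running, 1.0)
    return q


class TestBHAdjust:
    @pytest.mark.parametrize("p, expected", [
        ([0.03], [0.03]),
        ([0.01] * 10, [0.01] * 10),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
    ])
    def test_worked_examples(self, p, expected):
        assert np.allclose(tq.bh_adjust(p), expected)

    def test_invalid_pvalues(self):
        with pytest.raises(ValueError):
            tq.bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(deadline=None, derandomize=True)
    def test_matches_definitional_oracle(self, p):
        assert np.allclose(tq.bh_adjust(p), bh_oracle(p), atol=1e-12)


def make_records(effects, n=30, sd_resid=0.0, seed=0, collide_beta=0.0):
    rng = np.random.default_rng(seed)
    rows = []
    for geno, eff in effects.items():
        for i in range(n):
            ga = int(rng.integers(3, 6))
            pd_ = f"D{int(rng.integers(1, 5))}"
            collide = bool(rng.random() < 0.2)
            y = 20 + eff + collide_beta * collide + rng.normal(0, sd_resid)
            rows.append((geno, y, ga, pd_, collide, False))
    return pd.DataFrame(rows, columns=["genotype", "trait", "germAge",
                                       "plateDate", "collide", "along"])


class TestTraitModel:
    def test_noise_free_effect_recovered(self):
        rec = make_records({"M82": 0.0, "IL1": 10.0}, sd_resid=0.0)
        fit = tq.fit_trait_model(rec, "M82")
        assert fit.effects.loc["IL1", "effect"] == pytest.approx(10.0, abs=1e-6)
        assert fit.effects.loc["IL1", "q"] < 1e-10

    def test_null_genotype_not_significant(self):
        rec = make_records({"M82": 0.0, "IL1": 0.0}, n=120, sd_resid=5.0, seed=4)
        fit = tq.fit_trait_model(rec, "M82")
        assert abs(fit.effects.loc["IL1", "effect"]) < 2.5
        assert not fit.effects.loc["IL1", "significant"]

    def test_collide_term_absorbs_contact_shift(self):
        rec = make_records({"M82": 0.0, "IL1": 6.0}, n=200, sd_resid=1.0,
                           seed=5, collide_beta=8.0)
        fit = tq.fit_trait_model(rec, "M82")
        assert fit.effects.loc["IL1", "effect"] == pytest.approx(6.0, abs=0.6)

    def test_single_level_random_factor_dropped(self):
        rec = make_records({"M82": 0.0, "IL1": 3.0}, n=20, sd_resid=1.0, seed=6)
        rec["germAge"] = 4
        with pytest.warns(UserWarning):
            fit = tq.fit_trait_model(rec, "M82")
        assert "germAge" in fit.dropped_terms

    def test_reference_must_exist(self):
        rec = make_records({"A": 0.0, "B": 1.0})
        with pytest.raises(ValueError):
            tq.fit_trait_model(rec, "M82")


def rate_frame(groups, n_tp=10, seed=0):
    """groups: genotype → (n_roots, per-timepoint mean shift array or scalar)."""
    rng = np.random.default_rng(seed)
    rows = []
    for geno, (n, shift) in groups.items():
        shift = np.broadcast_to(np.asarray(shift, dtype=float), (n_tp,))
        for i in range(n):
            vals = shift + rng.normal(0, 1.0, size=n_tp)
            rows.append({"root_id": f"{geno}{i}", "genotype": geno,
                         **{f"T{k + 1}": v for k, v in enumerate(vals)}})
    return pd.DataFrame(rows)


class TestPerTimepointTests:
    def test_identical_groups_p_one(self):
        df = rate_frame({"M82": (4, 0.0), "IL1": (4, 0.0)}, seed=1)
        for tp in [c for c in df.columns if c.startswith("T")]:
            df[tp] = 1.0                        # all values identical
        m = tq.per_timepoint_tests(df, "M82")
        assert (m.p.to_numpy() == 1.0).all()

    def test_two_groups_reduce_to_t_test(self):
        df = rate_frame({"M82": (6, 0.0), "IL1": (7, 0.5)}, seed=2)
        m = tq.per_timepoint_tests(df, "M82")
        from scipy import stats
        for tp in m.timepoints:
            a = df.loc[df.genotype == "IL1", tp]
            b = df.loc[df.genotype == "M82", tp]
            t, p = stats.ttest_ind(a, b, equal_var=True)
            assert m.p.loc["IL1", tp] == pytest.approx(p, abs=1e-10)

    def test_windowed_effect_detected(self):
        shift = np.zeros(10)
        shift[4:8] = 2.5
        df = rate_frame({"M82": (25, 0.0), "IL1": (25, shift)}, seed=3)
        m = tq.per_timepoint_tests(df, "M82")
        sig = m.q.loc["IL1"] <= 0.05
        assert sig[["T5", "T6", "T7", "T8"]].all()
        assert not sig[["T1", "T2", "T3", "T10"]].any()


def runs_oracle(sig, min_run):
    """Brute force: scan all windows, keep maximal all-significant ones."""
    n = len(sig)
    runs = []
    for i in range(n):
        for j in range(i, n):
            if all(sig[i:j + 1]) and j - i + 1 >= min_run:
                if (i == 0 or not sig[i - 1]) and (j == n - 1 or not sig[j + 1]):
                    runs.append((i, j))
    return sorted(set(runs))


class TestConsecutiveRuns:
    def matrix(self, qrow, effects=None):
        tps = [f"T{k}" for k in range(len(qrow))]
        q = pd.DataFrame([qrow], index=["IL1"], columns=tps)
        eff = pd.DataFrame([effects or [1.0] * len(qrow)], index=["IL1"], columns=tps)
        return tq.TimepointTestMatrix(eff, q.copy(), q, "M82")

    def test_simple_run(self):
        m = self.matrix([0.04, 0.04, 0.04, 0.2, 0.2, 0.2])
        calls = tq.consecutive_runs(m)
        assert len(calls) == 1
        assert (calls[0].run_start, calls[0].run_end) == (0, 2)
        assert calls[0].phase == "early" and calls[0].direction == "faster"

    def test_short_runs_ignored(self):
        m = self.matrix([0.04, 0.04, 0.2, 0.04, 0.04, 0.2])
        assert tq.consecutive_runs(m) == []

    def test_slower_direction_and_phase(self):
        qrow = [0.2] * 34
        qrow[20:25] = [0.01] * 5
        effects = [0.0] * 34
        effects[20:25] = [-1.0] * 5
        m = self.matrix(qrow, effects)
        (call,) = tq.consecutive_runs(m)
        assert call.phase == "late" and call.direction == "slower"

    @given(st.lists(st.booleans(), min_size=5, max_size=34),
           st.integers(2, 4))
    @settings(deadline=None, derandomize=True)
    def test_matches_window_scan_oracle(self, sig, min_run):
        qrow = [0.01 if s else 0.5 for s in sig]
        m = self.matrix(qrow)
        calls = tq.consecutive_runs(m, q_threshold=0.05, min_run=min_run)
        got = sorted((c.run_start, c.run_end) for c in calls)
        assert got == runs_oracle(sig, min_run)


class TestOverlapAndCorrelation:
    def test_overlap_partitions(self):
        out = tq.trait_overlap({"a", "b", "c"}, {"c", "d"})
        assert out == {"angle_only": {"a", "b"}, "gravi_only": {"d"},
                       "shared": {"c"}}
        assert tq.trait_overlap({"a"}, {"b"})["shared"] == set()
        assert tq.trait_overlap({"a"}, {"a"}) == {"angle_only": set(),
                                                  "gravi_only": set(),
                                                  "shared": {"a"}}

    def test_perfect_and_missing_correlation(self):
        angles = pd.Series({"g1": 10.0, "g2": 20.0, "g3": 30.0, "g4": 40.0})
        rates = pd.DataFrame({"T1": angles * 0.3 + 2, "T2": [1, 1, 1, 1]},
                             index=angles.index)
        r2 = tq.correlate_trait_with_timepoints(angles, rates)
        assert r2["T1"] == pytest.approx(1.0)
        assert np.isnan(r2["T2"])

    def test_null_mean_r2(self):
        rng = np.random.default_rng(8)
        n = 12
        angles = pd.Series(rng.normal(size=n), index=[f"g{i}" for i in range(n)])
        rates = pd.DataFrame(rng.normal(size=(n, 200)), index=angles.index,
                             columns=[f"T{k}" for k in range(200)])
        r2 = tq.correlate_trait_with_timepoints(angles, rates)
        # E[R²] under independence is 1/(n−1)
        assert r2.mean() == pytest.approx(1 / (n - 1), abs=0.03)


class TestFixedModelPlate:
    def frame(self, geno_shift=0.0, plate_shift=0.0, interaction=0.0,
              noise=0.0, n=12, seed=0):
        rng = np.random.default_rng(seed)
        rows = []
        for geno in ("ctrl", "line"):
            for plate in (1, 2):
                for _ in range(n):
                    y = (10 + geno_shift * (geno == "line")
                         + plate_shift * (plate == 2)
                         + interaction * (geno == "line") * (plate == 2)
                         + rng.normal(0, noise))
                    rows.append((geno, plate, y))
        return pd.DataFrame(rows, columns=["genotype", "plate", "angle"])

    def test_pure_genotype_effect(self):
        table = tq.fixed_model_plate(self.frame(geno_shift=10.0, noise=0.01, seed=1))
        assert table.loc["C(genotype)", "PR(>F)"] < 1e-10
        assert table.loc["C(genotype):C(plate)", "F"] == pytest.approx(0.0, abs=1.0)

    def test_pure_plate_effect_leaves_genotype_null(self):
        table = tq.fixed_model_plate(self.frame(plate_shift=5.0, noise=1.0,
                                                n=60, seed=2))
        assert table.loc["C(genotype)", "PR(>F)"] > 0.05

    def test_interaction_recovered(self):
        df = self.frame(geno_shift=2.0, interaction=4.0, noise=1.0, n=100, seed=3)
        table = tq.fixed_model_plate(df)
        assert table.loc["C(genotype):C(plate)", "PR(>F)"] < 1e-6

    def test_empty_cell_rejected(self):
        df = self.frame(n=4)
        df = df[~((df.genotype == "line") & (df.plate == 2))]
        with pytest.raises(ValueError):
            tq.fixed_model_plate(df)
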