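"""Stage-2 pairwise ΔCT screen: averaging, filtering, t-matrices, selection."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from exopair import (CtDataset, PairPvalueMatrix, SelectionCriteria,
                     average_replicates, delta_ct, filter_ct_ceiling,
                     generate_ct_dataset, generate_ct_replicates,
                     permutation_pvalue, pvalue_matrix, run_screen,
                     screening_scenario, select_pairs, stricter_screen)

from conftest import make_ct_dataset


def long_records(rows):
    return pd.DataFrame(rows, columns=["sample_id", "group", "centre",
                                       "mirna_id", "replicate", "ct"])


class TestAverageReplicates:
    def test_arithmetic_mean_of_triplicate(self):
        raw = long_records([("s1", "KD", "C1", "mA", r, ct)
                            for r, ct in enumerate([25.0, 25.2, 25.4], 1)])
        ds = average_replicates(raw)
        assert ds.values.loc["s1", "mA"] == pytest.approx(25.2)
        assert ds.replicate_counts.loc["s1", "mA"] == 3

    def test_single_replicate_is_identity(self):
        raw = long_records([("s1", "KD", "C1", "mA", 1, 30.1)])
        ds = average_replicates(raw)
        assert ds.values.loc["s1", "mA"] == pytest.approx(30.1)

    def test_matches_independent_recomputation(self):
        """Per-cell means agree with a second, per-cell brute-force path."""
        raw, _ = generate_ct_replicates(screening_scenario(seed=21))
        ds = average_replicates(raw, n_replicates=3)
        for sample, mirna in [("KD-003", "miR-1246"),
                              ("Normal-017", "miR-328"),
                              ("ADV-002", "miR-sim-10")]:
            sel = (raw["sample_id"] == sample) & (raw["mirna_id"] == mirna)
            expected = raw.loc[sel, "ct"].sum() / sel.sum()
            assert ds.values.loc[sample, mirna] == pytest.approx(expected,
                                                                 abs=1e-12)

    def test_all_missing_cell_is_masked(self):
        raw = long_records([("s1", "KD", "C1", "mA", 1, np.nan),
                            ("s1", "KD", "C1", "mB", 1, 24.0)])
        ds = average_replicates(raw)
        assert np.isnan(ds.values.loc["s1", "mA"])

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="centre"):
            average_replicates(pd.DataFrame({"sample_id": [], "group": [],
                                             "mirna_id": [], "replicate": [],
                                             "ct": []}))


class TestCtCeiling:
    def test_single_high_sample_removes_whole_mirna(self):
        ds = make_ct_dataset([[30.0, 28.0], [35.2, 29.0]], ["KD", "KD"],
                             mirnas=["miR-X", "miR-Y"])
        filtered, removed = filter_ct_ceiling(ds)
        assert removed == ["miR-X"]
        assert filtered.mirna_ids == ["miR-Y"]

    def test_ct_exactly_35_is_retained(self):
        ds = make_ct_dataset([[35.0], [30.0]], ["KD", "KD"])
        filtered, removed = filter_ct_ceiling(ds)
        assert removed == []
        assert filtered.mirna_ids == ds.mirna_ids

    def test_clean_dataset_unchanged(self):
        ds = make_ct_dataset([[30.0, 28.0], [31.0, 29.0]], ["KD", "Normal"])
        filtered, removed = filter_ct_ceiling(ds)
        assert removed == []
        pd.testing.assert_frame_equal(filtered.values, ds.values)

    def test_everything_removed_is_an_error(self):
        ds = make_ct_dataset([[36.0], [37.0]], ["KD", "KD"])
        with pytest.raises(ValueError, match="no quantifiable"):
            filter_ct_ceiling(ds)


class TestDeltaCt:
    def test_plain_arithmetic(self):
        ds = make_ct_dataset([[28.4, 25.1]], ["KD"], mirnas=["i", "j"])
        assert delta_ct(ds, "i", "j").iloc[0] == pytest.approx(3.3)

    def test_antisymmetry(self):
        ds = make_ct_dataset(np.random.default_rng(0).normal(25, 2, (6, 3)),
                             ["KD"] * 6)
        np.testing.assert_allclose(delta_ct(ds, "m1", "m2"),
                                   -delta_ct(ds, "m2", "m1"))

    def test_per_sample_offset_cancels(self):
        ds = make_ct_dataset([[28.0, 25.0], [26.0, 24.0]], ["KD", "KD"])
        shifted = make_ct_dataset([[30.7, 27.7], [26.0, 24.0]], ["KD", "KD"])
        np.testing.assert_allclose(delta_ct(ds, "m1", "m2"),
                                   delta_ct(shifted, "m1", "m2"))

    def test_self_reference_rejected(self):
        ds = make_ct_dataset([[25.0]], ["KD"])
        with pytest.raises(ValueError, match="self-reference"):
            delta_ct(ds, "m1", "m1")

    def test_masked_samples_dropped(self):
        ds = make_ct_dataset([[28.0, np.nan], [26.0, 24.0]], ["KD", "KD"])
        d = delta_ct(ds, "m1", "m2")
        assert list(d.index) == ["s2"]


class TestPvalueMatrix:
    def dataset_for(self, x, y):
        """Two miRNAs whose ΔCT equals the given per-group samples."""
        vals = [[25.0 + v, 25.0] for v in x] + [[25.0 + v, 25.0] for v in y]
        return make_ct_dataset(vals, ["X"] * len(x) + ["Y"] * len(y))

    def test_frozen_pooled_t_example(self):
        """ΔCT {1,2,3} vs {4,5,6}: pooled t = −3.674 (df 4), p ≈ 0.0213;
        the exhaustive 20-relabeling enumeration ranks this split most
        extreme (permutation p = 2/20)."""
        ds = self.dataset_for([1, 2, 3], [4, 5, 6])
        mat = pvalue_matrix(ds, "X", "Y")
        assert mat.tstats[0, 1] == pytest.approx(-3.674, abs=1e-3)
        assert mat.pvalue("m1", "m2") == pytest.approx(0.02131, abs=1e-4)
        assert permutation_pvalue(np.array([1, 2, 3]),
                                  np.array([4, 5, 6])) == pytest.approx(2 / 20)

    def test_matches_scipy_ttest(self):
        ds, _ = generate_ct_dataset(screening_scenario(seed=2))
        mat = pvalue_matrix(ds, "KD", "Normal")
        kd = ds.group_values("KD").to_numpy()
        nm = ds.group_values("Normal").to_numpy()
        for i, j in [(0, 1), (3, 7), (10, 2)]:
            ref = stats.ttest_ind(kd[:, i] - kd[:, j], nm[:, i] - nm[:, j])
            assert mat.pvalues[i, j] == pytest.approx(ref.pvalue, rel=1e-10)
            assert mat.tstats[i, j] == pytest.approx(ref.statistic, rel=1e-10)

    def test_welch_variant_matches_scipy(self):
        ds, _ = generate_ct_dataset(screening_scenario(seed=2))
        mat = pvalue_matrix(ds, "KD", "ADV", equal_var=False)
        kd = ds.group_values("KD").to_numpy()
        adv = ds.group_values("ADV").to_numpy()
        ref = stats.ttest_ind(kd[:, 0] - kd[:, 4], adv[:, 0] - adv[:, 4],
                              equal_var=False)
        assert mat.pvalues[0, 4] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_symmetry_and_diagonal(self):
        ds, _ = generate_ct_dataset(screening_scenario(seed=3))
        mat = pvalue_matrix(ds, "KD", "+IVIG")
        off = ~np.eye(len(mat.mirna_ids), dtype=bool)
        np.testing.assert_allclose(mat.pvalues[off], mat.pvalues.T[off],
                                   atol=1e-12)
        assert np.isnan(np.diag(mat.pvalues)).all()

    def test_degenerate_equal_groups_give_p_one(self):
        ds = self.dataset_for([1.0, 1.0], [1.0, 1.0])
        mat = pvalue_matrix(ds, "X", "Y")
        assert mat.pvalues[0, 1] == 1.0
        assert mat.degenerate[0, 1]

    def test_degenerate_separated_groups_give_p_zero(self):
        ds = self.dataset_for([1.0, 1.0], [4.0, 4.0])
        mat = pvalue_matrix(ds, "X", "Y")
        assert mat.pvalues[0, 1] == 0.0
        assert mat.degenerate[0, 1]

    def test_too_small_group_rejected(self):
        ds = self.dataset_for([1.0, 2.0], [3.0])
        with pytest.raises(ValueError, match=">= 2 samples"):
            pvalue_matrix(ds, "X", "Y")

    def test_missing_values_use_pairwise_complete_cases(self):
        vals = np.array([[25.0, 24.0, 23.0], [26.0, 25.5, np.nan],
                         [27.0, 24.5, 22.0], [25.5, 26.0, 21.0],
                         [28.0, 25.0, 24.0], [26.5, 24.0, np.nan]])
        ds = make_ct_dataset(vals, ["X", "X", "X", "Y", "Y", "Y"])
        mat = pvalue_matrix(ds, "X", "Y")
        # (m1, m3): sample s2 and s6 dropped -> 2 vs 2 complete cases
        d13_x = [25.0 - 23.0, 27.0 - 22.0]
        d13_y = [25.5 - 21.0, 28.0 - 24.0]
        ref = stats.ttest_ind(d13_x, d13_y)
        assert mat.pvalues[0, 2] == pytest.approx(ref.pvalue, rel=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.lists(st.floats(-3, 3), min_size=10, max_size=10))
def test_global_sample_offsets_change_nothing(offsets):
    """Adding an arbitrary constant per sample to all of that sample's CTs
    leaves every p-value unchanged to 1e-9 — the self-referencing
    robustness guarantee."""
    ds, _ = generate_ct_dataset(screening_scenario(seed=17))
    shift = pd.Series(0.0, index=ds.values.index)
    shift.iloc[:len(offsets)] = offsets
    shifted = CtDataset(ds.values.add(shift, axis=0), ds.groups, ds.centres)
    m0 = pvalue_matrix(ds, "KD", "Normal")
    m1 = pvalue_matrix(shifted, "KD", "Normal")
    assert np.nanmax(np.abs(m0.pvalues - m1.pvalues)) < 1e-9


class TestSelectPairs:
    def matrices_from(self, p_by_comp, ids=("a", "b", "c")):
        """Build symmetric p-value matrices from an upper-triangle dict."""
        out = {}
        for comp, tri in p_by_comp.items():
            m = len(ids)
            P = np.full((m, m), np.nan)
            for (i, j), p in tri.items():
                P[i, j] = P[j, i] = p
            out[comp] = PairPvalueMatrix(
                comparison=comp, mirna_ids=list(ids), pvalues=P,
                tstats=np.full((m, m), np.nan),
                degenerate=np.zeros((m, m), dtype=bool))
        return out

    CRIT = SelectionCriteria(alpha=0.01,
                             require_significant=(("KD", "Normal"),
                                                  ("KD", "+IVIG")),
                             require_nonsignificant=(("Normal", "ADV"),))

    def test_unique_forward_pair_selected(self):
        mats = self.matrices_from({
            ("KD", "Normal"): {(0, 1): 1e-5, (0, 2): 1e-5, (1, 2): 0.5},
            ("KD", "+IVIG"): {(0, 1): 1e-4, (0, 2): 0.2, (1, 2): 0.5},
            ("Normal", "ADV"): {(0, 1): 0.8, (0, 2): 0.9, (1, 2): 0.9}})
        pairs = select_pairs(mats, self.CRIT)
        assert len(pairs) == 1
        assert pairs[0].trend == "forward"
        assert pairs[0].unordered == frozenset(("a", "b"))

    def test_opposite_trend_pair_selected(self):
        mats = self.matrices_from({
            ("KD", "Normal"): {(0, 1): 0.5, (0, 2): 1e-6, (1, 2): 1e-6},
            ("KD", "+IVIG"): {(0, 1): 0.4, (0, 2): 1e-6, (1, 2): 1e-6},
            ("Normal", "ADV"): {(0, 1): 1e-4, (0, 2): 1e-5, (1, 2): 1e-5}})
        pairs = select_pairs(mats, self.CRIT)
        assert [p.trend for p in pairs] == ["opposite"]
        assert pairs[0].unordered == frozenset(("a", "b"))

    def test_alpha_one_selects_nothing(self):
        """With alpha = 1 no p-value can strictly exceed alpha, so the
        non-significance requirement is unsatisfiable."""
        mats = self.matrices_from({
            ("KD", "Normal"): {(0, 1): 1e-9, (0, 2): 1e-9, (1, 2): 1e-9},
            ("KD", "+IVIG"): {(0, 1): 1e-9, (0, 2): 1e-9, (1, 2): 1e-9},
            ("Normal", "ADV"): {(0, 1): 0.99, (0, 2): 0.5, (1, 2): 0.1}})
        crit = SelectionCriteria(alpha=0.999999,
                                 require_significant=self.CRIT.require_significant,
                                 require_nonsignificant=self.CRIT.require_nonsignificant)
        assert select_pairs(mats, crit) == []

    def test_orientation_prefers_larger_ct_shift(self):
        mats = self.matrices_from({
            ("KD", "Normal"): {(0, 1): 1e-5, (0, 2): 0.9, (1, 2): 0.9},
            ("KD", "+IVIG"): {(0, 1): 1e-5, (0, 2): 0.9, (1, 2): 0.9},
            ("Normal", "ADV"): {(0, 1): 0.9, (0, 2): 0.9, (1, 2): 0.9}})
        pairs = select_pairs(mats, self.CRIT,
                             orientation={"a": -0.5, "b": -4.0, "c": 0.0})
        assert (pairs[0].target, pairs[0].reference) == ("b", "a")

    def test_mismatched_mirna_sets_rejected(self):
        mats = self.matrices_from({
            ("KD", "Normal"): {(0, 1): 0.5}, ("KD", "+IVIG"): {(0, 1): 0.5},
            ("Normal", "ADV"): {(0, 1): 0.5}}, ids=("a", "b"))
        other = self.matrices_from({("Normal", "ADV"): {(0, 1): 0.5}},
                                   ids=("a", "z"))
        mats[("Normal", "ADV")] = other[("Normal", "ADV")]
        with pytest.raises(ValueError, match="different miRNA sets"):
            select_pairs(mats, self.CRIT)

    def test_missing_comparison_rejected(self):
        mats = self.matrices_from({("KD", "Normal"): {(0, 1): 0.5}})
        with pytest.raises(ValueError, match="no p-value matrix"):
            select_pairs(mats, self.CRIT)


class TestStricterScreen:
    def test_no_pairs_below_strict_alpha(self):
        P = np.full((4, 4), 0.5)
        np.fill_diagonal(P, np.nan)
        mat = PairPvalueMatrix(("KD", "Normal"), list("abcd"), P,
                               np.full((4, 4), np.nan),
                               np.zeros((4, 4), bool))
        assert stricter_screen(mat, 1e-4) == 0

    def test_transpose_invariance(self):
        rng = np.random.default_rng(6)
        P = rng.uniform(0, 1, (5, 5))
        P = (P + P.T) / 2
        np.fill_diagonal(P, np.nan)
        mat = PairPvalueMatrix(("KD", "Normal"), list("abcde"), P,
                               np.full((5, 5), np.nan),
                               np.zeros((5, 5), bool))
        mat_t = PairPvalueMatrix(("KD", "Normal"), list("abcde"), P.T.copy(),
                                 np.full((5, 5), np.nan),
                                 np.zeros((5, 5), bool))
        assert stricter_screen(mat, 0.3) == stricter_screen(mat_t, 0.3)

    def test_planted_strong_pairs_counted_at_1e4(self):
        """Strongly planted effects survive a 1e-4 stringency screen."""
        ds, truth = generate_ct_dataset(screening_scenario(seed=23))
        mat = pvalue_matrix(ds, "KD", "Normal")
        assert mat.pvalue("miR-1246", "miR-4436b-5p") < 1e-4
        assert stricter_screen(mat, 1e-4) >= 1


def test_end_to_end_screen_recovers_planted_pairs(screening_dataset):
    ds, truth = screening_dataset
    pairs, mats, removed = run_screen(ds, SelectionCriteria())
    got = {(p.unordered, p.trend) for p in pairs}
    expected = {(frozenset((t, r)), trend)
                for t, r, trend in truth.expected_pairs}
    assert got == expected
    # the forward pair is oriented with the strongly shifted miRNA as target
    fwd = [p for p in pairs if p.trend == "forward"][0]
    assert (fwd.target, fwd.reference) == ("miR-1246", "miR-4436b-5p")
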