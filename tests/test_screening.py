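"""Unit and property tests of the marker-screening cascade."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from necsig.screening import (
    ScreeningThresholds,
    bky_fdr,
    candidate_set,
    filter_missingness,
    fold_change_ratio,
    folded_auc,
    impute_zeros,
    mann_whitney_p,
    missingness_quantified_threshold,
    screen_markers,
)
from conftest import make_matrix


def brute_force_auc(case: np.ndarray, ctrl: np.ndarray) -> float:
    """All-pairs counting oracle: wins + half ties over n1*n2 comparisons."""
    wins = sum(c > k for c in case for k in ctrl)
    ties = sum(c == k for c in case for k in ctrl)
    return (wins + 0.5 * ties) / (len(case) * len(ctrl))


class TestMissingnessFilter:
    @pytest.mark.parametrize(
        "n_samples,expected_min_quantified",
        [(42, 38), (40, 37), (30, 28), (10, 10), (12, 11)],
    )
    def test_strict_ten_percent_bound(self, n_samples, expected_min_quantified):
        assert missingness_quantified_threshold(n_samples) == expected_min_quantified

    def test_rows_at_the_boundary(self):
        values = np.ones((3, 42))
        mask = np.zeros((3, 42), dtype=bool)
        mask[1, :4] = True   # 38 quantified -> kept
        mask[2, :5] = True   # 37 quantified -> dropped
        values[mask] = np.nan
        kept = filter_missingness(make_matrix(values, mask))
        assert list(kept.protein_ids) == ["P000", "P001"]


class TestImputeZeros:
    def test_missing_cells_become_zero_and_counts_sum(self):
        values = np.arange(12, dtype=float).reshape(3, 4) + 1
        mask = np.zeros_like(values, dtype=bool)
        mask[0, 1] = mask[2, 3] = True
        values[mask] = np.nan
        out = impute_zeros(make_matrix(values, mask))
        assert out.values[0, 1] == 0.0 and out.values[2, 3] == 0.0
        assert out.missing_mask.sum() == 2

    def test_identity_without_missing(self):
        values = np.arange(6, dtype=float).reshape(2, 3)
        out = impute_zeros(make_matrix(values))
        np.testing.assert_array_equal(out.values, values)


class TestFoldedAuc:
    def test_example_three_wins_one_loss(self):
        res = folded_auc(np.array([3.0, 1.0, 2.0, 0.0]),
                         np.array([True, True, False, False]))
        assert res.auc == pytest.approx(0.75) and res.direction == "up"

    def test_all_ties_give_half(self):
        res = folded_auc(np.ones(8), np.array([True] * 4 + [False] * 4))
        assert res.auc == 0.5 and res.direction == "up"

    def test_perfect_separation_with_lower_cases_folds_down(self):
        res = folded_auc(np.array([1.0, 2.0, 10.0, 11.0]),
                         np.array([True, True, False, False]))
        assert res.auc == 1.0 and res.direction == "down"

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            folded_auc(np.array([1.0, 2.0]), np.array([True, True]))

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
        st.lists(st.integers(0, 8), min_size=1, max_size=12),
    )
    def test_matches_all_pairs_counting_exactly(self, case, ctrl):
        values = np.array(case + ctrl, dtype=float)
        labels = np.array([True] * len(case) + [False] * len(ctrl))
        raw = brute_force_auc(np.array(case), np.array(ctrl))
        res = folded_auc(values, labels)
        assert res.auc == pytest.approx(max(raw, 1 - raw), abs=1e-12)

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=10),
        st.lists(st.floats(-5, 5, allow_nan=False), min_size=2, max_size=10),
    )
    def test_relates_to_mann_whitney_u(self, case, ctrl):
        """Raw AUC equals U / (n1 n2) with U from the rank-sum statistic."""
        values = np.array(case + ctrl)
        labels = np.array([True] * len(case) + [False] * len(ctrl))
        u = sps.mannwhitneyu(case, ctrl, alternative="two-sided").statistic
        raw = u / (len(case) * len(ctrl))
        assert folded_auc(values, labels).auc == pytest.approx(max(raw, 1 - raw))


class TestMannWhitney:
    def test_symmetric_groups_give_p_one(self):
        assert mann_whitney_p(np.array([1.0, 2.0, 1.0, 2.0]),
                              np.array([True, True, False, False])) == 1.0

    def test_exact_two_sided_small_sample(self):
        # {4,5,6} vs {1,2,3}: U = 9, the most extreme of C(6,3) = 20 arrangements
        p = mann_whitney_p(np.array([4.0, 5, 6, 1, 2, 3]),
                           np.array([True, True, True, False, False, False]))
        assert p == pytest.approx(0.1)

    def test_invariant_to_monotone_transform(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=20)
        labels = rng.random(20) < 0.5
        labels[:2], labels[-2:] = True, False
        assert mann_whitney_p(values, labels) == pytest.approx(
            mann_whitney_p(np.exp(values), labels)
        )


def bky_two_stage_oracle(p: np.ndarray, alpha: float = 0.05) -> np.ndarray:
    """Literal hand-coded two-stage step-up procedure (independent oracle).

    Stage 1: Benjamini-Hochberg at alpha' = alpha/(1+alpha) estimates the
    number of true nulls m0 = m - r1.  Adjusted q-values are the BH
    step-up values scaled by m0/m (skipped when stage 1 rejects none or
    all) and by (1+alpha), clipped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    sorted_p = p[order]

    def bh_adjust(ps):
        adj = ps * m / np.arange(1, m + 1)
        for i in range(m - 2, -1, -1):
            adj[i] = min(adj[i], adj[i + 1])
        return np.minimum(adj, 1.0)

    alpha_prime = alpha / (1 + alpha)
    bh = bh_adjust(sorted_p)
    r1 = int((bh <= alpha_prime).sum())
    if r1 == 0 or r1 == m:
        q_sorted = bh * (1 + alpha)
    else:
        q_sorted = bh * ((m - r1) / m) * (1 + alpha)
    q_sorted = np.minimum(q_sorted, 1.0)
    out = np.empty(m)
    out[order] = q_sorted
    return out


class TestBkyFdr:
    def test_single_p_hand_walk(self):
        # m = 1, p = 0.04: stage 1 rejects (0.04 <= 0.05/1.05), so m0 = 0 and
        # the adjusted value is p * (1 + alpha) = 0.042
        assert bky_fdr([0.04])[0] == pytest.approx(0.042)

    def test_all_ones_stay_one(self):
        assert np.all(bky_fdr([1.0] * 5) == 1.0)

    def test_q_ordering_follows_p_ordering(self):
        rng = np.random.default_rng(1)
        p = rng.random(50)
        q = bky_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    def test_empty_input(self):
        assert bky_fdr([]).size == 0

    def test_matches_independent_hand_coded_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            m = rng.integers(1, 40)
            p = rng.random(m) ** rng.uniform(0.5, 3)
            np.testing.assert_allclose(bky_fdr(p), bky_two_stage_oracle(p), atol=1e-12)


class TestFoldChange:
    def test_simple_ratio(self):
        assert fold_change_ratio(np.array([4.0, 4, 2, 2]),
                                 np.array([True, True, False, False])) == 2.0

    def test_identical_groups_give_one(self):
        assert fold_change_ratio(np.array([3.0, 3, 3, 3]),
                                 np.array([True, True, False, False])) == 1.0

    def test_scale_invariance(self):
        vals = np.array([1.0, 5, 2, 3])
        labels = np.array([True, True, False, False])
        assert fold_change_ratio(vals, labels) == pytest.approx(
            fold_change_ratio(vals * 7.3, labels)
        )

    def test_zero_control_mean_flagged_infinite(self):
        assert fold_change_ratio(np.array([1.0, 1, 0, 0]),
                                 np.array([True, True, False, False])) == np.inf


def toy_screen_matrix(full_sheet, rng):
    """42-sample matrix with controlled filter triggers (see individual tests)."""
    is_case = full_sheet.is_case
    n = len(full_sheet)
    base = rng.normal(1000, 5, size=(8, n)).clip(min=1)
    values = base.copy()
    # rows 0-2: up markers sharing one gene entry, with graded AUCs
    values[0, is_case] += 40
    values[1, is_case] += 15
    values[2, is_case] += 9
    # row 3: strong up marker with 4 missing cells, all NEC
    values[3, is_case] += 40
    # row 4: strong down marker
    values[4, is_case] -= 40
    values[4] = values[4].clip(min=1)
    # rows 5-7: null
    mask = np.zeros_like(values, dtype=bool)
    mask[3, np.flatnonzero(is_case)[:4]] = True
    values[mask] = np.nan
    genes = ["GSH;GA", "GSH", "GSH;GB", "GD", "GE", "GF", "GG", "GH"]
    return make_matrix(values, mask, sample_ids=full_sheet.sample_ids, genes=genes)


class TestScreenCascade:
    def test_concentrated_imputed_zeros_exclude_despite_auc(self, full_sheet):
        rng = np.random.default_rng(0)
        matrix = toy_screen_matrix(full_sheet, rng)
        stats = screen_markers(matrix, None, full_sheet)
        by_id = {s.protein_id: s for s in stats}
        assert by_id["P003"].passed_auc
        assert by_id["P003"].n_imputed_nec == 4
        assert not by_id["P003"].passed_zero_bias
        assert not by_id["P003"].passed

    def test_redundancy_cap_keeps_two_highest_auc(self, full_sheet):
        rng = np.random.default_rng(0)
        matrix = toy_screen_matrix(full_sheet, rng)
        stats = screen_markers(matrix, None, full_sheet)
        by_id = {s.protein_id: s for s in stats}
        shared = sorted(
            [by_id["P000"], by_id["P001"], by_id["P002"]], key=lambda s: -s.auc
        )
        assert all(s.passed_auc for s in shared)
        assert shared[0].passed_redundancy and shared[1].passed_redundancy
        assert not shared[2].passed_redundancy

    def test_down_marker_direction_and_fold_change(self, full_sheet):
        rng = np.random.default_rng(0)
        stats = screen_markers(toy_screen_matrix(full_sheet, rng), None, full_sheet)
        down = {s.protein_id: s for s in stats}["P004"]
        assert down.direction == "down" and down.fold_change < 1 and down.passed_auc

    def test_output_invariant_to_row_order(self, full_sheet):
        rng = np.random.default_rng(0)
        matrix = toy_screen_matrix(full_sheet, rng)
        perm = np.random.default_rng(1).permutation(matrix.n_groups)
        shuffled = matrix.subset_rows(perm)
        a = screen_markers(matrix, None, full_sheet)
        b = screen_markers(shuffled, None, full_sheet)
        assert [s.protein_id for s in a] == [s.protein_id for s in b]
        assert [s.auc for s in a] == [s.auc for s in b]
        assert [s.passed for s in a] == [s.passed for s in b]

    def test_precursor_support_gate(self, small_cohort):
        stats_with = screen_markers(
            small_cohort.pg, small_cohort.pr, small_cohort.samples
        )
        stats_without = screen_markers(small_cohort.pg, None, small_cohort.samples)
        gated = {s.protein_id for s in stats_with if not s.passed_precursor}
        assert all(s.passed_precursor for s in stats_without)
        # the gate can only remove markers relative to the ungated screen
        assert {s.protein_id for s in candidate_set(stats_with)} <= {
            s.protein_id for s in candidate_set(stats_without)
        }
        for s in stats_with:
            if s.protein_id in gated:
                best = small_cohort.pr.max_quantified_by_protein().get(s.protein_id, 0)
                assert best < 35

    def test_recovers_most_planted_markers(self, small_cohort):
        stats = screen_markers(small_cohort.pg, small_cohort.pr, small_cohort.samples)
        cand = {s.protein_id for s in candidate_set(stats)}
        planted = set(small_cohort.truth.protein_id)
        assert len(cand & planted) / len(planted) >= 0.8

    def test_mismatched_sample_order_rejected(self, small_cohort):
        pg = small_cohort.pg
        reordered = list(reversed(pg.sample_ids))
        bad = make_matrix(pg.values[:5], pg.missing_mask[:5], sample_ids=reordered[: pg.n_samples])
        with pytest.raises(ValueError, match="sample order"):
            screen_markers(bad, None, small_cohort.samples)
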