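"""Rank-based comparison harness: Friedman, Nemenyi, Holm, CD, Wilcoxon.

Where scipy provides the same statistic it serves as the independent
cross-check; exact small-sample behaviour is checked against brute-force
enumeration oracles written here.
"""

from itertools import permutations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cgmbench.stats import (BlockedMetricMatrix, build_model_comparison,
                            critical_difference, friedman_test, holm_adjust,
                            nemenyi_pairwise, wilcoxon_signed_rank)


def matrix_of(values, direction="lower"):
    v = np.asarray(values, dtype=float)
    return BlockedMetricMatrix(
        patients=tuple(f"p{i}" for i in range(v.shape[0])),
        treatments=tuple(f"t{j}" for j in range(v.shape[1])),
        values=v, better_direction=direction)


def brute_force_wilcoxon(a, b):
    """Two-sided exact signed-rank p by enumerating all 2^n sign vectors."""
    d = np.asarray(a, float) - np.asarray(b, float)
    d = d[d != 0]
    n = d.size
    ranks = sps.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    sums = [np.sum(ranks[[bool(signs >> i & 1) for i in range(n)]])
            for signs in range(2 ** n)]
    sums = np.asarray(sums)
    lower = np.mean(sums <= observed + 1e-12)
    upper = np.mean(sums >= observed - 1e-12)
    return min(1.0, 2.0 * min(lower, upper))


def brute_force_friedman_permutation_p(values):
    """Exact within-block permutation p for the Friedman statistic."""
    v = np.asarray(values, float)
    n, k = v.shape
    ranks = np.apply_along_axis(sps.rankdata, 1, v)

    def stat(r):
        sums = r.sum(axis=0)
        raw = 12 / (n * k * (k + 1)) * (sums ** 2).sum() - 3 * n * (k + 1)
        tie = sum(float(np.sum(c ** 3 - c)) for row in r
                  for _, c in [np.unique(row, return_counts=True)])
        corr = 1 - tie / (n * (k ** 3 - k))
        return raw / corr if corr > 0 else 0.0

    observed = stat(ranks)
    count = total = 0
    for combo in product(list(permutations(range(k))), repeat=n):
        r = np.vstack([ranks[i, list(p)] for i, p in enumerate(combo)])
        total += 1
        count += stat(r) >= observed - 1e-9
    return count / total


class TestFriedman:
    def test_identically_ordered_blocks_closed_form(self):
        # rank sums 6/12/18: chi2 = 12, p = exp(-6)
        values = np.tile([1.0, 2.0, 3.0], (6, 1))
        chi2, p, avg = friedman_test(matrix_of(values))
        assert chi2 == pytest.approx(12.0)
        assert p == pytest.approx(np.exp(-6.0), rel=1e-6)
        assert list(avg.values()) == [1.0, 2.0, 3.0]

    def test_constant_rows_carry_no_information(self):
        values = np.tile([5.0, 5.0, 5.0], (4, 1))
        with pytest.warns(UserWarning):
            chi2, p, _ = friedman_test(matrix_of(values))
        assert chi2 == 0.0 and p == 1.0

    def test_matches_scipy_on_random_matrices(self):
        rng = np.random.default_rng(9)
        for _ in range(5):
            v = rng.normal(size=(8, 4))
            chi2, p, _ = friedman_test(matrix_of(v))
            ref = sps.friedmanchisquare(*v.T)
            assert chi2 == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_average_ranks_sum_to_rank_total(self):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(6, 3))
        _, _, avg = friedman_test(matrix_of(v, direction="higher"))
        assert sum(avg.values()) == pytest.approx(3 * 4 / 2)

    def test_permutation_method_matches_enumeration_oracle(self):
        rng = np.random.default_rng(5)
        v = rng.normal(size=(3, 3))
        _, p, _ = friedman_test(matrix_of(v), method="permutation")
        assert p == pytest.approx(brute_force_friedman_permutation_p(v))

    def test_direction_flip_reverses_ranks(self):
        v = np.tile([1.0, 2.0, 3.0], (4, 1))
        _, _, low = friedman_test(matrix_of(v, "lower"))
        _, _, high = friedman_test(matrix_of(v, "higher"))
        assert list(low.values()) == list(reversed(list(high.values())))


class TestNemenyi:
    def test_equal_ranks_give_p_one(self):
        out = nemenyi_pairwise({"a": 2.0, "b": 2.0, "c": 2.0}, n=6)
        assert all(row["p"] == pytest.approx(1.0) for row in out)

    def test_reference_rank_gap_exceeds_critical_difference(self):
        # average ranks 3.00 / 1.17 / 1.83 over 6 blocks: the 1.83 gap
        # between the worst and best treatments is significant at 5%
        ranks = {"ctf": 3.00, "tml": 1.17, "dnn": 1.83}
        cd = critical_difference(n=6, k=3, alpha=0.05)
        assert cd == pytest.approx(1.353, abs=0.002)
        assert ranks["ctf"] - ranks["tml"] > cd
        out = {frozenset(r["pair"]): r["p"]
               for r in nemenyi_pairwise(ranks, n=6)}
        assert out[frozenset(("ctf", "tml"))] < 0.05
        assert out[frozenset(("tml", "dnn"))] > 0.05

    def test_symmetric_and_direction_invariant(self):
        a = nemenyi_pairwise({"x": 1.0, "y": 2.5}, n=8)
        b = nemenyi_pairwise({"y": 2.5, "x": 1.0}, n=8)
        assert a[0]["p"] == pytest.approx(b[0]["p"])


class TestHolm:
    def test_worked_step_down_chain(self):
        # 0.01 <= 0.05/3 rejected; 0.03 > 0.05/2 stops the chain
        assert holm_adjust([0.01, 0.03, 0.04]) == [True, False, False]

    def test_all_ones_rejected_nowhere(self):
        assert holm_adjust([1.0, 1.0, 1.0]) == [False, False, False]

    def test_single_p_is_plain_alpha_comparison(self):
        assert holm_adjust([0.04]) == [True]
        assert holm_adjust([0.06]) == [False]

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8),
           st.floats(0.01, 0.2))
    @settings(deadline=None, max_examples=80)
    def test_sandwiched_between_bonferroni_and_unadjusted(self, ps, alpha):
        holm = holm_adjust(ps, alpha)
        m = len(ps)
        bonferroni = [p <= alpha / m for p in ps]
        unadjusted = [p <= alpha for p in ps]
        assert sum(holm) >= sum(bonferroni)
        assert sum(holm) <= sum(unadjusted)


class TestCriticalDifference:
    def test_shrinks_with_block_count(self):
        cds = [critical_difference(n, 3) for n in (4, 8, 16, 64)]
        assert all(a > b for a, b in zip(cds, cds[1:]))

    def test_two_treatment_reduction(self):
        q2 = sps.studentized_range.ppf(0.95, 2, np.inf)
        assert critical_difference(9, 2) == \
            pytest.approx(q2 / np.sqrt(2) * np.sqrt(1.0 / 9))

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            critical_difference(0, 3)
        with pytest.raises(ValueError):
            critical_difference(6, 3, alpha=1.5)


class TestWilcoxon:
    def test_all_zero_differences_warn_and_return_one(self):
        with pytest.warns(UserWarning):
            assert wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0]) == 1.0

    def test_matches_scipy_exact_without_ties(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            a = rng.normal(size=9)
            b = rng.normal(size=9)
            ours = wilcoxon_signed_rank(a, b)
            ref = sps.wilcoxon(a, b, zero_method="wilcox",
                               method="exact").pvalue
            assert ours == pytest.approx(ref)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_full_enumeration_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 12))
        a = rng.integers(0, 5, n).astype(float)
        b = rng.integers(0, 5, n).astype(float)
        if np.all(a == b):
            a[0] += 1
        assert wilcoxon_signed_rank(a, b) == \
            pytest.approx(brute_force_wilcoxon(a, b))

    def test_five_positive_one_zero_pair_structure(self):
        # one zero difference dropped, five same-sign: p = 2/32 = 0.0625
        a = [20.56, 18.67, 17.24, 24.08, 21.28, 21.78]
        b = [19.35, 18.52, 16.09, 24.08, 18.03, 21.49]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(0.0625)

    def test_balanced_rank_sums_give_p_one(self):
        # rank sums 11 vs 10 with n=6 sit at the null median
        a = [40.83, 32.00, 30.32, 39.23, 39.83, 30.20]
        b = [41.75, 32.33, 30.98, 36.63, 38.38, 30.38]
        assert wilcoxon_signed_rank(a, b) == pytest.approx(1.0)

    def test_normal_approximation_beyond_exact_limit(self):
        rng = np.random.default_rng(12)
        a = rng.normal(0.4, 1, 60)
        b = rng.normal(0.0, 1, 60)
        ours = wilcoxon_signed_rank(a, b)
        ref = sps.wilcoxon(a, b, zero_method="wilcox", method="approx",
                           correction=False).pvalue
        assert ours == pytest.approx(ref, rel=1e-6)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            wilcoxon_signed_rank([1.0], [1.0, 2.0])


class TestComparisonReport:
    def test_posthoc_gated_on_omnibus_significance(self):
        rng = np.random.default_rng(7)
        noisy = matrix_of(rng.normal(size=(6, 3)))
        report = build_model_comparison(noisy)
        if report.friedman_p >= 0.05:
            assert report.pairwise == [] and report.cd_value is None
        ordered = matrix_of(np.tile([1.0, 2.0, 3.0], (6, 1))
                            + rng.normal(0, 0.01, (6, 3)))
        report2 = build_model_comparison(ordered)
        assert report2.friedman_p < 0.05
        assert len(report2.pairwise) == 3
        assert report2.cd_value == pytest.approx(1.353, abs=0.002)

    def test_report_is_deterministic(self):
        rng = np.random.default_rng(1)
        v = rng.normal(size=(6, 3))
        a = build_model_comparison(matrix_of(v), gate_posthoc=False)
        b = build_model_comparison(matrix_of(v), gate_posthoc=False)
        assert a.friedman_p == b.friedman_p
        assert a.pairwise == b.pairwise

    def test_missing_cells_rejected(self):
        values = np.array([[1.0, np.nan], [2.0, 3.0]])
        with pytest.raises(ValueError):
            matrix_of(values)


class TestCdDiagram:
    def test_cliques_join_indistinguishable_treatments(self):
        from cgmbench.stats import rank_cliques
        ranks = {"ctf": 3.00, "tml": 1.17, "dnn": 1.83}
        cliques = rank_cliques(ranks, cd_value=1.353)
        assert ("tml", "dnn") in cliques          # gap 0.66 < CD
        assert ("dnn", "ctf") in cliques          # gap 1.17 < CD
        assert all("tml" not in c or "ctf" not in c for c in cliques)

    def test_diagram_written_to_disk(self, tmp_path):
        from cgmbench.stats import plot_cd_diagram
        path = plot_cd_diagram({"ctf": 3.0, "tml": 1.17, "dnn": 1.83},
                               1.353, tmp_path / "cd.png")
        assert path.exists() and path.stat().st_size > 0
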