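"""Rank tests against independent oracles; BH adjustment properties."""

from itertools import combinations, permutations

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from tbitriage import (
    association_table,
    benjamini_hochberg,
    jonckheere_terpstra,
    mann_whitney_u,
)
from tbitriage.stats import DegenerateScopeError, StatParameterError


def jt_permutation_oracle(groups):
    """Two-sided JT p by brute enumeration of all distinct orderings."""
    pooled = [v for g in groups for v in g]
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)

    def stat(values):
        j = 0.0
        for a in range(len(sizes)):
            for b in range(a + 1, len(sizes)):
                for x in values[bounds[a]:bounds[a + 1]]:
                    for y in values[bounds[b]:bounds[b + 1]]:
                        j += (x < y) + 0.5 * (x == y)
        return j

    obs = stat(pooled)
    stats = [stat(p) for p in permutations(pooled)]
    ge = sum(s >= obs - 1e-12 for s in stats) / len(stats)
    le = sum(s <= obs + 1e-12 for s in stats) / len(stats)
    return obs, min(1.0, 2.0 * min(ge, le))


class TestMannWhitney:
    def test_enumerated_two_by_two(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 4.0
        assert res.p_raw == pytest.approx(2 / 6)
        assert res.method == "exact"

    def test_enumerated_four_by_four(self):
        res = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        assert res.p_raw == pytest.approx(2 / 70)

    def test_identical_multisets_give_p_one(self):
        assert mann_whitney_u([1, 1, 2, 3], [1, 1, 2, 3]).p_raw == 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(StatParameterError):
            mann_whitney_u([], [1.0])

    def test_exact_matches_scipy_for_all_small_instances(self):
        """Full sweep: every assignment of distinct ranks with total n <= 8."""
        for n in range(2, 9):
            for nx in range(1, n):
                for chosen in combinations(range(1, n + 1), nx):
                    x = list(chosen)
                    y = [v for v in range(1, n + 1) if v not in chosen]
                    mine = mann_whitney_u(x, y)
                    ref = mannwhitneyu(x, y, alternative="two-sided",
                                       method="exact")
                    assert mine.method == "exact"
                    assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-12)

    def test_normal_approximation_matches_scipy_with_ties(self, rng):
        for _ in range(25):
            x = rng.integers(0, 8, size=18).astype(float)
            y = (rng.integers(0, 8, size=15) + rng.integers(0, 2, 15)).astype(float)
            mine = mann_whitney_u(x, y)
            ref = mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic")
            assert mine.method == "normal_approx"
            assert mine.p_raw == pytest.approx(ref.pvalue, abs=1e-9)


class TestJonckheereTerpstra:
    def test_maximal_trend(self):
        res = jonckheere_terpstra([[1, 2], [3, 4], [5, 6]])
        assert res.statistic == 12.0  # all 12 cross-pairs concordant
        assert res.p_raw == pytest.approx(2 / 90)
        assert res.method == "exact"

    def test_total_ties_give_p_one(self):
        flat = [[2.0, 2.0], [2.0, 2.0], [2.0, 2.0]]
        assert jonckheere_terpstra(flat).p_raw == 1.0
        assert jonckheere_terpstra(flat, method="normal_approx").p_raw == 1.0

    def test_two_groups_reduce_to_mann_whitney_u(self, rng):
        for _ in range(20):
            x = rng.normal(size=rng.integers(2, 7)).tolist()
            y = rng.normal(0.5, size=rng.integers(2, 7)).tolist()
            assert (jonckheere_terpstra([x, y]).statistic
                    == mann_whitney_u(x, y).statistic)

    def test_exact_matches_permutation_oracle(self, rng):
        cases = [
            [[1, 2], [3], [4, 5]],
            [[1, 1], [2, 3], [1, 4]],          # with ties
            [[3, 1], [2, 2], [5, 4, 1]],
            [[1.5, 2.5, 0.5], [2.0, 3.0], [4.0, 0.1]],
        ]
        for _ in range(4):
            sizes = rng.integers(2, 4, size=3)
            cases.append([rng.integers(0, 5, s).astype(float).tolist()
                          for s in sizes])
        for groups in cases:
            mine = jonckheere_terpstra(groups)
            obs, p = jt_permutation_oracle(groups)
            assert mine.method == "exact"
            assert mine.statistic == pytest.approx(obs)
            assert mine.p_raw == pytest.approx(p, abs=1e-12)

    def test_normal_approx_tracks_permutation_p(self, rng):
        """Balanced groups of size 8: tie-corrected normal approximation
        stays within 0.02 of the (Monte-Carlo) permutation p."""
        for trial in range(5):
            groups = [rng.normal(0.15 * k, 1, 8).tolist() for k in range(3)]
            pn = jonckheere_terpstra(groups, method="normal_approx").p_raw
            pm = jonckheere_terpstra(groups, method="montecarlo",
                                     n_mc=50_000, seed=trial).p_raw
            assert pn == pytest.approx(pm, abs=0.02 + 0.005)

    def test_single_group_rejected(self):
        with pytest.raises(StatParameterError):
            jonckheere_terpstra([[1, 2, 3]])


class TestBenjaminiHochberg:
    def test_hand_worked_examples(self):
        assert benjamini_hochberg([0.01, 0.02, 0.03]) == pytest.approx(
            [0.03, 0.03, 0.03])
        assert benjamini_hochberg([0.5, 1.0]) == pytest.approx([1.0, 1.0])
        assert benjamini_hochberg([0.2]) == [0.2]

    def test_out_of_range_rejected(self):
        with pytest.raises(StatParameterError):
            benjamini_hochberg([0.1, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=20))
    def test_matches_statsmodels_and_never_decreases(self, p):
        mine = benjamini_hochberg(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(mine, ref, atol=1e-12)
        assert all(0 <= a <= 1 and a >= r - 1e-12 for a, r in zip(mine, p))

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=12),
           st.randoms(use_true_random=False))
    def test_invariant_to_input_order(self, p, rand):
        idx = list(range(len(p)))
        rand.shuffle(idx)
        direct = benjamini_hochberg([p[i] for i in idx])
        reordered = [benjamini_hochberg(p)[i] for i in idx]
        assert direct == pytest.approx(reordered, abs=1e-12)


class TestAssociationTable:
    def test_structure_and_monotone_adjustment(self, cohort65):
        table = association_table(cohort65, outcome="brainstem_binary",
                                  scope="moderate_severe")
        assert list(table.index) == ["GFAP", "NFL", "NSE", "S100B", "Tau",
                                     "UCHL1", "sample_time_h"]
        assert (table["p_adjusted"] >= table["p_raw"] - 1e-12).all()
        assert table["p_raw"].between(0, 1).all()

    def test_ordinal_outcome_runs_trend_test(self, cohort65):
        table = association_table(cohort65, outcome="adams_gentry_ordinal",
                                  scope="moderate_severe", seed=0)
        assert len(table) == 7
        assert set(table["method"]) <= {"exact", "normal_approx", "montecarlo"}

    def test_degenerate_scope_raises(self, cohort65):
        healthy = [r for r in cohort65 if not r.brainstem_injury]
        with pytest.raises(DegenerateScopeError):
            association_table(healthy, outcome="brainstem_binary")

    def test_signal_detected_in_moderate_severe_defaults(self, cohort65):
        table = association_table(cohort65, scope="moderate_severe")
        assert table.loc["UCHL1", "p_raw"] < 0.05
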