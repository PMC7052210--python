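"""Rank statistics against brute-force oracles and scipy cross-checks."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from hscquant import (
    GroupedSeries,
    kruskal_wallis,
    mann_whitney,
    significance_stars,
    spearman,
    summarize,
    write_report,
)


def oracle_ranks(v):
    """Average ranks by brute-force sorting (independent of scipy.rankdata)."""
    v = list(v)
    order = sorted(range(len(v)), key=lambda i: v[i])
    ranks = [0.0] * len(v)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def oracle_spearman_r(x, y):
    rx, ry = np.array(oracle_ranks(x)), np.array(oracle_ranks(y))
    rx -= rx.mean()
    ry -= ry.mean()
    return float(rx @ ry / np.sqrt((rx @ rx) * (ry @ ry)))


class TestSpearman:
    def test_identity_gives_plus_one(self):
        x = [3.0, 1.0, 7.0, 4.0, 9.0]
        assert spearman(x, x)["r"] == pytest.approx(1.0)

    def test_reversal_gives_minus_one(self):
        x = [1, 2, 3, 4, 5]
        assert spearman(x, x[::-1])["r"] == pytest.approx(-1.0)

    def test_textbook_example_r_08(self):
        # 1 - 6*sum(d^2)/(n(n^2-1)) with d^2 = 4 -> 0.8
        res = spearman([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert res["r"] == pytest.approx(0.8)
        assert res["method"] == "exact-permutation"

    def test_exact_p_matches_enumeration_oracle(self):
        x = [1, 2, 3, 4, 5]
        y = [2, 1, 4, 3, 5]
        obs = abs(oracle_spearman_r(x, y))
        hits = sum(
            abs(oracle_spearman_r(x, perm)) >= obs - 1e-12
            for perm in itertools.permutations(y)
        )
        assert spearman(x, y)["p"] == pytest.approx(hits / 120)

    def test_r_matches_oracle_on_random_tied_vectors(self):
        rng = np.random.default_rng(0)
        for n in range(4, 9):
            for _ in range(20):
                x = rng.integers(0, 4, n).astype(float)
                y = rng.integers(0, 4, n).astype(float)
                if np.ptp(x) == 0 or np.ptp(y) == 0:
                    continue
                got = spearman(x, y, method="asymptotic")
                assert got["r"] == pytest.approx(oracle_spearman_r(x, y))

    def test_asymptotic_p_matches_scipy_at_large_n(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=40)
        y = 0.5 * x + rng.normal(size=40)
        got = spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert got["method"] == "t-approximation"
        assert got["r"] == pytest.approx(ref.statistic)
        assert got["p"] == pytest.approx(ref.pvalue, rel=1e-6)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            spearman([1, 2], [2, 1])

    @given(st.permutations(list(range(6))))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_invariant_under_monotone_transform(self, perm):
        x = np.arange(6, dtype=float)
        y = np.array(perm, dtype=float)
        base = spearman(x, y)["r"]
        assert spearman(np.exp(x), y**3 + 2 * y)["r"] == pytest.approx(base)


class TestMannWhitney:
    def test_complete_separation_gives_zero_u(self):
        res = mann_whitney([1, 2], [3, 4])
        assert res["U"] == 0.0

    def test_identical_multisets_give_half_max_u(self):
        a = [1.0, 2.0, 3.0]
        res = mann_whitney(a, list(a))
        assert res["U"] == pytest.approx(len(a) ** 2 / 2)

    def test_single_observations_exact_p_is_one(self):
        res = mann_whitney([1.0], [2.0])
        assert res["method"] == "exact-enumeration"
        assert res["p"] == 1.0

    def test_exact_p_matches_independent_enumeration(self):
        a = [1.0, 3.0, 5.0, 7.0]
        b = [2.0, 4.0, 6.0]
        res = mann_whitney(a, b)

        def u_min(av, bv):
            av, bv = np.asarray(av), np.asarray(bv)
            d = av[:, None] - bv[None, :]
            ua = (d > 0).sum() + 0.5 * (d == 0).sum()
            return min(ua, len(av) * len(bv) - ua)

        pooled = a + b
        obs = u_min(a, b)
        hits = sum(
            u_min([pooled[i] for i in pick],
                  [pooled[i] for i in range(7) if i not in pick]) <= obs + 1e-9
            for pick in itertools.combinations(range(7), 4)
        )
        assert res["p"] == pytest.approx(hits / 35)

    def test_asymptotic_matches_scipy_without_continuity_correction(self):
        rng = np.random.default_rng(2)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.5, 1, 12)
        res = mann_whitney(a, b)
        ref = sps.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic",
            use_continuity=False,
        )
        assert res["method"] == "normal-approximation"
        assert res["p"] == pytest.approx(ref.pvalue, rel=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.uniform(0, 5, 10)
        b = rng.uniform(1, 6, 14)
        p0 = mann_whitney(a, b)["p"]
        assert mann_whitney(np.exp(a), np.exp(b))["p"] == pytest.approx(p0)


class TestKruskalWallis:
    def test_identical_constant_groups_flagged_degenerate(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0], [2.0]])
        assert res["H"] == 0.0
        assert res["degenerate"]

    def test_h_matches_brute_force_rank_sum_formula(self):
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        res = kruskal_wallis(groups)
        # H = 12/(N(N+1)) * sum n_i (Rbar_i - Rbar)^2, no ties
        n = 9
        ranks = {v: i + 1 for i, v in enumerate(range(1, 10))}
        rbar = (n + 1) / 2
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean([ranks[v] for v in g]) - rbar) ** 2
            for g in groups
        )
        assert res["H"] == pytest.approx(h)
        assert res["df"] == 2

    def test_two_group_h_equals_mann_whitney_z_squared(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, 20)
        b = rng.normal(0.3, 1, 18)
        kw = kruskal_wallis([a, b])
        mw = mann_whitney(a, b, method="asymptotic")
        # chi2_1(z^2) identity: the two p-values coincide
        assert kw["p"] == pytest.approx(mw["p"], abs=1e-6)

    def test_matches_scipy_with_ties(self):
        rng = np.random.default_rng(5)
        groups = [rng.integers(0, 5, 12).astype(float) for _ in range(3)]
        res = kruskal_wallis(groups)
        ref = sps.kruskal(*groups)
        assert res["H"] == pytest.approx(ref.statistic)
        assert res["p"] == pytest.approx(ref.pvalue)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])

    def test_grouped_series_input(self):
        gs = GroupedSeries([1, 2, 3, 4, 5, 6], ["a", "a", "a", "b", "b", "b"])
        res = kruskal_wallis(gs)
        assert res["n"] == 6


class TestSummarize:
    def test_median_of_one_to_five_is_three(self):
        gs = GroupedSeries([1, 2, 3, 4, 5], ["g"] * 5)
        row = summarize(gs).iloc[0]
        assert row["median"] == 3.0

    def test_single_value_has_zero_iqr(self):
        gs = GroupedSeries([7.0], ["g"])
        row = summarize(gs).iloc[0]
        assert row["median"] == 7.0
        assert row["q3"] - row["q1"] == 0.0

    def test_quartiles_match_brute_force_linear_interpolation(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            v = rng.uniform(0, 10, rng.integers(3, 12))
            gs = GroupedSeries(v, ["g"] * len(v))
            row = summarize(gs).iloc[0]
            # oracle: sort and interpolate h = (n-1)q manually
            s = np.sort(v)
            for q, col in ((0.25, "q1"), (0.5, "median"), (0.75, "q3")):
                h = (len(s) - 1) * q
                lo = int(np.floor(h))
                hi = min(lo + 1, len(s) - 1)
                expected = s[lo] + (h - lo) * (s[hi] - s[lo])
                assert row[col] == pytest.approx(expected)


class TestReport:
    @pytest.mark.parametrize(
        "p,stars",
        [(0.2, "ns"), (0.04, "*"), (0.009, "**"), (0.004, "***"),
         (0.0004, "****"), (0.0005, "***"), (0.005, "**"), (0.05, "ns")],
    )
    def test_star_convention(self, p, stars):
        assert significance_stars(p) == stars

    def test_write_report_renders_markdown(self, tmp_path):
        path = tmp_path / "report.md"
        write_report(
            [
                {"name": "RF area SD vs CDAHFD", "p": 0.003, "U": 1.0,
                 "n_a": 5, "n_b": 6},
            ],
            path,
        )
        text = path.read_text()
        assert "RF area SD vs CDAHFD" in text
        assert "***" in text
        assert "p < 0.0005" in text
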