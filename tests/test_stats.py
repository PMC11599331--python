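"""Comparative statistics: contributions, diversity, Spearman, Wilcoxon."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from aerospora import (
    UndefinedStatisticError,
    ValidationError,
    daily_diversity,
    genus_overlap,
    monthly_distribution,
    monthly_mean_diversity,
    pct_contribution,
    significance_stars,
    spearman_meteo,
    wilcoxon_paired,
)
from conftest import make_series


# ---------------------------------------------------------------- oracles
def average_ranks(values):
    """Average ranks computed from first principles (sort positions)."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(x, y):
    """Pearson correlation of average ranks, written out longhand."""
    rx, ry = average_ranks(list(x)), average_ranks(list(y))
    n = len(rx)
    mx, my = sum(rx) / n, sum(ry) / n
    num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
    den = math.sqrt(sum((a - mx) ** 2 for a in rx) * sum((b - my) ** 2 for b in ry))
    return num / den


def wilcoxon_oracle(a, b):
    """Exhaustive signed-rank test: V from first-principles ranks, exact
    two-sided p by enumerating all 2^n sign assignments."""
    d = [x - y for x, y in zip(a, b) if x != y]
    n = len(d)
    ranks = average_ranks([abs(v) for v in d])
    V = sum(r for r, v in zip(ranks, d) if v > 0)
    stats = []
    for signs in itertools.product([0, 1], repeat=n):
        stats.append(sum(r for r, s in zip(ranks, signs) if s))
    lo = sum(1 for w in stats if w <= V) / len(stats)
    hi = sum(1 for w in stats if w >= V) / len(stats)
    return V, min(1.0, 2 * min(lo, hi))


# ------------------------------------------------------------ contributions
class TestPctContribution:
    def test_dominant_taxon_two_decimals(self):
        assert pct_contribution(1_649_583, 2_368_367, 2) == 69.65

    def test_full_share(self):
        assert pct_contribution(123.4, 123.4, 1) == 100.0

    def test_one_decimal(self):
        assert pct_contribution(172_948, 2_368_367, 1) == 7.3

    def test_rounds_half_up(self):
        assert pct_contribution(125, 1000, 1) == 12.5
        assert pct_contribution(1250, 100000, 1) == 1.3  # 1.25 -> 1.3, not 1.2

    def test_zero_total_rejected(self):
        with pytest.raises(ValidationError):
            pct_contribution(1, 0)


class TestMonthlyDistribution:
    def test_single_month_gets_everything(self):
        s = make_series([10.0] * 20, start="2022-07-01")
        dist = monthly_distribution(s)
        assert list(dist.index) == [7] and dist.iloc[0] == 100.0

    def test_two_equal_months_split_evenly(self):
        s = make_series([1.0] * 61, start="2022-07-01")  # 31 Jul + 30 Aug... days
        s2 = make_series([1.0] * 30 + [1.0] * 30, start="2022-06-01")
        dist = monthly_distribution(s2)
        assert dist.loc[6] == 50.0 and dist.loc[7] == 50.0

    def test_shares_sum_to_100(self, default_dataset):
        series, _, _ = default_dataset
        for s in series[:6]:
            if s.values.sum() > 0:
                assert monthly_distribution(s).sum() == pytest.approx(100.0, abs=0.1)

    def test_peak_month_is_argmax(self, default_dataset):
        series, _, _ = default_dataset
        clad = next(s for s in series if s.taxon == "Cladosporium" and s.site == "urban")
        dist = monthly_distribution(clad)
        assert dist.idxmax() in (6, 7, 8)  # mid-window season peaks in summer


class TestDailyDiversity:
    def test_counts_match_presence_matrix(self, rng):
        n_taxa, n_days = 12, 40
        presence = rng.random((n_taxa, n_days)) < 0.4
        series = [
            make_series(np.where(presence[i], rng.integers(1, 50, n_days), 0.0),
                        taxon=f"t{i}")
            for i in range(n_taxa)
        ]
        counts = daily_diversity(series)
        np.testing.assert_array_equal(counts.to_numpy(), presence.sum(axis=0))

    def test_no_positive_taxa_gives_zero(self):
        series = [make_series([0, 0]), make_series([0, 0], taxon="U")]
        assert daily_diversity(series).tolist() == [0, 0]

    def test_monthly_mean(self):
        s1 = make_series([1.0] * 59, start="2022-01-01")
        s2 = make_series([0.0] * 31 + [1.0] * 28, start="2022-01-01", taxon="U")
        monthly = monthly_mean_diversity([s1, s2])
        assert monthly.loc[1] == 1.0 and monthly.loc[2] == 2.0


# ------------------------------------------------------------- correlations
def _meteo_from(values, start="2022-06-01"):
    from aerospora import MeteoSeries

    idx = pd.date_range(start, periods=len(values), freq="D")
    frame = pd.DataFrame(
        {
            "temperature": values,
            "relative_humidity": 50.0,
            "wind_speed": 1.0,
            "sunshine": 5.0,
            "precipitation": 0.0,
        },
        index=idx,
    )
    return MeteoSeries("S", frame)


class TestSpearman:
    def test_perfect_positive(self):
        s = make_series([1, 2, 3, 4, 5], start="2022-06-01")
        cell = spearman_meteo(s, _meteo_from([10, 11, 12, 13, 14]), "temperature")
        assert cell.rho == pytest.approx(1.0)

    def test_perfect_negative(self):
        s = make_series([5, 4, 3, 2, 1], start="2022-06-01")
        cell = spearman_meteo(s, _meteo_from([1, 2, 3, 4, 5]), "temperature")
        assert cell.rho == pytest.approx(-1.0)

    def test_tied_example_matches_rank_formula_oracle(self):
        x = [3, 3, 7, 1, 9, 9, 9, 2]
        y = [5, 1, 8, 2, 4, 4, 10, 2]
        s = make_series(x, start="2022-06-01")
        cell = spearman_meteo(s, _meteo_from(y), "temperature")
        assert cell.rho == pytest.approx(spearman_oracle(x, y))

    def test_pairs_restricted_to_common_dates(self):
        s = make_series([1, 2, 3, 4, 5, 6], start="2022-06-01")
        met = _meteo_from([9, 8, 7, 6], start="2022-06-03")
        cell = spearman_meteo(s, met, "temperature")
        assert cell.n == 4 and cell.rho == pytest.approx(-1.0)

    def test_too_few_pairs_rejected(self):
        s = make_series([1, 2], start="2022-06-01")
        with pytest.raises(UndefinedStatisticError):
            spearman_meteo(s, _meteo_from([1, 2]), "temperature")

    def test_zero_variance_rejected(self):
        s = make_series([4, 4, 4, 4], start="2022-06-01")
        with pytest.raises(UndefinedStatisticError):
            spearman_meteo(s, _meteo_from([1, 2, 3, 4]), "temperature")

    @given(st.lists(st.integers(min_value=0, max_value=8), min_size=4, max_size=10),
           st.lists(st.integers(min_value=0, max_value=8), min_size=4, max_size=10))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_matches_oracle_on_small_inputs(self, x, y):
        n = min(len(x), len(y))
        x, y = x[:n], y[:n]
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        s = make_series(x, start="2022-06-01")
        cell = spearman_meteo(s, _meteo_from(y[:n]), "temperature")
        assert cell.rho == pytest.approx(spearman_oracle(x, y), abs=1e-12)


class TestStars:
    @pytest.mark.parametrize("p,stars", [
        (0.2, ""), (0.049, "*"), (0.009, "**"), (0.0009, "***"), (0.05, ""),
    ])
    def test_nested_levels(self, p, stars):
        assert significance_stars(p) == stars


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        with pytest.raises(UndefinedStatisticError):
            wilcoxon_paired([(1, 1), (2, 2)])

    def test_three_pairs_match_enumeration(self):
        # |differences| are tied here, so only the statistic is exact;
        # the p-value comes from the tie-corrected normal approximation
        pairs = [(3, 1), (5, 2), (2, 4)]
        result = wilcoxon_paired(pairs)
        V, _ = wilcoxon_oracle([a for a, _ in pairs], [b for _, b in pairs])
        assert result.V == V == 4.5
        assert 0 < result.p_value <= 1

    def test_statistic_range_invariant(self, rng):
        a = rng.integers(0, 100, 30).astype(float)
        b = rng.integers(0, 100, 30).astype(float)
        r = wilcoxon_paired(a, b)
        assert 0 <= r.V <= r.n_pairs * (r.n_pairs + 1) / 2

    def test_matches_scipy_exact_mode(self, rng):
        a = rng.normal(10, 3, 15)
        b = a + rng.normal(1, 2, 15)
        ours = wilcoxon_paired(a, b)
        ref = sps.wilcoxon(a, b, mode="exact")
        # scipy reports min(T+, T-); ours is T+ (R convention)
        assert ours.V in (ref.statistic, ours.n_pairs * (ours.n_pairs + 1) / 2 - ref.statistic)
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_normal_approximation_for_large_n(self, rng):
        a = rng.normal(10, 3, 60)
        b = a + rng.normal(0.8, 2, 60)
        ours = wilcoxon_paired(a, b)
        ref = sps.wilcoxon(a, b, correction=True, mode="approx")
        assert ours.p_value == pytest.approx(ref.pvalue, rel=1e-6)

    @given(st.lists(st.tuples(st.integers(0, 20), st.integers(0, 20)),
                    min_size=1, max_size=10))
    @settings(max_examples=150, derandomize=True, deadline=None)
    def test_exhaustive_oracle_on_small_inputs(self, pairs):
        if all(a == b for a, b in pairs):
            with pytest.raises(UndefinedStatisticError):
                wilcoxon_paired(pairs)
            return
        result = wilcoxon_paired(pairs)
        V, p = wilcoxon_oracle([a for a, _ in pairs], [b for _, b in pairs])
        assert result.V == V
        d = [a - b for a, b in pairs if a != b]
        if len(set(map(abs, d))) == len(d):  # exact path only without ties
            assert result.p_value == pytest.approx(p)


class TestGenusOverlap:
    def test_identical_sets(self):
        assert genus_overlap(["Alternaria", "Cladosporium"],
                             ["cladosporium", " Alternaria "]) == (0, 2, 0)

    def test_disjoint_sets(self):
        assert genus_overlap(["a", "b"], ["c", "d", "e"]) == (2, 0, 3)

    def test_partial_overlap(self):
        assert genus_overlap({"x", "y", "z"}, {"y", "z", "w"}) == (1, 2, 1)
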