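"""Cross-site and meteorological statistics.

Percentage contributions and monthly shares of the annual integral, daily
taxon-diversity counts, Spearman rank correlations between daily spore
concentrations and meteorological variables (with the usual significance
stars), the paired Wilcoxon signed-rank comparison of per-taxon annual
integrals between two sites (R ``wilcox.test`` conventions: V = sum of the
ranks of positive differences, zero differences dropped, average ranks for
ties), and Venn-style genus overlap counts between two identification
methods.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import (
    METEO_VARIABLES,
    DailyConcentrationSeries,
    MeteoSeries,
    UndefinedStatisticError,
    ValidationError,
)

__all__ = [
    "CorrelationCell",
    "SiteComparison",
    "pct_contribution",
    "monthly_distribution",
    "daily_diversity",
    "monthly_mean_diversity",
    "significance_stars",
    "spearman_meteo",
    "correlation_table",
    "wilcoxon_paired",
    "genus_overlap",
]

#: Maximum number of retained pairs for which the exact signed-rank null
#: distribution is used (normal approximation with continuity correction above).
EXACT_WILCOXON_N = 25


@dataclass(frozen=True)
class CorrelationCell:
    taxon: str
    variable: str
    rho: float
    p_value: float
    n: int

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


@dataclass(frozen=True)
class SiteComparison:
    n_pairs: int
    V: float
    p_value: float

    def __post_init__(self):
        if not 0 <= self.V <= self.n_pairs * (self.n_pairs + 1) / 2:
            raise ValidationError("signed-rank statistic out of range")


def pct_contribution(taxon_asin: float, total_asin: float, decimals: int = 2) -> float:
    """Percentage contribution of one taxon to the site total, rounded
    half-up to ``decimals`` places (matching printed tables)."""
    if total_asin <= 0:
        raise ValidationError("total integral must be positive")
    pct = Decimal(100) * Decimal(str(taxon_asin)) / Decimal(str(total_asin))
    q = Decimal(1).scaleb(-decimals)
    return float(pct.quantize(q, rounding=ROUND_HALF_UP))


def monthly_distribution(series: DailyConcentrationSeries | pd.Series) -> pd.Series:
    """Per-month percentage share of the summed concentration.

    Accepts a concentration series (or a raw date-indexed series, e.g. a
    site total). Shares sum to 100 up to floating-point rounding.
    """
    values = series.values if isinstance(series, DailyConcentrationSeries) else series
    total = float(values.sum())
    if total <= 0:
        raise ValidationError("annual integral is zero; monthly shares undefined")
    by_month = values.groupby(values.index.month).sum()
    return 100.0 * by_month / total


def daily_diversity(series: Iterable[DailyConcentrationSeries]) -> pd.Series:
    """Date -> number of taxa with a positive concentration on that day."""
    series = list(series)
    if not series:
        raise ValidationError("no series given")
    counts: pd.Series | None = None
    for s in series:
        present = (s.values > 0).astype(int)
        counts = present if counts is None else counts.add(present, fill_value=0)
    return counts.astype(int).sort_index()


def monthly_mean_diversity(series: Iterable[DailyConcentrationSeries]) -> pd.Series:
    """Month -> mean of the daily taxon counts in that month."""
    daily = daily_diversity(series)
    return daily.groupby(daily.index.month).mean()


def significance_stars(p_value: float) -> str:
    """Conventional significance annotation (strongest applicable level)."""
    if p_value < 0.001:
        return "***"
    if p_value < 0.01:
        return "**"
    if p_value < 0.05:
        return "*"
    return ""


def spearman_meteo(
    series: DailyConcentrationSeries,
    meteo: MeteoSeries,
    variable: str,
    period: tuple[int, int] | None = None,
) -> CorrelationCell:
    """Spearman rank correlation between daily concentrations and one
    meteorological variable, over the days present in both records.

    ``period`` optionally restricts the pairing to a DOY window (e.g. the
    MSS). Ties receive average ranks; the two-sided p-value uses the
    t-approximation. Fewer than 3 pairs or a constant input is an error.
    """
    met = meteo.variable(variable)
    joined = pd.concat([series.values, met], axis=1, join="inner").dropna()
    if period is not None:
        doys = joined.index.dayofyear
        joined = joined[(doys >= period[0]) & (doys <= period[1])]
    if len(joined) < 3:
        raise UndefinedStatisticError(
            f"({series.taxon}, {variable}): fewer than 3 paired days"
        )
    x = joined.iloc[:, 0].to_numpy()
    y = joined.iloc[:, 1].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedStatisticError(
            f"({series.taxon}, {variable}): zero-variance input"
        )
    rho, p = sps.spearmanr(x, y)
    return CorrelationCell(
        taxon=series.taxon, variable=variable,
        rho=float(rho), p_value=float(p), n=len(joined),
    )


def correlation_table(
    series: Iterable[DailyConcentrationSeries],
    meteo: MeteoSeries,
    variables: Sequence[str] = METEO_VARIABLES,
    period: tuple[int, int] | None = None,
    decimals: int = 3,
) -> pd.DataFrame:
    """Taxon x variable table of Spearman rho (rounded) with star annotation."""
    rows = []
    for s in series:
        row: dict[str, object] = {"taxon": s.taxon}
        for var in variables:
            cell = spearman_meteo(s, meteo, var, period=period)
            row[var] = f"{round(cell.rho, decimals)}{cell.stars}"
        rows.append(row)
    return pd.DataFrame(rows).set_index("taxon")


def _exact_signed_rank_sf(n: int):
    """Null pmf of the positive-rank sum W+ for n untied pairs, by dynamic
    programming over rank inclusion (2^n subsets enumerated implicitly)."""
    max_w = n * (n + 1) // 2
    counts = np.zeros(max_w + 1)
    counts[0] = 1.0
    for r in range(1, n + 1):
        counts[r:] += counts[:-r].copy()
    return counts / counts.sum()


def wilcoxon_paired(
    first: Sequence[float], second: Sequence[float] | None = None
) -> SiteComparison:
    """Paired Wilcoxon signed-rank test between two matched samples.

    Accepts either two aligned sequences or one sequence of ``(a, b)``
    pairs. Differences ``a - b`` equal to zero are dropped; ties in
    |difference| get average ranks. V is the sum of the ranks of the
    positive differences (R convention). The two-sided p-value is exact
    for at most 25 retained untied pairs, otherwise a normal approximation
    with continuity and tie corrections.
    """
    if second is None:
        pairs = np.asarray(list(first), dtype=float)
        if pairs.ndim != 2 or pairs.shape[1] != 2:
            raise ValidationError("expected (a, b) pairs")
        a, b = pairs[:, 0], pairs[:, 1]
    else:
        a = np.asarray(list(first), dtype=float)
        b = np.asarray(list(second), dtype=float)
        if a.shape != b.shape:
            raise ValidationError("paired samples differ in length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise UndefinedStatisticError("all paired differences are zero; no test")
    ranks = sps.rankdata(np.abs(d))
    V = float(ranks[d > 0].sum())

    has_ties = len(np.unique(np.abs(d))) < n
    if n <= EXACT_WILCOXON_N and not has_ties:
        pmf = _exact_signed_rank_sf(n)
        w = int(round(V))
        p = 2.0 * min(pmf[: w + 1].sum(), pmf[w:].sum())
        p = min(1.0, p)
    else:
        mu = n * (n + 1) / 4.0
        _, t = np.unique(np.abs(d), return_counts=True)
        sigma2 = n * (n + 1) * (2 * n + 1) / 24.0 - (t**3 - t).sum() / 48.0
        correction = 0.5 * np.sign(V - mu)
        z = (V - mu - correction) / np.sqrt(sigma2)
        p = float(2.0 * sps.norm.sf(abs(z)))
        p = min(1.0, p)
    return SiteComparison(n_pairs=n, V=V, p_value=p)


def _normalise(names: Iterable[str]) -> set[str]:
    return {str(n).strip().lower() for n in names if str(n).strip()}


def genus_overlap(set_a: Iterable[str], set_b: Iterable[str]) -> tuple[int, int, int]:
    """(unique to A, common, unique to B) genus counts, case-insensitive."""
    a, b = _normalise(set_a), _normalise(set_b)
    return len(a - b), len(a & b), len(b - a)
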