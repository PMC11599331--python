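"""Per-taxon seasonal statistics: spore integrals, the 90%-method main
spore season, peaks, high days, and the site-by-taxon season summary table.

The main spore season (MSS) follows the classical 90% method: the season
starts on the first day whose cumulative concentration sum strictly
exceeds 5% of the annual spore integral (ASIn) and ends on the first day
whose cumulative sum strictly exceeds 95%. By construction the seasonal
spore integral (SSIn, the sum over the MSS) always holds more than 90% of
the annual integral.

A *high day* (HD) is a day whose daily mean concentration strictly
exceeds a clinically relevant threshold: 3000 spores/m3 for
*Cladosporium*, 100 spores/m3 for all other taxa.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .types import (
    DailyConcentrationSeries,
    NoSeasonError,
    TaxonProfile,
    ValidationError,
    to_doy,
)

__all__ = [
    "DEFAULT_HD_THRESHOLD",
    "CLADOSPORIUM_HD_THRESHOLD",
    "HDThresholds",
    "SeasonSummary",
    "annual_spore_integral",
    "occurrence_frequency",
    "mss_90",
    "seasonal_spore_integral",
    "peak",
    "high_days",
    "season_length",
    "select_abundant_taxa",
    "summarise_season",
    "build_mss_table",
    "asin_table",
]

logger = logging.getLogger(__name__)

DEFAULT_HD_THRESHOLD = 100.0
CLADOSPORIUM_HD_THRESHOLD = 3000.0

#: Default ASIn filter for the season summary table: only taxa whose annual
#: integral strictly exceeds this at every site are summarised.
DEFAULT_ABUNDANCE_THRESHOLD = 2000.0


@dataclass(frozen=True)
class HDThresholds:
    """High-day concentration thresholds (spores/m3)."""

    default: float = DEFAULT_HD_THRESHOLD
    cladosporium: float = CLADOSPORIUM_HD_THRESHOLD

    def __post_init__(self):
        if self.default <= 0 or self.cladosporium <= 0:
            raise ValidationError("high-day thresholds must be positive")

    def for_taxon(self, taxon: str, profile: TaxonProfile | None = None) -> float:
        if profile is not None:
            return profile.hd_threshold
        if taxon.strip().lower().startswith("cladosporium"):
            return self.cladosporium
        return self.default


@dataclass(frozen=True)
class SeasonSummary:
    """One row of the season summary table for a (taxon, site)."""

    taxon: str
    site: str
    start_doy: int
    end_doy: int
    length_days: int
    ssin: float
    peak_value: float
    peak_doy: int
    high_days: int
    asin: float
    frequency_pct: float

    def __post_init__(self):
        if self.start_doy > self.end_doy:
            raise ValidationError(f"{self.taxon}/{self.site}: season start after end")
        if not 0 <= self.ssin <= self.asin + 1e-9:
            raise ValidationError(f"{self.taxon}/{self.site}: SSIn exceeds ASIn")
        if not self.start_doy <= self.peak_doy <= self.end_doy:
            # The whole-period maximum can legitimately fall outside the MSS
            # (a large isolated day in the 5% tails), so this is not fatal.
            logger.warning(
                "%s/%s: peak day %d outside season [%d, %d]",
                self.taxon, self.site, self.peak_doy, self.start_doy, self.end_doy,
            )


def _require_nonempty(series: DailyConcentrationSeries) -> None:
    if series.n_sampled == 0:
        raise ValidationError(
            f"({series.site}, {series.taxon}): no sampled days"
        )


def annual_spore_integral(series: DailyConcentrationSeries) -> float:
    """Sum of recorded daily mean concentrations over the operation period
    (spore.day/m3). Missing sampled days contribute zero (warned once)."""
    _require_nonempty(series)
    n_missing = series.n_period_days - series.n_sampled
    if n_missing > 0:
        logger.warning(
            "(%s, %s): %d missing day(s) in operation period counted as 0",
            series.site, series.taxon, n_missing,
        )
    return float(series.values.sum())


def occurrence_frequency(series: DailyConcentrationSeries) -> float:
    """Percentage of sampled days with a positive concentration.

    The denominator is the number of days actually sampled, not the
    calendar year.
    """
    _require_nonempty(series)
    return float(100.0 * (series.concentrations > 0).sum() / series.n_sampled)


def mss_90(series: DailyConcentrationSeries) -> tuple[int, int]:
    """Main spore season by the 90% method, as (start_doy, end_doy).

    Start: first day whose cumulative sum strictly exceeds 5% of ASIn.
    End: first day whose cumulative sum strictly exceeds 95% of ASIn.
    """
    asin = annual_spore_integral(series)
    if asin <= 0:
        raise NoSeasonError(
            f"({series.site}, {series.taxon}): annual integral is zero, no season"
        )
    cum = np.cumsum(series.concentrations)
    start_idx = int(np.argmax(cum > 0.05 * asin))
    end_idx = int(np.argmax(cum > 0.95 * asin))
    return to_doy(series.dates[start_idx]), to_doy(series.dates[end_idx])


def seasonal_spore_integral(
    series: DailyConcentrationSeries, start_doy: int, end_doy: int
) -> float:
    """Sum of daily concentrations on days with start_doy <= DOY <= end_doy."""
    if start_doy > end_doy:
        raise ValidationError("season start after end")
    doys = series.doys
    mask = (doys >= start_doy) & (doys <= end_doy)
    return float(series.concentrations[mask].sum())


def peak(series: DailyConcentrationSeries) -> tuple[float, int]:
    """Maximum daily concentration and its DOY; ties go to the earliest day."""
    if annual_spore_integral(series) <= 0:
        raise NoSeasonError(
            f"({series.site}, {series.taxon}): all-zero series has no peak"
        )
    idx = int(np.argmax(series.concentrations))  # argmax -> first maximum
    return float(series.concentrations[idx]), to_doy(series.dates[idx])


def high_days(series: DailyConcentrationSeries, threshold: float) -> int:
    """Number of sampled days whose concentration strictly exceeds ``threshold``,
    counted over the whole operation period."""
    if threshold <= 0:
        raise ValidationError("high-day threshold must be positive")
    _require_nonempty(series)
    return int((series.concentrations > threshold).sum())


def season_length(start_doy: int, end_doy: int) -> int:
    """Inclusive season duration in days (start and end both counted)."""
    if start_doy > end_doy:
        raise ValidationError("season start after end")
    return int(end_doy) - int(start_doy) + 1


def asin_table(series: Iterable[DailyConcentrationSeries]) -> pd.DataFrame:
    """Annual spore integrals as a taxon x site table (NaN where unrecorded)."""
    records = {}
    for s in series:
        records.setdefault(s.taxon, {})[s.site] = annual_spore_integral(s)
    table = pd.DataFrame.from_dict(records, orient="index").sort_index()
    table.index.name = "taxon"
    return table


def select_abundant_taxa(
    table: pd.DataFrame,
    threshold: float = DEFAULT_ABUNDANCE_THRESHOLD,
    require_all_sites: bool = True,
) -> list[str]:
    """Taxa whose ASIn strictly exceeds ``threshold`` at every site
    (or at any site when ``require_all_sites`` is False). Absent entries
    never pass."""
    if table.shape[1] == 0 or table.shape[0] == 0:
        return []
    passing = table.fillna(0.0) > threshold
    keep = passing.all(axis=1) if require_all_sites else passing.any(axis=1)
    return list(table.index[keep])


def summarise_season(
    series: DailyConcentrationSeries,
    hd_threshold: float | None = None,
    thresholds: HDThresholds | None = None,
) -> SeasonSummary:
    """Compute the full season summary row for one (taxon, site) series."""
    thresholds = thresholds or HDThresholds()
    if hd_threshold is None:
        hd_threshold = thresholds.for_taxon(series.taxon)
    start, end = mss_90(series)
    value, pday = peak(series)
    return SeasonSummary(
        taxon=series.taxon,
        site=series.site,
        start_doy=start,
        end_doy=end,
        length_days=season_length(start, end),
        ssin=seasonal_spore_integral(series, start, end),
        peak_value=value,
        peak_doy=pday,
        high_days=high_days(series, hd_threshold),
        asin=annual_spore_integral(series),
        frequency_pct=occurrence_frequency(series),
    )


def build_mss_table(
    series: Iterable[DailyConcentrationSeries],
    thresholds: HDThresholds | None = None,
    asin_min: float = DEFAULT_ABUNDANCE_THRESHOLD,
    require_all_sites: bool = True,
) -> list[SeasonSummary]:
    """Season summary rows for every (taxon, site) whose taxon passes the
    abundance filter (ASIn > ``asin_min`` at every site). Non-passing taxa
    are excluded with a logged warning."""
    series = list(series)
    table = asin_table(series)
    keep = set(select_abundant_taxa(table, asin_min, require_all_sites))
    dropped = sorted(set(table.index) - keep)
    if dropped:
        logger.warning(
            "%d taxa below the ASIn threshold %g excluded: %s",
            len(dropped), asin_min, ", ".join(dropped[:8]) + ("..." if len(dropped) > 8 else ""),
        )
    rows = [
        summarise_season(s, thresholds=thresholds)
        for s in series
        if s.taxon in keep
    ]
    rows.sort(key=lambda r: (r.taxon, r.site))
    return rows


def mss_table_frame(rows: Sequence[SeasonSummary]) -> pd.DataFrame:
    """Season summaries as a tidy DataFrame (one row per taxon and site)."""
    cols = [
        "taxon", "site", "start_doy", "end_doy", "length_days", "ssin",
        "peak_value", "peak_doy", "high_days", "asin", "frequency_pct",
    ]
    return pd.DataFrame([asdict(r) for r in rows], columns=cols)
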