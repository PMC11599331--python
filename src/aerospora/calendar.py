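"""Spieksma-style spore calendar.

Mean daily concentrations over 10-day periods (month thirds: days 1-10,
11-20, 21-end) are mapped onto six exponential concentration classes.
Two class scales exist: the general one (a 1-10, b 11-50, c 51-100,
d 101-500, e 501-1000, f >1000 spores/m3) and a *Cladosporium*-specific
one an order of magnitude higher (a 1-300, b 301-1500, c 1501-3000,
d 3001-5000, e 5001-10000, f >10000). Because bin means are real-valued,
the classes are implemented as a half-open partition of [1, inf); means
below 1 carry no class.

Taxa whose 10-day means exceed class "d" (the high-day threshold embedded
in each scale) continuously for over a month are *seasonal* and are
categorised as summer, summer-autumn, autumn or all-year-round spores;
shorter exceedances are short-term.
"""

from __future__ import annotations

import calendar as _cal
import datetime as dt
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .season import annual_spore_integral, mss_90, seasonal_spore_integral
from .types import DailyConcentrationSeries, ValidationError

__all__ = [
    "CLASS_BOUNDS",
    "TenDayBin",
    "ten_day_bins",
    "exponential_class",
    "seasonal_category",
    "CalendarMatrix",
    "build_calendar",
]

logger = logging.getLogger(__name__)

CLASS_LABELS = ("a", "b", "c", "d", "e", "f")

#: Upper bounds of classes a-e per scale; class f is everything above the
#: last bound. Class membership of a mean m >= 1 is the first class whose
#: upper bound is >= m (i.e. half-open intervals (prev, bound]).
CLASS_BOUNDS = {
    "general": (10.0, 50.0, 100.0, 500.0, 1000.0),
    "cladosporium": (300.0, 1500.0, 3000.0, 5000.0, 10000.0),
}

#: Minimum ASIn for a taxon to appear in the calendar at all.
DEFAULT_CALENDAR_ASIN_MIN = 250.0

#: Number of consecutive above-threshold bins that counts as "over a month".
SEASONAL_RUN_BINS = 4

_SUMMER = (6, 7, 8)
_AUTUMN = (9, 10, 11)


@dataclass(frozen=True)
class TenDayBin:
    """One 10-day period (month third); the last third absorbs days 21-28/31."""

    year: int
    month: int
    third: int
    start_date: dt.date
    end_date: dt.date
    mean_concentration: float | None  # None when no day in the bin was sampled

    @property
    def label(self) -> str:
        return f"{self.year:04d}-{self.month:02d}.{self.third}"

    @property
    def n_days(self) -> int:
        return (self.end_date - self.start_date).days + 1


def _month_thirds(year: int, month: int):
    last = _cal.monthrange(year, month)[1]
    yield 1, dt.date(year, month, 1), dt.date(year, month, 10)
    yield 2, dt.date(year, month, 11), dt.date(year, month, 20)
    yield 3, dt.date(year, month, 21), dt.date(year, month, last)


def iter_bins(period: tuple[dt.date, dt.date]):
    """All month-third bins of the months overlapped by ``period``."""
    start, end = period
    y, m = start.year, start.month
    while (y, m) <= (end.year, end.month):
        for third, a, b in _month_thirds(y, m):
            if b < start or a > end:
                continue
            yield y, m, third, a, b
        m += 1
        if m == 13:
            y, m = y + 1, 1


def ten_day_bins(series: DailyConcentrationSeries) -> list[TenDayBin]:
    """Partition the series' operation period into month-third bins with the
    mean concentration over the days recorded in each bin (missing days are
    excluded from the mean; a bin with no recorded day has mean None)."""
    if series.n_sampled == 0:
        raise ValidationError(f"({series.site}, {series.taxon}): empty series")
    dates = series.dates
    out = []
    for y, m, third, a, b in iter_bins(series.operation_period):
        mask = (dates >= pd.Timestamp(a)) & (dates <= pd.Timestamp(b))
        vals = series.concentrations[mask]
        mean = float(vals.mean()) if len(vals) else None
        out.append(TenDayBin(y, m, third, a, b, mean))
    return out


def exponential_class(mean_concentration: float | None, scale: str = "general") -> str:
    """Exponential class label ('a'..'f') for a 10-day mean; '' below class a."""
    if scale not in CLASS_BOUNDS:
        raise ValidationError(f"unknown calendar scale {scale!r}")
    if mean_concentration is None:
        return ""
    if mean_concentration < 0 or not np.isfinite(mean_concentration):
        raise ValidationError(f"invalid bin mean {mean_concentration!r}")
    if mean_concentration < 1.0:
        return ""
    for label, bound in zip(CLASS_LABELS, CLASS_BOUNDS[scale]):
        if mean_concentration <= bound:
            return label
    return "f"


def _above_threshold(labels: Sequence[str]) -> np.ndarray:
    return np.array([lab in ("d", "e", "f") for lab in labels], dtype=bool)


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """(start_index, end_index) of each maximal run of True values."""
    runs, start = [], None
    for i, v in enumerate(mask):
        if v and start is None:
            start = i
        elif not v and start is not None:
            runs.append((start, i - 1))
            start = None
    if start is not None:
        runs.append((start, len(mask) - 1))
    return runs


def seasonal_category(labels: Sequence[str], months: Sequence[int]) -> str:
    """Seasonal category of a taxon from its per-bin class labels.

    A bin is above threshold when its class is at least 'd'. With R the
    longest run of consecutive above-threshold bins:

    * ``all_year_round`` -- R >= 4 and above-threshold bins appear by May
      and persist into September or later;
    * ``summer`` / ``autumn`` / ``summer_autumn`` -- R >= 4 with the run
      inside Jun-Aug, inside Sep-Nov, or spanning from Jun-Aug into
      Sep-Nov respectively (runs beginning before June are treated as
      starting in June for this window matching);
    * ``short_term`` -- some above-threshold bin exists but R < 4;
    * ``none`` -- no bin reaches class 'd'.
    """
    if len(labels) != len(months):
        raise ValidationError("labels and months must align")
    above = _above_threshold(labels)
    if not above.any():
        return "none"
    runs = _runs(above)
    longest = max(runs, key=lambda r: (r[1] - r[0], -r[0]))
    run_len = longest[1] - longest[0] + 1
    if run_len < SEASONAL_RUN_BINS:
        return "short_term"
    idx = np.flatnonzero(above)
    m_first, m_last = months[idx[0]], months[idx[-1]]
    if m_first <= 5 and m_last >= 9:
        return "all_year_round"
    rs, re = months[longest[0]], months[longest[1]]
    rs = max(rs, _SUMMER[0])  # pre-June onset counts as a June start
    if re <= _SUMMER[-1]:
        return "summer"
    if rs >= _AUTUMN[0]:
        return "autumn"
    return "summer_autumn"


@dataclass(frozen=True)
class CalendarMatrix:
    """Spore calendar: taxa x 10-day-bin class labels plus categories.

    ``frame`` has one row per included taxon and one column per bin label
    (e.g. ``2022-06.2``), cells holding class letters or ''. ``categories``
    and ``scales`` map taxon -> seasonal category / class scale.
    """

    site: str
    frame: pd.DataFrame
    categories: dict[str, str]
    scales: dict[str, str]

    @property
    def taxa(self) -> list[str]:
        return list(self.frame.index)

    def to_frame(self) -> pd.DataFrame:
        out = self.frame.copy()
        out["category"] = [self.categories[t] for t in out.index]
        return out

    def to_text(self) -> str:
        """Monospaced text rendering of the calendar grid."""
        width = max([len(t) for t in self.taxa] or [5]) + 2
        bins = list(self.frame.columns)
        header = " " * width + " ".join(b[-4:] for b in bins)
        lines = [f"spore calendar - {self.site}", header]
        for taxon in self.taxa:
            cells = " ".join(
                f"{(self.frame.at[taxon, b] or '.'):>4}" for b in bins
            )
            lines.append(f"{taxon:<{width}}{cells}  [{self.categories[taxon]}]")
        return "\n".join(lines)


def build_calendar(
    series: Iterable[DailyConcentrationSeries],
    asin_min: float = DEFAULT_CALENDAR_ASIN_MIN,
    scales: dict[str, str] | None = None,
    sort: str = "season-start",
) -> CalendarMatrix:
    """Build the spore calendar for one site.

    Taxa with ASIn >= ``asin_min`` are included; rows are ordered by MSS
    start DOY (ties broken by descending SSIn) or alphabetically with
    ``sort='taxon'``. ``scales`` overrides the class scale per taxon
    (default: 'cladosporium' for taxa named Cladosporium*, else 'general').
    """
    series = [s for s in series]
    if not series:
        raise ValidationError("no concentration series given")
    sites = {s.site for s in series}
    if len(sites) > 1:
        raise ValidationError(f"calendar is per-site; got sites {sorted(sites)}")
    site = next(iter(sites))
    scales = dict(scales or {})

    kept = []
    for s in series:
        if annual_spore_integral(s) >= asin_min:
            kept.append(s)
    if not kept:
        logger.warning("no taxon reaches ASIn %g; calendar is empty", asin_min)
        return CalendarMatrix(site=site, frame=pd.DataFrame(), categories={}, scales={})

    order_key = {}
    rows, cats, used_scales = {}, {}, {}
    columns: list[str] | None = None
    for s in kept:
        scale = scales.get(
            s.taxon,
            "cladosporium" if s.taxon.strip().lower().startswith("cladosporium") else "general",
        )
        bins = ten_day_bins(s)
        labels = [exponential_class(b.mean_concentration, scale) for b in bins]
        months = [b.month for b in bins]
        if columns is None:
            columns = [b.label for b in bins]
        rows[s.taxon] = labels
        cats[s.taxon] = seasonal_category(labels, months)
        used_scales[s.taxon] = scale
        start, end = mss_90(s)
        order_key[s.taxon] = (start, -seasonal_spore_integral(s, start, end))

    if sort == "taxon":
        taxa = sorted(rows)
    elif sort == "season-start":
        taxa = sorted(rows, key=lambda t: (*order_key[t], t))
    else:
        raise ValidationError(f"unknown sort option {sort!r}")
    frame = pd.DataFrame([rows[t] for t in taxa], index=taxa, columns=columns)
    frame.index.name = "taxon"
    return CalendarMatrix(site=site, frame=frame, categories=cats, scales=used_scales)
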