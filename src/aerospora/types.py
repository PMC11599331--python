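"""Core domain types for daily bioaerosol monitoring data.

The atom of every downstream statistic is a per-(site, taxon) series of
daily mean airborne spore concentrations (spores/m3) as produced by a
Hirst-type volumetric trap. Days on which the sampler ran but the taxon
was not seen are recorded zeros; days absent from the record are treated
as *missing* and are distinguishable from zeros throughout.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "NoSeasonError",
    "UndefinedStatisticError",
    "to_doy",
    "DEFAULT_OPERATION_PERIOD",
    "DailyConcentrationSeries",
    "MeteoSeries",
    "TaxonProfile",
    "SiteMetadata",
]


class ValidationError(ValueError):
    """Input data violates a domain invariant (negative concentration, ...)."""


class NoSeasonError(ValueError):
    """A main spore season is undefined (annual integral is zero)."""


class UndefinedStatisticError(ValueError):
    """A statistic cannot be computed from the given input (too few pairs, ...)."""


#: Default sampler operation window (the monitoring campaign convention:
#: 1 February through 31 October of one year).
DEFAULT_OPERATION_PERIOD = (dt.date(2022, 2, 1), dt.date(2022, 10, 31))

METEO_VARIABLES = (
    "temperature",
    "relative_humidity",
    "wind_speed",
    "sunshine",
    "precipitation",
)


def to_doy(date: dt.date | dt.datetime | str | pd.Timestamp) -> int:
    """Day of year counted from 1 January (1 January -> 1; leap-year aware)."""
    ts = pd.Timestamp(date)
    return int(ts.dayofyear)


def _as_date(value) -> dt.date:
    return pd.Timestamp(value).date()


@dataclass(frozen=True)
class DailyConcentrationSeries:
    """Daily mean spore concentrations for one taxon at one site.

    Parameters
    ----------
    site, taxon
        Identifiers; free-form strings.
    values
        Mapping date -> concentration (spores/m3). Stored internally as a
        date-sorted :class:`pandas.Series`. Dates missing from the mapping
        are *missing observations*, not zeros.
    operation_period
        ``(first_date, last_date)`` the sampler was running. All recorded
        dates must fall inside it. Defaults to the span of the data.
    """

    site: str
    taxon: str
    values: pd.Series = field(repr=False)
    operation_period: tuple[dt.date, dt.date] | None = None

    def __init__(
        self,
        site: str,
        taxon: str,
        values: Mapping | pd.Series,
        operation_period: tuple | None = None,
    ):
        if not isinstance(values, pd.Series):
            values = pd.Series(dict(values), dtype=float)
        values = values.astype(float)
        values.index = pd.DatetimeIndex(values.index).rename(None)
        if values.index.has_duplicates:
            dup = values.index[values.index.duplicated()][0]
            raise ValidationError(
                f"duplicate date {dup.date()} for ({site}, {taxon})"
            )
        values = values.sort_index()
        if values.isna().any():
            raise ValidationError(f"NaN concentration in ({site}, {taxon})")
        if (values < 0).any():
            bad = values[values < 0].index[0]
            raise ValidationError(
                f"negative concentration on {bad.date()} for ({site}, {taxon})"
            )
        if operation_period is None:
            if len(values) == 0:
                raise ValidationError(
                    f"empty series for ({site}, {taxon}) needs an explicit operation_period"
                )
            operation_period = (values.index[0].date(), values.index[-1].date())
        else:
            operation_period = (_as_date(operation_period[0]), _as_date(operation_period[1]))
        if operation_period[0] > operation_period[1]:
            raise ValidationError("operation_period start after end")
        if len(values) and (
            values.index[0].date() < operation_period[0]
            or values.index[-1].date() > operation_period[1]
        ):
            raise ValidationError(
                f"recorded dates outside operation period for ({site}, {taxon})"
            )
        object.__setattr__(self, "site", site)
        object.__setattr__(self, "taxon", taxon)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "operation_period", operation_period)

    # -- convenience views -------------------------------------------------
    def __len__(self) -> int:
        return len(self.values)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.values.index

    @property
    def concentrations(self) -> np.ndarray:
        return self.values.to_numpy()

    @property
    def doys(self) -> np.ndarray:
        return self.values.index.dayofyear.to_numpy()

    @property
    def n_sampled(self) -> int:
        """Number of days with a recorded observation."""
        return len(self.values)

    @property
    def n_period_days(self) -> int:
        a, b = self.operation_period
        return (b - a).days + 1

    @property
    def missing_dates(self) -> pd.DatetimeIndex:
        full = pd.date_range(*self.operation_period, freq="D")
        return full.difference(self.values.index)

    def year(self) -> int:
        return self.operation_period[0].year


@dataclass(frozen=True)
class MeteoSeries:
    """Daily meteorological record for one site.

    Columns: temperature (degC, daily mean), relative_humidity (%, 0-100),
    wind_speed (m/s, >= 0), sunshine (h, 0-24), precipitation (mm, >= 0).
    """

    site: str
    frame: pd.DataFrame = field(repr=False)

    def __init__(self, site: str, frame: pd.DataFrame):
        frame = frame.copy()
        frame.index = pd.DatetimeIndex(frame.index).rename(None)
        if frame.index.has_duplicates:
            raise ValidationError(f"duplicate meteorological dates for {site}")
        frame = frame.sort_index()
        missing = [c for c in METEO_VARIABLES if c not in frame.columns]
        if missing:
            raise ValidationError(f"meteo table missing columns: {missing}")
        frame = frame[list(METEO_VARIABLES)].astype(float)
        rh = frame["relative_humidity"]
        if ((rh < 0) | (rh > 100)).any():
            raise ValidationError("relative_humidity outside [0, 100]")
        if (frame["wind_speed"] < 0).any():
            raise ValidationError("negative wind_speed")
        sun = frame["sunshine"]
        if ((sun < 0) | (sun > 24)).any():
            raise ValidationError("sunshine outside [0, 24] h")
        if (frame["precipitation"] < 0).any():
            raise ValidationError("negative precipitation")
        object.__setattr__(self, "site", site)
        object.__setattr__(self, "frame", frame)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def dates(self) -> pd.DatetimeIndex:
        return self.frame.index

    def variable(self, name: str) -> pd.Series:
        if name not in METEO_VARIABLES:
            raise KeyError(f"unknown meteorological variable {name!r}")
        return self.frame[name]


@dataclass(frozen=True)
class TaxonProfile:
    """Static metadata for one spore taxon.

    ``group`` is the coarse taxonomic group (A Ascomycota, B Basidiomycota,
    P Protozoa, Ch Chromista). ``hd_threshold`` is the clinically relevant
    daily concentration above which a day counts as a high day (100
    spores/m3 by default; 3000 for *Cladosporium*). ``calendar_scale``
    selects which exponential class boundaries apply in the spore calendar.
    """

    name: str
    group: str = "A"
    hd_threshold: float = 100.0
    calendar_scale: str = "general"
    release_mode: str = "unknown"
    allergen_listed: bool = False

    def __post_init__(self):
        if self.group not in {"A", "B", "P", "Ch"}:
            raise ValidationError(f"unknown taxonomic group {self.group!r}")
        if self.hd_threshold <= 0:
            raise ValidationError("hd_threshold must be positive")
        if self.calendar_scale not in {"general", "cladosporium"}:
            raise ValidationError(f"unknown calendar scale {self.calendar_scale!r}")
        if self.release_mode not in {"dry", "wet", "unknown"}:
            raise ValidationError(f"unknown release mode {self.release_mode!r}")


@dataclass(frozen=True)
class SiteMetadata:
    name: str
    latitude: float = float("nan")
    longitude: float = float("nan")
    sampler_height: float = float("nan")

    def __post_init__(self):
        if not np.isnan(self.latitude) and not -90 <= self.latitude <= 90:
            raise ValidationError("latitude outside [-90, 90]")
        if not np.isnan(self.longitude) and not -180 <= self.longitude <= 180:
            raise ValidationError("longitude outside [-180, 180]")


def group_by_site(series: Iterable[DailyConcentrationSeries]) -> dict[str, list[DailyConcentrationSeries]]:
    """Bucket a collection of concentration series by site identifier."""
    out: dict[str, list[DailyConcentrationSeries]] = {}
    for s in series:
        out.setdefault(s.site, []).append(s)
    return out
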