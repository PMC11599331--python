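"""CSV ingestion and emission for concentration, meteorology and taxon tables.

All tables are plain UTF-8 comma-separated files with ISO-8601 dates.
Concentration data travel in long format (``date,site,taxon,concentration``),
one row per sampled day; meteorology as one row per day with the five
standard variables.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .types import (
    METEO_VARIABLES,
    DailyConcentrationSeries,
    MeteoSeries,
    TaxonProfile,
    ValidationError,
)

__all__ = [
    "read_concentration_csv",
    "write_concentration_csv",
    "read_meteo_csv",
    "write_meteo_csv",
    "read_taxon_profiles",
]

_CONC_COLUMNS = ("date", "site", "taxon", "concentration")


def _parse_dates(raw: pd.Series, date_format: str | None, path) -> pd.Series:
    try:
        return pd.to_datetime(raw, format=date_format)
    except (ValueError, TypeError) as exc:
        raise ValidationError(f"{path}: unparseable date ({exc})") from exc


def read_concentration_csv(
    path,
    date_format: str | None = None,
    operation_period: tuple | None = None,
) -> list[DailyConcentrationSeries]:
    """Read a long-format concentration table into one series per (site, taxon).

    Raises :class:`ValidationError` on missing columns, unparseable dates,
    negative concentrations (naming the offending row) or duplicated
    (date, site, taxon) rows.
    """
    df = pd.read_csv(path)
    missing = [c for c in _CONC_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise ValidationError(f"{path}: empty concentration table")
    df["date"] = _parse_dates(df["date"], date_format, path)
    conc = pd.to_numeric(df["concentration"], errors="coerce")
    if conc.isna().any():
        row = int(df.index[conc.isna()][0]) + 2  # header + 1-based
        raise ValidationError(f"{path}: non-numeric concentration at line {row}")
    if (conc < 0).any():
        row = int(df.index[conc < 0][0]) + 2
        raise ValidationError(f"{path}: negative concentration at line {row}")
    df["concentration"] = conc
    dup = df.duplicated(subset=["date", "site", "taxon"])
    if dup.any():
        r = df[dup].iloc[0]
        raise ValidationError(
            f"{path}: duplicate row for ({r['date'].date()}, {r['site']}, {r['taxon']})"
        )
    out = []
    for (site, taxon), grp in df.groupby(["site", "taxon"], sort=True):
        values = pd.Series(grp["concentration"].to_numpy(), index=grp["date"])
        out.append(
            DailyConcentrationSeries(
                site=str(site), taxon=str(taxon), values=values,
                operation_period=operation_period,
            )
        )
    return out


def write_concentration_csv(series: Iterable[DailyConcentrationSeries], path) -> None:
    rows = []
    for s in series:
        for date, c in s.values.items():
            rows.append((date.date().isoformat(), s.site, s.taxon, c))
    pd.DataFrame(rows, columns=list(_CONC_COLUMNS)).to_csv(path, index=False)


def read_meteo_csv(path, site: str | None = None, date_format: str | None = None) -> MeteoSeries:
    """Read a daily meteorology table (``date`` plus the five variables).

    An optional ``site`` column is honoured; with several sites present the
    ``site`` argument selects one.
    """
    df = pd.read_csv(path)
    if len(df) == 0:
        raise ValidationError(f"{path}: empty meteorology table")
    if "date" not in df.columns:
        raise ValidationError(f"{path}: missing 'date' column")
    df["date"] = _parse_dates(df["date"], date_format, path)
    if "site" in df.columns:
        sites = df["site"].unique()
        if site is None:
            if len(sites) > 1:
                raise ValidationError(
                    f"{path}: multiple sites {list(sites)}; pass site=..."
                )
            site = str(sites[0])
        df = df[df["site"] == site]
        if len(df) == 0:
            raise ValidationError(f"{path}: no rows for site {site!r}")
    elif site is None:
        site = Path(str(path)).stem
    frame = df.set_index("date")
    return MeteoSeries(site=str(site), frame=frame)


def write_meteo_csv(meteo: MeteoSeries, path) -> None:
    out = meteo.frame.copy()
    out.insert(0, "site", meteo.site)
    out.index.name = "date"
    out.reset_index().assign(date=lambda d: d["date"].dt.date).to_csv(path, index=False)


def read_taxon_profiles(path) -> dict[str, TaxonProfile]:
    """Read taxon metadata (name,group,hd_threshold,calendar_scale,release_mode[,allergen_listed])."""
    df = pd.read_csv(path)
    if "name" not in df.columns:
        raise ValidationError(f"{path}: missing 'name' column")
    profiles = {}
    for _, row in df.iterrows():
        profiles[str(row["name"])] = TaxonProfile(
            name=str(row["name"]),
            group=str(row.get("group", "A")),
            hd_threshold=float(row.get("hd_threshold", 100.0)),
            calendar_scale=str(row.get("calendar_scale", "general")),
            release_mode=str(row.get("release_mode", "unknown")),
            allergen_listed=bool(row.get("allergen_listed", False)),
        )
    return profiles
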