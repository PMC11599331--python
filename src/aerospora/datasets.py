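"""Bundled reference tables from a 2022 two-site aerobiological survey.

A Hirst-trap monitoring campaign ran February-October 2022 at an urban
station (Bratislava, "BA") and a rural station (Kaplna, "KP") in
southwestern Slovakia. The raw daily counts are not public, but the
published summary tables are, and several derived quantities (totals,
percentage contributions, season lengths, rank tests on the per-taxon
annual integrals) can be recomputed from them. The two tables are bundled
as plain CSV:

* ``slovakia2022_asin.csv`` -- all 67 spore groups with their annual spore
  integral (ASIn, spore.day/m3) and occurrence frequency (% of sampled
  days) per site; an empty cell means the taxon was not recorded there.
* ``slovakia2022_mss.csv`` -- the 19 abundant taxa (ASIn > 2000 at both
  sites) with their main-spore-season characteristics per site: start/end
  day of year, printed season length, seasonal spore integral (SSIn), peak
  value and day, and number of high days.

A few cells of the season table were typeset ambiguously in the source;
the bundled values are the unique readings consistent with the row's own
integrals and thresholds (peak <= ASIn, high days = 0 iff the peak does
not exceed the threshold, out-of-season peak mass <= ASIn - SSIn).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_asin_table", "load_season_table", "SITES"]

SITES = ("BA", "KP")


def _read(name: str) -> pd.DataFrame:
    with resources.files("aerospora.data").joinpath(name).open("rb") as fh:
        return pd.read_csv(fh)


def load_asin_table() -> pd.DataFrame:
    """Annual spore integrals and frequencies for all 67 spore groups.

    Columns: taxon, group, asin_ba, freq_ba, asin_kp, freq_kp. ASIn cells
    are NaN where the taxon was absent from a site's record.
    """
    return _read("slovakia2022_asin.csv")


def load_season_table() -> pd.DataFrame:
    """Main-spore-season characteristics of the 19 abundant taxa, long
    format (one row per taxon and site)."""
    return _read("slovakia2022_mss.csv")
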