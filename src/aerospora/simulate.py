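"""Synthetic daily spore-concentration and meteorology generator.

Emulates a two-site (urban vs rural) Hirst-trap monitoring campaign in a
temperate continental climate: a February-October operation period, one
unimodal sporulation season per taxon, multiplicative lognormal day-to-day
noise (daily concentrations are non-negative and right-skewed), and
meteorological coupling through standardised covariates. Dry-released taxa
respond positively to temperature and sunshine and negatively to humidity;
wet-released taxa respond positively to humidity and precipitation. The
urban site scales every taxon's seasonal amplitude by a common multiplier
(default 2, mimicking the commonly observed two-fold urban excess).

Every stream of randomness derives deterministically from one global seed,
so a simulated dataset is byte-identically reproducible.

The daily concentration model is::

    c(t) = round( (baseline + m_site * amplitude * k(t)) * exp(sum_j beta_j z_j(t)) * eps(t) )

with ``k`` a unimodal kernel on the season window (Hann bump by default,
0 outside), ``z_j`` the meteorological variables standardised over the
simulated period, ``beta_j`` dimensionless couplings and
``eps ~ lognormal(0, noise_sigma)``. The release-mechanics modulation
``exp(beta . z)`` multiplies the background as well as the seasonal
source: spores present outside the main season are liberated by the same
weather that drives in-season release, which is what makes the full-period
concentration-humidity rank correlation of a wet-released taxon positive
rather than an artefact of season placement.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import write_concentration_csv, write_meteo_csv
from .types import (
    DEFAULT_OPERATION_PERIOD,
    DailyConcentrationSeries,
    MeteoSeries,
    ValidationError,
)

__all__ = [
    "MeteoSimSpec",
    "TaxonSimSpec",
    "SimulationTruth",
    "simulate_meteo",
    "simulate_taxon",
    "simulate_dataset",
    "default_taxon_specs",
]

_DRY_BETAS = {"temperature": 0.35, "relative_humidity": -0.25, "sunshine": 0.15, "precipitation": 0.0}
_WET_BETAS = {"temperature": 0.0, "relative_humidity": 1.0, "sunshine": -0.25, "precipitation": 0.35}


@dataclass(frozen=True)
class MeteoSimSpec:
    """Generative parameters for the daily meteorology of one site.

    Temperature follows an annual sinusoid plus Gaussian noise; relative
    humidity is a baseline minus a temperature anomaly coupling, clipped to
    [20, 100] %; precipitation is a Bernoulli wet-day indicator times a
    gamma magnitude; sunshine is the astronomical daylight sinusoid scaled
    down on wet days; wind speed is lognormal. Defaults approximate a
    lowland Central European station (annual mean ~11 degC, ~800 mm/yr).
    """

    period: tuple[dt.date, dt.date] = DEFAULT_OPERATION_PERIOD
    temp_mean: float = 11.0          # degC annual mean
    temp_amplitude: float = 10.5     # degC seasonal half-range
    temp_peak_doy: int = 200         # mid-July maximum
    temp_noise_sd: float = 2.0
    rh_baseline: float = 72.0        # % at the annual mean temperature
    rh_temp_coupling: float = 0.8    # % drop per degC of temperature anomaly
    rh_noise_sd: float = 11.0        # day-to-day (rain-event) variability
    wet_day_prob: float = 0.33
    precip_gamma_shape: float = 0.7
    precip_gamma_scale_mm: float = 9.0
    sunshine_clear_fraction: float = 0.55
    sunshine_wet_penalty: float = 0.35
    sunshine_noise_sd: float = 0.15
    wind_median_ms: float = 3.0
    wind_sigma: float = 0.4

    def noiseless_temperature(self, doys: np.ndarray) -> np.ndarray:
        phase = 2.0 * np.pi * (doys - self.temp_peak_doy) / 365.25
        return self.temp_mean + self.temp_amplitude * np.cos(phase)


def _daylight_hours(doys: np.ndarray) -> np.ndarray:
    # ~48 deg N: daylight between ~8.2 h (winter) and ~15.8 h (summer)
    return 12.0 + 3.8 * np.cos(2.0 * np.pi * (doys - 172) / 365.25)


def simulate_meteo(spec: MeteoSimSpec, seed: int | np.random.SeedSequence, site: str = "site") -> MeteoSeries:
    """Simulate one daily meteorological record; identical seed, identical output."""
    rng = np.random.default_rng(seed)
    dates = pd.date_range(spec.period[0], spec.period[1], freq="D")
    doys = dates.dayofyear.to_numpy()
    n = len(dates)

    temp = spec.noiseless_temperature(doys) + rng.normal(0.0, spec.temp_noise_sd, n)
    rh = (
        spec.rh_baseline
        - spec.rh_temp_coupling * (temp - spec.temp_mean)
        + rng.normal(0.0, spec.rh_noise_sd, n)
    )
    rh = np.clip(rh, 20.0, 100.0)
    wet = rng.random(n) < spec.wet_day_prob
    precip = np.where(
        wet, rng.gamma(spec.precip_gamma_shape, spec.precip_gamma_scale_mm, n), 0.0
    )
    daylight = _daylight_hours(doys)
    frac = (
        spec.sunshine_clear_fraction
        - spec.sunshine_wet_penalty * wet
        + rng.normal(0.0, spec.sunshine_noise_sd, n)
    )
    sunshine = daylight * np.clip(frac, 0.0, 1.0)
    wind = rng.lognormal(np.log(spec.wind_median_ms), spec.wind_sigma, n)

    frame = pd.DataFrame(
        {
            "temperature": temp,
            "relative_humidity": rh,
            "wind_speed": wind,
            "sunshine": sunshine,
            "precipitation": precip,
        },
        index=dates,
    )
    return MeteoSeries(site=site, frame=frame)


@dataclass(frozen=True)
class TaxonSimSpec:
    """Generative parameters for one taxon's daily concentration series."""

    name: str
    amplitude: float                  # spores/m3 at the kernel maximum
    season_start_doy: int
    season_end_doy: int
    baseline: float = 0.5             # spores/m3 background outside the season
    kernel: str = "hann"              # 'hann' (smooth bump) or 'rect'
    noise_sigma: float = 0.4          # lognormal sd on the log scale
    release_mode: str = "unknown"
    betas: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        if self.amplitude < 0 or self.baseline < 0:
            raise ValidationError(f"{self.name}: negative baseline/amplitude")
        if self.season_start_doy > self.season_end_doy:
            raise ValidationError(f"{self.name}: season window reversed")
        if self.kernel not in {"hann", "rect"}:
            raise ValidationError(f"{self.name}: unknown kernel {self.kernel!r}")

    @classmethod
    def dry(cls, name, amplitude, season_start_doy, season_end_doy, **kw):
        """Dry-release defaults: warm/sunny days up, humid days down."""
        kw.setdefault("betas", dict(_DRY_BETAS))
        return cls(name, amplitude, season_start_doy, season_end_doy,
                   release_mode="dry", **kw)

    @classmethod
    def wet(cls, name, amplitude, season_start_doy, season_end_doy, **kw):
        """Wet-release defaults: humid/rainy days up, sunny days down."""
        kw.setdefault("betas", dict(_WET_BETAS))
        return cls(name, amplitude, season_start_doy, season_end_doy,
                   release_mode="wet", **kw)

    def kernel_weights(self, doys: np.ndarray) -> np.ndarray:
        start, end = self.season_start_doy, self.season_end_doy
        inside = (doys >= start) & (doys <= end)
        if self.kernel == "rect":
            return inside.astype(float)
        span = max(end - start, 1)
        x = (doys - start) / span
        w = np.where(inside, 0.5 - 0.5 * np.cos(2.0 * np.pi * np.clip(x, 0, 1)), 0.0)
        return w


def _standardise(frame: pd.DataFrame) -> pd.DataFrame:
    sd = frame.std(ddof=0).replace(0.0, 1.0)
    return (frame - frame.mean()) / sd


def simulate_taxon(
    spec: TaxonSimSpec,
    meteo: MeteoSeries,
    seed: int | np.random.SeedSequence,
    site_multiplier: float = 1.0,
) -> DailyConcentrationSeries:
    """Simulate one (taxon, site) daily concentration series on the meteo dates."""
    if site_multiplier < 0:
        raise ValidationError("site_multiplier must be non-negative")
    rng = np.random.default_rng(seed)
    dates = meteo.dates
    doys = dates.dayofyear.to_numpy()
    z = _standardise(meteo.frame)
    coupling = np.zeros(len(dates))
    for var, beta in spec.betas.items():
        coupling += beta * z[var].to_numpy()
    eps = (
        rng.lognormal(0.0, spec.noise_sigma, len(dates))
        if spec.noise_sigma > 0
        else np.ones(len(dates))
    )
    source = spec.baseline + site_multiplier * spec.amplitude * spec.kernel_weights(doys)
    c = source * np.exp(coupling) * eps
    values = pd.Series(np.rint(c), index=dates)
    return DailyConcentrationSeries(
        site=meteo.site, taxon=spec.name, values=values,
        operation_period=(dates[0].date(), dates[-1].date()),
    )


@dataclass
class SimulationTruth:
    """Everything needed to reproduce a simulated dataset and check recovery."""

    seed: int
    sites: tuple[str, str]
    urban_multiplier: float
    meteo_spec: MeteoSimSpec
    taxa: list[TaxonSimSpec]
    realised_asin: dict[str, dict[str, float]] = field(default_factory=dict)
    #: MSS of the noise-free expectation series, per taxon and site; this is
    #: the "true" season a perfect estimator would recover.
    realised_window: dict[str, dict[str, tuple[int, int]]] = field(default_factory=dict)

    def kernel_window(self, taxon: str) -> tuple[int, int]:
        spec = next(t for t in self.taxa if t.name == taxon)
        return spec.season_start_doy, spec.season_end_doy

    def to_json(self) -> str:
        payload = {
            "seed": self.seed,
            "sites": list(self.sites),
            "urban_multiplier": self.urban_multiplier,
            "meteo_spec": {
                **dataclasses.asdict(self.meteo_spec),
                "period": [d.isoformat() for d in self.meteo_spec.period],
            },
            "taxa": [dataclasses.asdict(t) for t in self.taxa],
            "realised_asin": self.realised_asin,
            "realised_window": self.realised_window,
        }
        return json.dumps(payload, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "SimulationTruth":
        raw = json.loads(text)
        mspec = dict(raw["meteo_spec"])
        mspec["period"] = tuple(dt.date.fromisoformat(d) for d in mspec["period"])
        return cls(
            seed=raw["seed"],
            sites=tuple(raw["sites"]),
            urban_multiplier=raw["urban_multiplier"],
            meteo_spec=MeteoSimSpec(**mspec),
            taxa=[TaxonSimSpec(**t) for t in raw["taxa"]],
            realised_asin=raw["realised_asin"],
            realised_window={
                taxon: {site: tuple(w) for site, w in per_site.items()}
                for taxon, per_site in raw.get("realised_window", {}).items()
            },
        )


def _mss_of(series: DailyConcentrationSeries) -> tuple[int, int]:
    # local import: season depends on types only, no cycle in practice
    from .season import mss_90

    return mss_90(series)


def default_taxon_specs() -> list[TaxonSimSpec]:
    """Nineteen abundant-taxon specifications emulating the mix of dry- and
    wet-released taxa, season windows and intensities typical of a lowland
    Central European season (rural-site amplitudes; the urban site applies
    the urban multiplier on top)."""
    d, w = TaxonSimSpec.dry, TaxonSimSpec.wet
    return [
        d("Cladosporium", 8000.0, 96, 323, baseline=30.0),
        d("Alternaria", 450.0, 166, 299, baseline=4.0),
        d("Epicoccum", 120.0, 166, 308, baseline=4.0),
        d("Ganoderma", 220.0, 164, 300, baseline=2.0),
        d("Arthrinium", 60.0, 74, 295, baseline=3.0),
        d("Oidium type", 500.0, 113, 230, baseline=2.0),
        d("Periconia", 30.0, 62, 307, baseline=2.0),
        d("Torula", 30.0, 74, 290, baseline=2.0),
        d("Aspergillus/Penicillium", 50.0, 86, 295, baseline=1.0),
        d("Xylariaceae", 110.0, 160, 312, baseline=3.0),
        w("Coprinus type", 1800.0, 130, 311, baseline=10.0),
        w("Leptosphaeria type", 600.0, 116, 307, baseline=8.0),
        w("Coprinus", 70.0, 131, 322, baseline=3.0),
        w("Agaricus type", 800.0, 219, 304, baseline=4.0),
        w("Agrocybe", 90.0, 159, 321, baseline=3.0),
        w("Ascochyta", 55.0, 117, 307, baseline=2.0),
        w("Fusarium", 45.0, 116, 312, baseline=2.0),
        w("Myxomycetes", 280.0, 130, 315, baseline=4.0),
        w("Pleospora", 45.0, 90, 326, baseline=2.0),
    ]


def simulate_dataset(
    taxa: Sequence[TaxonSimSpec] | None = None,
    meteo_spec: MeteoSimSpec | None = None,
    sites: tuple[str, str] = ("urban", "rural"),
    urban_multiplier: float = 2.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[list[DailyConcentrationSeries], dict[str, MeteoSeries], SimulationTruth]:
    """Simulate a full two-site campaign.

    The first site in ``sites`` is the urban one and gets every amplitude
    multiplied by ``urban_multiplier``. With ``out_dir`` set, writes
    ``concentrations.csv``, ``meteo.csv`` and ``truth.json`` there.
    """
    taxa = list(taxa) if taxa is not None else default_taxon_specs()
    if not taxa:
        raise ValidationError("at least one taxon spec required")
    meteo_spec = meteo_spec or MeteoSimSpec()

    root = np.random.SeedSequence(seed)
    site_seqs = root.spawn(len(sites))
    all_series: list[DailyConcentrationSeries] = []
    meteo_by_site: dict[str, MeteoSeries] = {}
    truth = SimulationTruth(
        seed=seed, sites=tuple(sites), urban_multiplier=urban_multiplier,
        meteo_spec=meteo_spec, taxa=taxa,
    )
    for site, seq in zip(sites, site_seqs):
        met_seq, *taxon_seqs = seq.spawn(len(taxa) + 1)
        meteo = simulate_meteo(meteo_spec, met_seq, site=site)
        meteo_by_site[site] = meteo
        mult = urban_multiplier if site == sites[0] else 1.0
        for spec, tseq in zip(taxa, taxon_seqs):
            s = simulate_taxon(spec, meteo, tseq, site_multiplier=mult)
            all_series.append(s)
            truth.realised_asin.setdefault(spec.name, {})[site] = float(s.values.sum())
            noiseless = simulate_taxon(
                dataclasses.replace(spec, noise_sigma=0.0), meteo, tseq,
                site_multiplier=mult,
            )
            truth.realised_window.setdefault(spec.name, {})[site] = _mss_of(noiseless)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_concentration_csv(all_series, out / "concentrations.csv")
        frames = []
        for site, met in meteo_by_site.items():
            f = met.frame.copy()
            f.insert(0, "site", site)
            f.index.name = "date"
            frames.append(f.reset_index())
        combined = pd.concat(frames, ignore_index=True)
        combined["date"] = combined["date"].dt.date
        combined.to_csv(out / "meteo.csv", index=False)
        (out / "truth.json").write_text(truth.to_json())
    return all_series, meteo_by_site, truth
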