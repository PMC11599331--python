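# Methods

## Data model

The atom is a per-(site, taxon) series of daily mean airborne spore
concentrations (spores/m³), as produced by a Hirst-type volumetric trap
read under light microscopy. Days the sampler ran but the record lacks are
*missing* and are kept distinct from recorded zeros: integrals and
cumulative sums treat missing days as 0 (with a warning), occurrence
frequency divides by sampled days only, and 10-day bin means average over
the recorded days in the bin. The default operation period is
1 February – 31 October of one year (273 days), configurable everywhere.

## Main spore season (90 % method)

The MSS is the central block of the annual integral: start = first day
whose cumulative sum strictly exceeds 5 % of ASIn, end = first day whose
cumulative sum strictly exceeds 95 %. Strict exceedance on *both* ends is
deliberate: it makes the two boundaries symmetric, guarantees
SSIn > 0.90·ASIn, and resolves the degenerate cases (a day landing exactly
on the 5 % or 95 % line belongs outside the season). Season length uses
the inclusive convention `end − start + 1`, which reproduces every
published urban-site length of the bundled 2022 table (the rural lengths
there are systematically `end − start`, an off-by-one in the source that
we do not emulate).

The whole-period maximum can legitimately fall outside the MSS (a single
large day inside the 5 % tails); the season summary therefore warns rather
than fails when `peak_doy` is outside `[start, end]`. On unimodal
synthetic data the peak is always inside, and the test suite asserts it.

High days are counted over the whole operation period, not only inside the
MSS, with strict exceedance of the threshold (100 spores/m³ default,
3000 spores/m³ for *Cladosporium*); this reproduces rows where a taxon has
a defined season but zero high days because its peak never tops the
threshold.

## Spore calendar

Ten-day periods are month thirds (1–10, 11–20, 21–end; the third period
spans 8–11 days), which keeps columns aligned with month labels. The six
exponential classes are printed as integer ranges; since bin means are
real-valued the classes are implemented as the half-open partition of
[1, ∞): a [1,10], b (10,50], c (50,100], d (100,500], e (500,1000],
f (1000,∞), and ten-fold analogues for the *Cladosporium* scale with
f above 10 000 (the printed "> 10 001" for the top class is treated as a
typo; a gap between 10 000 and 10 001 would break the partition). Means
below 1 carry no class.

A taxon is *seasonal* when its 10-day means stay above class "d"
(i.e. above the embedded high-day threshold) continuously for over a
month, implemented as ≥ 4 consecutive bins (3 bins are exactly one month;
"over" requires more). Categories: all-year-round when above-threshold
bins appear by May and persist into September; otherwise summer / autumn /
summer–autumn by whether the longest run falls inside June–August, inside
September–November, or spans from the former into the latter (a run
beginning before June that is not all-year-round counts as starting in
June for this window matching — the published rule leaves such runs
unnamed, and this fallback makes the function total without affecting any
stated case). Shorter exceedances are short-term; no exceedance, none.

Calendar rows require ASIn ≥ 250 spore·day/m³ and are ordered by MSS start
day (ties by descending SSIn); calendars in the literature order rows
"chronologically by season intensity", which underdetermines the sort, so
it is an explicit option.

## Comparative statistics

Percentage contributions round half-up to the printed number of decimals.
Spearman correlations pair each taxon's daily concentrations with the five
standard meteorological variables over the full operation period by
default (`--mss-only` restricts to the season); ties receive average
ranks and the two-sided p-value uses the t-approximation
(scipy.stats.spearmanr underneath, cross-checked in the tests against a
longhand rank-formula oracle). The paired Wilcoxon test follows the R
`wilcox.test` conventions (V = sum of ranks of positive differences,
zeros dropped, average ranks): the null distribution is exact for up to
25 retained untied pairs (dynamic programming over rank subsets),
otherwise a normal approximation with continuity and tie corrections.
When comparing two sites' per-taxon integrals, every taxon recorded at
either site forms a pair, with absent entries imputed as 0.

## Synthetic data generator

The generator emulates the design of a two-site urban/rural campaign:

* **Meteorology.** Temperature is an annual sinusoid (mean 11 °C,
  half-range 10.5 °C, mid-July peak) plus N(0, 2 °C) noise. Relative
  humidity is a 72 % baseline minus 0.8 %/°C of the temperature anomaly
  plus N(0, 11 %) day-to-day variability, clipped to [20, 100] %; the
  large daily term reflects rain-event variability, which in temperate
  climates is comparable to the seasonal swing — without it humidity would
  be a pure mirror of temperature and no humidity-specific coupling could
  ever be expressed. Precipitation is Bernoulli(0.33) wet days with
  gamma(0.7, 9 mm) magnitudes (≈ 800 mm/yr); sunshine is the astronomical
  daylight sinusoid at ~48° N scaled down on wet days; wind is lognormal
  (median 3 m/s, σ = 0.4).
* **Concentrations.**
  `c(t) = round((baseline + m_site · A · k(t)) · exp(Σ β_j z_j(t)) · ε(t))`
  with `k` a Hann bump on the taxon's season window (rectangular
  optional), `z_j` the meteorological variables standardised over the
  simulated period (keeping the couplings β unitless), and
  `ε ~ lognormal(0, σ)` with σ = 0.4 by default — multiplicative
  right-skewed noise, matching the heavy-tailed daily peaks of real count
  data; results are rounded to whole spores. The weather modulation
  multiplies the background *and* the seasonal source: out-of-season
  spores are liberated by the same mechanics as in-season ones, and this
  is what lets a wet-released taxon show the positive full-period
  concentration–humidity rank correlation observed in real data instead
  of an artefact of season placement.
* **Release modes.** Dry: β = (+0.35 temperature, −0.25 humidity,
  +0.15 sunshine, 0 precipitation). Wet: β = (0, +1.0, −0.25, +0.35).
  The humidity coupling for wet taxa must be strong because the
  season-versus-humidity confound (seasons peak when humidity is lowest)
  works against it; +1.0 per standard unit is the level at which the
  mechanism, not the season placement, determines the correlation sign
  across all default windows.
* **Sites.** The first site multiplies every amplitude by the urban
  multiplier (default 2, the commonly observed urban excess); both sites
  draw independent weather from the same climate.
* **Defaults.** Nineteen taxa named after the abundant groups of the 2022
  survey, with season windows taken from its published season table and
  amplitudes/baselines chosen so the generated integrals clear the
  2000 spore·day/m³ abundance filter at both sites.
* **Determinism.** One global seed fans out through
  `numpy.random.SeedSequence.spawn` to one stream per site, meteorology
  and taxon; identical seeds give byte-identical CSVs.

**Ground truth for recovery tests.** `SimulationTruth` records, besides
every parameter, the *realised* season window per (taxon, site): the MSS
of the noise-free twin (σ = 0) of each series under the same weather.
That — not the kernel support — is what a perfect estimator would recover:
the 5 %/95 % crossings of a smooth kernel sit well inside its support, so
comparing against kernel edges would measure the kernel shape, not
estimator error. Under the defaults, noisy-replicate boundaries fall
within ±5 days of the noise-free ones ~93 % of the time (asserted ≥ 90 %
over 100 replicates), the dry-mode temperature correlation is positive in
effectively all of 200 simulated seasons (asserted ≥ 95 %), and the
per-taxon median humidity correlation is negative for every dry and
positive for every wet default taxon.

**What the generator does not emulate.** No spore transport or
resuspension, no autocorrelated weather (days are conditionally
independent), no multi-day rain episodes, no sampler failure patterns
beyond simple missingness, and site weather is independent rather than
spatially correlated. Passing recovery tests therefore demonstrate the
pipeline's correctness on data of this structure, not forecasting skill on
real seasons.

## Reference tables and their recomputation

The bundled 2022 survey tables let the tests recompute every quantity
derivable from published cells: the urban total integral (exact), the
dominant-taxon percentage contributions (exact at printed precision), all
urban season lengths (exact under the inclusive convention), the mean
urban SSIn (117,480.5 vs printed 117,480), and the presence/abundance
counts (64/59 spore groups, 19 abundant taxa — identical to the published
season-table taxa). Two published aggregates do not recompute from their
own table: the mean urban peak value (printed 3845; the per-taxon column
yields 4203.9, and no reading of the ambiguous cells can bring the column
mean below ~4100) and the paired Wilcoxon statistic (printed V = 1644.5;
the 67 pairs with absent sites as zero give V = 1678.5 at p = 7.6·10⁻⁴,
and no defensible pairing variant reproduces the printed value, though the
published significance level holds). The corresponding tests assert the
printed values and fail, documenting the discrepancy rather than hiding
it.

## Numerical choices

Cumulative-sum crossings use exact comparisons (no epsilon): daily inputs
are integer-valued in practice and the strict/non-strict distinction is
part of the season definition. Peak ties break to the earliest day.
Percentages round half-up (`decimal`), not banker's rounding, to match
printed tables. Simulated concentrations round to integers via `rint`.
Problem sizes in the tests (100 boundary-recovery replicates, 200
sign-recovery seasons, oracle inputs of length ≤ 10–30) are the sizes at
which the exhaustive oracles are exact and the stochastic assertions have
comfortable margins.
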