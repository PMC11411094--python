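# Methods

## Signal model

The analysis unit is the 30-min mean R-R interval series `P_t` (ms) of one
animal over its final gestation week, modelled as

    P_t = trend_t + seasonal_t + remainder_t

where the trend carries the pre-calving pattern (slow rise → peak → sharp
decline), the seasonal component is a 24-h cycle (feeding/activity rhythm),
and the remainder is short-term autocorrelated variability. The calving
signal is the *turning point*: the time at which the trend switches from
rising to falling, operationalised as the peak of a technical indicator
computed on the estimated trend.

## Preprocessing

Beat-level cleaning removes any R-R interval deviating from "the average"
by more than 30 %. The average is deliberately causal: the mean of the last
60 *accepted* beats (all accepted beats so far during warm-up, first beat
always accepted), so the rule works online and adapts to the slow trend
drift the analysis depends on. The comparison is strict (`> 0.30`), so a
beat at exactly 1.3× the running mean survives. Because rejected beats
never enter later means, the filter is idempotent. Both the threshold and
the window are configurable.

Accepted beats are averaged over left-closed, right-open 30-min bins
aligned to recording start. A bin with fewer than 30 beats is declared
missing — a lenient floor, since a 30-min bin at cow heart rates holds
over 2,000 beats. Interior missing runs of at most 48 bins (24 h) are
filled by linear interpolation; longer runs are refused rather than
invented. Leading/trailing missing bins are trimmed.

## Decomposition

The primary trend extractor is STL with period 48 bins. The seasonal LOESS
window defaults to "periodic" (one fixed daily shape for the whole
recording), implemented as a degree-0 seasonal LOESS whose window spans
every cycle — with only ~7 daily cycles per recording there is no basis for
estimating a drifting daily pattern. The trend window defaults to the
standard STL formula (73 bins ≈ 36.5 h for these settings); robustness
iterations are off (Gaussian error model). The remainder is defined by the
reconstruction identity, which therefore holds exactly.

A plain LOESS smoother (tricube-weighted local polynomial; span 0.75,
degree 2 by default) is provided as an alternative single-curve trend
estimate. It is hand-implemented because the available lowess routines
support local-linear fits only, and the degree-2 variant is part of the
method's standard parameterisation. Inside STL the trend LOESS is locally
linear, per the canonical algorithm.

## Indicators

All four indicators operate on the trend with trading-chart defaults:
SMA n = 12 bins (6 h), MAD n = 12, MACD 12/26, RSI n = 14. Design choices
where conventions diverge:

* **MAD and MACD are per-cent forms by default** (`100·(P−SMA)/SMA`,
  `100·(EMA_s−EMA_l)/EMA_l`). Deviation-*rate* is the defining property of
  MAD, and per-cent values of order 0.1–0.5 are the natural scale for a
  ~600–750 ms trend; raw millisecond differences are available via
  `mode="difference"`.
* **EMA initialisation**: mean of the first n values (warm-up n−1), the
  usual charting convention; first-value initialisation is available.
* **MACD short window**: 12 (the common 12/26 default); 9 can be set in
  config.
* **RSI uses simple (unweighted) sums** of upward and absolute downward
  changes (Cutler's form), which makes it exactly scale-invariant and
  insensitive to the series start; Wilder's exponential smoothing is
  optional. An all-zero-change window yields 50 (balance) rather than 0/0.

Warm-up regions are explicit NaNs: SMA/EMA n−1 bins, MACD long−1, RSI n.

## Turning-point detection

*Retrospective*: global maximum of the defined indicator values, earliest
bin on ties. An indicator that never strictly exceeds its floor (MAD/MACD
0, RSI 50; none for SMA) has produced no signal — this reproduces the
expected silence of momentum indicators on animals whose trend only
declines during the observation window. *Online*: first local maximum
above the floor confirmed by k = 3 consecutive non-increasing bins
(1.5 h confirmation lag); deliberately simple so it runs in real time on a
stream. The combined MAD+RSI rule restricts online MAD-peak search to bins
where MAD > 0 and RSI > 50 simultaneously. Divergence (indicator moving
against the trend over a trailing window) is surfaced as a flag but never
gates a signal.

## Statistical comparison

Each animal contributes one remaining time per indicator — a randomized
complete block design with the animal as block. For complete balanced data
the omnibus indicator effect is computed exactly from sums of squares
(F with (a−1), (a−1)(b−1) degrees of freedom); this is identical to the
Gaussian mixed model with a subject random intercept for that layout.
Subjects missing any of MAD/MACD/RSI are dropped by default; an unbalanced
path fits the mixed model by REML and Wald-tests the indicator effect with
containment denominator degrees of freedom. Pairwise contrasts are paired
comparisons (F = squared paired t) at Bonferroni-adjusted α = 0.05/3,
using all subjects with both members of the pair unless restricted to
complete triples. Summaries use n−1 standard deviations and omit missing
cells; single observations carry no SD.

## Synthetic generator

The generator emulates the statistical structure the pipeline assumes, at
the scale of the six-cow reference data, with defaults:

| parameter | default | rationale |
|---|---|---|
| baseline R-R | 650 ms | mid-range of the reference SMA values (578–744 ms) |
| rise amplitude / duration | 30 ms over 48 h | produces MAD peaks of ~0.3–0.5 %, matching the reference matrix's 0.1–0.4 range |
| rise shape | convex power ramp (x²) | the observed trends are convex into the peak; a decelerating (half-cosine) rise would place the P−SMA maximum mid-rise instead of at the turning point (half-cosine remains available) |
| decline rate | 2 ms/h | a "sharp" ~100 ms fall over the final two days |
| turning offset | 55 h before calving | centre of the observed 42.5–76 h remaining times |
| daily amplitude | 15 ms | visually plausible daily cycle; not readable from published figures, hence configurable |
| remainder | AR(1), sd 8 ms, φ = 0.6 | autocorrelated physiological variability on the 30-min grid |
| beat jitter | 20 ms | beat-to-beat variability; averages out at ~2,700 beats/bin |
| artifacts | 2 % of beats, ×[1.4, 2.0] or reciprocal | mis-detected R waves; sized so the 30 % filter catches them |
| duration | 168 h, calving at the end | one-week attachment before expected calving |

The composite is held constant within each 30-min bin when driving beat
generation, so noiseless binning recovers it exactly; beat times advance by
each beat's own R-R; artifacts corrupt recorded values without moving
times; dropout segments delete beats. All randomness flows from one seed
(three independent substreams for components, jitter, artifacts);
identical specs give bit-identical output.

What the generator does **not** emulate: inter-animal heterogeneity in
baseline and shape (one spec = one animal), non-stationary daily rhythms,
activity-driven trend excursions, device-specific artifact morphology.
Passing recovery tests therefore show the pipeline is correct for data
satisfying its own model, not that field recordings behave this way.

## Recovery study and a known limitation

Turning-point recovery is scored by replicate simulation: per replicate a
fresh seed (and optionally a turning offset drawn from Uniform[40, 76] h),
the pipeline run, and the detected peak compared with the true trend peak.
The replicate sweeps run at the binned-series level (trend + seasonal +
AR(1) remainder on the grid): beat jitter contributes < 0.5 ms to a 30-min
mean, so beat-level plumbing adds nothing to recovery statistics; a
smaller beat-level batch exercises the full chain end to end (its RMSE
matches the binned-level figure). Default problem sizes: 100 replicates of
336 bins for the sweeps, 10 beat-level replicates (~1 M beats each).

The central limitation these studies quantify: **MAD and MACD are
trailing-slope functionals, and trend smoothing displaces their peaks.**
A symmetric smoother of half-width h shifts the maximum of the smoothed
trend's slope — and hence the MAD argmax — to roughly (true peak − h),
for *any* rise-then-fall trend shape; with the standard STL trend window
(36.5 h) the displacement is about −12.5 h noiseless and −15 ± 8 h under
default noise (MACD, whose EMA lag partially cancels the displacement,
sits nearer −9 h). Shrinking the trend window reduces the displacement but
lets remainder noise through: at the default noise level the MAD peak
(≤ 0.5 %) then falls below the week-long maximum of MAD noise, and the
global argmax lands elsewhere. Within this design the displacement is
irreducible; the *trend apex itself* is not displaced (the SMA peak, which
brackets the apex, recovers the true turning time to one bin noiseless).
Detected remaining times are correspondingly longer than the true turning
offset by the displacement — conservative in deployment (alerts fire
early, never late). The acceptance suite asserts the idealised
recover-within-2 h targets and fails them transparently, reporting the
measured bias; the qualitative findings (MAD precedes MACD in every
replicate; RSI silent on all monotone declines) hold at 100 %.

## Numerical notes

* Reconstruction identity: exact by construction for both STL and LOESS
  paths; tested to 1e−8 relative.
* Argmax ties: earliest bin, making multi-peak indicator series (an
  observed RSI behaviour) deterministic.
* Degenerate inputs: empty beat series filter to empty; all-missing bins
  are unimputable; zero-variance paired differences report a degenerate
  (infinite/zero) F with a warning rather than dividing by zero.
* Pipeline artifacts are written atomically (temp file + rename); CSV
  artifacts are byte-reproducible under a fixed config and seed (the run
  log carries wall-clock timestamps and is excluded from that guarantee).
* Online/combined detector simulation properties are pinned at their pilot
  seeds: online agreement with the retrospective argmax is asserted on
  clean peaks (deterministic); the combined MAD+RSI signal falls within
  two bins of MAD-only in ≥ 70 % of default-noise replicates.
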