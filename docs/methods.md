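# Methods

This note records the models, parameter choices and numerical conventions
behind `heatwalk`, and what the synthetic test campaigns do and do not
establish about real field data.

## Thermal index chain

**Saturation vapour pressure.** Magnus form over water,
e<sub>s</sub>(T) = 6.112 hPa · exp(17.62 T / (243.12 + T)); actual vapour
pressure is RH/100 · e<sub>s</sub>. The constants are the WMO-recommended
set; any Magnus variant differs by well under 1% over the campaign range,
far below the index's sensitivity to radiation.

**Mean radiant temperature.** The default path inverts the forced-convection
globe-thermometer balance,
T<sub>mrt</sub> = [(T<sub>g</sub>+273.15)⁴ + h<sub>cg</sub>(T<sub>g</sub>−T<sub>a</sub>)]<sup>1/4</sup> − 273.15
with h<sub>cg</sub> = 1.1·10⁸ · v<sub>a</sub><sup>0.6</sup>/(ε·D<sup>0.4</sup>),
because the device carries a globe channel — the physically direct
measurement of the radiant field. Defaults D = 0.04 m, ε = 0.95 describe the
small grey globe typical of low-cost handheld builds; both are configurable,
and a small globe's large convective coefficient (≈2.8·10⁸ at 0.5 m/s) means
T<sub>mrt</sub> responds strongly (≈3.5×) to globe–air differences, which is
why sensor noise on the globe channel matters most. A negative radicand
(extreme T<sub>g</sub> < T<sub>a</sub>) is resolved by signed magnitude and
flagged rather than rejected. An alternative irradiance-only estimate
(flat short-wave gain on a standing person, f<sub>p</sub> = 0.25, α = 0.7)
is available behind `tmrt_method="irradiance"` and is flagged
`tmrt_approximate` on every record; it exists for logs without a globe
channel and is deliberately crude.

**Wind.** Transect wind was not measured (hand-carried device, calm summer
conditions), so a fixed 10-m speed is assumed — default 0.5 m/s, the lower
validity bound of the UTCI polynomial, appropriate for near-calm urban
canyons. Every record carries a `wind_assumed` flag; the speed is a single
configurable scalar, not a model.

**UTCI.** The published sixth-order polynomial approximation of the
thermoregulation-model equivalent temperature, in T<sub>a</sub>,
v<sub>a</sub>, (T<sub>mrt</sub>−T<sub>a</sub>) and vapour pressure. Inputs
are clamped into the approximation's validity box (T<sub>a</sub> ∈ [−50, 50] °C,
T<sub>mrt</sub>−T<sub>a</sub> ∈ [−30, 70] K, v<sub>a</sub> ∈ [0.5, 17] m/s,
vapour pressure ≤ saturation and ≤ 50 hPa) with per-record flags, rather
than rejected: mobile data contain brief excursions and the downstream
extraction needs complete series. The transcribed coefficient table is
checked in the tests against frozen reference values of the operational
procedure and against structural properties (|UTCI−T<sub>a</sub>| ≤ 2 K at
reference conditions over 16–32 °C, monotonicity in air and radiant
temperature).

**Stress categories** are half-open intervals [lower, upper) on the
standard assessment scale (…, 9, 26, 32, 38, 46 °C), so a value exactly on
a boundary belongs to the more severe class; the classifier partitions the
real line and the tests scan the boundaries exhaustively.

**Unused channels.** Pressure and surface temperature are validated,
carried through and exported, but do not enter the index computation; no
within-lap temporal (drift) calibration is applied — over a ~35-minute lap
the ambient trend is small against the spatial radiation contrasts of
interest, and a calibration hook would add a tuning knob without changing
the ranking of extremes.

## Hotspot / coldspot prioritisation

* **Extraction** is nearest-rank: exactly ⌈f·n⌉ records per lap (default
  f = 0.05), so the count is integral and there is no interpolation
  ambiguity. Ties at the cut are broken toward earlier timestamps; a
  constant lap (zero spread) warns and degrades to record order.
* **Snapping** projects each extreme point to the nearest location on the
  route polyline (local ellipsoidal east/north frame; over a 3-km route the
  projection error is < 0.1‰, negligible against the 30-m snap tolerance).
  Points farther than `snap_max_m` are dropped and counted; all points
  dropped is treated as a wrong-route error.
* **Pooling.** Extraction is per lap, but clustering pools each session's
  snapped points across all laps and days: the session (time of day) is the
  unit at which the spatial pattern is expected to repeat. This pooling is
  an interpretation choice; per-day clustering would fragment clusters at
  desk-scale point counts.
* **Clustering** is single-linkage in one dimension (route chainage) with a
  metre gap (default 25 m, the scale separating adjacent facade sections);
  clusters with fewer than 4 members — "isolated points of three or fewer" —
  are omitted. One-dimensional single linkage is exact and
  order-independent; the test suite verifies it against a quadratic
  transitive-closure reference on 200 random instances.
* **Session intersection.** A consistent zone is a non-empty intersection of
  one cluster interval per session after dilating each interval by
  `intersect_buffer_m` (default 10 m) — and the intersection is then
  *eroded* by the same amount. Dilate–intersect–erode tolerates
  session-to-session drift of cluster edges without inflating zones:
  identical intervals round-trip unchanged, and buffer 0 is strict interval
  intersection. Non-maximal intersections are pruned; zones are reported in
  chainage order.
* **Loop routes.** Chainage does not wrap at the route end: the start/end
  point of a monitoring loop is typically a fixed landmark, and wrap-around
  merging is left disabled (clusters touching both ends stay separate).

## Survey stage

Stop-level UTCI is the mean over records within a configurable radius
(default 25 m, matching the hyperlocal 10–30 m scale of the measurements)
of each stop during the concurrent afternoon laps; votes are pooled over
participants and survey dates before any statistic. Pearson correlation is
used for the vote–UTCI comparison (Spearman would be defensible for ordinal
scales; Pearson on per-stop *means* is the convention this analysis style
reports). The neutral-comfort range is the pre-image of a ±0.25-vote band
under the OLS fit of mean comfort vote on mean UTCI, clipped to the
observed span — a deliberately simple, reproducible reading of "where the
average pedestrian is neutral"; the band width is a choice, and band 0
returns the bare zero-crossing. Discrepancy stops are flagged where the
z-score of the mean sensation vote differs from the z-score of mean UTCI by
more than 1 (direction retained: perceived hotter/cooler). Pedestrian
presence uses the four printed count classes (≤2, 3–5, 6–15, >15) with
half-up rounding of fractional means.

## Synthetic campaign generator

The generator produces the study conditions end to end: a closed ~3.1-km
loop (regular polygon with chord length matched to the configured length,
centred on the study city), walked at 1.5 m/s with 1-Hz sampling
(≈ 34.5 min per lap), two laps per session at 06:00 / 12:00 / 15:30 /
20:00, six campaign days with the two afternoon laps of one day and one
evening lap of another excluded (48 − 3 = 45 laps), and 15 participants
voting at 12 stops on the afternoon laps.

Forcing and sensors:

* air temperature: sinusoid, mean 24 °C, half-amplitude 6 K, peak 15:30 —
  a hot Central European summer day — plus a shade-coupled offset of
  1.0 K × (0.5 − shade);
* irradiance: 900 W/m² clear-sky half-sine between 04:45 and 21:15, scaled
  by (1 − shade) of the segment being walked, floored at 0;
* globe temperature: air temperature + 0.013 K/(W m⁻²) × irradiance
  (≈ +12 K in full sun, typical of a 40-mm globe in near-calm air);
* relative humidity anti-phased with temperature (55% ± 15%); pressure
  constant at 1005 hPa;
* Gaussian sensor noise per channel (σ: 0.2 K air, 0.3 K globe, 1.5% RH,
  20 W/m² irradiance, 2 m GNSS), all zeroable.

The planted layout has four 35-m stretches sunny in every session
(shade 0.02) and four 35-m stretches shaded in every session (0.95); filler
segments rotate a moderate pattern (0.45/0.60/0.75/0.60) across sessions so
that no filler is extreme at all four times of day. Segment widths are
chosen so that a session's planted records (≈ 93 per lap) fit inside the
5% extraction budget (⌈0.05 × 2067⌉ = 104): recovery then probes the
pipeline's geometry rather than a knife-edge ranking. The second lap of
each session is walked in the reverse direction — a standard transect
design that balances the within-lap diurnal trend (≈ 2 K of UTCI over
35 min in the morning and evening ramps) over the route, so that spatial
contrast rather than visit order determines which segments are extreme.
Ordinal votes are linear in (UTCI − neutral) with slopes +0.4 (sensation)
and −0.3 (comfort) per K, neutral at 35 °C (mid-span of the afternoon
stop UTCIs), Gaussian latent noise σ = 0.5 votes, rounded and clipped to
the scales; preference follows the comfort sign.

What the generator does **not** emulate: wind (assumed constant downstream
anyway), clouds and diffuse/reflected radiation anisotropy, GNSS multipath
(noise is isotropic Gaussian), inter-participant heterogeneity and
psychological adaptation in votes, and pedestrian-count dynamics. Passing
recovery tests therefore demonstrates that the pipeline correctly recovers
spatially consistent radiation-driven contrasts under realistic sensor
noise — not that any particular city exhibits them.

## Problem sizes and determinism

Tests and the acceptance script use a two-day, 16-lap campaign for zone
recovery (20 seeds with default noise, plus noise-free runs), the full
six-day 45-lap schedule for bookkeeping and file-format checks, and 100
vote-noise replicates for the survey stage — sizes chosen to exercise
pooling across days while keeping a full run in tens of seconds. All
randomness flows through numpy `SeedSequence`s derived from one
user-supplied seed; identical configuration and seed reproduce campaigns
byte for byte.

## Known limitations

* The wind assumption makes UTCI a lower-bound-wind reading; in genuinely
  windy conditions both T<sub>mrt</sub> and UTCI would need measured speeds.
* The neutral-range procedure is one defensible estimator among several
  (probit/ordinal regression would use vote distributions, not means).
* Chainage-based clustering assumes route-constrained measurements; off-route
  excursions beyond the snap tolerance are dropped, not analysed.
* The local projection is exact only near the route; campaigns spanning tens
  of kilometres should substitute a proper projected CRS.
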