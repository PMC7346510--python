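# Methods

This note documents the models, algorithms and numerical choices behind
the `stopover` package, and what its synthetic-data tests do and do not
establish about real field data.

## Departure-event detection

A departure of a radio-tagged bird appears in a multi-antenna station's
raw signal-strength stream as a rapid surge on all or most antennas (the
bird leaves the ground and sheds body/vegetation attenuation), followed
by a decline on fewer and fewer antennas as it exits the detection
volume, ending in permanent signal loss.

`segment_departure_event` operationalizes this shape. The across-antenna
maximum signal per timestamp is the working series. A *candidate rise* is
a sample at least `rise_db` (default 10 dB) above the median of the
trailing `rise_window` (default 10 min, requiring at least 3 baseline
samples). Consecutive candidate samples are grouped into rises
represented by their onsets, so elevated samples during the decay do not
spawn spurious events. The departure is the **final** rise whose window
runs to the end of the stream without an internal silence of
`gap_min` (default 30 min) — a rise followed by a long gap and renewed
activity is not terminal. A stream that simply ceases without this shape
yields no event (`no_event_found`), mirroring field practice where such
birds are excluded. The take-off is the single highest signal inside the
event; ties resolve to the earliest time.

Event-window boundaries are not uniquely defined by the field protocol;
the choices above (onset threshold, trailing-median baseline, terminal
gap) are this package's and are all configurable.

## Bearing estimation

The departure bearing is a weighted circular mean of the bearings of the
antennas that received the **second half** of the event (time axis,
midpoint of `[event_start, event_end]`); early detections are excluded
because they are prone to back/side-lobe contamination. Each detection
contributes its antenna's alignment with weight

    w_i = (t_i − t_mid) / (t_last − t_mid) ∈ [0, 1],

a linear ramp towards the last detection (`t_last`). "Weighted by
temporal proximity to the last detection" admits many monotone schemes;
the linear ramp is the simplest and is documented so users can swap in
alternatives. A single detection exactly at the midpoint falls back to
an unweighted bearing. Two discard rules follow the field protocol:

* `short_event` — signal lost less than 3 min after take-off;
* `pivotal_antenna_missing` — no detection in the event window from an
  antenna within half the array spacing of the computed bearing
  (spacing inferred from the antenna table; 30° for the default
  twelve-antenna radial array).

Internally all detection times are handled as nanoseconds relative to
the event start; weights computed from absolute epoch seconds would lose
~1e−7 s to floating-point cancellation. Timestamps are UTC throughout;
local time appears only in I/O.

Minimum stopover duration counts calendar days from the capture day to
the departure night inclusive (a departure during the night after
capture = 1). Take-offs after midnight (UTC hour < 12) are referred back
to the previous evening's night.

## Energy stores

Lean body mass is predicted from maximum wing length by species- and
muscle-score-specific linear calibrations (redstart score 2:
6.69 + 0.08·wing; robin score 2: 2.48 + 0.17·wing; robin score 3:
2.77 + 0.17·wing; grams, wing in mm). Combinations without a
calibration raise an explicit error rather than extrapolate. Energy
stores are `(body mass − lean mass)/lean mass`: dimensionless, negative
for birds below structural mass; typical migrating birds fall within
roughly −0.05 to 0.2. (Some literature prints these fractions with a
stray percent sign — e.g. "0.01%" for a fraction of 0.01; this package
works in fractions throughout.) Where analyses need comparability
across species, stores are z-scored within species using the sample SD
(n−1 denominator).

## Solar timing

Sunset and sunrise come from the NOAA solar-position algorithm
(declination and equation of time from the Julian century, one
refinement pass at the event time) at the standard rise/set zenith of
90.833° (refraction + solar radius), accurate to about ±2 min at
mid-latitudes — verified in the tests against an independent
Spencer-series ephemeris. Polar conditions (|lat| ≥ 66°) are rejected.
A take-off is expressed as minutes after sunset and as the proportion
of the night, `(take-off − sunset)/(sunrise − sunset)`, which normalizes
for seasonal night-length change; take-offs outside the night are
flagged diurnal with the proportion undefined. Weather is matched to
the hour nearest the computed sunset (±3 h window, else flagged
missing); wind direction is kept meteorological (blowing-from), with a
derived blowing-toward value for plotting.

## Circular statistics

Angles are degrees at the API boundary and radians internally. The
mean direction and resultant length are `atan2(Σw sinθ, Σw cosθ)` and
`|Σw e^{iθ}|/Σw`; an exactly vanishing resultant leaves the mean
undefined. The Rayleigh uniformity p uses the refined approximation
`p = exp(√(1+4n+4(n²−R²)) − (1+2n))` with `R = nρ`, the formula used by
standard circular-statistics software; it is never reported as exactly
zero. Watson's two-sample U² is computed from the pooled empirical
CDFs with mid-rank treatment of ties (warned), and its p reported as a
bracket from the asymptotic critical values (0.152/0.187/0.268/0.385
for 0.10/0.05/0.01/0.001), optionally refined by a seeded permutation
test. The circular–linear correlation follows the
Jammalamadaka–SenGupta construction from the three Pearson
correlations of x with cosθ, sinθ and of cosθ with sinθ. Its p-value is
a randomization test: each replicate resamples the circular and the
linear variable **independently** with replacement — the only scheme
that produces a null of no association — and p is the plain fraction of
replicates (default 10,000) whose coefficient strictly exceeds the
observed one. The replicate loop is vectorized; a type-I calibration of
the test (1,000 null datasets at n = 30) runs in ~30 s.

## Beta regression and linear models

Nocturnal departure timing as a proportion of the night lies strictly
in (0, 1) and is modelled by beta regression: logit mean link, constant
precision φ, maximum likelihood over (β, log φ). The optimizer is
L-BFGS with the analytic gradient, warm-started from an OLS fit of
logit(y) and a method-of-moments φ; convergence is checked on the
gradient norm. Standard errors come from the observed information
(numerical Hessian at the optimum); the pseudo-R² is the squared
Pearson correlation between the fitted linear predictor and logit(y),
matching the convention of the widely used reference implementation
(against which the fit is cross-checked in the tests). Boundary
responses raise an explicit error. Linear models are OLS (statsmodels)
with an optional log10 response transform, as used for departure time
in minutes after sunset. Mann–Whitney W follows the R `wilcox.test`
convention (the U statistic of the first sample), exact for small
untied samples, so printed W values from field studies are directly
reproducible; the Fisher test is the two-sided exact hypergeometric
sum. Two-sided p-values throughout; no multiple-testing correction.
Species coding everywhere: redstart is the reference level, robin the
indicator.

`run_study` wires these together from a single capture table: energy
stores, species comparisons, stopover durations, first-night departure
fractions, beta-regression and linear timing models, and the circular
analyses of departure directions (per species, for all birds and for
first-night departers; Watson between species; circular–linear
correlations of direction with energy stores). The mean direction is
reported only alongside a significant Rayleigh test. Any model whose
energy-store term would mix birds measured at different times is
restricted to first-night departers. Wind enters the directional
analysis through the circular–linear correlation of departure direction
with wind **speed**; a circular–circular association with wind
direction is outside the package's statistical surface. Subsets below
the minimum n are skipped and listed under `exclusions`.

## Synthetic-data generator

The generator emulates the study conditions: two single-day capture
cohorts (defaults 14 redstarts captured 2 Sep, 21 robins 6 Oct, at
Helgoland 54.18° N 7.88° E), wing lengths N(78, 2) / N(73, 1.8) mm
rounded to 0.5 mm, muscle scores from the calibrated set, energy stores
uniform on [−0.05, 0.2] (the observed range). Body mass is
`lean(wing, score) · (1 + e)` and is deliberately not re-rounded so the
drawn `e` round-trips exactly through the energetics equations — the
tests exploit this as an invariant. Behaviour is driven by the
within-species z-score z of the stores: first-night departure
~ Bernoulli(logit⁻¹(−0.5 + 1.2 z)); proportion of night ~ Beta with
logit mean −1.20 + 1.15·[robin] − 0.45·z and precision φ = 15 (the
mean-model coefficients are the reported first-night point estimates,
which is what makes parameter-recovery testing meaningful); bearings
von Mises (232°, κ = 4.5) for redstarts and (185°, κ = 15) for robins.
Non-first-night birds stay 1 + Geometric(0.35) extra nights, capped at
17 (the observed maximum). Take-off instants place the drawn
night-proportion into the actual night of the departure date.

Detections: antennas radial at 30°; received signal
`P0 − 20 log10(d) + G(Δ) + ε`, with P0 = 110 dB at 1 m, free-space path
loss, a cos^k boresight gain (k = 4) floored at −30 dB, and Gaussian
noise (σ = 1 dB). On the ground the bird sits 20 m from the station
under 25 dB of ground attenuation; at take-off the attenuation drops
(the surge) and the bird departs along its true bearing in a straight
line at 10 m/s. Tag bursts every 5 s with a random phase relative to
the take-off. These defaults describe a strong near-station signal;
with them the detector recovers all simulated take-offs within one
burst interval and bearings with a median error of ~1–2°.

**What passing tests show — and don't.** The generator's propagation
model is deliberately idealized: no multipath, no real back/side lobes
beyond the gain floor, straight-line trajectories, constant weather.
Recovery accuracy on synthetic streams therefore demonstrates the
correctness of the segmentation/bearing algorithms, not the accuracy
attainable on real Motus-style data, where event shapes are noisier and
bearing errors larger. Likewise, parameter recovery confirms that the
estimation chain is unbiased under the stated behavioural model, not
that the model is true in nature.

Randomness: a single integer seed; each bird uses the deterministic
substream `default_rng([seed, bird_index])`, so enlarging a cohort
never perturbs earlier birds, and all outputs are bit-reproducible.

## Problem sizes and limitations

The test suite and the acceptance script use cohorts of 35–500 birds,
100-departure telemetry experiments and 1,000-dataset calibrations;
these sizes give stable statistics while keeping a full run to a few
minutes. Known limitations: no polar-night handling; no cross-station
triangulation (bearings are single-station); Watson p is bracketed, not
continuous, unless the permutation option is used; beta regression
assumes constant precision; the capture-table reader expects the
historical column names (including the legacy misspelling
`dep.realtive.night`, which is accepted and normalized).
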