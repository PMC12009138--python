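# Methods

This note documents the models implemented in `boutometry`, the
defaults and why they were chosen, the numerical conventions, and what
the synthetic-data validation does and does not establish.

## Conventions

Times are seconds from session start; every interval is half-open
`[start, end)` so block and bout membership is unambiguous. One
exception: a bout *end* time falling exactly on a block boundary is
assigned to the block it closes, so bouts truncated at a boundary do
not count as block-spanning. All on-disk artifacts are comma-separated
text with times serialized at 6 decimal places; reading back a written
object reproduces it exactly at that precision. Every quantile in the
package is nearest-rank (the ⌈qn⌉-th order statistic): exact on small
samples, no interpolation ambiguity.

## Feeding microstructure

A bout is a maximal run of licks whose inter-lick intervals (ILIs) are
all ≤ a threshold; an ILI strictly greater than the threshold opens a
new bout (equality continues the bout). The threshold is derived from
behavior: food-zone radius = 95th percentile of mouth-to-tail-base
distance (one body length), food-zone times (FZT) = maximal runs of
frames with the mouth inside that radius of the spout, threshold =
lower decile of FZT durations. The rationale is that a bout ends when
the animal leaves the food zone, so the briefest zone dwells bound the
within-bout pause length. The mouth is the zone reference point (it is
the eating effector).

Runs with fewer than `min_licks` licks (default 2, configurable to 1)
are dropped from the bout table but tallied, because a single-lick
"bout" has zero duration and degrades every duration-based statistic.
Bout duration is last-lick − first-lick time; no terminal lick-cycle
allowance is added.

The fundamental lick-oscillator interval is the mode of the ILI
distribution, computed on 10-ms bins over (0, 1] s with ties broken to
the smallest bin center. Energy intake applies the delivery rule
(⌊licks/3⌋ × 3 µL) and the diet's caloric density (220 kcal / 237 mL,
scaled by dilution).

Per-block statistics assign each bout to the block containing its
start; bouts whose start and end fall in different blocks are flagged
and excluded from block-conditioned analyses only. Condition means of
licks-per-block include only blocks with at least one lick; a condition
with no licked blocks is reported as missing, never zero.

## Photometry

Signal model assumed by the pipeline: the 470 nm channel carries the
indicator signal plus bleaching and motion; the 415 nm isosbestic
channel carries bleaching and motion only. The correction scales 415 to
470 by iteratively reweighted least squares with bisquare (Tukey)
weights, tuning constant 4.685, ≤ 50 iterations, tolerance 1e-8 —
the standard robust-regression default, resistant to the transients
themselves acting as outliers. `mode="chunked"` fits independent
contiguous 5-minute chunks (a trailing piece ≥ 2.5 min is fit alone,
shorter tails merge into the previous chunk) and absorbs
channel-specific slow bleaching; chunked residuals are never worse than
the global fit in the nested sense. ΔF = 470 / fitted 415. Fitted
values within 1 % of the median fitted level indicate a degenerate fit
and raise an error (no silent clipping).

The baseline is non-consummatory: samples more than 10 s from every
lick and at least 60 s after session start (settling). A sample exactly
at the exclusion distance is excluded. z = (ΔF − baseline mean) /
baseline SD.

Peri-event matrices align z to bout onsets over −5..+20 s at the native
0.05 s sample interval. The fixed-window mean averages all bouts in
every bin, so bins after short bouts' ends drag the late profile down;
the variable-length mean NaN-pads each row past its bout's end and
takes the per-bin `nanmean`, leaving bins past the longest bout
missing. The two estimators agree exactly on every bin at or before the
shortest bout duration.

Per-bout AUC is the trapezoidal integral of z from bout onset to offset
(default) or over a fixed onset + 20 s window; endpoints off the sample
grid are interpolated, making AUC exactly additive over interior split
points. Bouts may overhang the recorded trace by at most one sample
interval (the slack interleaved acquisition leaves at the session
edges). AUC is regressed on bout duration per condition by OLS — the
slope, in z·s per s, is the palatability metric — and AUC and duration
are also regressed on bout index across the session to expose
within-session drift (e.g. satiety).

## Closed-loop controllers

Block schedules alternate two labels over equal blocks tiling the
session exactly. Stimulation: the first lick inside an ON block opens a
1-s train of 25-ms pulses at 20 /s anchored at that lick; each
subsequent ON-block lick within the train window extends the train end
to lick + 1 s while preserving the original pulse grid, so the emitted
rate never exceeds the protocol rate (a phase-restart option re-anchors
at each lick and merges overlapping pulses). Trains close after 1 s
without licks. Gating tests the *trigger lick's* block; a train may
overhang the block boundary and is flagged rather than truncated.
Inhibition uses continuous illumination with the same extension rule,
followed by a linear 1-s ramp-off (limiting rebound firing).

The yoked (noncontingent) control draws, for each ON block, exactly as
many pseudo-event times as the contingent session opened trains there,
uniformly at random within the block with no minimum separation; each
pseudo event then triggers one standard non-extended train. Per-block
counts are conserved exactly for every seed.

Calibration: with transduction penetrance p (fraction of target neurons
expressing the opsin) and target ratio r, the transduced subpopulation
must be driven to m = r / p times the reference response (m = 2 at
p = 0.5, r = 1). `calibrate_stim_gain` titrates a stimulation gain over
a grid, simulating low-palatability sessions whose per-lick transient
amplitude is increased by gain × evoked-amplitude, running the full
photometry pipeline, and returning the smallest gain whose mean
per-bout AUC reaches the target (reporting the best achieved AUC if the
grid falls short).

## Statistics

Paired block summaries compare per-subject condition means with a
paired t test; an all-zero difference vector is reported as effect 0
with a degeneracy flag rather than an indeterminate statistic.
Bout-duration distributions are compared with the two-sample
Kolmogorov–Smirnov test (asymptotic p). All tests are two-sided.

The binned count table is long-format (animal, bout, 1-s bin over the
first 20 s, condition, count, missing flag) — the exact input an
external negative-binomial mixed model with animal and
bout-within-animal random intercepts consumes. A per-bin zero-fraction
summary accompanies it (the observed zero proportion rises across bins
as bouts end, which motivates zero-inflated count models). The
self-contained alternative is a permutation contrast: condition labels
are permuted across bouts within each animal; the per-bin statistic is
the absolute difference of condition means ignoring missing bins. When
the number of distinct assignments is within the permutation budget the
test enumerates them exhaustively (exact); otherwise it samples and
reports the add-one Monte-Carlo p. BH step-up adjustment is applied
across the 20 bins.

Permutation tests on integer counts are conservative under ties (tied
permuted statistics count against rejection), so type-I calibration at
α is only measurable where the statistic has resolution: enough bouts
per bin and variable counts. The calibration suite therefore simulates
nulls with long bouts (mean 25 s, so all 20 bins stay populated) and
ILI CV 0.5 at 3 bouts/min (~90 bouts per 32-min session); under those
conditions the measured false-positive rate is ≈ 0.05, and under
sparser or metronomic conditions it falls below α — never above.

## Synthetic sessions

The generator produces what the analysis assumes, with ground truth:

* **Licks** — bout onsets are homogeneous Poisson (default 1.0
  bouts/min, low enough that overlapping bout draws — which are merged
  and flagged — stay rare); intended durations are
  Gamma(shape 2, mean 10 s high / 5 s low palatability), truncated at
  block boundaries (the delivered food changes there) and session end;
  intra-bout licks are a Gamma renewal process with mean ILI 0.125 s
  (the ~8 Hz murine lick rhythm) and CV 0.1.
* **Pose** — mouth at the spout (0.3 cm jitter) during true bouts;
  between bouts a persistent-velocity (OU) walk, speed SD 4 cm/s with a
  1-s velocity correlation time, reflecting at the walls of a
  29 × 29 cm arena. Frame-by-frame positional jitter is deliberately
  avoided: it produces single-frame zone crossings and a degenerate
  (sub-ILI) derived bout threshold. Tail-base trails the mouth by one
  body length (8 ± 0.3 cm per frame) in a slowly wandering direction.
* **Photometry** — 470 = F₀·exp(−t/τ₄₇₀)·(1 + Σ A_c·c_c(t)) + m(t) +
  noise; 415 = F₀·exp(−t/τ₄₁₅) + g·m(t) + noise. c_c is the per-lick
  impulse train of condition c convolved with a unit-peak
  difference-of-exponentials kernel (rise 0.2 s, decay 1.0 s); m is
  unit-variance low-pass (0.5 s) Gaussian noise scaled by
  `motion_sd`·F₀, entering 470 additively and 415 with gain g = 1 so a
  linear channel regression can remove it (a multiplicative option
  exists for stress tests); white measurement noise has fractional SD
  0.005. `transient_amplitude` is the fractional modulation at the
  single-lick kernel peak; at the 8 Hz rhythm kernels superpose to
  ~12× that value in sustained ΔF, so the defaults (0.004 high / 0.002
  low — a 2× contrast) give ~5 %/2.5 % sustained ΔF and bout z of
  ~3–7, typical magnitudes for these sensors. Negative amplitudes model
  the negative responses seen for the less palatable option under
  hedonic contrast.

All draws come from one generator seeded by `SimParams.seed`; identical
seeds give bit-identical bundles, and no global random state is used.

What the generator does **not** emulate: indicator biophysics
(saturation, adaptation, onset anticipation before the first lick),
hemodynamic or spectral crosstalk, pose-estimation errors and identity
swaps, session-scale nonstationarity (satiety drift), or between-animal
variability. Passing recovery tests therefore demonstrates that the
pipeline is a faithful estimator of the quantities it defines under its
own signal model — not that those assumptions hold in any particular
recording.

## Validation problem sizes

The test and acceptance suites use 10–32 min sessions at the native
rates (20 Hz photometry, 30 fps pose): segmentation is checked exactly
against a brute-force splitter on 1 000 random trains (≤ 50 licks);
estimator identity on 100 random peri-event matrices; artifact
rejection (≥ 80 % attenuation) on 5 seeded artifact-only traces;
duration-ratio and slope-ratio recovery pooled over 20 seeded 30-min
sessions; yoked conservation over 100 seeds; type-I calibration over 50
null runs with 199 permutations per run. The full suite runs in well
under a minute on one CPU.

## Known limitations

* The derived ILI threshold depends on the pose model's dwell-time
  distribution; the generator's walk yields ~0.8–1.1 s. Real housings
  produce longer zone dwells (and thus larger thresholds); the
  threshold can always be supplied explicitly.
* `calibrate_stim_gain` models stimulation as an additive increment to
  the per-lick transient amplitude; real opsin responses saturate.
* The negative-binomial mixed model itself is not fit here; the package
  emits the table such a fit consumes and offers the permutation
  contrast as the self-contained alternative.
* With extreme bout rates overlapping bout draws are merged and
  flagged; heavy merging biases duration statistics upward, which is
  why the default rate keeps merges rare.
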