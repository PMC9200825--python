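# Methods

This note documents the models, defaults, and numerical choices behind
`dualcue`, and what the synthetic-data tests do and do not establish.

## Feature model

Patch probabilities are estimated by counting every `patch_side × patch_side`
window of binarised images at stride 1 with no wraparound (maximises the
sample count; the conventional sliding-window estimate). Binarisation
defaults to the image median with ties (pixel == median) mapped to 1, so a
constant image becomes all-ones; Otsu thresholding is available and raises on
constant images. Patch codes are row-major with the most-significant bit at
the top-left cell — an arbitrary but fixed convention required for
reproducible dictionaries.

Optimal-feature selection maximises `H(D) = −Σ p_i log2 p_i` subject to
`|D| ≤ N` and `Σ p_i ≤ W`. Entropy is in bits; the base only rescales the
objective and never changes the argmax. The solver is exact (vectorised
exhaustive subset search) for alphabets of up to 20 positive-probability
patches, which covers every oracle test. For the full 512-patch alphabet the
problem is a cardinality-constrained knapsack, so a heuristic is used:
candidates are ranked by `|p_i − W/N|` ascending (constrained solutions
concentrate near the equal-share mass `W/N`), greedily added while feasible,
then improved by single swaps; the result is lower-bounded by a
greedy-by-entropy baseline, which the implementation computes and never
returns less than. Zero-probability patches are never selected; if `W` is
below every positive probability the dictionary is empty and flagged.

Defaults: `patch_side = 3`, `N = 50` per dictionary, `W = 0.05`. The
bandwidth actually used to build the published 50-feature dictionaries is
not recoverable, so no claim is made to reproduce any particular feature
set; `W` is configurable and all downstream stages are agnostic to it.
Synthetic stand-in images are 1/f² Gaussian noise — they reproduce the
spatial-correlation structure that makes uniform and edge-like patches
dominate patch statistics, but none of the higher-order structure of
photographs.

## Experiment design

Schedules reproduce the printed bookkeeping exactly: per session and
condition, the covert task has 112 neutral + 250 non-neutral trials (125/125
at 50% validity, 200/50 at 80%), totalling 1448 over two sessions × two
conditions; the gaze task has 100 neutral + 250 non-neutral, totalling 1400.
Within every (condition × trial type × contrast) cell, target sides are
balanced to within one trial and Gabor tilts (±20°) likewise; contrast levels
(default 8 log-spaced values on 0.01–0.09) receive near-equal counts with the
remainder assigned by seeded draw. Trial order is a seeded permutation, and
the same seed reproduces a schedule byte-for-byte. Cue duration is not part
of the printed design; it is carried as metadata (default 25 ms) and unused
by any analysis. The covert "neutral block" of a session interleaves both
conditions' neutral trials — the totals are unambiguous even though the
block composition is not.

## Synthetic observers

**Covert.** P(correct) follows a cumulative Gaussian with guess rate 0.5
(2AFC) and lapse 0: `Ψ(c) = 0.5 + 0.5·Φ((c − μ_t)/σ)`, where
`μ_t = μ_neutral·(1 + effect_t)`. Defaults: `μ_neutral = 0.045`,
`σ = 0.012`, `effect_valid = −0.05`, `effect_invalid = +0.10` — the
magnitudes of the reported group threshold changes. Effects are injected
directly at the summary level; no attention dynamics are modelled, by
design: the simulator exists to give the analysis known ground truth, not to
explain the effect.

**Gaze.** Traces are sampled at 1 kHz from cue onset (−150 ms) to +700 ms,
with white Gaussian fixation noise (default sd 0.05°). Saccades use an
error-function position profile — a Gaussian velocity profile with a linear
main sequence (peak velocity = 55 s⁻¹ × amplitude), so the profile width is
σ = 1/(55·√(2π)) ≈ 7.25 ms independent of amplitude. A movement's
*programmed onset* is defined as the instant its velocity profile crosses
30 deg/s (the detector's default velocity threshold), which makes round-trip
latency checks well-posed. Regular-saccade latencies are truncated Gaussians
on (80, 500) ms (mean 165 ms × (1 + effect), sd 25 ms; an ex-Gaussian option
exists); defaults `effect_valid = −0.04`, `effect_invalid = +0.05`.
Direction errors flip the 5° movement with probability 2.5%/0.7%/5.5%
(neutral/valid/invalid). With probability 4% (neutral) / 8% (non-neutral) an
anticipatory saccade (1–2.5°, onset uniform on (−70, 80) ms, directed to the
salient side with probability 0.8) precedes a corrective saccade that always
reaches the target and starts at least 40 ms after the anticipatory movement
ends, so the two events never merge in detection. Trial-to-trial latency sd
and the anticipatory probabilities are not printed anywhere and were chosen
once as field-typical values consistent with the reported summary ranges.

What the generator does **not** emulate: drift/tremor spectra, blinks,
pursuit, binocular disparity, the nonlinear main sequence of real saccades,
inter-subject variability in μ or baseline latency, or any cue-locked
attentional dynamics. A green recovery test therefore establishes that the
analysis chain is faithful to its own definitions — not that it would be
robust to every artefact of real recordings.

## Psychometric fitting

Binomial MLE over (μ, log σ) with a 7×7 coarse-grid evaluation followed by
Nelder-Mead from the three best grid points (tolerances 1e−9 on parameters,
1e−10 on the objective). Fitting is on linear contrast, matching the tested
0.01–0.09 range. Data at ceiling or at chance on all levels are flagged
`converged = False` rather than returning arbitrary parameters, and
thresholds are refused on non-converged fits. The threshold is analytic:
`μ + σ·Φ⁻¹((criterion − guess)/(1 − guess − lapse))`, so evaluating the
fitted curve at the returned threshold reproduces the criterion to machine
precision. Cells whose threshold exceeds 3× the largest tested contrast are
reported missing, never extrapolated. Guess is fixed at 0.5 and lapse at 0
by default (both config-exposed).

Relative changes are `100·(value − baseline)/baseline`, computed per
participant against the same condition's (and validity block's) neutral
cell, then averaged across participants — the mean of per-participant
changes, not the change of means. At the printed cell sizes the 50-trial
invalid cells make these ratios right-skewed: cohort-mean changes
overestimate large positive effects even though threshold *ordering* and
median recovery error remain reliable. This is a property of the design's
cell sizes, not of the estimator, and is left as-is.

## Oculomotor analysis

Filtering is a zero-phase (forward–backward) Butterworth, order 2, 30 Hz
cutoff, with odd-reflection padding of 3 characteristic times (3·fs/cutoff
samples), which preserves DC and linear trends at the edges. The two-pass
magnitude response is `1/(1 + (f/fc)⁴)`: 0.5 at the cutoff and 1/17 at twice
the cutoff — at 1 kHz sampling the bilinear transform warps the 60-Hz gain
by ≈ −3%, so the filter-contract tests measure on 8-kHz sinusoids where the
analog prototype is faithfully represented. Velocity and acceleration use
central differences (exact for polynomials of degree ≤ 2).

Detection: an event begins where speed > 30 deg/s **and** acceleration
magnitude > 2000 deg/s², extends while speed > 10 deg/s (one third of the
velocity threshold), merges with neighbours closer than 20 ms, and is
discarded under 8 ms. The acceleration default is deliberately below the
8000 deg/s² used by hardware trackers: with the *linear* main sequence used
here, a 1° saccade peaks near 4 600 deg/s² (≈35% lower after filtering), so
8000 would silently reject the anticipatory saccades the taxonomy exists to
count; 2000 is still ~8× the acceleration noise floor at 0.05° fixation
noise. Both thresholds, the offset fraction, and the merge gap are
parameters. Amplitude is the net horizontal displacement read 5 ms outside
the thresholded interval (`amplitude_margin_ms`), because the sub-threshold
tails of the velocity profile carry ≈2% of the displacement; direction is
the sign of that displacement (targets are strictly left/right).

Classification windows are open intervals — an event exactly at 80 ms is
neither regular nor anticipatory — matching the strictly-greater wording of
the definitions. The regular saccade is the *first* qualifying event; a
trial may hold both anticipatory events and one regular event; trials with
no detected events are aberrant and excluded. Direction-error and
anticipatory percentages use all detected saccades (regular + anticipatory)
as the denominator by default, switchable to regular-only. Across
participants, latency and percentage measures are averaged subject-wise,
while anticipatory direction preference is weighted by each participant's
anticipatory count (participants without anticipatory saccades contribute
nothing rather than undefined ratios).

## Group statistics

The repeated-measures factorial ANOVA computes the classical within-subject
sums-of-squares partition by Möbius inversion over factor subsets; each
effect is tested against its own effect-by-subject interaction, and
η² = SS_effect/SS_total (the classical form, consistent with small η²
alongside large F in fully within designs). F values agree with statsmodels
`AnovaRM` to machine precision in tests, and the partition
ΣSS_effects + ΣSS_errors + SS_subject = SS_total is asserted to 1e−6.
Sphericity corrections are intentionally absent by default (the reported
dfs are uncorrected). Friedman's χ² (scipy, midranks under ties) is
accompanied by Kendall's W = χ²/(n(k−1)) and Conover pairwise rank-sum tests
with df = (n−1)(k−1) and Bonferroni correction; the two-proportion z test
uses the pooled-variance formula (cross-checked against statsmodels) and
warns, rather than fails, below 30 observations per group.

## Pipeline and reproducibility

Per-participant, per-stage seeds derive from the root seed as
`SeedSequence([seed, participant_index, stage_code])`, so cohorts are
reproducible from the config alone and extensible without disturbing
existing participants. `run_end_to_end` writes every intermediate artifact
(schedules, responses, event tables, summaries, statistics) as CSV/JSON with
SHA-256 checksums in the manifest; identical configs produce byte-identical
result files. Degenerate statistical situations (fewer than 3 complete
participants, zero error variance) are skipped with a note in the manifest
rather than fabricated.

## Known limitations

- The published 50-feature dictionaries cannot be reproduced (bandwidth and
  image corpus unknown); only the selection *procedure* is validated.
- The 512-patch optimal selection is heuristic; optimality is guaranteed
  only relative to the greedy baseline and for alphabets ≤ 20.
- Cohort-mean relative changes are right-skewed at 50-trial cell sizes (see
  above); ordering and median-error statements are the reliable summaries.
- The saccade simulator's linear main sequence underestimates small-saccade
  velocities of real eyes; detector thresholds tuned here should be
  re-examined before use on hardware recordings.
- Reaction times are generated but never analysed (a null result in the
  source design), and no EyeLink file formats are parsed — traces enter as
  CSV.
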