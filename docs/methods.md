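# Methods

This note documents the models, algorithmic choices, and calibration behind
`knobmap`, in the order data flow through the pipeline.

## Grid geometry

The mapping grid is anchored to a digitized gyrus–sulcus border polyline in
a continuous MNI-like millimetre frame (x lateral, y anterior, z superior);
no voxel indexing exists anywhere. Line 1 is the border itself, resampled at
equal arc-length steps (default 5 mm, 7 targets; alternatively the spacing
can be derived from the curve length). Lines 2–5 are produced by displacing
a dense equal-arc resampling of the base line by k·5 mm along the local
*in-plane anterior normal* — the component of the anterior axis orthogonal
to the local tangent. Coil orientations are those normals: unit vectors
perpendicular to the local line direction, pointing anteriorly.

Two numerical choices matter on digitized (piecewise-linear) input:

* **Tangent smoothing.** Pointwise central-difference tangents kink at every
  digitization vertex; offsetting 15–20 mm along kinked normals folds the
  offset polyline (we observed chord errors > 4 mm by line 4 on a 3 mm-bowed
  border). Offsets therefore use symmetric-chord tangents over ≈ 2 mm of
  arc, which are exact for straight segments and symmetric arcs and smooth
  across digitization kinks. The standalone `offset_line` operation keeps
  plain central differences, which is adequate for a single short offset.
* **Span preservation.** Offsetting toward a bowed curve's centre of
  curvature shortens the line (a 20 mm offset against the default 3 mm bow
  loses ≈ 40 % of arc), so a shortened line could not carry 7 targets at
  5 mm. Each offset line is extended tangentially at both ends to the
  nominal 30 mm span, centred on the line's arc midpoint — mirroring the
  protocol requirement that every line covers the knob's full longitudinal
  extent. On straight curves this is a no-op and all positions are exact
  closed-form; on curved ones consecutive-target chords stay within 2 % of
  the nominal spacing (tested).

Degenerate inputs (zero-length curves, tangents parallel to the anterior
axis, curves shorter than the target span) raise `GeometryError`.

## MEP extraction

EMG is assumed hardware band-passed at acquisition; no re-filtering. Trials
are stimulus-locked sweeps (−100…+60 ms at 10 kHz). The protocol's two
manual steps are replaced by objective surrogates with exposed parameters:

* **Artifact rejection** (for visual trial inspection): a trial is invalid
  when the RMS of the −100…0 ms baseline exceeds 0.02 mV. At the default
  background noise (SD 0.01 mV) the false-rejection rate is ≪ 1 %.
* **Onset latency** (for expert onset marking): the earliest time in the
  10–40 ms window at which |signal − baseline mean| exceeds 3 × baseline SD
  continuously for 0.5 ms. With a silent baseline the rule degenerates to
  "first strictly nonzero sustained deviation", so noise-free onsets are
  recovered to one sample and all-zero traces return "absent". Reported
  latencies are bounded by the window by construction; the surrogate is
  validated against generator ground truth (median |error| < 0.3 ms at
  1 mV MEPs on 0.01 mV noise), not against a human rater.

Amplitude is max − min within 10–40 ms post-stimulus. Site means are taken
over valid trials only; a site with no valid trial is flagged, logged, and
excluded from the hotspot search (all sites flagged → `AnalysisError`). The
hotspot is the site of maximal mean amplitude; exact ties (measure-zero
under noise) break deterministically toward the posterior then medial site
and are logged. The subject's corticomotor latency is the minimum valid
latency among the hotspot's trials — a min-over-trials statistic, which
matters for calibration (below).

**Resting motor threshold.** The adaptive maximum-likelihood staircase
refits, after every yes/no response, the threshold of a fixed-slope
(2 % MSO) logistic recruitment curve by maximum likelihood over a 1 % MSO
grid (1–100), stimulating next at the running estimate; 20 trials, start at
50 % MSO. These four constants follow common adaptive-threshold practice.
All-yes/all-no runs pin the estimate at the grid boundary and are flagged.
Against logistic responders (slope 2, threshold 58) the mean absolute error
is ≈ 0.9 % MSO over 1000 runs (tested ≤ 2).

## Rostrality index

Per muscle, the hotspot y-coordinate and the shortest latency are min–max
normalised across the whole cohort (never per group), and multiplied. The
index is invariant to separate affine transforms of y and latency and
monotone in both. Cohorts whose extremes coincide (max = min) leave the
index undefined and raise rather than silently returning 0/1. Whether to
normalise over all subjects or only those entering a given correlation is
undetermined by the formula; the package normalises over all subjects with
valid TMS data. Groups: grid lines 1–2 → caudal, 3–5 → rostral.

## Movement timing

Peak detection follows the protocol constants exactly: the trace is
thresholded at 0.6 V, local maxima must be ≥ 400 ms apart (smaller
neighbours of a larger peak dropped first) and have topographic prominence
≥ ⅓ of the per-trace maximum. Saturated taps appear as plateaus at 2.5 V;
a plateau's midpoint is its peak time, so clipping does not bias intervals.
When two candidate peaks have *exactly* equal height within the minimum
distance the survivor is implementation-defined (the underlying sort is
unstable); in the paced task taps are 1 s apart, so this never affects real
traces. Intervals are successive peak differences strictly within movement
blocks (block bounds come from the cue schedule; crossing rest blocks would
inject ≈ 11 s artifacts). The SD uses the sample (n − 1) denominator — the
protocol does not state the denominator — and CV = SD/mean. All within-block
intervals of a finger's 18 blocks are pooled (9 × 18 = 162 intervals).

## Cohort statistics

Pearson r with two-sided p from the t transform (n − 2 dof; type-I error
calibrated to 0.04–0.06 at n = 20 under the null), Welch's t with
Welch–Satterthwaite dof (plus a summary-statistic variant for mean/SEM
inputs), paired t, Bonferroni as min(1, m·p) with explicit family sizes.
The battery's families mirror the protocol's three analysis sets: ROI
contrasts (m = 3 paired tests), hotspot-coordinate vs latency correlations
(m = 2), structure–function correlations (m = 6), with sub-ROI follow-ups
and thickness controls as separate families. Subjects without usable R1 are
excluded from R1 rows only. A degenerate row (constant column, too few
complete observations) errors individually and is reported with the reason;
other rows are unaffected.

## Synthetic-cohort generator

A single standard-normal **myelin trait** z₁ drives every R1-coupled
quantity via Gaussian-copula loadings z = ρ·z₁ + √(1−ρ²)·ε — the simplest
structure that reproduces all pairwise reference correlations:

* **R1.** Caudal/rostral Pre-CG R1 share the trait with loadings a, b and
  an anti-symmetric split ±s·u solved from the reference SEMs (between-
  subject SD = SEM·√n; n = 20) and the paired-t of the ROI contrast (which
  fixes the SD of the within-subject difference, 35.1 ms⁻¹). This makes the
  hand-knob mean R1 an *exact* linear function of z₁, so copula loadings
  translate directly into population correlations. Thickness, curvature and
  BOLD use the same split construction on their own latents (BOLD's latent
  is z₁-coupled; thickness/curvature are independent, as the reference data
  show no functional coupling).
* **Hotspot geometry.** The FDI rostrality driver z₂ loads on z₁
  (ρ = 0.811); the true hotspot is (x, y) with y = −16.6 + 4.9·z₂ mm and
  independent x scatter. The ADM driver follows z₂ (loading 0.97), giving
  FDI–ADM rostrality-index correlations ≈ 0.7–0.8 at n = 20.
* **Latency.** latency = intercept + slope·(y − ȳ) + ε with slope
  0.225 ms/mm (FDI) and residual 0.95 ms, calibrated so the *measured*
  correlation between detected hotspot y (which is grid-quantised at 5 mm)
  and extracted shortest latency is 0.697 at n = 20.
* **Timing CV.** cv = 0.05 + 0.015·z (floored at 10⁻⁴), with negative
  z₁-loadings; 5 % is a realistic interval CV for 1 Hz paced tapping and
  0.015 a plausible between-subject spread (neither is printed in the
  reference work).
* **MEP model.** Expected site amplitude is an isotropic Gaussian bump of
  σ = 5 mm centred on the true hotspot, scaled by a lognormal subject
  amplitude; trial amplitudes are lognormal with CV 0.4 around site means;
  trial latencies jitter N(0, 0.3 ms). σ = 5 mm makes hotspot detection
  reliable but not trivial at 20 trials/site: the true-hotspot site wins in
  > 99 % of sessions and the detected site lies within 5 mm of ground truth
  in > 95 % — with σ = 7 mm the 5 mm-neighbour false-win rate would be ≈ 9 %
  and both properties would fail. The waveform is one sharp-onset biphasic
  sine cycle of 8 ms scaled to the trial's peak-to-peak amplitude; a
  slow-onset (e.g. cosine-windowed) template would smear the onset the
  latency rule is designed to find and push its median detection delay to
  ≈ 0.7 ms.
* **Force traces.** One raised-cosine pulse (0.25 s) per 1 Hz cue, onset
  jitter SD = cv/√2 per tap (so interval SD = cv and interval CV ≈ cv), tap
  amplitudes lognormal (mean 2.2 V, CV 0.25) so ≈ a quarter of taps saturate
  the 2.5 V sensor ceiling, plus 5 mV sensor noise; 18 movement blocks of
  10 cues separated by 10 s rests per finger.
* **Determinism.** All randomness descends from
  `SeedSequence([seed, subject_index, stream])`: cohorts are bit-reproducible
  and adding subjects leaves existing ones untouched (both tested).

### Calibration

Printed reference values become generator defaults directly (means; SDs via
SEM·√n). Four defaults have no printed counterpart and were solved once by
Monte-Carlo secant iteration so that the **analysed** synthetic data — not
the generative parameters — match the reference statistics, then frozen:

* copula loadings ρ(R1→rostrality driver) = 0.811, ρ(R1→BOLD) = 0.664/0.757,
  ρ(R1→CV) = −0.656/−0.737 — chosen so the mean *sample* correlation over
  simulated cohorts of n = 20 equals the reference r (this absorbs
  grid-quantisation of y, the nonlinearity of the min–max product index,
  CV-extraction noise from 162 intervals, and small-sample attenuation of r);
* amplitude scales 1.165/0.508 mV — the extracted hotspot mean sits below
  the generative peak (the detected site misses the true hotspot centre by
  up to ≈ 3.5 mm) and above it (max-selection over 35 noisy site means);
  the net factor ≈ 0.95 is measured, not assumed;
* latency intercepts 22.99/23.21 ms — the reported "shortest" latency is a
  min-over-20-trials statistic (≈ −0.56 ms extremum bias at 0.3 ms jitter)
  plus a small threshold-crossing delay; the intercepts place the *extracted*
  grand means at 22.6/22.9 ms.

The derivation is re-runnable via
`knobmap.calibration.solve_generator_defaults()`.

## Problem sizes

The recovery simulations average 200 site-level cohorts of n = 20 for the
correlation targets (site level carries the same trial statistics as the
waveform path at ~100× the speed; force traces are always rendered and
analysed in full) and 100 EMG-level cohorts of n = 24 (35 sites × 20
rendered trials each) for the amplitude/latency marginals — enough for
Monte-Carlo SEs of ≈ 0.007 on recovered correlations, ≈ 0.02 mV on the
amplitude, and ≈ 0.04 ms on the latency, an order of magnitude inside the
recovery tolerances.

## What the synthetic data do and do not show

The generator emulates the *statistical* structure the analysis assumes:
calibrated marginals, a single-factor correlation structure, Gaussian
excitability surfaces, stationary background EMG, and ideal 1 Hz pacing with
Gaussian timing jitter. It does not emulate cortical geometry (no E-field
physics, no scalp/coil distance), non-Gaussian or multi-peaked excitability
maps, EMG artifacts other than elevated baseline noise, pre-activation,
fatigue or learning drifts in the force task, or missing-data mechanisms
beyond dropping R1 in a fixed number of subjects. Passing recovery tests
therefore demonstrates that the *analysis chain is unbiased and correctly
implemented under the stated model*, not that the model captures every
property of real recordings.

## Known limitations

* The latency surrogate is validated against generator ground truth; human
  raters marking superimposed waveforms may differ by a constant offset
  (which cohort-level correlations ignore).
* The "shortest latency" is read per-trial at the hotspot; reading it across
  superimposed trials of neighbouring sites would be an alternative the
  package does not implement.
* Bonferroni family memberships follow the three-set narrative of the
  protocol but exact printed family sizes are not available; sizes are
  reported alongside every adjusted p.
* The 3-way mixed ANOVA of hotspot coordinates is out of scope; its
  between-group content is covered by coordinate-wise Welch tests.
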