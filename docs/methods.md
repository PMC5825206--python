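# Methods

This note documents the models, estimators and numerical choices behind
`smstoich`, and what the synthetic-data tests do and do not establish about
real microscope data.

## The measurement problem

Three single-cell fluorescence readouts are quantified:

1. **Receptor stoichiometry by photobleaching.** A surface receptor carries
   a self-labeling tag; labeled monomers bleach in one discrete intensity
   step, labeled dimers in two. Counting steps per diffraction-limited spot
   across many spots gives the monomer/dimer composition of the surface
   population.
2. **Copy numbers and assembly kinetics of signalling complexes.** Bright
   spots assembling at the membrane are detected and tracked over time;
   their fluorescence, referenced to a surface-attached dimeric-GFP
   standard imaged under identical illumination, gives molecules per
   complex (`copies = 2 · I_complex / I_ref`); appearance times and track
   lifetimes give the assembly/disassembly kinetics.
3. **NF-κB translocation dynamics.** Per cell, the nuclear:cytoplasmic
   ratio of a tagged transcription factor is followed over hours; the time
   and magnitude of its first peak and the fold increase of a
   promoter-driven reporter are extracted and rank-correlated across cells.

## Synthetic data generator

Because the original microscope stacks are not available, every estimator
is exercised against a generator with complete ground truth.

* **Photobleaching movies.** Immobile spots on a jittered grid (default
  minimum separation 6 PSF sigma, ≥3 sigma from edges), rendered as
  pixel-integrated 2-D Gaussians (PSF sigma 1.2 px). Each spot is a dimer
  with probability `dimer_fraction` (default 0.22), each subunit labeled
  independently with probability `labeling_efficiency`, and each
  fluorophore bleaches geometrically with per-frame probability 0.01
  (mean bleach frame 100 of 400 — most bleaching falls inside the
  acquisition, as an experimenter would set laser power). Background is
  additive Gaussian on a constant offset (EMCCD data at these intensities
  is near-Gaussian; an optional Poisson switch exists, off by default). No
  blinking or other photophysics: the step-counting QC assumes monotone
  step-down traces. Frame interval 35 ms over 400 frames.
* **Intensity scale.** Detector units are arbitrary; the default is
  20 000 ADU per fluorophore on a 2 000 ADU background. The scale is not
  free in practice because the spot-finder threshold (500 ADU) is an
  absolute number: the default puts the matched-filter response of one
  fluorophore (~650 ADU at SNR 5) safely above it. SNR is defined as the
  brightest-pixel amplitude of one fluorophore over the background SD.
* **Kinetic movies.** Complexes appear as per-frame Poisson events at
  random positions, persist for exponential lifetimes rounded to whole
  frames (floored at one frame, since observed lifetimes are counted in
  whole 30 s frames and many tracks last a single frame), and carry a
  fixed number of fluorophores (default 6). Photobleaching is neglected on
  these short, sparsely sampled acquisitions.
* **Cell time series.** The nuclear:cytoplasmic ratio follows a
  fixed-width Gaussian pulse (default width 12 min) peaking exactly at
  `t_peak`; the width deliberately does not scale with the peak time —
  first-translocation peaks have a characteristic duration set by
  import/export kinetics, not by when they occur. The reporter rises
  logistically from 1× to `reporter_fold`× its baseline after a delay.
  Noise is multiplicative Gaussian (default 5%), sampling every 3 min.
  With `emit_images=True` a two-channel stack plus the true
  nucleus/cytoplasm masks are rendered so segmentation is testable
  separately from all downstream statistics.

What the generator does **not** emulate: drift, blinking, uneven
illumination, cell movement or division, autofluorescence, or background
structure. Passing tests therefore demonstrate correctness of the
estimators under the stated statistical model, not robustness to every
artefact of real data.

## Spot detection

Per frame the background (frame median, or a local annulus median) is
subtracted and the frame is matched-filtered with a Gaussian
(`smoothing_sigma_px`, default 1 px). Spots are local maxima of the
filtered frame above the spot-finder threshold (default 500 ADU); maxima
sharing a detection window (Chebyshev distance ≤ 2× the window halfwidth,
default halfwidth 3 px) merge to the brighter — this also absorbs
point-spread halo maxima beside bright complexes. Kept maxima are refined
to the intensity-weighted centroid of the negative-clipped raw window; no
Gaussian fitting is performed. Thresholding the matched-filter response
rather than the raw peak is what makes a fixed ADU threshold workable at
single-fluorophore signal levels: at SNR 5 the raw threshold would sit 2.4
noise SDs above background and admit large numbers of false maxima.

## Linking

Greedy distance-sorted assignment between open tracks and new detections
within `max_link_distance_px` (default 2 px); greedy acceptance over
sorted candidate pairs yields mutual-nearest-neighbour matches and is
independent of detection input order (ties break deterministically after a
(frame, y, x) sort). Tracks unmatched longer than `max_gap_frames` close
(default 0 for photobleaching stacks, 1 for kinetic movies, tolerating
near-threshold flicker). No motion model: receptors are immobilized and
complexes immobile on the linking timescale.

## Photobleaching trace analysis

Traces are extracted at fixed positions (the median position of tracks
present from frame 0) as background-subtracted window sums. The local
background is the annulus median smoothed over 11 frames: in dense fields
the frame median drifts by an appreciable fraction of one fluorophore step
as neighbours bleach, and an unsmoothed annulus injects white noise ~80%
of the window-sum noise; the smoothed annulus tracks the drift at ~25%
added noise.

**Chung-Kennedy filter.** Forward and backward window means weighted by
the inverse of each predictor's recent mean squared prediction error
raised to an exponent (defaults: window 8, exponent 2; the pipeline uses
window 12, see below). Prediction-error weighting — not window-variance
weighting — is what preserves edges: at the last bright frame the
backward window lies wholly in the dark plateau and is internally quiet,
but it mispredicts the bright samples and is switched off. A predictor
with exactly zero accumulated error is treated as perfect; two perfect but
disagreeing predictors (possible only at a noiseless edge) resolve to the
one matching the current sample; a constant trace passes unchanged.

**Two-stage step fit.** Exact dynamic programming over piecewise-constant
segmentations (minimum segment 3 frames, up to 6 steps) on the filtered
trace proposes candidate change points for every step count; the locations
are then refined (±4 frames) and the count selected against the **raw**
trace by `n·log(RSS/n) + 3·k·log(n)`. Selecting on the raw trace matters
twice over: filtered noise is serially correlated over the filter window,
so a BIC on the filtered residuals overstates the evidence for extra
steps; and plateaus shorter than the filter window are smeared into ramps
that a single-stage fit resolves as spurious intermediate steps. Steps
whose level change falls below 3 residual SDs are pruned (weakest first).
On noiseless traces the fit is exact in count and location (verified
against exhaustive enumeration up to 4 steps); the RSS floor in the
selection score makes the zero-residual case well defined.

**Quality control.** A trace is accepted when (i) it was found by the spot
finder (threshold 500 ADU); (ii) the step function fits the filtered
trajectory with R² ≥ 0.95; (iii) the spot does not move after any
bleaching step by more than mean + 3 SD of its own frame-to-frame
displacements (positions are NaN once the spot is too dim to localize, so
the final bleach to background is exempt automatically; with fewer than
two valid displacement pairs the rule abstains). Additionally the fitted
levels must be strictly decreasing (an upward step means arrival or
aggregation, not bleaching) and the final plateau must lie within 3
residual SDs of zero (a trace that has not fully bleached gives only a
lower bound on its step count). Accepted traces classify as monomer (1
step), dimer (2), multimer (≥3); fractions are reported over monomers and
dimers only, with multimers tallied separately. The SEM is computed
across cells when cell labels exist, else as a binomial SE.

The R² is evaluated over a *balanced span* `[0, min(n, 2·last step)]`
rather than the full 400-frame window. Experimental trajectories come
from tracks that end when the spot disappears; on full-length traces cut
from a movie the full-span R² rejects early-bleaching monomers (~26% of
monomers vs ~10% of dimers at SNR 5), because a trace that is mostly
empty background has little signal variance. That asymmetry would bias
the dimer fraction upward by 2–4 percentage points. Capping the dark tail
at the occupied length maximizes the fitted step's signal balance q(1−q)
for every bleach time and makes the gate class-symmetric, the behaviour
the threshold is intended to have. Both the span rule and the filter
window are configurable (`steps.r2_span`, `steps.ck_window`); the
pipeline default window of 12 frames lowers the filtered-noise floor the
R² gate sees — with the two-stage fit a longer window no longer costs
step resolution.

With these defaults the end-to-end pipeline on 1024-spot movies at SNR 5
recovers a 22% dimer fraction within ±2 percentage points across seeds,
with cross-class misclassification essentially absent (dimers lost only
when their two bleach frames fall within the 3-frame minimum segment).

## Stoichiometry and the labeling model

All observable fractions are conditional on a spot carrying ≥1 labeled
fluorophore — unlabeled species are invisible. For dimer fraction `d` and
labeling probability `p`, the two-step fraction among visible spots is
`f₂ = d·p²/(d·p(2−p) + (1−d)·p) = d·p/(1 + d(1−p))`, increasing in both
arguments; hence the smallest `p` consistent with an observed `f₂` is
attained at `d = 1`: `p_min = 2f₂/(1+f₂)`. An observed f₂ of 0.22 gives
p_min ≈ 0.361 — the origin of the ">30% labeling" inference. Copy numbers
use the population mean of the reference distribution (the estimator the
reference spread propagates most simply through); "super" complexes are
called by intensity alone (≥ (2 − 0.25)× the single-complex reference),
with no spatial merging analysis. Surface density corrects observed
track counts for partial labeling: `(n_tracks/p)/area`.

The simulated dimeric standard is rendered sparse and measured against a
local-annulus background: in a dense single-frame field the global median
background swallows a third of the standard's flux through its own PSF
halos. Copy numbers in the kinetic workflow are estimated from tracks
observed in ≥2 frames, which excludes single-frame noise detections
without biasing the estimate (copy number is independent of lifetime).

## NF-κB dynamics

The nuclear:cytoplasmic ratio is computed per timepoint on valid samples,
gaps propagated as NaN. The first peak is the earliest local maximum of
the lightly smoothed ratio (5-sample centred moving average) whose
*topographic prominence* exceeds 20% of the pre-stimulus baseline (mean of
the first 3 samples) and which stands above baseline by the same margin.
Prominence, not height-above-baseline, is essential: on a noisy rising
flank every noise bump exceeds a height threshold before the true peak
does. The reported peak magnitude is the smoothed peak ratio (a
baseline-subtracted alternative is available via a flag). Reporter fold
is final-plateau mean over initial-baseline mean (5 samples each, so a
constant channel gives exactly 1). Rank correlations use Spearman's rho
with mid-ranked ties and the large-sample two-sided p-value; with fewer
than five responded cells the estimate is flagged underpowered but still
reported.

Segmentation is intentionally simple (Otsu on the smoothed green channel
for the cell; the brighter Otsu class of the eroded interior for the
nucleus) and is bypassed entirely when ground-truth masks are provided —
every downstream statistic is therefore testable independently of
segmentation. A cell with no intensity contrast between compartments
(ratio ≈ 1 throughout) cannot be segmented this way and is flagged.

## Reproducibility

Every workflow consumes one YAML config plus a seed; all randomness flows
from `numpy.random.default_rng(seed)`. Outputs are CSV/JSON with a
manifest carrying the config hash, seed and package version; reruns are
byte-identical. Problem sizes in the test-suite Monte-Carlo checks (e.g.
400 traces for step-count recovery, 1024-spot movies for composition
recovery, 20-seed cohorts for peak-time regression) were chosen to hold
the sampling error of each check well below its tolerance.

## Known limitations

* Two bleaching events closer than the 3-frame minimum segment merge into
  one step; at bleach rate 0.01/frame this reclassifies ~3% of dimers as
  monomers (a ~0.7 point composition bias, inside the reported SEM).
* The spot-finder threshold admits a few single-frame noise tracks per
  kinetic movie at SNR 5; they inflate the 1-frame lifetime bin slightly
  and are excluded from copy-number statistics as described.
* Fractions assume a pure monomer/dimer mixture; higher oligomers land in
  the multimer bin and are not modelled further.
* The labeling bound is sharp only under binomial (independent) labeling;
  cooperative labeling would break the inversion.
* Segmentation requires nucleus/cytoplasm contrast and one cell per field;
  it is a fallback, not a contribution.
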