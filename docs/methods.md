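# Methods

## Assay and measurement model

The package analyzes (and, for testing, synthesizes) an hourly-sampled
liquid-culture growth assay of *C. elegans* larvae scored on a large-particle
flow cytometer. Each detected object carries TOF (instrument units,
proportional to axial length), EXT (integrated optical density; norm.EXT =
EXT/TOF is the width proxy) and red fluorescence from ingested beads (a
feeding proxy). The analysis unit downstream of gating is the **well
summary**: per-well, per-hour medians of TOF, norm.EXT, and per-object red
fluorescence normalized by the optical area proxy TOF·norm.EXT. "Area" is
not directly measured by the instrument; the TOF·norm.EXT proxy is the
package's choice and is applied per object before the median.

## Synthetic growth model

Each strain profile plants a ground-truth trajectory with closed forms, so
every downstream estimator can be checked against analytic oracles:

- **Stages and molts.** Molts at `stage_boundaries` (h post-feeding) split
  1–42 h into L1–L4. Each animal jitters its molt times by N(0, σ²) with
  σ = 0.3/0.6/1.0 h for molts 1–3, emulating growing population
  desynchronization.
- **Lethargus plateaus.** Growth stalls for 2.5 h before each molt
  (lethargus, feeding stops) and 3.0 h after it (the post-molt
  relaxation/re-equilibration period). The post-molt side is deliberately
  longer than the relaxation-measurement margin (2 h) so that, even with
  molt-time jitter, the pre/post windows sample the flat portion of the
  trajectory; without this, ordinary growth leaking into the windows
  (≈ g·Δt ≈ 20 µm) would swamp relaxation steps of a few µm.
- **Length** grows piecewise-linearly at `growth_rates[k]` µm/h within the
  active window of each stage.
- **Width** follows the cuticle-stretch phenomenology: dW/dL = c_k (the
  baseline aspect slope) until the nonlinear onset at a configurable
  fraction (default 0.7) of the active window, then dW/dL ramps linearly to
  c_k·gain (default 1.5) by stage end. Width is therefore piecewise
  linear/quadratic in time with exact closed forms.
- **Post-molt relaxation.** At each molt the named axis steps by
  +`relaxation_magnitude` µm and the other axis by −0.5× that:
  length-relax (N2-like) means ΔL > 0, ΔW < 0; width-relax (dpy-5-like)
  means ΔW > 0, ΔL < 0. Magnitudes (5–6 µm primary; dpy-1 reduced to 2 µm)
  are sized so the step is visible in population medians, which is the
  regime in which relaxation is reported for the real assay.
- **Feeding** dips by `feeding_dip_depth` (default 0.6) with Gaussian width
  1 h at each molt; red fluorescence ∝ feeding × length × width ×
  multiplicative noise.
- **Measurement.** tof = gain·(L + ε), norm_ext = gain·(W + ε′), with
  additive noise σ_L = 15 µm, σ_W = 1.5 µm per object (a few percent of
  size) and 15 % multiplicative fluorescence noise. Contaminants (default
  rate 0.1) are an equal mixture of dense small "bacterial clump"-like
  objects (small TOF, high EXT) and faint elongated "shed cuticle"-like
  streaks (low EXT); the truth table labels every object.
- **Seeding.** One master seed; each (strain, hour, well) derives its own
  counter-based stream, so changing the well count never reshuffles other
  wells, and identical configs are bit-identical.

The default strain roster encodes the qualitative contrasts of the
four-strain panel: lon-3 tracks N2; both dpy profiles molt later (dpy-1
latest at every transition); dpy profiles are shorter, wider (larger c_k)
and dpy-1 has a weak nonlinear regime (gain 1.1); dpy-5 relaxes in width
where the others relax in length. The defaults (30 wells/hour, 30
animals/well) are fixed study conditions, not tuning knobs.

What the generator does **not** emulate: bacterial food depletion, arrested
or dead animals, optical saturation, per-animal growth-rate heterogeneity
beyond molt-time jitter, and next-generation hatchlings (the late-hour
minimum-TOF gate exists for them but is exercised only by the contaminant
classes). Passing tests therefore demonstrate correctness of the estimators
under the stated statistical structure, not robustness to every artifact of
real cytometer data.

## Gating

Non-animal objects are removed by model-based clustering on
(log TOF, log EXT), pooled per hour across wells and strains. The number of
mixture components is selected by BIC over k ∈ {1, 2, 3} (one animal
component plus up to two contaminant classes); the component with the
largest mean log TOF is the animal class. A component is only discarded if
its mean is at least 1.0 (one e-fold) from the animal mean in log space —
this guard makes gating idempotent and bounds false positives on clean
pools, where a forced two-component split would shave the animal cloud.
Pools smaller than 20 objects fall back to robust 1.5·IQR gating; a single
object passes through. After hour 30, kept objects smaller than 25 % of the
hour's median TOF are additionally removed (next-generation larvae). The
rule never reads the synthetic truth columns.

## Calibration

Manual image measurements (pixels) are converted to µm by the fixed
magnification factor 3.2937 pixels/µm, reduced to per-well medians, matched
to well summaries on (hour, well), and regressed through the origin:
µm = slope · instrument units, separately for length (TOF) and width
(norm.EXT). The intercept is omitted because a zero-length object has zero
TOF; this also avoids extrapolation artifacts at L1 sizes. At least 10
matched wells are required; residual SDs are reported as diagnostics.

## Molt detection

Per strain, the population median of normalized fluorescence per hour is
smoothed (same local-linear machinery as below, bandwidth 2.0 h) and molts
are called as local minima with prominence ≥ 0.15 of the smoothed dynamic
range, separated by ≥ 5 h, at most three per assay. Prominence is
range-relative, so detection is invariant to affine rescaling of the
fluorescence values. Stage windows are the intervals between minima.
Detected molts feed the relaxation analysis; for the Stretcher windows the
published per-strain growth windows ship as the default and detection is
advisory (`--windows detected` switches).

## Stretcher estimators

- **Kernel regression.** Tricube local-linear regression (the LOESS
  kernel), default bandwidth (support radius) 1.75 h, evaluation grid 0.25 h.
  The local slope coefficient is the derivative estimate. Local-linear fits
  reproduce straight lines exactly; the compact tricube support bounds how
  far end-of-stage curvature can leak backward along the time axis — with a
  Gaussian kernel the unbounded tails advance the apparent nonlinear onset
  by 1–2 h, and the bias *grows* with well count because the bootstrap SD
  shrinks while the bleed does not. 1.75 h is the smallest support that
  keeps at least three hourly observations in the window at every grid
  point.
- **Uncertainty.** Cluster bootstrap over wells (resample wells with
  replacement, re-smooth; default 1000 replicates, seeded). Bands are the
  SD across replicates.
- **Slope ratio.** r(t) = W′(t)/L′(t) is formed per replicate and then
  averaged, so the band reflects ratio variability rather than a ratio of
  averaged derivatives. Grid points where |L′| is below 5 % of the window's
  median |L′| (growth plateaus) are masked; an absolute epsilon guards
  exactly-flat curves.
- **Regime segmentation.** The linear baseline is the median of r over the
  first third of the window. The nonlinear onset is the earliest grid time
  after the baseline region from which r(t) − baseline > z·SD(t) at every
  later unmasked point (z default 2.5), so nonlinear labels always form a
  suffix of the window. When replicate curves exist the rule is applied to
  each replicate and the median onset over replicates is reported, provided
  at least one third of replicates find one. These defaults were fixed by a
  planted-onset recovery study: replicate aggregation removes the
  correlated "tilt" error of a single noisy baseline, z = 2.5 suppresses
  spurious crossings in the desynchronization-smeared ramp tail with no
  false onsets measured on linear-only data. On a single curve (no
  replicates) increasing z can only move the onset later.
- **Relaxation.** ΔL and ΔW are post- minus pre-molt medians of the well
  summaries in ±2 h margins around each molt. Direction follows the sign
  pattern (length-relax: ΔL > 0, ΔW < 0; width-relax: ΔL < 0, ΔW > 0);
  magnitude is the absolute value of the negative component; other sign
  patterns are flagged ambiguous; molts too close to the span edge are
  skipped. Reported values are signed, so genotypes whose relaxation is
  described differently in different sources can be read off directly
  rather than forced into a label.

## Report conventions

Quartiles use linear interpolation between order statistics (the numpy
default); whiskers sit at the most extreme observations within 1.5·IQR of
the box and points beyond are outliers. The phase plane plots median length
(x) against median width (y). Tables are written with a fixed float format
so identical inputs give byte-identical CSVs; the manifest records row
counts and SHA-256 checksums for provenance.

## Problem sizes

Tests and the acceptance script run the pipeline on reduced assays (6–30
wells/hour, 15–30 animals/well, single-stage hour ranges where a full span
is not needed, bootstrap 100–600 replicates) chosen as the smallest sizes at
which the planted-truth recovery statements hold with margin; the package
defaults remain 30 wells × 30 animals × 42 h × 1000 replicates.

## Known limitations

- Onset localization inherits an irreducible early bias of a few tenths of
  an hour from population desynchronization: the population-median ramp
  begins where the *earliest* animals stiffen.
- The z·SD suffix rule labels exactly one linear→nonlinear transition; it
  does not model re-entrant or non-monotone regimes.
- Gating assumes contaminants are separable from animals in
  (log TOF, log EXT); contaminant classes overlapping the animal cloud in
  both coordinates would require additional features.
- The calibration is a single global slope per dimension; stage- or
  magnification-specific calibration is not modeled.
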