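# Methods

`disuse` implements the analysis chain for studying disuse-driven
plasticity with dense-sampling fMRI during limb immobilization: a
participant is scanned daily before, during, and after wearing an arm
cast; seed-based functional connectivity (FC) of the upper-extremity
primary somatomotor cortex (left SM1ue) is compared across phases; large
spontaneous lateralized BOLD transients ("disuse pulses") are detected
and characterized; and FC change is related to motor-task topography and
followed over time with a two-rate exponential model. Everything runs on
a synthetic multi-session generator with full ground truth, and on real
grayordinate data supplied as NIfTI/TSV.

## Spatial substrate

A `GrayordinateSpace` holds per-grayordinate coordinates (mm, RAS),
anatomical structure labels, and a symmetric irreflexive neighbor graph:
cortical sheets are 2-D lattices with 4-neighborhoods, subcortical and
cerebellar boxes are 3-D lattices with 6-neighborhoods placed at
plausible anatomical centers on a common 3-mm voxel grid. Neighborhoods
never cross structure boundaries, so smoothing and cluster formation are
per-structure by construction. Surface geometry formats are out of
scope; surface-like grayordinates are represented abstractly by their
adjacency.

## Synthetic data generator

The generator produces the statistical structure the analyses assume,
not MR physics. Per run, grayordinate *i* is

    y_i(t) = snr_i * (B + 0.01 B * s_i(t)),

with baseline B = 1000 and fluctuations `s_i` in ~percent units composed
of: unit-variance AR(1) noise (coefficient 0.5), spatially smoothed
within structure to 4.7 mm FWHM and renormalized to unit SD; a global
latent (loading 0.3 everywhere); a homotopic sensorimotor latent
(loading 1.0 in left and right SM1ue); a seed-coupled latent whose
loading on a 40-voxel thalamic blob differs by phase; injected pulse
kernels; and motion-locked artifacts when enabled. The SNR profile
`snr_i = 1 - 0.6 exp(-(r_i/40 mm)^2)` (r = distance from the brain
center) scales each voxel's whole series — emulating coil-distance
signal loss in the temporal-SNR map — and additionally scales pulse
kernels inside the fluctuation term, so pulse amplitude relative to
local noise is lower in deep structures, as observed in real data.

Default problem sizes are scaled-down versions of the study design:
240 frames at TR 1.1 s per run (the study used 30-minute daily runs at
TR 1.1 s or 2.2 s), 6 sessions per phase (the study had 14), ~660
grayordinates. These sizes keep every protocol within desk-scale compute
while preserving the session-level statistics that the analyses operate
on.

**FC effect calibration.** The generator's contract is that the
*empirical* cast-vs-pre Cohen's d of seed FC at the target blob equals
`effect_d` (default 2.5, inside the subcortical range the method is
meant to resolve). Because the between-session SD of a sample
correlation depends on the run's effective temporal degrees of freedom
and on seed-voxel noise correlations induced by smoothing, the coupling
loading is calibrated by Monte Carlo with the actual measurement
protocol: simulate pulse-free sessions, measure mean and between-session
SD of blob seed-FC, convert the requested d into a population-
correlation shift (folding in the Hedges small-sample factor at the
configured session count), and invert analytically for the loading.
Calibration uses a fixed internal seed and is cached per parameter set,
so it is a pure function of the parameters. Ground truth refers to FC
measured on raw generated sessions; preprocessing (band-pass filtering
in particular) reduces effective degrees of freedom and hence the
realized d, which is why recovery tests on preprocessed data are stated
as detection rates, not d equality.

**Pulses.** Pulse events are double-gamma kernels (peak 5 s, dispersion
1 s, undershoot peak 15 s, ratio 1/6) added to left SM1ue and to
configured subcortical regions, with region-specific latency offsets
implemented by shifting the kernel onset (default thalamus +0.95 s, a
value in the range reported for real participants). Amplitude is
expressed in SD units of the left-ROI detection series (noise plus
network latents) — the scale the detection thresholds are applied to —
and refers to the peak *sample* on the TR grid. Default rate is 2 pulses
per cast-phase run; the rate per run is not characterized in the
literature and is a free simulation parameter.

**Motion.** Rigid-body parameters are a slow random walk plus
frame-to-frame measurement jitter (baseline FD ≈ 0.02 mm), with Poisson
censorable spikes (FD > 0.1 mm). Optional motion-locked artifact events
copy the spiked motion-parameter waveform into the left-ROI series at
large amplitude: nuisance regression can shrink but not reshape such an
artifact, so it survives preprocessing yet correlates highly with head
motion over the screening window. Artifacts are placed away from
censorable spikes, whose censoring residue would otherwise dominate the
window.

What the generator does *not* emulate: physiological (cardiac or
respiratory) noise, scanner drift beyond what the filters remove,
distance-dependent motion artifacts across the brain, real cortical
geometry, and between-session scanner instabilities. Passing tests
therefore demonstrate that the pipeline recovers known structure of this
statistical form at these SNRs, not that it is robust to every real-data
pathology.

## Preprocessing

The denoising chain mirrors the study: censoring of frames with FD >
0.1 mm; zero-phase Butterworth (order 2, forward-backward) band-pass
0.005–0.1 Hz; nuisance regression of the six motion parameters, the
gray-matter global mean, and sequentially Gram-Schmidt-orthogonalized
tissue waveforms when supplied; graph smoothing at 6 mm FWHM on
surface-like and 4.7 mm on volume-like structures. Censored frames are
linearly interpolated before filtering and dropped afterwards
(censor → interpolate → filter → re-censor). DC is removed exactly
(it lies in every mode's stopband). Smoothing uses the doubly
stochastic diffusion operator `S = I − (w/k) L` iterated m times with
`m·(2w/k)·h²` matched to the requested Gaussian variance on the lattice;
mass and constants are preserved exactly and structures never mix.

Temporal SNR follows the study's definition — temporal mean divided by
temporal *variance* (a config switch selects the conventional SD
denominator) — computed before nuisance regression, displayed as percent
with the map maximum subtracted.

For pulse-shape analyses the chain drops the low-pass stage (high-pass
at 0.005 Hz only), since a 0.1-Hz low-pass distorts pulse waveforms; a
literal 0.1-Hz high-pass variant is also exposed but is not the default,
because it would remove the band the resting-state analyses keep.

## Seed FC and effect-size mapping

Per session, the seed FC map is the average of the whole-brain Pearson
correlation maps of each seed voxel (a seed voxel's unit
self-correlation is excluded from its own average). Cast-vs-pre change
is Cohen's d per grayordinate with the classical pooled SD; d is the
effect-size of choice because subcortical correlations are weak but
consistent across sessions, and d is more stable than t under small,
unequal session counts.

**Permutation cluster correction.** Significance is assessed within
individual by randomizing session-phase labels (default 1000
permutations) with a multi-threshold, per-structure cluster-size
criterion: thresholds are the 10 upper deciles of the suprazero d
values ("every 10%" of the value distribution), connected components are
formed per structure under the space adjacency, and a cluster must pass
the size criterion at ≥ 2 thresholds. Two details make the test well
calibrated:

- *Per-permutation adaptive thresholds.* Each permutation map is
  thresholded at its own deciles, exactly as the observed map is.
  Thresholding permutations at the observed map's deciles breaks
  exchangeability (the observed map always has exactly 10% of its
  positive voxels above its 90th decile; a permutation map typically
  does not) and measurably inflates the error rate.
- *Family-wise calibration.* Cluster sizes are studentized against
  their (structure, threshold) permutation null; the family statistic of
  a map is the largest, over structures, of the 2nd-largest studentized
  cell value; the cell criterion is the (1−α) rank of the permutation
  family statistics. By exchangeability this makes α the family-wise
  rate of reporting *any* cluster anywhere. Applying the per-cell (1−α)
  quantile independently in each of the ~120 (structure, threshold)
  cells — the literal reading of the original procedure — gave a
  measured family-wise rate of 0.87 on null studies; the uncalibrated
  variant remains available as `family_control=False`.

Reported per cluster: member voxels, size, peak |d| coordinate (ties:
highest |d|, then lowest index), number of thresholds passed, and a
cluster p-value (best rank of its size across threshold nulls). Default
is one-sided (cast > pre); two-sided thresholds |d|.

## Pulse detection and modeling

Left and right SM1ue mean series are demeaned per run and variance-
normalized by the pooled across-run SD. Candidate pulses are frames
where (left − right) exceeds 2.3 SD of the difference *and* the left
series exceeds 2.3 SD (of the left series by default; the difference-SD
reading is a switch). Suprathreshold frames within 8.8 s (one HRF width)
merge into one event at the frame of maximal difference; events whose
left-ROI series correlates > 0.8 (absolute) with any motion parameter
over an 18-s window centered on the peak are screened out; a constant
motion trace gives r = 0 (retained). Events with truncated windows are
retained but flagged. SDs are computed over all retained frames of the
concatenated normalized runs, matching the across-run normalization.

**Parametric fit.** At each locus and event, a double-gamma waveform
with free amplitude, onset shift (±3 s), time-to-peak (2–10 s),
dispersion (0.3–3 s) and undershoot ratio (0–0.5) is fitted by bounded
nonlinear least squares over a 33-s window (17.6 s before the detected
left-SM1ue peak, 15.4 s after). Convergence — optimizer success with
every parameter strictly inside its bounds — defines the presence of
pulse activity; on white noise the bounds reject ≳80% of fits. The
bounds bracket canonical HRFs; their exact values are this package's
choice. Detectability per grayordinate is the converged fraction
(an amplitude-t-statistic variant is available); latency is the mean
fitted peak time minus the fitted left-SM1ue peak time (fitted peaks
give sub-TR resolution); display maps keep the top 20% detectability and
latencies ≤ 1.1 s by default. The gamma dispersion converts to FWHM via
2·√(2·ln 2).

**FIR.** A lagged-indicator design over the same window (one column per
lag at TR resolution, detected events as onsets, ≥ 5 events required) is
solved by least squares with AR(1) pre-whitening estimated from
first-pass residuals, respecting run boundaries; collinear lags from
overlapping events are dropped with a warning. Peak height, FWHM (linear
interpolation between half-max crossings, parabolic refinement of the
peak position) and peak delay relative to the reference curve are
extracted. The parametric and FIR routes agree on synthetic events to
within a fraction of a TR in peak delay and ~10% in FWHM. Two estimator
effects matter here: TR-grid alignment smears the FIR average by a few
percent, and the bound-interior convergence rule selectively rejects
wide fits, truncating the dispersion distribution. Waveform features at
loci known to pulse are therefore computed from all optimizer-successful
fits (which are unbiased for the dispersion), while the bound-interior
rule remains the presence criterion behind detectability maps.

**Amplitude normalization.** Pulse amplitude distributions are
standardized against the dominant mode of a Gaussian mixture: one- and
two-component spherical mixtures are fitted (10 restarts, derived seed)
and compared by BIC, and values are z-scored against the largest-weight
component of the winner; median/MAD is the fallback if the fit fails.

## Motor-task GLM

Block designs (per-condition boxcar, per-condition onset impulse, and a
shared offset impulse — a per-condition switch exists — all convolved
with the canonical double-gamma HRF, plus polynomial drift up to order
2) are fitted per run by AR(1)-pre-whitened least squares; contrasts are
t = c'β̂/SE. The second level combines runs within participant by fixed
effects (inverse-variance weighting), matching within-individual
precision-mapping inference; group-level random effects are explicitly
out of scope.

## Spatially constrained nulls

Map-similarity claims (e.g. FC-change vs task-activation topography in
the thalamus) are tested against Moran spectral randomization
surrogates: the doubly centered, symmetrized row-normalized adjacency is
eigendecomposed (Moran eigenvector maps), and the map's coefficients in
that basis have their signs randomized — the singular procedure — which
preserves the map's variance and Moran's I exactly while scrambling its
arrangement. Surrogates are built per structure (default 1000); the
observed within-structure Pearson correlation is compared to the
surrogate correlations with the (1+k)/(n+1) rule. Surrogates are built
on the first map only (a symmetric variant is a documented extension
point); a distribution-preserving mode rank-remaps surrogates onto the
original value multiset. Benjamini–Hochberg FDR corrects across test
families. Atlas-label summaries (mean t per thalamic nucleus, voxel
counts, surrogate p, BH q) take nucleus label images as *inputs*;
segmentation itself is out of scope.

**VIM box.** The ventral-intermediate nucleus is localized indirectly
from AC-PC landmarks: the anterior-posterior anchor sits 0.25 of the
third-ventricle length anterior to the PC point; the lateral band runs
from 11 mm lateral of the ventricle border to 14 mm lateral of the
ventricle center (both published criteria honored as the medial/lateral
bounds of an interval, resolved per hemisphere); the box extends 3 mm
superior and 2 mm anterior, rasterized at 3 mm with an overlap rule.

## Recovery dynamics

Dynamics ROIs are the intersection of significant FC-change clusters
(≥ 2 thresholds) with the structure's top 1% motor-task t-values. The
per-session ROI FC time course is fitted with the package's two-rate
exponential model,

    FC(t) = b                                  t < t_cast
    FC(t) = b + A (1 − e^{−a1 (t − t_cast)})   during cast
    FC(t) = b + A_end e^{−a2 (t − t_off)}      after cast,

continuous at the cast-off boundary, time in days, by multi-start
bounded least squares (rates ≥ 0, flat start included so the fitted RSS
never exceeds the baseline-only model's). Fits with negligible amplitude
against the residual scale are flagged unidentifiable. The exact
functional form of the historical two-alpha model is not printed in the
source literature; this piecewise saturating-rise/exponential-recovery
form is the model definition of this package.

## Numerical and design notes

- One global seed; every stage derives a child seed by hashing
  (seed, stage name), so the pipeline output is a pure function of
  (inputs, config, seed).
- Grayordinate order is canonical (sorted by structure label, then
  linear index); all maps share it.
- Degenerate inputs are flagged, not propagated: zero-variability SNR
  denominators, zero pooled SDs, zero-variance seed voxels, flat FIR
  curves and constant surrogate maps all yield NaN/flags with warnings
  rather than infinities or exceptions.
- Zero-duration onset/offset events are impulses convolved with the
  same HRF; the offset regressor is shared across conditions by default.
- Cluster-threshold grids, tie-breaks and bound margins are fixed
  deterministic rules stated above, chosen for reproducibility.

## Known limitations

- The generator's network model is low-rank (two latents plus seed
  coupling); real FC structure is far richer, so specificity results
  here bound only latent-driven confounds.
- Family-wise calibration of the cluster test assumes exchangeability of
  session-phase labels within participant; slow physiological drifts
  across phases would violate it in real data.
- FIR estimation at few events is noisy by design (the study itself
  required TR-resolution windows and ≥ 5 events); features from single
  events should not be interpreted.
- The VIM box is a geometric construction; no claim is made about
  individual functional boundaries.
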