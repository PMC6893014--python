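# Methods

## Scope and model

`telo3d` quantifies telomeres in 3D wide-field fluorescence z-stacks of
interphase nuclei: how many there are, how long they are (relative
lengths from integrated qFISH intensity), how large their diffraction-
limited images are (ellipsoidal spot volumes), and how much of the
expected complement is hidden inside unresolved clusters.  Because a
normal diploid human cell in G0/G1 carries a fixed complement of 92
telomeres (two per end of 46 chromosomes), the telomere count is a
built-in truth standard: a calibrated pipeline should recover ~92 spots
per G1 nucleus, and any systematic deficit measures spatial clustering
below the resolution limit.

The package pairs the analysis pipeline with a synthetic microscope
(`synthetic_nuclei`) so that every stage is testable by parameter
recovery without any external data.

## Image formation (the simulator)

Telomeres are modelled as point emitters: their physical extent is below
the diffraction limit, so the rendered spot is the PSF itself.  Each
telomere of length `L` kb emits a total flux of `photons_per_kb * L`
photons — the qFISH assumption of uniform probe hybridisation.  The PSF
is a separable anisotropic Gaussian with FWHMs (220, 220, 660) nm, the
theoretical lateral and axial resolutions of a 1.4 NA oil objective at
647 nm emission (3x axial elongation).  Emitters are integrated exactly
over voxels with per-axis erf differences, so the noise-free render
conserves flux to numerical precision — the anchor for all intensity
book-keeping tests.

The camera chain is: Gaussian vignetting of the illumination (centred,
strength 0.3, width 20 µm — a typical wide-field fall-off), Poisson shot
noise on the expected photon count, gain (1 count/photon), a dark offset
of 6 counts, Gaussian read noise (sd 1 count), rounding, and clipping to
the bit depth (12 bits, 0–4095, matching the worked example; 16
available).  Voxel spacing defaults to 108 nm laterally and 100 nm
axially.

Nucleus geometry: an axis-aligned ellipsoid, default semi-axes
(7, 5, 1.2) µm — a flattened fibroblast nucleus that fits a 41-step
z-stack with more than one axial FWHM of out-of-focus margin on both
sides.  Telomere *sites* are placed uniformly in the ellipsoid by dart
throwing with a minimum pairwise separation (default 0.5 µm; recovery
experiments use 1 µm so that no merging occurs by construction).  A
`cluster_fraction` of telomeres is placed in pairs 0.1 µm apart —
sub-resolution, so each pair images as one spot; with fraction `f` the
expected observable count is `N (1 - f/2)`.

Telomere lengths are lognormal with mean 5.3 kb and sd 1.6 kb (CV 0.30)
for the normal-fibroblast condition, and mean 18.9 kb (same CV) for the
telomerase-extended condition — the two conditions' means reproduce the
~3.5-fold length difference between the reference cell lines.  The
flux scale (`photons_per_kb = 2000`) puts a median telomere's peak ~150
counts above offset on the 12-bit scale, i.e. well-exposed but far from
saturation, with the brightest telomerase-condition telomeres still
below clipping.

The DNA channel renders the same ellipsoid as a smooth (0.3 µm edge)
uniform stain at 60 expected photons/voxel, scaled by DNA content (1
for G1, 2 for G2); it exists to drive segmentation and cell-cycle
gating, not to model chromatin texture.

What the simulator deliberately does *not* emulate: chromatin-density
variation of the DNA stain, probe off-target binding, telomere
decompaction (spot sizes beyond the PSF), spectral crosstalk, axial
vignetting, stage drift, or depth-dependent aberrations.  Passing tests
therefore demonstrate the *pipeline's* correctness under a known
optical model, not robustness to every real-world artefact.

## Restoration

Shading correction is `M (raw − dark) / (flat − dark)` computed in
32-bit float, with `M = 3000` restoring a camera-like scale.  The dark
frame is the pixel-wise mean of 15 simulated dark exposures; the flat
field images a uniform fluorescent target through the vignetted
illumination.  Pixels where `flat − dark ≤ epsilon` (default 1 count)
are masked; if more than 1% of the field is masked the flat is rejected
as unusable.

Deconvolution is plain Richardson–Lucy — the multiplicative
expectation-maximisation iteration for the Poisson imaging model, i.e.
the textbook core of commercial CMLE implementations — run for 50
iterations by default.  The assumed SNR (40) is recorded in provenance
metadata but does not alter the update: plain RL has no regulariser,
a deliberate simplification.  Boundaries are handled by reflective
padding of half the PSF support; flux of interior objects is conserved
to within 1%.  The implementation caches the PSF's transfer function,
so one iteration costs four real FFTs; a dense spatial-domain
implementation (`richardson_lucy_direct`) is kept as an independent
cross-check and agrees to < 1e-9 absolute on small stacks in double
precision.

## 2D counting

The maximum-intensity projection is searched for local maxima with a
noise-tolerance (prominence) parameter: a peak is accepted exactly when
it exceeds every saddle toward higher ground by more than the
tolerance.  All prominences are computed in one union-find sweep over
pixels in descending order, which makes tolerance sweeps cheap;
equal-valued plateaus count once, at their centroid, and edge-touching
maxima are excluded by default.  Calibration picks the tolerance whose
mean count over control images is closest to the expected karyotype
count (92), breaking ties toward the larger (more conservative)
tolerance.  Area/intensity measurement uses Otsu thresholding and
marker-based watershed on inverted intensity, seeded by the accepted
maxima; mask components containing no seed remain unlabelled.

Projection folds the axial dimension, so telomeres that overlap in
(x, y) but not in z merge: 2D counts are systematically at or below 3D
counts.  This is the documented reason the 3D path is the primary
readout.

## 3D detection and measurement

Spot centres are local maxima of an anisotropic Laplacian-of-Gaussian
("quality") response with lateral scale matched to the expected spot
diameter (220 nm) and axial scale 3x larger; anisotropy is handled by
scaling the filter, not by resampling the stack.  A candidate must pass
a quality threshold (default: 3x the median absolute response of the
stack) and an intensity threshold at the spot centre.  On synthetic
data the intensity threshold is derived per condition from one
calibration scene: half the dimmest true telomere's peak intensity —
the reproducible analogue of interactively picking "the lowest
intensity that is still telomeric signal" (800 on the reference
system's corrected scale, which remains the configuration default).

Detection runs on the deconvolved stack; geometry is measured on the
pre-deconvolution corrected stack.  The split exists because
unregularised RL on clean data collapses a point source to ~1 voxel:
grown radii would all hit the floor and the volume readout would
degenerate.  The lateral radius is read off a Gaussian model of the
azimuthally averaged profile — `r = sigma_hat * sqrt(2 ln(A/T))` with
`sigma_hat` the spot's measured lateral second moment and `A` its
centre intensity above local background — rather than a grid-crossing
search, which would quantise radii to the 108 nm pixel pitch and
fabricate spurious volume modes.  The radius is floored at half the
expected lateral diameter and capped at 8x that floor.  The axial
radius is the fixed ratio (3) times the lateral radius — volumes are
explicitly *relative* measurements of the diffraction image, not
physical telomere sizes.  Note that because the intensity threshold is
calibrated per condition (it scales with that condition's brightness),
volumes are comparable *within* a condition; comparing volumes *across*
conditions the way the reference workflow does requires holding one
fixed threshold for both, in which case brighter (longer) telomeres
yield systematically larger spot volumes.  Intensity sum/mean are taken over the
ellipsoid on the detection stack, where the concentrated flux makes the
sum insensitive (±5%) to the exact threshold; the intensity maximum is
the centre-voxel value by definition.

Bead calibration: sub-resolution (100 nm) beads are rendered as PSFs;
per-bead 1D Gaussian fits through the peak give lateral and axial
FWHMs, medians are reported, and the minimal resolvable volume is the
ellipsoid volume of those two FWHMs.  The analytic value for
(220, 660) nm is (π/6)·0.22²·0.66 ≈ 0.0167 µm³; measured values are
slightly larger laterally (~232 nm) because pixel integration adds
dx²/12 to the profile variance.

## Gating and statistics

Nuclei are segmented from the flat-corrected DNA channel by Otsu
thresholding after 0.25 µm Gaussian smoothing (largest component, holes
filled); 0.25 µm is small enough not to erode the thin axial caps of a
flattened nucleus (volume bias ≈ +3% on a (7, 5, 2) µm test ellipsoid).
DNA content is the background-subtracted in-mask sum.  The G1 reference
is the mode of the median-normalised DNA-content histogram (robust when
the S/G2 fraction is large), and cells within [0.75, 1.3]x the mode are
gated G1 — the window is a documented default, made scale-invariant by
the normalisation.

Condition statistics: per-cell counts (G1 cells only; zero-spot cells
count as zero), spot-volume and intensity-sum distributions with CVs,
and the volume-vs-intensity OLS fit (R² = squared Pearson r).  Relative
telomere length between conditions is the ratio of per-replicate
intensity-sum means, with sd across replicates (mean by default, median
behind a flag since the reference procedure does not say which it
used).

Clustering is quantified two ways from the count deficit, because the
printed "20–25%" band is ambiguous between them: `(E − O)/E` (fraction
of telomeres not individually resolved) and `(E − O)/O` (fraction of
observed spots holding >1 telomere if every merged spot is a pair; each
merged pair hides exactly one count).  For E = 92, O = 73 these are
20.7% and 26.0%.  Both are always reported; negative values (O > E) are
reported as-is and flagged by sign.

Volume bimodality (single-telomere vs merged-spot modes) is assessed by
1- vs 2-component Gaussian mixtures on log-volume chosen by BIC, with
one extra gate: the fitted mixture density must itself have two local
maxima.  The gate exists because a 2-component fit to a merely *skewed*
unimodal distribution often wins the information criterion — on
simulated data with no clustering at all, BIC prefers 2 components
while the density stays one-moded.  The resulting detector is
conservative: under the default length variability (CV 0.30) the
single and pair modes at cluster fraction 0.4 overlap (≈ 2 within-mode
SDs apart at minority weight 0.24) and are *not* flagged, while
well-separated mixtures are detected with the reported threshold (the
crossing of the weighted component densities) falling between the
modes.  Count-based recovery is the reliable clustering readout;
bimodality is a qualitative companion.  This is a known limitation.

## Problem sizes and numerical choices

The full reference scene is 256x256x41 voxels; count-recovery
experiments (and the acceptance script) use 20 such nuclei plus one
calibration nucleus per condition, about six minutes of single-core
compute, dominated by the 50 RL iterations per stack (single-precision
FFTs; double precision is used only in oracle comparisons).  The
property suites run on reduced fields (160–192 px laterally, nuclei
scaled to keep the 92-telomere packing density feasible: random
placement at min-separation 1 µm jams near 38% volume fraction, so
small-scene semi-axes are chosen to stay near 30%).  Fold-recovery
experiments use 4 nuclei per condition; clustering recovery uses 6 per
fraction without deconvolution (detection on the corrected stack is
sufficient when sites are 1 µm apart).

Randomness: every simulation takes an explicit integer seed; one run
seed fans out through `numpy.random.SeedSequence.spawn`, the single
splitting rule used everywhere.  Identical seed and parameters yield
bit-identical stacks and reports.

Degenerate inputs are defined errors, not silent defaults: infeasible
emitter packing names the separation constraint; a flat field within
epsilon of the dark frame over >1% of pixels is rejected; a constant
image has no Otsu threshold; fewer than 3 cells cannot be gated; fewer
than 3 usable beads cannot calibrate resolution.

## Known limitations

* Volumes (and everything downstream of them) are relative to the fixed
  3:1 spot model; no per-spot ellipsoid fitting is attempted.
* Plain RL with no regulariser over-sharpens clean data; the
  corrected-stack measurement path compensates, but deconvolved
  intensity profiles should not be interpreted morphologically.
* The bimodality detector favours specificity over sensitivity (see
  above).
* Absolute length calibration (kb per intensity unit) requires external
  standards and is out of scope; only ratios are meaningful.
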