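# Methods

This note records the modelling choices behind `cardiacpvc`, what the
synthetic data do and do not emulate, and the numerical decisions a user
should know before trusting or extending the results.

## 1. The phantom

The ground truth is a fully parametric thorax, not an anthropomorphic
voxel phantom.  Every structure is an analytic solid voxelised on a
regular grid (0.8 mm native, 2 mm "desk" scale):

* **LV** — a prolate half-ellipsoid shell (endocardial semi-axes
  17 × 29 mm, wall 10 mm at end-diastole), long axis along +z, truncated
  at the base plane.  The wall thickness is a package default; clinical
  end-diastolic walls are 6–12 mm.
* **RV** — the shell of an offset ellipsoid (wall 5 mm) clipped outside
  the LV epicardium, which produces the crescent-shaped cross-section.
* **Blood** fills both cavities and a 15 mm cap above the base plane (an
  atria stand-in so that the basal myocardium borders blood, not air).
* **Pericardium** — a 3 mm shell around the heart (distance transform).
  It matters: in the MR contrast table the lung and the LV share the same
  intensity, and the pericardial layer is what keeps the Bowsher
  neighbour selection from linking wall voxels to lung voxels.
* **Thorax** — elliptic cylinder (soft tissue) with a subcutaneous fat
  rim, two lung ellipsoids, a liver ellipsoid and a spine cylinder.

Tissue activities (kBq/cc): LV 18, RV 12, blood pool 5.5, liver 6.5,
lung 0.9, non-transmural lesion L1 = 8, transmural lesion L2 = 0; all
other tissues are cold.  Attenuation at 511 keV: soft tissue / blood /
muscle / liver 0.096 cm⁻¹, fat 0.090, lung 0.027, bone 0.12, air 0.

### Lesions

Both lesions are wedges of the LV wall defined in wall coordinates
(transmural depth `t` ∈ [0, 1] from endo- to epicardium, wall angle θ,
normalised long-axis position `l`):

* **L1** — `t ≤ 0.6` (60 % transmurality measured from the endocardium),
  centred on the mid inferolateral wall (θ = 120°), spanning the mid-cavity
  band; the angular half-width is grown by bisection until the voxelised
  volume reaches 3 ml.
* **L2** — transmural, centred on the inferior wall (θ = 180°), spanning
  the apical band; the upper longitudinal bound is grown to reach 1.5 ml.

The bisection never shrinks a lesion below the extent of the polar-map
segment it is assigned to (segment 11 for L1, segment 13 for L2), so the
segmental contracts (mean-count segment 11 ≈ the 8/18 transmural mix,
segment 13 ≈ 0) hold by construction.  L2 is carved first; L1 excludes
L2's voxels, so the masks are disjoint.  At 0.8 mm the realised volumes
are 3.00 and 1.60 ml (voxelisation quantises the 1.5 ml target by whole
wedge layers).

### Derived anatomies

* **HRCT**: HU = 1000 (μ/μ_water − 1) with blood raised to +300 HU
  (contrast enhancement by thresholding).  Lesions share the attenuation
  of muscle, so the HRCT carries *no* lesion contrast — by construction.
* **MR**: per-class intensities (LV/RV 10, lesion 55, blood 45,
  pericardium 70, lung 10, soft tissue 30, fat 100, bone 0), plus Rician
  noise `m = sqrt((v+n₁)² + n₂²)` with σ = 5 (5 % of the fat intensity —
  the level is a package default).  An anisotropic variant averages over
  8 mm z-slabs and replicates, emulating thick-slice acquisition.
* Mismatched anatomies: heart *volume* scale (0.90 for "10 % smaller
  diastole", 1.05 for "5 % larger") applied as a linear factor
  `scale^(1/3)` to the heart only; a cardiac-phase surrogate shrinks the
  cavity and thickens the wall by a stated fraction (default ±8 %).
  These are geometric surrogates, not kinematics.

### What the phantom does not emulate

No beating-heart motion within a gate, no papillary muscles or
trabeculation, no bone marrow or rib detail, no scatter-relevant
out-of-field anatomy.  Tissue activities are homogeneous, so every
regional mean is exactly recoverable in principle — passing the recovery
tests shows the *reconstruction machinery* is unbiased under a matched
model, not that real hearts would quantify this well.

## 2. Acquisition model

Parallel-beam 2-D (multi-slice) geometry: 168 angles over 180° (84 at
desk scale), 2 mm radial bins covering the image diagonal.  The projector
is Joseph's method assembled once as a sparse matrix per
(geometry, grid); back projection is the exact transpose, so the adjoint
identity holds to machine precision and EM is consistent by construction.
The camera PSF is applied in image space before projection.  Attenuation
uses survival factors from the forward-projected μ-map; the same sinogram
corrects attenuation during reconstruction (no attenuation mismatch is
studied).  Scatter and randoms are not modelled.  Poisson realizations
are drawn per (seed, index) with independent generator streams.

Count budgets follow the gating arithmetic: a 30 min scan with 5
respiratory × 10 cardiac gates gives 36 s per dual gate (3.9 × 10⁶
counts); ECG-only gating combines all breathing states (5× counts, the
expected sinogram is the sum over the respiratory-state sinograms, so
motion blur is retained); ECG+R keeps the reference state at 5× counts.

## 3. Reconstruction

OSEM with angle-interleaved subsets processed in bit-reversed order;
scheme `3i42s + 2i24s + 2i1s` (desk scale: `3i12s + 2i6s + 2i1s`, the
subset counts must divide the angle count).  Resolution recovery applies
the PSF inside every forward and back projection.  The initial image is a
uniform constant scaled to the measured counts.  Reconstructions are
returned in activity units by dividing out the count-calibration factor;
the RD/TV/Bowsher gradients are invariant under that global scale, so the
penalised fixed point is unaffected.

**MAP via one-step-late (OSL):** the subset sensitivity plus
`(1/n_subsets) ∂P/∂f` at the current image forms the update denominator.
OSL is simple and uniform across the three priors but is only stable
while the prior gradient is small against the subset sensitivity.  Two
numerical guards:

* `δ = 10⁻¹² × max(y)` in the EM ratio;
* the OSL denominator is clipped below at **0.5 × the subset
  sensitivity**.  A relative floor (rather than a small absolute one) is
  a no-op at β = 0 — so `map_osem` with zero weight is bitwise identical
  to `osem` — and bounds the multiplicative boost of a strongly negative
  gradient at 2× per subset update.  With an absolute floor the Bowsher
  prior at high weight diverges (the floored denominator admits ~100×
  boosts).  Beyond the stable region (desk scale: Bowsher β ≳ 10 with
  n = 9, RD β ≳ 30 with γ = 10) OSL oscillates and the reconstructions
  get *noisier* with increasing β; the shipped operating points are well
  inside the stable region.  A convergent optimizer (e.g. relaxed block
  sequential regularized EM) would remove this limitation.

**Penalties.** Pair weights are inverse centre-to-centre distance in
voxel units; pairwise terms are counted once per ordered pair; the
numerical floor ε defaults to 10⁻⁶ × image max.  The Bowsher selection is
asymmetric (a voxel's penalty sums over its own selected set), uses the
18-neighbour quasi-spherical 3×3×3 neighbourhood, breaks ties by a fixed
canonical offset order, and sees only the anatomical image, resampled to
the reconstruction grid by volume-weighted block averaging.

## 4. Parameter selection and the two parameter sets

Penalty weights are not transferable across discretisations: the
likelihood term scales with counts and system geometry while the penalty
scales with the voxel lattice.  The package therefore carries **two
clinical parameter sets**:

* `pipeline.FULL_CLINICAL` — Bowsher β = 10/n = 9, TV β = 0.005,
  RD β = 4/γ = 10 — for the full-scale configuration (1.35 mm
  reconstruction voxels, 168 angles);
* `pipeline.DESK_CLINICAL` — Bowsher β = 4/n = 6, TV β = 1.0,
  RD β = 10/γ = 100 — selected once for the desk grid by the same
  procedure used for the full-scale set: reconstruct the β grids, plot
  bias-vs-noise (LV) and contrast-vs-noise (L1), and take each
  algorithm's parameter at the knee of its curve, where the algorithms
  sit in a common LV-noise band (≈0.45–0.7 kBq/cc at desk scale; on the
  desk grid the full-scale TV grid is inert — its gradient is two orders
  of magnitude below the sensitivity — which is why the desk TV weight
  is much larger).

The desk set is frozen; it is a study condition, not a tuning knob.

## 5. Evaluation conventions

* Region masks: the ground truth is block-averaged onto the
  reconstruction grid; a region voxel survives at ≥ 70 % of the region's
  true activity within the region's majority support.  Sample (n−1)
  standard deviations throughout; region means are taken per realization
  first.  CRC/CNR per-realization values share the ensemble background
  noise (noise is not estimable from one realization).
* RC/CRC guards: RC is refused for the zero-activity transmural lesion;
  CRC is undefined at zero true contrast.  Undefined entries are reported
  as NaN, never fabricated.
* Matched-model recovery is asserted against the *resampled truth* over
  the same mask (the self-consistency fixed point).  At 3 mm desk voxels
  the 70 % mask necessarily contains partial-volume boundary voxels, so
  recovery measured against the raw tissue value saturates near 0.94
  even for a perfect reconstruction, while Gibbs ringing inflates the
  interior; the resampled-truth comparison is the meaningful
  unbiasedness statement.
* Polar maps: the LV wall model is a surface of revolution from the
  analytic heart geometry (an image-driven delineation from a boolean LV
  mask is provided for real data; its mid-wall estimate carries the
  annulus-centroid outward bias ≈ t²/(12 r) and is unreliable at the
  solid apex tip).  Fixed 6 mm imposed thickness, quarter-voxel radial
  sampling, 36 longitudinal × 72 angular bins.  Segment numbering is the
  standard 17-segment layout for the basal/mid rings; the four apical
  sectors are numbered starting from the inferior wall (so the
  transmural apical-inferior lesion falls in segment 13), and the apical
  cap covers the lowest 25 % of the long axis.  This apical convention is
  fixed here and used everywhere.

## 6. Problem sizes

The default desk study uses a 96³ phantom at 2 mm, reconstruction on
64³ at 3 mm (axial rebinned to match), 84 angles, 10 noise realizations
— chosen so a full study runs in minutes on one CPU while keeping the
wall ≳3 voxels thick.  The full-scale configuration (0.8 mm phantom,
1.35 mm reconstruction, 168 angles, 20–25 realizations) exercises the
same code paths and is intended for cluster use.

## 7. Known limitations

* OSL is not a convergent MAP optimizer; its fixed points satisfy the
  stationarity condition of the penalised likelihood only inside the
  stable region (verified by the KKT balance test).
* The 2-D multi-slice parallel-beam geometry ignores oblique LORs, arc
  effects and detector gaps; conclusions about *relative* algorithm
  behaviour are the intended use, absolute scanner realism is not.
* Polar-map statements about lesion visibility are grid-dependent:
  block-averaging the truth to 3 mm partially fills the thin healthy
  layer outside L1, so the max-count "hiding" contract is asserted at
  native resolution.
* The paired t test treats per-realization CNR values that share an
  ensemble noise estimate; the test is exact for the contrast component
  only.
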