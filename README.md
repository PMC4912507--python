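# cardiacpvc

Simulation framework for studying **partial-volume correction (PVC) in
gated cardiac ¹⁸F-FDG PET**: can penalized (MAP) reconstruction — with
edge-preserving priors or with anatomical side information from CT/MR —
recover the activity of thin myocardial walls and small scars from a
low-count, dual-gated acquisition, and what happens when the anatomical
image is shifted, mismatched or has poor through-plane resolution?

The package is aimed at image-reconstruction researchers: it generates its
own ground truth (a parametric thorax phantom with two myocardial lesions),
simulates the acquisition analytically, reconstructs with a family of
algorithms, and quantifies lesion recovery and detectability.

## The model

The acquisition model is Poisson:

```
y ~ Poisson( a ⊙ P B f )
```

where `f` is the activity image (kBq/cc), `B` a shift-invariant Gaussian
camera PSF (FWHM 4.3 mm transaxial / 4.5 mm axial), `P` a parallel-beam
Joseph ray-tracing projector (exact sparse adjoint), and `a` the per-ray
attenuation survival factors `exp(−∫μ dl)` from the matched 511 keV μ-map.
A global scale calibrates the expected counts to the gate budget
(3.9 × 10⁶ counts for the 36 s gate of a 30 min scan split into 5
respiratory × 10 cardiac gates).

Reconstruction maximizes the penalized likelihood

```
f̂ = argmax [ L(f) − P(β, γ, f) ]
```

by OSEM (angle-interleaved subsets, scheme `3i42s + 2i24s + 2i1s`), with
optional resolution recovery (the PSF applied inside every forward/back
projection) and a one-step-late (OSL) update for the penalty:

* **RD** — relative difference, `β Σ w_jk (f_j−f_k)² / (f_j+f_k+γ|f_j−f_k|)`;
  `γ` controls edge preservation;
* **TV** — smoothed isotropic total variation;
* **Bowsher** — RD with `γ = 0` restricted per voxel to the `n` neighbours
  most similar in a co-registered anatomical image (MR shows the lesions,
  HRCT does not).

Evaluation follows the standard figures of merit — bias/noise in the LV,
recovery coefficient RC = r̄/r_true, contrast recovery
CRC = contrast_recon/contrast_true, contrast-to-noise CNR, a paired t test
at α = 0.01 — plus 17-segment bull's-eye (polar) maps with max-count and
mean-count wall sampling (the non-transmural lesion sits in segment 11, the
transmural one in segment 13).

## Worked example

```python
from cardiacpvc import (PhantomParams, build_phantom, region_masks)
from cardiacpvc.pipeline import StudyConfig, run_study

result = run_study(StudyConfig(n_realizations=10))
for name, rep in result["reports"].items():
    t = rep.table
    print(f"{name:18s} CNR(L1)={t.loc['L1','cnr']:6.2f} "
          f"CRC(L1)={t.loc['L1','crc']:.3f} noise={t.attrs['noise_lv']:.3f}")
```

prints (desk-scale study: 96³ phantom at 2 mm, 64³ reconstruction at 3 mm,
84 angles, 10 noise realizations, ~3 min on one CPU):

```
osem3d_rr_post5    CNR(L1)=  7.28 CRC(L1)=0.584 noise=0.672
map_tv             CNR(L1)=  8.79 CRC(L1)=0.643 noise=0.659
map_rd             CNR(L1)=  8.67 CRC(L1)=0.668 noise=0.703
bowsher_mr_perf    CNR(L1)= 18.95 CRC(L1)=0.922 noise=0.470
bowsher_mr_shift4  CNR(L1)= 11.79 CRC(L1)=0.612 noise=0.455
bowsher_mr_shift6  CNR(L1)=  9.69 CRC(L1)=0.511 noise=0.455
```

Reading: with a perfectly aligned, lesion-bearing MR as side information
the Bowsher prior recovers 92 % of the non-transmural lesion's contrast at
the lowest LV noise — clearly ahead of the best non-anatomical prior (TV)
and of smoothed resolution-recovery OSEM.  Shifting the same MR by 4–6 mm
destroys that advantage: the lesion CRC falls *below* TV's, which is why
anatomy-guided PVC demands ≲2 mm registration accuracy.

A command-line interface mirrors the library
(`cardiacpvc generate | project | reconstruct | evaluate | polarmap |
run-study`); volumes are exchanged as NIfTI-1.

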