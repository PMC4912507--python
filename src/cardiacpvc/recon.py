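"""Iterative emission reconstruction.

Implements ordered-subsets expectation maximisation (OSEM) with optional
image-space resolution recovery (RR: the camera PSF is applied before each
forward projection and after each back projection), and penalised
reconstruction via a one-step-late (OSL) modification of the OSEM update:
the prior gradient, evaluated at the current image, is added to the subset
sensitivity in the denominator.  With a zero prior weight the OSL update is
bitwise identical to OSEM.

The forward model for measured counts is ``ybar = a * P (B f)`` with ``P``
the line-integral projector, ``a`` the per-ray survival factors and ``B``
the (self-adjoint) Gaussian PSF; attenuation correction therefore uses the
same factors as the simulation.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np

from .image import Image
from .priors import NeighbourGraph, PriorSpec, penalty_gradient
from .projector import (PsfModel, Sinogram, _blur_array, gaussian_blur,
                        get_projector)

FULL_SCHEME = ((3, 42), (2, 24), (2, 1))
DESK_SCHEME = ((3, 12), (2, 6), (2, 1))

#: one-step-late stabilisation: the OSL denominator is clipped below at this
#: fraction of the subset sensitivity, bounding the multiplicative boost a
#: strongly negative prior gradient can apply in one subset update
OSL_FLOOR = 0.5


def parse_scheme(text: str) -> tuple[tuple[int, int], ...]:
    """Parse an iteration scheme such as ``"3i42s,2i24s,2i1s"``."""
    stages = []
    for part in text.replace(" ", "").split(","):
        m = re.fullmatch(r"(\d+)i(\d+)s", part)
        if not m:
            raise ValueError(f"cannot parse scheme stage {part!r}")
        stages.append((int(m.group(1)), int(m.group(2))))
    return tuple(stages)


@dataclass
class ReconSpec:
    """Reconstruction recipe: grid, iteration scheme, RR, prior, smoothing."""
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_mm: float | tuple[float, float, float] = 1.35
    scheme: tuple[tuple[int, int], ...] = FULL_SCHEME
    rr: bool = False
    psf: PsfModel | None = None
    prior: PriorSpec | None = None
    post_fwhm_mm: float | None = None
    initial_value: float | None = None  # None -> scaled to the measured counts

    def __post_init__(self) -> None:
        vm = np.atleast_1d(self.voxel_mm).astype(float)
        self.voxel_mm = tuple(vm) * 3 if vm.size == 1 else tuple(vm)  # type: ignore
        if any(v <= 0 for v in self.voxel_mm):
            raise ValueError("output voxel size must be positive")
        if self.rr and self.psf is None:
            raise ValueError("resolution recovery requires a PSF model")


def _bit_reversed_order(n: int) -> list[int]:
    """Balanced subset processing order (bit-reversed permutation)."""
    if n == 1:
        return [0]
    width = max(1, math.ceil(math.log2(n)))
    order = []
    for i in range(2 ** width):
        r = int(format(i, f"0{width}b")[::-1], 2)
        if r < n:
            order.append(r)
    return order


def _iterate(data: Sinogram, acf: Sinogram, spec: ReconSpec,
             graph: NeighbourGraph | None) -> Image:
    geom = data.geometry
    if acf.geometry != geom:
        raise ValueError("data and attenuation sinograms have different geometry")
    for (_, n_sub) in spec.scheme:
        if geom.n_angles % n_sub:
            raise ValueError(f"{n_sub} subsets do not divide {geom.n_angles} angles")
    proj = get_projector(geom, spec.grid_shape[:2], spec.voxel_mm[:2])
    y = np.asarray(data.values, dtype=np.float64)
    a = np.asarray(acf.values, dtype=np.float64)
    if y.shape != a.shape:
        raise ValueError("data and attenuation sinogram shapes differ")
    nz = y.shape[2]
    if spec.grid_shape[2] != nz:
        raise ValueError("grid axial extent must match the sinogram slice count")
    psf = spec.psf if spec.rr else None
    vm = spec.voxel_mm
    delta = 1e-12 * max(float(y.max()), 1.0)

    def fwd(vol, ns, s):
        return proj.forward_subset(_blur_array(vol, psf, vm), ns, s)

    def bwd(rays, ns, s):
        return _blur_array(proj.back_subset(rays, ns, s), psf, vm)

    B = geom.n_radial

    def subset_data(arr, ns, s):
        ang = proj.subset_angles(ns, s)
        return arr[ang].reshape(len(ang) * B, nz)

    # per-(n_subsets, subset) sensitivity images
    sens_cache: dict[tuple[int, int], np.ndarray] = {}

    def sensitivity(ns, s):
        key = (ns, s)
        if key not in sens_cache:
            sens_cache[key] = bwd(subset_data(a, ns, s), ns, s)
        return sens_cache[key]

    # initial image: uniform, scaled so the model total matches the data total
    if spec.initial_value is not None:
        f = np.full(spec.grid_shape, float(spec.initial_value))
    else:
        ones = np.ones(spec.grid_shape)
        model_total = float((a * proj.forward(_blur_array(ones, psf, vm))).sum())
        scale = float(y.sum()) / model_total if model_total > 0 else 1.0
        f = np.full(spec.grid_shape, max(scale, delta))

    sens_full = sensitivity(1, 0)
    support = sens_full > 1e-10 * float(sens_full.max())
    f = np.where(support, f, 0.0)

    for (n_iter, n_sub) in spec.scheme:
        order = _bit_reversed_order(n_sub)
        for _ in range(n_iter):
            for s in order:
                ybar = a.reshape(-1, nz)[proj.subset_rows(n_sub, s)] * fwd(f, n_sub, s)
                ratio = subset_data(y, n_sub, s) / (ybar + delta)
                corr = bwd(subset_data(a, n_sub, s) * ratio, n_sub, s)
                denom = sensitivity(n_sub, s)
                if spec.prior is not None and spec.prior.beta != 0.0:
                    g = penalty_gradient(Image(f, vm), spec.prior, graph).data
                    # OSL denominator, clipped below at a fraction of the
                    # sensitivity: keeps every update positive and bounds the
                    # per-subset boost where the gradient is strongly negative
                    # (a no-op for beta = 0)
                    denom = np.maximum(denom + g / n_sub, OSL_FLOOR * denom)
                f = np.where(support, f * corr / np.maximum(denom, 1e-300), 0.0)
                np.maximum(f, 0.0, out=f)
    # undo the acquisition count calibration to report activity units
    out = Image(f / data.calibration, vm, "kBq/cc")
    if spec.post_fwhm_mm:
        out = post_smooth(out, spec.post_fwhm_mm)
    return out


def osem(data: Sinogram, acf: Sinogram, spec: ReconSpec) -> Image:
    """Ordered-subsets EM reconstruction (optionally with RR and smoothing).

    The multiplicative update per subset is
    ``f <- f * Bt Pt_s (a_s y_s / (a_s P_s B f + delta)) / (Bt Pt_s a_s)``
    with angle-interleaved subsets processed in bit-reversed order.
    """
    base = ReconSpec(**{**spec.__dict__, "prior": None})
    return _iterate(data, acf, base, None)


def map_osem(data: Sinogram, acf: Sinogram, spec: ReconSpec,
             graph: NeighbourGraph | None = None) -> Image:
    """Penalised OSEM via the one-step-late update.

    The subset denominator becomes ``sens_s + (1/n_subsets) dP/df`` evaluated
    at the current image and clipped below at a small positive floor.  A
    Bowsher prior requires the anatomical neighbour graph.
    """
    if spec.prior is None:
        raise ValueError("map_osem requires a prior; use osem otherwise")
    if spec.prior.kind == "BOWSHER" and graph is None:
        raise ValueError("Bowsher prior requires a neighbour graph")
    return _iterate(data, acf, spec, graph)


def post_smooth(img: Image, fwhm_mm: float) -> Image:
    """Spatially-invariant isotropic Gaussian post-smoothing."""
    if fwhm_mm == 0:
        return img.copy()
    return gaussian_blur(img, PsfModel(fwhm_mm, fwhm_mm))


def poisson_loglik(data: Sinogram, acf: Sinogram, img: Image,
                   psf: PsfModel | None = None) -> float:
    """Poisson log-likelihood (up to the data-only constant) of an image."""
    proj = get_projector(data.geometry, img.shape[:2], img.voxel_mm[:2])
    ybar = np.asarray(acf.values) * proj.forward(_blur_array(
        np.asarray(img.data, dtype=np.float64), psf, img.voxel_mm))
    y = np.asarray(data.values)
    delta = 1e-12 * max(float(y.max()), 1.0)
    return float((y * np.log(ybar + delta) - ybar).sum())
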