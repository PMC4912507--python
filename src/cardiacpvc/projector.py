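"""Analytic PET acquisition model.

Parallel-beam, multi-slice (2-D per axial slice) line-integral projector
built with Joseph's interpolation method.  The projector is assembled once
as a sparse matrix per (geometry, grid) pair, so the forward/back projection
pair is exactly adjoint by construction and both operations reduce to sparse
mat-vec products vectorised over slices.

Sinogram axis order is (angle, radial bin, slice).  Line integrals carry
units of value * mm; attenuation coefficients are supplied in cm^-1 and
converted internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, sparse

from .image import Image


@dataclass(frozen=True)
class SinogramGeometry:
    """Parallel-beam sampling over 180 degrees."""
    n_angles: int = 168
    n_radial: int = 136
    radial_mm: float = 2.0

    def __post_init__(self) -> None:
        if self.n_angles < 1 or self.n_radial < 1 or self.radial_mm <= 0:
            raise ValueError("invalid sinogram geometry")

    @property
    def angles(self) -> np.ndarray:
        return np.pi * np.arange(self.n_angles) / self.n_angles

    @property
    def radial_coords(self) -> np.ndarray:
        return (np.arange(self.n_radial) - (self.n_radial - 1) / 2.0) * self.radial_mm

    @property
    def fov_mm(self) -> float:
        return self.n_radial * self.radial_mm

    @classmethod
    def covering(cls, img: Image, n_angles: int = 168, radial_mm: float = 2.0,
                 pad_mm: float = 4.0) -> "SinogramGeometry":
        """Geometry whose radial extent covers the image's in-plane diagonal."""
        diag = math.hypot(img.shape[0] * img.voxel_mm[0],
                          img.shape[1] * img.voxel_mm[1])
        n_rad = int(math.ceil((diag + 2 * pad_mm) / radial_mm))
        return cls(n_angles, n_rad, radial_mm)


@dataclass
class Sinogram:
    """Projection-space array with geometry metadata.

    ``kind`` tags the role of the values: ``line_integrals``,
    ``expected_counts``, ``counts`` or ``attenuation_factors``.
    """
    geometry: SinogramGeometry
    values: np.ndarray  # (n_angles, n_radial, n_slices)
    kind: str = "line_integrals"
    units: str = "a.u."
    #: counts per (activity * mm): the global scale applied by the count
    #: calibration; reconstructions are divided by it to recover activity units
    calibration: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim == 2:
            self.values = self.values[..., None]
        expected = (self.geometry.n_angles, self.geometry.n_radial)
        if self.values.shape[:2] != expected:
            raise ValueError(
                f"sinogram shape {self.values.shape[:2]} does not match geometry {expected}")
        if self.kind == "attenuation_factors":
            if np.any(self.values <= 0) or np.any(self.values > 1 + 1e-12):
                raise ValueError("attenuation (survival) factors must lie in (0, 1]")

    def copy(self, values: np.ndarray | None = None, kind: str | None = None) -> "Sinogram":
        return Sinogram(self.geometry,
                        self.values.copy() if values is None else values,
                        kind or self.kind, self.units)


@dataclass(frozen=True)
class PsfModel:
    """Shift-invariant Gaussian camera resolution (FWHM in mm)."""
    fwhm_transaxial_mm: float = 4.3
    fwhm_axial_mm: float = 4.5

    def __post_init__(self) -> None:
        if self.fwhm_transaxial_mm < 0 or self.fwhm_axial_mm < 0:
            raise ValueError("FWHM must be non-negative")


def fwhm_to_sigma(fwhm_mm: float) -> float:
    """Gaussian sigma for a given full width at half maximum."""
    if fwhm_mm < 0:
        raise ValueError("FWHM must be non-negative")
    return fwhm_mm / math.sqrt(8.0 * math.log(2.0))


def gaussian_blur(img: Image, psf: PsfModel) -> Image:
    """Separable Gaussian convolution, per-axis sigma from the PSF FWHMs.

    Zero padding at the boundary; the phantom support is interior to the
    field of view, so the total sum is conserved in practice.
    """
    sigmas_mm = (fwhm_to_sigma(psf.fwhm_transaxial_mm),
                 fwhm_to_sigma(psf.fwhm_transaxial_mm),
                 fwhm_to_sigma(psf.fwhm_axial_mm))
    sigmas_vox = [s / v for s, v in zip(sigmas_mm, img.voxel_mm)]
    if max(sigmas_vox) == 0:
        return img.copy()
    data = ndimage.gaussian_filter(img.data.astype(np.float64), sigmas_vox,
                                   mode="constant", cval=0.0, truncate=5.0)
    return Image(data, img.voxel_mm, img.units)


def _blur_array(data: np.ndarray, psf: PsfModel | None,
                voxel_mm: tuple[float, float, float]) -> np.ndarray:
    if psf is None:
        return data
    sigmas = [fwhm_to_sigma(f) / v for f, v in
              zip((psf.fwhm_transaxial_mm, psf.fwhm_transaxial_mm, psf.fwhm_axial_mm),
                  voxel_mm)]
    if max(sigmas) == 0:
        return data
    return ndimage.gaussian_filter(data, sigmas, mode="constant", cval=0.0,
                                   truncate=5.0)


# --------------------------------------------------------------- projector

class Projector:
    """Sparse Joseph-method projector for a fixed geometry and image grid.

    The system matrix maps an (nx, ny) slice to an (n_angles * n_radial) ray
    vector; 3-D volumes are handled by applying it to all slices at once.
    Back projection uses the exact transpose.
    """

    def __init__(self, geom: SinogramGeometry, grid_shape: tuple[int, int],
                 voxel_mm: tuple[float, float]):
        self.geom = geom
        self.grid_shape = tuple(int(n) for n in grid_shape)
        self.voxel_mm = (float(voxel_mm[0]), float(voxel_mm[1]))
        self.matrix = self._build().tocsr()
        self._subset_cache: dict[tuple[int, int], sparse.csr_matrix] = {}

    def _build(self) -> sparse.coo_matrix:
        nx, ny = self.grid_shape
        vx, vy = self.voxel_mm
        xc = (np.arange(nx) - (nx - 1) / 2.0) * vx
        yc = (np.arange(ny) - (ny - 1) / 2.0) * vy
        s = self.geom.radial_coords
        B = self.geom.n_radial
        rows_all, cols_all, vals_all = [], [], []
        for ia, phi in enumerate(self.geom.angles):
            d = np.array([math.cos(phi), math.sin(phi)])   # ray direction
            nvec = np.array([-math.sin(phi), math.cos(phi)])  # radial normal
            if abs(d[0]) >= abs(d[1]):
                # march along x; interpolate in y
                step = vx / abs(d[0])
                # y(s, xi) = s*n_y + ((xi - s*n_x)/d_x) * d_y
                t = (xc[None, :] - s[:, None] * nvec[0]) / d[0]
                ycont = s[:, None] * nvec[1] + t * d[1]
                idx = (ycont - yc[0]) / vy
                j0 = np.floor(idx).astype(np.int64)
                frac = idx - j0
                bb, ii = np.meshgrid(np.arange(B), np.arange(nx), indexing="ij")
                for joff, w in ((0, 1.0 - frac), (1, frac)):
                    jj = j0 + joff
                    ok = (jj >= 0) & (jj < ny) & (w > 0)
                    rows_all.append(ia * B + bb[ok])
                    cols_all.append(ii[ok] * ny + jj[ok])
                    vals_all.append(w[ok] * step)
            else:
                # march along y; interpolate in x
                step = vy / abs(d[1])
                t = (yc[None, :] - s[:, None] * nvec[1]) / d[1]
                xcont = s[:, None] * nvec[0] + t * d[0]
                idx = (xcont - xc[0]) / vx
                i0 = np.floor(idx).astype(np.int64)
                frac = idx - i0
                bb, jj = np.meshgrid(np.arange(B), np.arange(ny), indexing="ij")
                for ioff, w in ((0, 1.0 - frac), (1, frac)):
                    ii = i0 + ioff
                    ok = (ii >= 0) & (ii < nx) & (w > 0)
                    rows_all.append(ia * B + bb[ok])
                    cols_all.append(ii[ok] * ny + jj[ok])
                    vals_all.append(w[ok] * step)
        rows = np.concatenate(rows_all)
        cols = np.concatenate(cols_all)
        vals = np.concatenate(vals_all)
        n_rays = self.geom.n_angles * B
        return sparse.coo_matrix((vals, (rows, cols)),
                                 shape=(n_rays, nx * ny))

    # ------------------------------------------------------------- actions
    def forward(self, volume: np.ndarray) -> np.ndarray:
        """(nx, ny, nz) volume -> (n_angles, n_radial, nz) line integrals."""
        nx, ny = self.grid_shape
        nz = volume.shape[2]
        flat = volume.reshape(nx * ny, nz)
        sino = self.matrix @ flat
        return sino.reshape(self.geom.n_angles, self.geom.n_radial, nz)

    def back(self, sino: np.ndarray) -> np.ndarray:
        """Exact adjoint of :meth:`forward`."""
        nz = sino.shape[2]
        flat = sino.reshape(-1, nz)
        vol = self.matrix.T @ flat
        return vol.reshape(self.grid_shape[0], self.grid_shape[1], nz)

    # subset support: angle interleaving
    def subset_angles(self, n_subsets: int, subset: int) -> np.ndarray:
        if self.geom.n_angles % n_subsets:
            raise ValueError(
                f"{n_subsets} subsets do not divide {self.geom.n_angles} angles")
        return np.arange(subset, self.geom.n_angles, n_subsets)

    def subset_rows(self, n_subsets: int, subset: int) -> np.ndarray:
        B = self.geom.n_radial
        ang = self.subset_angles(n_subsets, subset)
        return (ang[:, None] * B + np.arange(B)[None, :]).ravel()

    def subset_matrix(self, n_subsets: int, subset: int) -> sparse.csr_matrix:
        key = (n_subsets, subset)
        if key not in self._subset_cache:
            self._subset_cache[key] = self.matrix[self.subset_rows(*key)]
        return self._subset_cache[key]

    def forward_subset(self, volume: np.ndarray, n_subsets: int, subset: int) -> np.ndarray:
        nx, ny = self.grid_shape
        return self.subset_matrix(n_subsets, subset) @ volume.reshape(nx * ny, -1)

    def back_subset(self, rays: np.ndarray, n_subsets: int, subset: int) -> np.ndarray:
        nx, ny = self.grid_shape
        out = self.subset_matrix(n_subsets, subset).T @ rays
        return out.reshape(nx, ny, -1)


_PROJECTOR_CACHE: dict[tuple, Projector] = {}


def get_projector(geom: SinogramGeometry, grid_shape: tuple[int, int],
                  voxel_mm: tuple[float, float]) -> Projector:
    key = (geom, grid_shape, tuple(float(v) for v in voxel_mm))
    if key not in _PROJECTOR_CACHE:
        _PROJECTOR_CACHE[key] = Projector(geom, grid_shape, voxel_mm)
    return _PROJECTOR_CACHE[key]


def _check_support(img: Image, geom: SinogramGeometry) -> None:
    nz = np.nonzero(np.any(img.data != 0, axis=2))
    if len(nz[0]) == 0:
        return
    xc = img.axis_coords(0)[nz[0]]
    yc = img.axis_coords(1)[nz[1]]
    r = np.sqrt(xc ** 2 + yc ** 2).max()
    s_max = abs(geom.radial_coords).max() + geom.radial_mm / 2.0
    if r > s_max:
        raise ValueError(
            f"image support (radius {r:.1f} mm) exceeds the sinogram field of "
            f"view ({s_max:.1f} mm)")


def forward_project(img: Image, geom: SinogramGeometry) -> Sinogram:
    """Parallel-beam line integrals (value * mm) of a volume."""
    _check_support(img, geom)
    proj = get_projector(geom, img.shape[:2], img.voxel_mm[:2])
    return Sinogram(geom, proj.forward(np.asarray(img.data, dtype=np.float64)),
                    "line_integrals", f"{img.units}*mm")


def back_project(sino: Sinogram, grid_shape: tuple[int, int, int],
                 voxel_mm: tuple[float, float, float]) -> Image:
    """Adjoint of :func:`forward_project` onto the stated grid."""
    proj = get_projector(sino.geometry, grid_shape[:2], voxel_mm[:2])
    return Image(proj.back(np.asarray(sino.values, dtype=np.float64)), voxel_mm)


def attenuation_factors(mu_map: Image, geom: SinogramGeometry) -> Sinogram:
    """Per-ray photon survival factors exp(-integral of mu dl).

    ``mu_map`` is in cm^-1; path lengths are in mm.  The attenuation
    *correction* factor used elsewhere is the reciprocal of these values.
    """
    if np.any(mu_map.data < 0):
        raise ValueError("attenuation coefficients must be non-negative")
    line_int = forward_project(mu_map, geom).values  # (cm^-1) * mm
    return Sinogram(geom, np.exp(-line_int / 10.0), "attenuation_factors", "1")


def simulate_acquisition(activity: Image, mu: Image, geom: SinogramGeometry,
                         psf: PsfModel | None, total_counts: float) -> Sinogram:
    """Noise-free expected-counts sinogram.

    The camera resolution is applied in image space before projection, the
    survival factors multiply the projections, and a global scale calibrates
    the total expected counts to ``total_counts`` (so the output is invariant
    to the absolute activity scale).
    """
    if total_counts <= 0:
        raise ValueError("total_counts must be positive")
    blurred = gaussian_blur(activity, psf) if psf is not None else activity
    proj = forward_project(blurred, geom).values
    af = attenuation_factors(mu, geom).values
    expected = af * proj
    total = expected.sum()
    if total <= 0:
        raise ValueError("zero total expected signal; nothing to calibrate")
    scale = total_counts / total
    return Sinogram(geom, expected * scale, "expected_counts", "counts",
                    calibration=scale)


def poisson_realizations(expected: Sinogram, n: int, seed: int = 0) -> list[Sinogram]:
    """Independent seeded Poisson realizations of an expected-counts sinogram."""
    if np.any(expected.values < 0):
        raise ValueError("expected counts must be non-negative")
    out = []
    for i in range(n):
        rng = np.random.default_rng([int(seed) & 0x7FFFFFFF, i])
        draw = rng.poisson(expected.values).astype(np.float64)
        out.append(Sinogram(expected.geometry, draw, "counts", "counts",
                            calibration=expected.calibration))
    return out


@dataclass(frozen=True)
class GateBudget:
    """Acquisition time and count budget of one gate."""
    seconds: float
    count_scale: float          # counts relative to the dual-gated budget
    average_respiratory_states: bool  # expected data = mean over breathing states


def gate_budget(scan_minutes: float, n_resp: int, n_card: int,
                mode: str = "DUAL") -> GateBudget:
    """Per-gate scan time under the three gating strategies.

    DUAL: one cardiac x respiratory gate.  ECG: one cardiac gate, breathing
    uncorrected (counts from all respiratory states are combined, so the
    expected sinogram must average the respiratory-state sinograms).  ECG+R:
    one cardiac gate after ideal respiratory motion compensation (reference
    state only, same count budget as ECG).
    """
    if scan_minutes <= 0 or n_resp < 1 or n_card < 1:
        raise ValueError("scan time and gate counts must be positive")
    mode = mode.upper().replace("-", "+")
    dual_s = scan_minutes * 60.0 / (n_resp * n_card)
    if mode == "DUAL":
        return GateBudget(dual_s, 1.0, False)
    if mode == "ECG":
        return GateBudget(scan_minutes * 60.0 / n_card, float(n_resp), True)
    if mode == "ECG+R":
        return GateBudget(scan_minutes * 60.0 / n_card, float(n_resp), False)
    raise ValueError(f"unknown gating mode {mode!r}")
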