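"""Voxel-grid image container and resampling utilities.

All volumes in this package are regular voxel grids with a physical voxel
size in millimetres.  Array axes are ordered (x, y, z); the third axis is
the cranio-caudal (slice) direction.  Values carry activity (kBq/cc),
attenuation (cm^-1) or anatomical intensity (a.u.) depending on context.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import nibabel as nib
import numpy as np


@dataclass
class Image:
    """A 3-D volume on a regular grid.

    Parameters
    ----------
    data:
        3-D float array, axis order (x, y, z).
    voxel_mm:
        Physical voxel size per axis in millimetres.
    units:
        Free-text unit tag (``kBq/cc``, ``cm^-1``, ``HU``, ``a.u.``).
    """

    data: np.ndarray
    voxel_mm: tuple[float, float, float]
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Image data must be 3-D, got shape {self.data.shape}")
        vm = tuple(float(v) for v in np.atleast_1d(self.voxel_mm).ravel()) \
            if np.ndim(self.voxel_mm) else (float(self.voxel_mm),) * 3
        if len(vm) == 1:
            vm = vm * 3
        if any(v <= 0 for v in vm):
            raise ValueError("voxel size must be positive")
        self.voxel_mm = vm  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in millilitres (1 ml = 1000 mm^3)."""
        return float(np.prod(self.voxel_mm)) / 1000.0

    def copy(self, data: np.ndarray | None = None) -> "Image":
        return replace(self, data=self.data.copy() if data is None else data)

    def same_grid(self, other: "Image") -> bool:
        return self.shape == other.shape and np.allclose(self.voxel_mm, other.voxel_mm)

    # physical coordinates of voxel centres, grid centre at the origin
    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.shape[axis]
        return (np.arange(n) - (n - 1) / 2.0) * self.voxel_mm[axis]

    def coord_grids(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return np.meshgrid(
            self.axis_coords(0), self.axis_coords(1), self.axis_coords(2),
            indexing="ij",
        )

    # ------------------------------------------------------------------ I/O
    def to_nifti(self, path: str) -> None:
        affine = np.diag(list(self.voxel_mm) + [1.0])
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), path)

    @classmethod
    def from_nifti(cls, path: str, units: str = "a.u.") -> "Image":
        img = nib.load(path)
        vox = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), vox, units)


def block_average(img: Image, out_voxel_mm: float | tuple[float, float, float],
                  out_shape: tuple[int, int, int] | None = None) -> Image:
    """Volume-weighted resampling onto a coarser grid.

    Each output voxel value is the mean of the input values over the output
    voxel's physical extent (overlap-weighted), so region means and total
    activity are preserved.  Both grids are centred on the same origin.
    """
    out_vm = np.broadcast_to(np.atleast_1d(out_voxel_mm).astype(float), (3,))
    if out_shape is None:
        out_shape = tuple(
            max(1, int(np.floor(img.shape[a] * img.voxel_mm[a] / out_vm[a])))
            for a in range(3)
        )
    # separable 1-D overlap matrices: out = W2 (W1 (W0 x))
    data = img.data.astype(np.float64)
    for axis in range(3):
        w = _overlap_matrix(img.shape[axis], img.voxel_mm[axis],
                            out_shape[axis], out_vm[axis])
        data = np.moveaxis(np.tensordot(w, np.moveaxis(data, axis, 0), axes=(1, 0)),
                           0, axis)
    return Image(data, tuple(out_vm), img.units)


def _overlap_matrix(n_in: int, d_in: float, n_out: int, d_out: float) -> np.ndarray:
    """1-D overlap-fraction matrix (n_out x n_in), rows normalised by d_out."""
    in_edges = (np.arange(n_in + 1) - n_in / 2.0) * d_in
    out_edges = (np.arange(n_out + 1) - n_out / 2.0) * d_out
    lo = np.maximum.outer(out_edges[:-1], in_edges[:-1])
    hi = np.minimum.outer(out_edges[1:], in_edges[1:])
    return np.clip(hi - lo, 0.0, None) / d_out
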