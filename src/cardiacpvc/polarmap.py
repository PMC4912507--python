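"""LV wall sampling and 17-segment bull's-eye quantification.

The LV wall is modelled as a mid-wall surface of revolution around the long
axis (the package's +z), with endocardial/epicardial bounds offset by half
of an imposed fixed thickness.  Wall values are sampled radially per
(longitudinal position, wall angle) bin with the maximum or the mean across
the wall, then averaged per segment of the standard nuclear-medicine
17-segment layout (6 basal, 6 mid, 4 apical, 1 apical cap).

Wall angle convention: 0 deg at the anterior wall (+y), increasing towards
the lateral wall (+x).  Basal/mid sectors follow the standard numbering
(segment 11 = mid inferolateral, the site of the non-transmural lesion).
The four apical sectors are numbered starting from the inferior wall
(segment 13 = apical inferior, the site of the transmural lesion); this
apical ordering is a package convention, fixed here and used everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .image import Image
from .phantom import HeartGeometry

L1_SEGMENT = 11
L2_SEGMENT = 13
APEX_CAP_FRACTION = 0.25  # longitudinal fraction assigned to segment 17

_BASAL = (1, 6, 5, 4, 3, 2)   # 60-deg wedges from anterior towards lateral
_MID = (7, 12, 11, 10, 9, 8)
_APICAL = (15, 14, 13, 16)    # 90-deg wedges: anterior, lateral, inferior, septal


@dataclass
class WallModel:
    """Delineated LV wall: mid-wall radius per (longitudinal, angular) bin."""
    axis_xy: tuple[float, float]
    apex_z: float
    base_z: float
    mid_radius: np.ndarray      # (n_long, n_theta), mm
    thickness_mm: float

    @property
    def n_long(self) -> int:
        return self.mid_radius.shape[0]

    @property
    def n_theta(self) -> int:
        return self.mid_radius.shape[1]

    @property
    def endo_radius(self) -> np.ndarray:
        return np.maximum(self.mid_radius - self.thickness_mm / 2.0, 0.0)

    @property
    def epi_radius(self) -> np.ndarray:
        return self.mid_radius + self.thickness_mm / 2.0


@dataclass
class PolarMap:
    """Bull's-eye raster plus its 17 segment means."""
    raster: np.ndarray          # (n_long, n_theta)
    mode: str                   # max | mean
    segment_means: np.ndarray   # (17,), index s-1 for segment s
    segment_map: np.ndarray     # (n_long, n_theta) int, values 1..17


def delineate_lv(source, thickness_mm: float = 6.0,
                 geometry: HeartGeometry | None = None,
                 n_long: int = 36, n_theta: int = 72) -> WallModel:
    """Delineate the LV wall with an imposed fixed thickness.

    With an analytic :class:`~cardiacpvc.phantom.HeartGeometry` the mid-wall
    surface is computed in closed form.  Otherwise ``source`` must be a
    boolean LV mask :class:`Image` (e.g. the LV label of an anatomy-driven
    reconstruction); the mid-wall radius per bin is the mean radius of the
    mask voxels falling in that bin, with empty bins filled from the ring
    mean of their longitudinal row.
    """
    if geometry is not None:
        cx, cy, cz = geometry.centre
        a_m = (geometry.endo_semi[0] + geometry.epi_semi[0]) / 2.0
        c_m = (geometry.endo_semi[1] + geometry.epi_semi[1]) / 2.0
        apex_z, base_z = geometry.apex_z, geometry.base_z
        l = (np.arange(n_long) + 0.5) / n_long
        z = apex_z + l * (base_z - apex_z)
        dz = z - base_z
        arg = np.clip(1.0 - (dz / c_m) ** 2, 0.0, None)
        r = a_m * np.sqrt(arg)
        r[np.abs(dz) > c_m] = 0.0  # below the mid-wall apex: solid tip
        mid = np.repeat(r[:, None], n_theta, axis=1)
        return WallModel((cx, cy), apex_z, base_z, mid, thickness_mm)

    mask_img: Image = source
    mask = np.asarray(mask_img.data, dtype=bool)
    if not mask.any():
        raise ValueError("empty LV mask: cannot delineate")
    ix, iy, iz = np.nonzero(mask)
    xs = mask_img.axis_coords(0)[ix]
    ys = mask_img.axis_coords(1)[iy]
    zs = mask_img.axis_coords(2)[iz]
    cx, cy = xs.mean(), ys.mean()
    vz = mask_img.voxel_mm[2]
    apex_z, base_z = zs.min() - vz / 2.0, zs.max() + vz / 2.0
    l = np.clip((zs - apex_z) / (base_z - apex_z), 0.0, 1.0 - 1e-9)
    theta = np.degrees(np.arctan2(xs - cx, ys - cy)) % 360.0
    il = (l * n_long).astype(int)
    it = (theta / 360.0 * n_theta).astype(int)
    r = np.hypot(xs - cx, ys - cy)
    sums = np.zeros((n_long, n_theta))
    counts = np.zeros((n_long, n_theta))
    np.add.at(sums, (il, it), r)
    np.add.at(counts, (il, it), 1.0)
    with np.errstate(invalid="ignore"):
        mid = sums / counts
    # fill empty angular bins from the longitudinal ring mean (0 near the tip)
    row_mean = np.where(counts.sum(axis=1) > 0,
                        sums.sum(axis=1) / np.maximum(counts.sum(axis=1), 1), 0.0)
    empty = counts == 0
    mid[empty] = np.repeat(row_mean[:, None], n_theta, axis=1)[empty]
    return WallModel((float(cx), float(cy)), float(apex_z), float(base_z),
                     mid, thickness_mm)


def wall_samples(img: Image, wall: WallModel, mode: str = "mean",
                 radial_step_mm: float | None = None) -> np.ndarray:
    """Polar raster: per-bin max or mean of the image across the wall.

    Samples are taken along the radial ray of each (longitudinal, angular)
    bin between the endocardial and epicardial bounds, with trilinear
    interpolation at quarter-voxel steps.
    """
    if mode not in ("max", "mean"):
        raise ValueError("mode must be 'max' or 'mean'")
    step = radial_step_mm or min(img.voxel_mm) / 4.0
    n_r = max(2, int(np.ceil(wall.thickness_mm / step)) + 1)
    frac = np.linspace(0.0, 1.0, n_r)

    l = (np.arange(wall.n_long) + 0.5) / wall.n_long
    z = wall.apex_z + l * (wall.base_z - wall.apex_z)
    theta = np.radians((np.arange(wall.n_theta) + 0.5) / wall.n_theta * 360.0)

    endo = wall.endo_radius[..., None]
    epi = wall.epi_radius[..., None]
    r = endo + (epi - endo) * frac  # (n_long, n_theta, n_r)
    x = wall.axis_xy[0] + r * np.sin(theta)[None, :, None]
    y = wall.axis_xy[1] + r * np.cos(theta)[None, :, None]
    zz = np.broadcast_to(z[:, None, None], r.shape)

    coords = np.stack([
        x / img.voxel_mm[0] + (img.shape[0] - 1) / 2.0,
        y / img.voxel_mm[1] + (img.shape[1] - 1) / 2.0,
        zz / img.voxel_mm[2] + (img.shape[2] - 1) / 2.0,
    ])
    samples = ndimage.map_coordinates(
        np.asarray(img.data, dtype=np.float64), coords.reshape(3, -1),
        order=1, mode="constant", cval=0.0).reshape(r.shape)
    return samples.max(axis=2) if mode == "max" else samples.mean(axis=2)


def segment_of(l_frac: np.ndarray, theta_deg: np.ndarray) -> np.ndarray:
    """Segment number (1..17) for normalised longitudinal position and angle."""
    l_frac = np.asarray(l_frac, dtype=np.float64)
    theta_deg = np.asarray(theta_deg, dtype=np.float64) % 360.0
    k6 = (((theta_deg + 30.0) % 360.0) // 60.0).astype(int)
    k4 = (((theta_deg + 45.0) % 360.0) // 90.0).astype(int)
    seg = np.where(l_frac >= 2.0 / 3.0, np.take(_BASAL, k6),
                   np.where(l_frac >= 1.0 / 3.0, np.take(_MID, k6),
                            np.where(l_frac >= APEX_CAP_FRACTION,
                                     np.take(_APICAL, k4), 17)))
    return seg


def to_17_segments(raster: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-segment means of a polar raster.

    Returns ``(segment_means, segment_map)`` where ``segment_means[s-1]`` is
    the mean raster value of segment ``s`` and ``segment_map`` assigns every
    raster pixel to exactly one segment.
    """
    raster = np.asarray(raster, dtype=np.float64)
    n_long, n_theta = raster.shape
    l = np.repeat(((np.arange(n_long) + 0.5) / n_long)[:, None], n_theta, axis=1)
    th = np.repeat(((np.arange(n_theta) + 0.5) / n_theta * 360.0)[None, :],
                   n_long, axis=0)
    seg_map = segment_of(l, th)
    means = np.array([raster[seg_map == s].mean() for s in range(1, 18)])
    return means, seg_map


def polar_map(img: Image, wall: WallModel, mode: str = "mean") -> PolarMap:
    """Wall sampling plus segmental averaging in one step."""
    raster = wall_samples(img, wall, mode)
    means, seg_map = to_17_segments(raster)
    return PolarMap(raster, mode, means, seg_map)


def lesion_summary(segment_means_per_realization) -> dict:
    """Normal / L1 / L2 polar-map summaries across realizations.

    ``normal`` is the mean over all segments except 11 and 13.  Returns, per
    region, the mean, min and max over realizations.
    """
    stack = np.stack([np.asarray(m, dtype=np.float64)
                      for m in segment_means_per_realization])
    if stack.shape[1] != 17:
        raise ValueError("expected 17 segment means per realization")
    normal_idx = [s - 1 for s in range(1, 18) if s not in (L1_SEGMENT, L2_SEGMENT)]
    per_real = {
        "normal": stack[:, normal_idx].mean(axis=1),
        "L1": stack[:, L1_SEGMENT - 1],
        "L2": stack[:, L2_SEGMENT - 1],
    }
    return {name: {"mean": float(v.mean()), "min": float(v.min()),
                   "max": float(v.max())}
            for name, v in per_real.items()}


def save_polar_png(pm: PolarMap, path: str, title: str = "") -> None:
    """Render a bull's-eye plot (apex at the centre, anterior wall up)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n_long, n_theta = pm.raster.shape
    theta_edges = np.radians(np.linspace(0, 360, n_theta + 1))
    r_edges = np.linspace(0, 1, n_long + 1)
    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)
    # radius grows apex -> base from the centre outwards
    mesh = ax.pcolormesh(theta_edges, r_edges, pm.raster, shading="auto",
                         cmap="inferno")
    ax.set_yticks([])
    ax.set_xticks([])
    if title:
        ax.set_title(title)
    fig.colorbar(mesh, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=110, bbox_inches="tight")
    plt.close(fig)
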