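"""Parametric cardiac thorax phantom for single-gate FDG-PET simulation.

Generates the linked ground-truth bundle used throughout the package: a
piecewise-constant activity volume (kBq/cc), the matched 511 keV attenuation
map, an integer tissue label map, and derived anatomical volumes (a
contrast-enhanced HRCT in Hounsfield units and an MR-like volume with
Rician noise), plus lesion and evaluation region masks.

Geometry
--------
The left ventricle is a truncated prolate half-ellipsoid shell with its long
axis along +z (apex down, base plane at the top), a crescent-shaped right
ventricle wrapped around the septal side, blood-filled cavities, a thin
pericardial shell, two lung ellipsoids, a liver ellipsoid, a spine cylinder,
and soft tissue/subcutaneous fat inside an elliptic-cylinder thorax.

Anatomical directions (fixed convention used by the whole package):
``+x`` lateral, ``-x`` septal, ``+y`` anterior, ``-y`` inferior,
``+z`` towards the valve plane (base).  The wall angle ``theta`` is measured
from the anterior direction towards the lateral one.

Two myocardial lesions are carved out of the LV wall:

* L1 — non-transmural, about 3 ml, crossing 60 % of the wall from the
  endocardium, centred on the mid inferolateral wall.
* L2 — transmural, 1.5 ml, in the apical portion of the inferior wall,
  with zero activity.

The lesions' angular/longitudinal extents are solved by bisection so that
the voxelised masks hit their target volumes while still covering the polar
map segments (11 and 13) they are assigned to.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .image import Image, block_average

# ----------------------------------------------------------------- tissues

AIR, LV_MYO, RV_MYO, BLOOD, PERICARDIUM, LUNG, SOFT, FAT, BONE, LIVER, L1, L2 = range(12)

LABEL_NAMES = {
    AIR: "air", LV_MYO: "lv_myo", RV_MYO: "rv_myo", BLOOD: "blood",
    PERICARDIUM: "pericardium", LUNG: "lung", SOFT: "soft_tissue",
    FAT: "fat", BONE: "bone", LIVER: "liver", L1: "lesion_l1", L2: "lesion_l2",
}

#: tissue activity concentrations [kBq/cc]
DEFAULT_ACTIVITIES = {
    LV_MYO: 18.0, RV_MYO: 12.0, LUNG: 0.9, BLOOD: 5.5, LIVER: 6.5,
    L1: 8.0, L2: 0.0,
    AIR: 0.0, PERICARDIUM: 0.0, SOFT: 0.0, FAT: 0.0, BONE: 0.0,
}

#: linear attenuation coefficients at 511 keV [cm^-1]
MU_WATER_511 = 0.096
DEFAULT_MU = {
    AIR: 0.0, LV_MYO: 0.096, RV_MYO: 0.096, BLOOD: 0.096,
    PERICARDIUM: 0.096, LUNG: 0.027, SOFT: 0.096, FAT: 0.090,
    BONE: 0.120, LIVER: 0.096, L1: 0.096, L2: 0.096,
}

#: MR-like class intensities (a.u.)
DEFAULT_MR_INTENSITIES = {
    AIR: 0.0, LV_MYO: 10.0, RV_MYO: 10.0, BLOOD: 45.0, PERICARDIUM: 70.0,
    LUNG: 10.0, SOFT: 30.0, FAT: 100.0, BONE: 0.0, LIVER: 30.0,
    L1: 55.0, L2: 55.0,
}

HRCT_BLOOD_HU = 300.0  # contrast-enhanced blood plateau


class GeometryError(ValueError):
    """A phantom component cannot be realised with the requested geometry."""


class ConfigurationError(ValueError):
    """Inconsistent or incomplete phantom configuration."""


# ------------------------------------------------------------------ params

@dataclass
class LesionSpec:
    """Myocardial lesion carved from the LV wall.

    ``theta_deg``/``long_band`` give the wedge centre and the normalised
    longitudinal band (0 apex, 1 base) the lesion must cover; the angular
    half-width (L1) or the upper longitudinal bound (L2-style transmural
    lesions) is then grown by bisection until the mask volume reaches
    ``volume_ml``.
    """
    name: str
    volume_ml: float
    transmurality: float  # fraction of wall crossed, measured from endocardium
    theta_deg: float
    theta_halfwidth_deg: float  # minimum half-width (coverage requirement)
    long_band: tuple[float, float]
    activity: float
    grow: str = "theta"  # which extent the volume bisection grows: theta | long

    def __post_init__(self) -> None:
        if not 0.0 < self.transmurality <= 1.0:
            raise GeometryError(f"transmurality must be in (0, 1], got {self.transmurality}")
        if self.volume_ml <= 0:
            raise GeometryError("lesion volume must be positive")


@dataclass
class PhantomParams:
    """Full parameterisation of the synthetic thorax.

    Lengths are millimetres, activities kBq/cc, attenuation cm^-1.
    """
    shape: tuple[int, int, int] = (240, 240, 240)
    voxel_mm: float = 0.8
    # LV shell: prolate half-ellipsoid, truncated at the base plane
    lv_centre: tuple[float, float, float] = (0.0, 0.0, 21.0)  # base-plane centre
    lv_endo_semi: tuple[float, float] = (17.0, 29.0)  # (short-axis, long-axis)
    lv_wall_mm: float = 10.0
    # RV: thinner shell of an offset ellipsoid, clipped outside the LV
    rv_offset: tuple[float, float, float] = (-18.0, 0.0, 0.0)
    rv_epi_semi: tuple[float, float, float] = (30.0, 26.0, 36.0)
    rv_wall_mm: float = 5.0
    blood_cap_mm: float = 15.0        # blood above the base plane (atria stand-in)
    pericardium_mm: float = 3.0
    # thorax
    thorax_semi: tuple[float, float] = (88.0, 70.0)
    fat_rim_fraction: float = 0.93
    lung_centre: tuple[float, float, float] = (52.0, 8.0, 5.0)
    lung_semi: tuple[float, float, float] = (30.0, 40.0, 78.0)
    liver_centre: tuple[float, float, float] = (35.0, -5.0, -62.0)
    liver_semi: tuple[float, float, float] = (48.0, 50.0, 34.0)
    spine_centre_y: float = -52.0
    spine_radius: float = 10.0
    # carved in order; later lesions exclude the voxels of earlier ones
    lesions: tuple[LesionSpec, ...] = (
        LesionSpec("L2", 1.5, 1.0, theta_deg=180.0, theta_halfwidth_deg=48.0,
                   long_band=(0.23, 1.0 / 3.0 + 0.015),
                   activity=0.0, grow="long"),
        LesionSpec("L1", 3.0, 0.60, theta_deg=120.0, theta_halfwidth_deg=33.0,
                   long_band=(1.0 / 3.0 - 0.03, 2.0 / 3.0 + 0.03),
                   activity=8.0, grow="theta"),
    )
    activities: dict = field(default_factory=lambda: dict(DEFAULT_ACTIVITIES))
    mu: dict = field(default_factory=lambda: dict(DEFAULT_MU))
    mr_intensities: dict = field(default_factory=lambda: dict(DEFAULT_MR_INTENSITIES))
    mr_rician_sigma: float = 5.0  # 5 % of the fat intensity
    mr_aniso_slice_mm: float = 8.0
    heart_scale: float = 1.0          # volume scale factor of the whole heart
    cardiac_phase_delta: float = 0.0  # fractional cavity shrink / wall growth
    heart_offset_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)  # respiratory
    diaphragm_motion_mm: float = 20.0
    ap_expansion_mm: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_mm <= 0:
            raise ConfigurationError("voxel size must be positive")
        if any(v < 0 for v in self.activities.values()):
            raise ConfigurationError("activities must be non-negative")
        if self.heart_scale <= 0:
            raise GeometryError("heart_scale must be positive")

    @classmethod
    def desk(cls, **overrides) -> "PhantomParams":
        """Reduced desk-scale grid (96^3 voxels at 2 mm) for fast studies."""
        return cls(shape=(96, 96, 96), voxel_mm=2.0, **overrides)

    @property
    def lv_epi_semi(self) -> tuple[float, float]:
        a, c = self.lv_endo_semi
        return (a + self.lv_wall_mm, c + self.lv_wall_mm)


@dataclass
class HeartGeometry:
    """Analytic LV description shared with the polar-map module."""
    centre: tuple[float, float, float]    # base-plane centre (x, y, z)
    endo_semi: tuple[float, float]
    epi_semi: tuple[float, float]
    wall_mm: float

    @property
    def apex_z(self) -> float:
        return self.centre[2] - self.epi_semi[1]

    @property
    def base_z(self) -> float:
        return self.centre[2]

    @property
    def long_axis_mm(self) -> float:
        return self.epi_semi[1]


@dataclass
class RegionMasks:
    """Boolean evaluation masks on a stated grid."""
    masks: dict
    voxel_mm: tuple[float, float, float]
    threshold_fraction: float
    flags: dict = field(default_factory=dict)

    def __getitem__(self, name: str) -> np.ndarray:
        return self.masks[name]


@dataclass
class PhantomSet:
    """The linked ground-truth bundle."""
    activity_true: Image
    mu_map: Image
    label_map: Image
    hrct: Image
    mr: Image
    mr_aniso: Image
    masks: dict                  # region name -> bool array on the phantom grid
    heart: HeartGeometry
    params: PhantomParams

    def lesion_volume_ml(self, name: str) -> float:
        return float(self.masks[name].sum()) * self.activity_true.voxel_volume_ml


# ----------------------------------------------------------- construction

def _ellipsoid(x, y, z, centre, semi) -> np.ndarray:
    return (((x - centre[0]) / semi[0]) ** 2
            + ((y - centre[1]) / semi[1]) ** 2
            + ((z - centre[2]) / semi[2]) ** 2) <= 1.0


def _transmural_coordinate(x, y, dz, endo_semi, wall_mm, inside_wall) -> np.ndarray:
    """Normalised transmural coordinate t in [0, 1] (0 endo, 1 epi).

    Semi-axes interpolate linearly across the wall; for each wall voxel the
    shell parameter s with |p| on the s-surface is found by bisection.
    """
    a0, c0 = endo_semi
    xx, yy, zz = x[inside_wall], y[inside_wall], dz[inside_wall]
    lo = np.zeros(xx.shape)
    hi = np.ones(xx.shape)
    for _ in range(30):
        mid = 0.5 * (lo + hi)
        a = a0 + wall_mm * mid
        c = c0 + wall_mm * mid
        outside = (xx / a) ** 2 + (yy / a) ** 2 + (zz / c) ** 2 > 1.0
        lo = np.where(outside, mid, lo)
        hi = np.where(outside, hi, mid)
    t = np.full(x.shape, np.nan)
    t[inside_wall] = 0.5 * (lo + hi)
    return t


def _lesion_mask(spec: LesionSpec, wall: np.ndarray, t: np.ndarray,
                 theta_deg: np.ndarray, long_frac: np.ndarray,
                 voxel_volume_ml: float) -> np.ndarray:
    """Voxelise a lesion, growing one extent by bisection to hit its volume.

    The grown extent never shrinks below the stated minimum (the polar-map
    segment coverage requirement); among the final bisection bracket the
    extent whose voxelised volume is nearest the target is kept.
    """
    widx = np.nonzero(wall.ravel())[0]
    tw = t.ravel()[widx]
    lfw = long_frac.ravel()[widx]
    dth = np.abs((theta_deg.ravel()[widx] - spec.theta_deg + 180.0) % 360.0 - 180.0)
    base = (tw <= spec.transmurality + 1e-9) & (lfw >= spec.long_band[0])

    def select(halfwidth: float, long_hi: float) -> np.ndarray:
        return base & (dth <= halfwidth) & (lfw <= long_hi)

    def volume(halfwidth: float, long_hi: float) -> float:
        return float(select(halfwidth, long_hi).sum()) * voxel_volume_ml

    hw, lhi = spec.theta_halfwidth_deg, spec.long_band[1]
    if spec.grow == "theta":
        get = lambda p: volume(p, lhi)
        lo_p, hi_p = hw, 179.0
    else:
        get = lambda p: volume(hw, p)
        lo_p, hi_p = lhi, 0.95
    if get(lo_p) >= spec.volume_ml:
        p = lo_p  # minimum coverage already meets the target
    elif get(hi_p) < spec.volume_ml:
        raise GeometryError(
            f"lesion {spec.name}: cannot reach {spec.volume_ml} ml within the wall")
    else:
        for _ in range(40):
            mid = 0.5 * (lo_p + hi_p)
            if get(mid) < spec.volume_ml:
                lo_p = mid
            else:
                hi_p = mid
        # nearest of the two bracketing discretised volumes
        p = lo_p if (spec.volume_ml - get(lo_p)) < (get(hi_p) - spec.volume_ml) else hi_p
    sel = select(p, lhi) if spec.grow == "theta" else select(hw, p)
    mask = np.zeros(wall.size, dtype=bool)
    mask[widx[sel]] = True
    return mask.reshape(wall.shape)


def build_phantom(params: PhantomParams | None = None) -> PhantomSet:
    """Generate the full ground-truth bundle for one cardiac/respiratory gate.

    Returns a :class:`PhantomSet` whose activity is piecewise constant at the
    configured tissue concentrations.  Deterministic for a fixed seed (the
    only random component is the Rician noise of the MR volume).
    """
    p = params or PhantomParams()
    vm = p.voxel_mm
    img0 = Image(np.zeros(p.shape), (vm, vm, vm))
    x, y, z = img0.coord_grids()

    # heart-level transforms: respiratory offset, volume scale, phase change
    s_lin = p.heart_scale ** (1.0 / 3.0)
    ph = p.cardiac_phase_delta
    hx = (x - p.heart_offset_mm[0]) / s_lin
    hy = (y - p.heart_offset_mm[1]) / s_lin
    hz = (z - p.heart_offset_mm[2]) / s_lin

    cx, cy, cz = p.lv_centre
    endo_a = p.lv_endo_semi[0] * (1.0 - ph)
    endo_c = p.lv_endo_semi[1] * (1.0 - ph)
    wall = p.lv_wall_mm * (1.0 + ph)
    epi_a, epi_c = endo_a + wall, endo_c + wall
    if endo_a <= 0 or endo_c <= 0:
        raise GeometryError("cardiac phase change collapses the LV cavity")

    dx, dy, dz = hx - cx, hy - cy, hz - cz
    below_base = dz <= 0.0
    in_endo = ((dx / endo_a) ** 2 + (dy / endo_a) ** 2 + (dz / endo_c) ** 2) <= 1.0
    in_epi = ((dx / epi_a) ** 2 + (dy / epi_a) ** 2 + (dz / epi_c) ** 2) <= 1.0
    lv_wall = in_epi & ~in_endo & below_base
    lv_cavity = in_endo & below_base

    rvc = (cx + p.rv_offset[0], cy + p.rv_offset[1], cz + p.rv_offset[2])
    rv_epi_semi = p.rv_epi_semi
    rv_endo_semi = tuple(s - p.rv_wall_mm for s in rv_epi_semi)
    if min(rv_endo_semi) <= 0:
        raise GeometryError("RV wall thicker than the RV ellipsoid")
    in_rv_epi = _ellipsoid(hx, hy, hz, rvc, rv_epi_semi) & below_base
    in_rv_endo = _ellipsoid(hx, hy, hz, rvc, rv_endo_semi) & below_base
    rv_wall = in_rv_epi & ~in_rv_endo & ~in_epi
    rv_cavity = in_rv_endo & ~in_epi

    # blood cap above the base plane (atrial blood stand-in)
    cap = (~below_base) & (dz <= p.blood_cap_mm) & (
        (((dx / epi_a) ** 2 + (dy / epi_a) ** 2 + (dz / epi_c) ** 2) <= 1.0)
        | _ellipsoid(hx, hy, hz, rvc, rv_epi_semi))

    heart = lv_wall | lv_cavity | rv_wall | rv_cavity | cap

    # check the heart stays inside the thorax
    tx, ty = p.thorax_semi
    thorax_frac = (x / tx) ** 2 + (y / ty) ** 2
    if np.any(heart & (thorax_frac > p.fat_rim_fraction ** 2)):
        raise GeometryError("heart exits the thorax soft-tissue compartment")

    # lesions, defined on the unscaled LV wall coordinates
    theta = np.degrees(np.arctan2(dx, dy)) % 360.0
    t = _transmural_coordinate(dx, dy, dz, (endo_a, endo_c), wall, lv_wall)
    long_frac = (dz + epi_c) / epi_c  # 0 at epicardial apex, 1 at base
    vox_ml = img0.voxel_volume_ml * p.heart_scale
    lesion_masks = {}
    wall_avail = lv_wall
    for spec in p.lesions:
        if spec.transmurality * wall > wall + 1e-9:
            raise GeometryError("lesion extent exceeds the wall thickness")
        lesion_masks[spec.name] = _lesion_mask(spec, wall_avail, t, theta,
                                               long_frac, vox_ml)
        wall_avail = wall_avail & ~lesion_masks[spec.name]

    # pericardial shell around the heart
    voxel_radius = p.pericardium_mm / vm
    dist = ndimage.distance_transform_edt(~heart)
    pericardium = (dist > 0) & (dist <= voxel_radius)

    # thorax compartments
    in_thorax = thorax_frac <= 1.0
    fat_rim = in_thorax & (thorax_frac > p.fat_rim_fraction ** 2)
    lungs = (_ellipsoid(x, y, z, p.lung_centre, p.lung_semi)
             | _ellipsoid(-x, y, z, p.lung_centre, p.lung_semi))
    lungs &= in_thorax & ~heart & ~pericardium & ~fat_rim
    liver = _ellipsoid(x, y, z, p.liver_centre, p.liver_semi)
    liver &= in_thorax & ~heart & ~pericardium & ~lungs & ~fat_rim
    spine = ((x ** 2 + (y - p.spine_centre_y) ** 2) <= p.spine_radius ** 2) & in_thorax

    labels = np.zeros(p.shape, dtype=np.int16)
    labels[in_thorax] = SOFT
    labels[fat_rim] = FAT
    labels[lungs] = LUNG
    labels[liver] = LIVER
    labels[spine & ~heart & ~pericardium] = BONE
    labels[pericardium] = PERICARDIUM
    labels[lv_wall] = LV_MYO
    labels[rv_wall] = RV_MYO
    labels[lv_cavity | rv_cavity | cap] = BLOOD
    labels[lesion_masks["L1"]] = L1
    labels[lesion_masks["L2"]] = L2

    activity = np.zeros(p.shape)
    mu = np.zeros(p.shape)
    for lab in LABEL_NAMES:
        sel = labels == lab
        activity[sel] = p.activities.get(lab, 0.0)
        mu[sel] = p.mu.get(lab, 0.0)

    vox3 = (vm, vm, vm)
    activity_img = Image(activity, vox3, "kBq/cc")
    mu_img = Image(mu, vox3, "cm^-1")
    label_img = Image(labels, vox3, "label")

    hrct = derive_hrct(mu_img, label_img)
    mr = derive_mr(label_img, p.mr_intensities, p.mr_rician_sigma, p.seed)
    mr_aniso = make_anisotropic(mr, p.mr_aniso_slice_mm)

    masks = {
        "LV": labels == LV_MYO,
        "RV": labels == RV_MYO,
        "BP": labels == BLOOD,
        "L1": lesion_masks["L1"],
        "L2": lesion_masks["L2"],
    }
    geom = HeartGeometry(
        centre=(cx * s_lin + p.heart_offset_mm[0],
                cy * s_lin + p.heart_offset_mm[1],
                cz * s_lin + p.heart_offset_mm[2]),
        endo_semi=(endo_a * s_lin, endo_c * s_lin),
        epi_semi=(epi_a * s_lin, epi_c * s_lin),
        wall_mm=wall * s_lin,
    )
    return PhantomSet(activity_img, mu_img, label_img, hrct, mr, mr_aniso,
                      masks, geom, p)


# ------------------------------------------------------ derived anatomies

def derive_hrct(mu_map: Image, label_map: Image) -> Image:
    """Contrast-enhanced HRCT in Hounsfield units from the attenuation map.

    HU = 1000 (mu / mu_water - 1); blood-pool voxels are raised to a
    contrast plateau.  Lesion voxels keep the attenuation of muscle, so the
    HRCT carries no lesion contrast by construction.
    """
    if not mu_map.same_grid(label_map):
        raise ConfigurationError("mu map and label map are not aligned")
    hu = 1000.0 * (mu_map.data / MU_WATER_511 - 1.0)
    hu[label_map.data == BLOOD] = HRCT_BLOOD_HU
    return Image(hu, mu_map.voxel_mm, "HU")


def derive_mr(label_map: Image, intensities: dict | None = None,
              rician_sigma: float = 5.0, seed: int = 0) -> Image:
    """MR-like volume: per-class intensities plus Rician noise.

    The noise model is the magnitude of the class value perturbed by two
    independent Gaussian components: m = sqrt((v + n1)^2 + n2^2),
    n1, n2 ~ N(0, sigma).  sigma = 0 returns the class map exactly.
    """
    intensities = dict(DEFAULT_MR_INTENSITIES if intensities is None else intensities)
    labels = np.asarray(label_map.data).astype(np.int64)
    present = np.unique(labels)
    missing = [int(l) for l in present if l not in intensities]
    if missing:
        raise ConfigurationError(f"missing MR intensity for classes {missing}")
    lut = np.zeros(int(labels.max()) + 1)
    for lab, val in intensities.items():
        if lab <= labels.max():
            lut[lab] = val
    clean = lut[labels]
    if rician_sigma <= 0:
        return Image(clean, label_map.voxel_mm, "a.u.")
    rng = np.random.default_rng(seed)
    n1 = rng.normal(0.0, rician_sigma, clean.shape)
    n2 = rng.normal(0.0, rician_sigma, clean.shape)
    noisy = np.sqrt((clean + n1) ** 2 + n2 ** 2)
    return Image(noisy, label_map.voxel_mm, "a.u.")


def make_anisotropic(mr: Image, slice_thickness_mm: float) -> Image:
    """Degrade through-plane resolution to the stated slice thickness.

    Values are averaged over z-slabs of the given thickness and replicated
    back onto the original grid, emulating thick-slice MR acquisition.
    """
    dz = mr.voxel_mm[2]
    factor = slice_thickness_mm / dz
    if abs(factor - round(factor)) > 1e-6:
        raise ConfigurationError(
            f"slice thickness {slice_thickness_mm} mm is not a multiple of the "
            f"{dz} mm through-plane voxel size")
    f = int(round(factor))
    if f == 1:
        return mr.copy()
    data = mr.data.astype(np.float64)
    nz = data.shape[2]
    out = np.empty_like(data)
    for start in range(0, nz, f):
        sl = slice(start, min(start + f, nz))
        out[:, :, sl] = data[:, :, sl].mean(axis=2, keepdims=True)
    return Image(out, mr.voxel_mm, mr.units)


def shift_image(img: Image, vector_mm, background: float = 0.0,
                order: int = 1) -> Image:
    """Rigid translation by a millimetre vector (linear interpolation).

    Out-of-field voxels are filled with ``background``.
    """
    vec = np.asarray(vector_mm, dtype=float)
    shift_vox = vec / np.asarray(img.voxel_mm)
    data = ndimage.shift(img.data.astype(np.float64), shift_vox, order=order,
                         mode="constant", cval=background, prefilter=order > 1)
    return Image(data, img.voxel_mm, img.units)


def random_shift_vectors(magnitudes_mm, n_directions: int, seed: int = 0) -> list[np.ndarray]:
    """Random 3-D shift vectors: uniform directions x stated magnitudes.

    Returns ``n_directions * len(magnitudes_mm)`` vectors; the directions are
    shared across magnitudes, matching a direction-grid study design.
    """
    mags = [float(m) for m in magnitudes_mm]
    if any(m <= 0 for m in mags):
        raise ConfigurationError("magnitudes must be positive")
    rng = np.random.default_rng(seed)
    dirs = rng.normal(size=(n_directions, 3))
    dirs /= np.linalg.norm(dirs, axis=1, keepdims=True)
    return [m * d for m in mags for d in dirs]


def mismatch_phantom(params: PhantomParams, heart_scale: float = 1.0,
                     phase_delta: float = 0.0) -> PhantomSet:
    """Regenerate the phantom with a mismatched heart (anatomy-only use).

    ``heart_scale`` is a *volume* scale (linear scale = heart_scale^(1/3));
    ``phase_delta`` emulates a different cardiac phase as a fractional cavity
    shrink and wall growth.  Non-cardiac tissues are unchanged.
    """
    return build_phantom(replace(params, heart_scale=heart_scale,
                                 cardiac_phase_delta=phase_delta))


def respiratory_states(params: PhantomParams, n_states: int) -> list[PhantomSet]:
    """Phantoms along a respiratory trajectory.

    The heart is displaced rigidly along a cranio-caudal (z) plus
    antero-posterior (y) trajectory spanning the diaphragm-motion amplitude;
    state 0 is the reference end-expiration phantom.
    """
    if n_states < 1:
        raise ConfigurationError("n_states must be >= 1")
    out = []
    for k in range(n_states):
        frac = 0.0 if n_states == 1 else k / (n_states - 1)
        off = (0.0, frac * params.ap_expansion_mm, -frac * params.diaphragm_motion_mm)
        out.append(build_phantom(replace(params, heart_offset_mm=off)))
    return out


# -------------------------------------------------------- evaluation masks

def threshold_region_mask(resampled_values: np.ndarray, support: np.ndarray,
                          true_value: float, threshold_fraction: float) -> np.ndarray:
    """Voxels of the (resampled) ground truth retaining at least the stated
    fraction of the region's true activity, within the region's support."""
    support = np.asarray(support, dtype=bool)
    return support & (np.asarray(resampled_values) >= threshold_fraction * true_value)


def region_masks(phantom: PhantomSet, out_voxel_mm: float,
                 out_shape: tuple[int, int, int] | None = None,
                 threshold_fraction: float = 0.7) -> RegionMasks:
    """Evaluation masks on the reconstruction grid.

    The ground-truth activity and each region indicator are resampled by
    volume-weighted block averaging; a region voxel survives when it keeps at
    least ``threshold_fraction`` of the region's true activity and the region
    occupies the majority of the voxel.  For zero-activity regions (the
    transmural lesion) the majority-support rule alone applies.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise ConfigurationError("threshold_fraction must be in (0, 1]")
    act = block_average(phantom.activity_true, out_voxel_mm, out_shape)
    masks, flags = {}, {}
    for name, mask in phantom.masks.items():
        true_val = _region_true_value(phantom, name)
        ind = block_average(
            Image(mask.astype(np.float64), phantom.activity_true.voxel_mm),
            out_voxel_mm, out_shape).data
        support = ind >= 0.5
        m = threshold_region_mask(act.data, support, true_val, threshold_fraction)
        if not m.any():
            flags[name] = "empty"
        masks[name] = m
    if flags:
        import warnings
        warnings.warn(f"empty region masks: {sorted(flags)}", stacklevel=2)
    return RegionMasks(masks, act.voxel_mm, threshold_fraction, flags)


def _region_true_value(phantom: PhantomSet, region: str) -> float:
    label = {"LV": LV_MYO, "RV": RV_MYO, "BP": BLOOD, "L1": L1, "L2": L2}[region]
    return float(phantom.params.activities.get(label, 0.0))
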