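"""Penalty functions for MAP reconstruction.

Three penalties are provided:

* **RD** — the relative-difference penalty.  For each voxel pair (j, k) in a
  neighbourhood, the contribution is
  ``w_jk (f_j - f_k)^2 / (f_j + f_k + gamma |f_j - f_k| + eps)``;
  ``gamma`` controls edge preservation (gamma = 0 gives a quadratic-like
  penalty with no edge preservation).
* **TV** — smoothed (isotropic) total variation,
  ``sum_j sqrt(sum_d (forward difference)_d^2 + eps^2)``.
* **BOWSHER** — the RD penalty with gamma = 0 restricted, per voxel, to the
  ``n`` neighbours most similar in a co-registered anatomical image.  The
  selection is asymmetric (j may select k without k selecting j) and never
  sees the activity image.

Pair weights are the inverse centre-to-centre distance in voxel units.  All
penalties include the weight ``beta``; the gradients are the exact analytic
derivatives of the stated forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .image import Image

try:  # optional acceleration of the pairwise gradient kernel
    import numba as _numba
except ImportError:  # pragma: no cover - numba is normally available
    _numba = None

_EPS_SCALE = 1e-6  # numerical floor: eps = 1e-6 * max(image)


def neighbourhood_18() -> list[tuple[int, int, int]]:
    """The 18-neighbour offsets: the 3x3x3 cube minus centre and the eight
    corners, giving an approximately spherical neighbourhood.  The canonical
    ordering (by distance, then lexicographic) is the deterministic
    tie-break order used by the Bowsher selection."""
    offsets = [(dx, dy, dz)
               for dx in (-1, 0, 1) for dy in (-1, 0, 1) for dz in (-1, 0, 1)
               if (dx, dy, dz) != (0, 0, 0) and abs(dx) + abs(dy) + abs(dz) < 3]
    offsets.sort(key=lambda o: (o[0] ** 2 + o[1] ** 2 + o[2] ** 2, o))
    return offsets


@dataclass
class PriorSpec:
    """Penalty definition: kind, weight and shape parameters."""
    kind: str = "RD"            # RD | TV | BOWSHER
    beta: float = 1.0
    gamma: float = 0.0          # RD edge-preservation parameter
    n_neighbours: int = 9       # Bowsher selected-neighbour count
    offsets: list = field(default_factory=neighbourhood_18)
    epsilon: float | None = None  # None -> 1e-6 * max(image) at evaluation

    def __post_init__(self) -> None:
        self.kind = self.kind.upper()
        if self.kind not in ("RD", "TV", "BOWSHER"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if self.beta < 0 or self.gamma < 0:
            raise ValueError("beta and gamma must be non-negative")
        if self.kind == "BOWSHER" and not 1 <= self.n_neighbours <= len(self.offsets):
            raise ValueError("n_neighbours must lie in [1, |neighbourhood|]")


@dataclass
class NeighbourGraph:
    """Per-voxel Bowsher neighbour selection.

    ``selected[i]`` is a boolean volume marking, for offset ``offsets[i]``,
    the voxels that selected that neighbour.  ``boundary_flagged`` is True
    when some boundary voxel had fewer in-bounds neighbours than requested
    (all available ones are then selected).
    """
    offsets: list
    selected: np.ndarray  # (n_offsets, nx, ny, nz) bool
    n_neighbours: int
    boundary_flagged: bool = False


def _shifted_view(data: np.ndarray, offset: tuple[int, int, int],
                  fill: float) -> np.ndarray:
    """Neighbour values a[j + offset], out-of-bounds positions -> fill."""
    out = np.full(data.shape, fill, dtype=np.float64)
    src = tuple(slice(max(o, 0), data.shape[a] + min(o, 0)) for a, o in enumerate(offset))
    dst = tuple(slice(max(-o, 0), data.shape[a] + min(-o, 0)) for a, o in enumerate(offset))
    out[dst] = data[src]
    return out


def _pair_slices(shape, offset):
    """Index slices (centre j, neighbour k = j + offset) of in-bounds pairs."""
    ctr = tuple(slice(max(-o, 0), shape[a] + min(-o, 0)) for a, o in enumerate(offset))
    nbr = tuple(slice(max(o, 0), shape[a] + min(o, 0)) for a, o in enumerate(offset))
    return ctr, nbr


def bowsher_select(anatomy: Image, n: int,
                   offsets: list | None = None) -> NeighbourGraph:
    """Select, per voxel, the n neighbours most similar in the anatomy.

    Similarity is the absolute intensity difference; ties are broken by the
    canonical offset ordering.  Boundary voxels with fewer than n in-bounds
    neighbours select all available ones.
    """
    offsets = list(offsets) if offsets is not None else neighbourhood_18()
    if n > len(offsets):
        raise ValueError("n exceeds the neighbourhood size")
    a = np.asarray(anatomy.data, dtype=np.float64)
    diffs = np.stack([np.abs(_shifted_view(a, o, np.inf) - a) for o in offsets])
    order = np.argsort(diffs, axis=0, kind="stable")  # stable -> canonical tie-break
    rank = np.empty_like(order)
    idx = np.indices(order.shape[1:])
    rank[(order, *idx)] = np.arange(len(offsets)).reshape(-1, 1, 1, 1)
    selected = (rank < n) & np.isfinite(diffs)
    boundary_flagged = bool(np.any(selected.sum(axis=0) < n))
    return NeighbourGraph(offsets, selected, n, boundary_flagged)


def _epsilon(img_data: np.ndarray, spec: PriorSpec) -> float:
    if spec.epsilon is not None:
        return float(spec.epsilon)
    m = float(np.max(np.abs(img_data)))
    return _EPS_SCALE * m if m > 0 else 1e-12


def _offset_weight(offset) -> float:
    return 1.0 / float(np.linalg.norm(offset))


def penalty_value(img: Image, spec: PriorSpec,
                  graph: NeighbourGraph | None = None) -> float:
    """Penalty P(f) >= 0 (including the weight beta)."""
    f = np.asarray(img.data, dtype=np.float64)
    if spec.kind in ("RD", "BOWSHER") and np.any(f < 0):
        raise ValueError("RD/Bowsher penalties require a non-negative image")
    eps = _epsilon(f, spec)
    if spec.kind == "TV":
        grad2 = np.zeros(f.shape)
        for ax in range(3):
            d = np.diff(f, axis=ax, append=0.0)
            # zero the one-past-the-end difference (no forward neighbour)
            idx = [slice(None)] * 3
            idx[ax] = slice(f.shape[ax] - 1, f.shape[ax])
            d[tuple(idx)] = 0.0
            grad2 += d ** 2
        return float(spec.beta * np.sqrt(grad2 + eps ** 2).sum())
    # RD / Bowsher
    total = 0.0
    offsets = graph.offsets if (spec.kind == "BOWSHER" and graph is not None) else spec.offsets
    if spec.kind == "BOWSHER" and graph is None:
        raise ValueError("Bowsher penalty requires a neighbour graph")
    for i, o in enumerate(offsets):
        ctr, nbr = _pair_slices(f.shape, o)
        fj, fk = f[ctr], f[nbr]
        d = fj - fk
        gamma = 0.0 if spec.kind == "BOWSHER" else spec.gamma
        den = fj + fk + gamma * np.abs(d) + eps
        term = _offset_weight(o) * d ** 2 / den
        if spec.kind == "BOWSHER":
            term = term * graph.selected[i][ctr]
        total += term.sum()
    return float(spec.beta * total)


def _rd_gradient_pairs_numpy(f, offsets, gamma, eps, selected):
    grad = np.zeros(f.shape)
    for i, o in enumerate(offsets):
        ctr, nbr = _pair_slices(f.shape, o)
        fj, fk = f[ctr], f[nbr]
        d = fj - fk
        sgn = np.sign(d)
        den = fj + fk + gamma * np.abs(d) + eps
        w = _offset_weight(o)
        dj = w * (2.0 * d * den - d ** 2 * (1.0 + gamma * sgn)) / den ** 2
        dk = w * (-2.0 * d * den - d ** 2 * (1.0 - gamma * sgn)) / den ** 2
        if selected is not None:
            sel = selected[i][ctr]
            dj = dj * sel
            dk = dk * sel
        grad[ctr] += dj
        grad[nbr] += dk
    return grad


if _numba is not None:

    @_numba.njit(cache=True)
    def _rd_gradient_pairs_kernel(f, offsets, weights, gamma, eps, selected,
                                  use_sel):  # pragma: no cover - jitted
        nx, ny, nz = f.shape
        grad = np.zeros((nx, ny, nz))
        n_off = offsets.shape[0]
        for i in range(nx):
            for j in range(ny):
                for k in range(nz):
                    fj = f[i, j, k]
                    for m in range(n_off):
                        ii = i + offsets[m, 0]
                        jj = j + offsets[m, 1]
                        kk = k + offsets[m, 2]
                        if ii < 0 or ii >= nx or jj < 0 or jj >= ny \
                                or kk < 0 or kk >= nz:
                            continue
                        if use_sel and not selected[m, i, j, k]:
                            continue
                        fk = f[ii, jj, kk]
                        d = fj - fk
                        s = 0.0 if d == 0.0 else (1.0 if d > 0.0 else -1.0)
                        den = fj + fk + gamma * abs(d) + eps
                        w = weights[m]
                        grad[i, j, k] += w * (2.0 * d * den
                                              - d * d * (1.0 + gamma * s)) / den ** 2
                        grad[ii, jj, kk] += w * (-2.0 * d * den
                                                 - d * d * (1.0 - gamma * s)) / den ** 2
        return grad


def _rd_gradient_pairs(f, offsets, gamma, eps, selected):
    """Accumulated pairwise RD gradient; numba-accelerated when available."""
    if _numba is None:
        return _rd_gradient_pairs_numpy(f, offsets, gamma, eps, selected)
    offs = np.asarray(offsets, dtype=np.int64)
    weights = np.array([_offset_weight(o) for o in offsets])
    use_sel = selected is not None
    sel = np.ascontiguousarray(selected) if use_sel \
        else np.zeros((1, 1, 1, 1), dtype=bool)
    return _rd_gradient_pairs_kernel(np.ascontiguousarray(f, dtype=np.float64),
                                     offs, weights, float(gamma), float(eps),
                                     sel, use_sel)


def penalty_gradient(img: Image, spec: PriorSpec,
                     graph: NeighbourGraph | None = None) -> Image:
    """Analytic gradient dP/df of :func:`penalty_value`."""
    f = np.asarray(img.data, dtype=np.float64)
    if spec.kind in ("RD", "BOWSHER") and np.any(f < 0):
        raise ValueError("RD/Bowsher penalties require a non-negative image")
    eps = _epsilon(f, spec)
    grad = np.zeros(f.shape)
    if spec.kind == "TV":
        grad2 = np.zeros(f.shape)
        diffs = []
        for ax in range(3):
            d = np.diff(f, axis=ax, append=0.0)
            idx = [slice(None)] * 3
            idx[ax] = slice(f.shape[ax] - 1, f.shape[ax])
            d[tuple(idx)] = 0.0
            diffs.append(d)
            grad2 += d ** 2
        r = np.sqrt(grad2 + eps ** 2)
        for ax, d in enumerate(diffs):
            q = d / r
            grad -= q  # d(P_j)/df_j for the forward difference at j
            # d(P_{j - e_ax})/df_j: shift q forward along ax
            shifted = np.zeros_like(q)
            idx_dst = [slice(None)] * 3
            idx_src = [slice(None)] * 3
            idx_dst[ax] = slice(1, None)
            idx_src[ax] = slice(0, -1)
            shifted[tuple(idx_dst)] = q[tuple(idx_src)]
            grad += shifted
        return Image(spec.beta * grad, img.voxel_mm, img.units)
    # RD / Bowsher
    offsets = graph.offsets if (spec.kind == "BOWSHER" and graph is not None) else spec.offsets
    if spec.kind == "BOWSHER" and graph is None:
        raise ValueError("Bowsher penalty requires a neighbour graph")
    gamma = 0.0 if spec.kind == "BOWSHER" else spec.gamma
    selected = graph.selected if spec.kind == "BOWSHER" else None
    grad = _rd_gradient_pairs(f, offsets, gamma, eps, selected)
    return Image(spec.beta * grad, img.voxel_mm, img.units)
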