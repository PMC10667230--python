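"""Spatial influence weights of suture anchors.

Each suture ``l`` has an area of influence ``w_l(x) = exp(-k d_l(x))`` where
``d_l(x)`` is the straight-line Euclidean distance from ``x`` to the nearest
grid point belonging to either bone that ``l`` separates (or to ``l``
itself), so ``w_l = 1`` on those bones and decays outside them with rate
``k`` (mm^-1).  Each anchor ``a`` on ``l`` further concentrates its
contribution with a Gaussian-type kernel

    w_l^a(x) = w_l(x) * exp(-0.5 (x - x_a)^T Sigma_l (x - x_a)),

where ``Sigma_l`` (mm^-2) acts directly as a concentration matrix -- it is
applied exactly as written, without inversion.  Per grid point, the raw
weights of all anchors from all sutures are normalized to sum to one; grid
points whose total raw weight falls below a support threshold are flagged
static and receive zero velocity.

Weights are computed once on the reference (standardized-domain) geometry
and held fixed during flow integration: they are material weights attached
to grid indices, not re-evaluated at advected positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .geometry import Label, SphericalMap, SutureAnchors, bone_adjacency

DEFAULT_K = 0.5             # mm^-1
DEFAULT_SIGMA_MM = 20.0     # kernel length scale; Sigma = sigma_mm^-2 * I
DEFAULT_SUPPORT_THRESHOLD = 1e-8


class InfluenceError(ValueError):
    pass


def isotropic_sigma(sigma_mm: float) -> np.ndarray:
    """Isotropic concentration matrix for a kernel of length scale ``sigma_mm``."""
    if sigma_mm <= 0:
        raise InfluenceError("sigma_mm must be positive")
    return np.eye(3) / float(sigma_mm) ** 2


def _check_spd(mat: np.ndarray, name: str = "Sigma") -> None:
    mat = np.asarray(mat, float)
    if mat.shape != (3, 3):
        raise InfluenceError(f"{name} must be 3x3, got {mat.shape}")
    if not np.allclose(mat, mat.T, atol=1e-10):
        raise InfluenceError(f"{name} must be symmetric")
    eig = np.linalg.eigvalsh(mat)
    if eig.min() <= 0:
        raise InfluenceError(f"{name} must be positive definite; eigenvalues {eig}")


@dataclass
class WeightShapeParams:
    """Shape parameters of the weighting scheme.

    ``k`` is shared across sutures; ``sigma`` maps each suture label to its
    3x3 SPD concentration matrix (isotropic by default).
    """

    k: float = DEFAULT_K
    sigma: dict[Label, np.ndarray] = field(default_factory=dict)

    def validate(self) -> None:
        if self.k <= 0:
            raise InfluenceError("k must be positive")
        for s, mat in self.sigma.items():
            _check_spd(mat, f"Sigma[{Label(s).name}]")

    @classmethod
    def isotropic(cls, sutures, k: float = DEFAULT_K,
                  sigma_mm: float = DEFAULT_SIGMA_MM) -> "WeightShapeParams":
        return cls(k=k, sigma={Label(s): isotropic_sigma(sigma_mm) for s in sutures})


def suture_locality(smap: SphericalMap, suture: Label, k: float,
                    adjacency: dict | None = None,
                    return_distance: bool = False):
    """Per-grid-point suture area-of-influence weight ``w_l = exp(-k d_l)``.

    ``d_l`` is the Euclidean distance to the nearest grid point labeled with
    either bone the suture separates or with the suture itself (those points
    have ``d_l = 0``, hence weight one).
    """
    if k <= 0:
        raise InfluenceError("k must be positive")
    if adjacency is None:
        adjacency = bone_adjacency(smap)
    if Label(suture) not in adjacency:
        raise InfluenceError(f"suture {Label(suture).name} absent from adjacency")
    d = suture_distance_field(smap, suture, adjacency)
    w = np.exp(-k * d)
    if return_distance:
        return w, d
    return w


def suture_distance_field(smap: SphericalMap, suture: Label,
                          adjacency: dict | None = None) -> np.ndarray:
    """Euclidean distance ``d_l`` from every grid point to the zero set of
    suture ``l`` (the two bones it separates plus the suture band itself)."""
    if adjacency is None:
        adjacency = bone_adjacency(smap)
    bones = adjacency[Label(suture)]
    zero_codes = {int(b) for b in bones} | {int(suture)}
    lab = smap.label.reshape(-1)
    pts = smap.flat_coords()
    in_zero = np.isin(lab, list(zero_codes))
    d = np.zeros(lab.size)
    outside = ~in_zero
    if outside.any():
        d[outside] = cdist(pts[outside], pts[in_zero]).min(axis=1)
    return d.reshape(smap.grid_shape)


def anchor_kernel(smap: SphericalMap, anchors: SutureAnchors,
                  shape: WeightShapeParams,
                  adjacency: dict | None = None) -> np.ndarray:
    """Raw (unnormalized) per-anchor weights, shape (M, A) over flat grid points."""
    shape.validate()
    if adjacency is None:
        adjacency = bone_adjacency(smap)
    pts = smap.flat_coords()
    M, A = pts.shape[0], anchors.n_anchors
    raw = np.empty((M, A))
    for s in set(anchors.suture.tolist()):
        lab = Label(int(s))
        w_l = suture_locality(smap, lab, shape.k, adjacency).reshape(-1)
        sigma = shape.sigma.get(lab)
        if sigma is None:
            raise InfluenceError(f"no Sigma for suture {lab.name}")
        _check_spd(sigma, f"Sigma[{lab.name}]")
        for a in anchors.anchors_of(lab):
            diff = pts - anchors.x[a]
            q = np.einsum("ij,jk,ik->i", diff, sigma, diff)
            raw[:, a] = w_l * np.exp(-0.5 * q)
    return raw


@dataclass
class WeightField:
    """Normalized per-anchor influence weights over the flat grid.

    ``values[m, a]`` is the normalized weight of anchor ``a`` at grid point
    ``m``; rows of supported points sum to one, rows of static points are
    exactly zero.  Cached quantities (``dist``: ``d_l`` per anchor column;
    ``quad``: the kernel quadratic form per entry) support analytic
    derivatives with respect to the shape parameters.
    """

    values: np.ndarray        # (M, A) normalized
    static: np.ndarray        # (M,) bool
    raw: np.ndarray           # (M, A) thresholded raw weights
    dist: np.ndarray | None = None     # (M, A) suture distance d_l per anchor column
    sq_dist: np.ndarray | None = None  # (M, A) squared distance |x_m - x_a|^2
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD

    @property
    def n_anchors(self) -> int:
        return self.values.shape[1]


def normalize_weights(raw: np.ndarray,
                      support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
                      **cached) -> WeightField:
    """Normalize raw anchor weights per grid point (partition of unity).

    Raw weights below ``support_threshold`` are set to exactly zero; grid
    points whose total raw weight is below the threshold are flagged static
    and receive zero weight from every anchor.
    """
    raw = np.asarray(raw, float)
    if raw.ndim != 2 or raw.shape[1] < 1:
        raise InfluenceError("raw weights must be (M, A) with at least one anchor")
    thr = raw.copy()
    thr[thr < support_threshold] = 0.0
    total = thr.sum(axis=1)
    static = total < support_threshold
    values = np.zeros_like(thr)
    sup = ~static
    values[sup] = thr[sup] / total[sup, None]
    return WeightField(values=values, static=static, raw=thr,
                       support_threshold=support_threshold, **cached)


def build_weight_field(smap: SphericalMap, anchors: SutureAnchors,
                       shape: WeightShapeParams,
                       support_threshold: float = DEFAULT_SUPPORT_THRESHOLD) -> WeightField:
    """Compute the full normalized weight field on the map's geometry.

    Also caches, per (grid point, anchor) entry, the suture distance ``d_l``
    and the unscaled squared distance to the anchor, which the inference
    module uses for analytic gradients with respect to ``k`` and isotropic
    ``Sigma_l``.
    """
    shape.validate()
    adjacency = bone_adjacency(smap)
    pts = smap.flat_coords()
    M, A = pts.shape[0], anchors.n_anchors
    dist = np.empty((M, A))
    sq_dist = np.empty((M, A))
    raw = np.empty((M, A))
    for s in set(anchors.suture.tolist()):
        lab = Label(int(s))
        d_l = suture_distance_field(smap, lab, adjacency).reshape(-1)
        sigma = shape.sigma[lab]
        for a in anchors.anchors_of(lab):
            diff = pts - anchors.x[a]
            q = np.einsum("ij,jk,ik->i", diff, sigma, diff)
            dist[:, a] = d_l
            sq_dist[:, a] = np.einsum("ij,ij->i", diff, diff)
            raw[:, a] = np.exp(-shape.k * d_l - 0.5 * q)
    return normalize_weights(raw, support_threshold, dist=dist, sq_dist=sq_dist)
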