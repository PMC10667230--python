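"""Standardized spherical-map calvaria representation and suture anchor frames.

The calvarial surface is sampled on a 2D (azimuth x elevation) grid carrying
3D Euclidean coordinates (mm) and an anatomical label per grid point.  The
azimuth index wraps (periodic); the elevation index does not, and elevation
row 0 is the boundary ring between the calvaria and the cranial base.  Grid
correspondence is anatomical: the same grid index refers to the same
anatomical location in every subject.

Sutural growth is modeled at discrete anchor (control) points along each
suture band.  Each anchor carries a unit growth direction ``u`` tangential to
the cranial surface and perpendicular to the suture, and -- for anchors
adjacent to the cranial-base boundary -- a unit displacement direction ``y``
perpendicular to the cranial surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
from scipy.spatial.transform import Rotation


class Label(IntEnum):
    """Anatomical label codes used on the spherical map."""

    BASE_BOUNDARY = 0
    LF = 1   # left frontal bone
    RF = 2   # right frontal bone
    LP = 3   # left parietal bone
    RP = 4   # right parietal bone
    O = 5    # occipital bone
    M = 10   # metopic suture
    LC = 11  # left coronal suture
    RC = 12  # right coronal suture
    S = 13   # sagittal suture
    LL = 14  # left lambdoid suture
    RL = 15  # right lambdoid suture


BONE_LABELS = frozenset({Label.LF, Label.RF, Label.LP, Label.RP, Label.O})
SUTURE_LABELS = frozenset({Label.M, Label.LC, Label.RC, Label.S, Label.LL, Label.RL})
VALID_LABELS = frozenset({Label.BASE_BOUNDARY}) | BONE_LABELS | SUTURE_LABELS

#: Sutures whose growth direction is predominantly lateral (left-right); used
#: only to pick a reproducible sign for the anchor direction ``u`` (the flow
#: is invariant to the sign of ``u``).
_LATERAL_U_SUTURES = frozenset({Label.M, Label.S})


class GeometryError(ValueError):
    """Raised for invalid spherical maps or degenerate geometry."""


@dataclass
class SphericalMap:
    """A labeled calvaria surface at one age.

    Attributes
    ----------
    coords : (n_az, n_el, 3) float64 array, mm.
    label : (n_az, n_el) uint8 array of :class:`Label` codes.
    age_days : non-negative age in days.
    subject_id : opaque identifier.
    """

    coords: np.ndarray
    label: np.ndarray
    age_days: float
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.coords = np.ascontiguousarray(self.coords, dtype=np.float64)
        self.label = np.ascontiguousarray(self.label, dtype=np.uint8)

    @property
    def grid_shape(self) -> tuple[int, int]:
        return self.label.shape

    @property
    def n_points(self) -> int:
        return self.label.size

    def flat_coords(self) -> np.ndarray:
        """Coordinates as an (M, 3) array in C order of the (az, el) grid."""
        return self.coords.reshape(-1, 3)

    def sutures_present(self) -> list[Label]:
        present = set(np.unique(self.label))
        return [s for s in SUTURE_LABELS if int(s) in present]

    def copy(self, coords: np.ndarray | None = None,
             age_days: float | None = None,
             subject_id: str | None = None) -> "SphericalMap":
        return SphericalMap(
            coords=self.coords.copy() if coords is None else np.asarray(coords, float),
            label=self.label.copy(),
            age_days=self.age_days if age_days is None else float(age_days),
            subject_id=self.subject_id if subject_id is None else subject_id,
        )

    def validate(self) -> None:
        """Check the structural invariants; raise :class:`GeometryError` if broken."""
        if self.coords.ndim != 3 or self.coords.shape[2] != 3:
            raise GeometryError(f"coords must be (n_az, n_el, 3), got {self.coords.shape}")
        if self.label.shape != self.coords.shape[:2]:
            raise GeometryError("label grid does not match coords grid")
        n_az, n_el = self.grid_shape
        if n_az < 8 or n_el < 8:
            raise GeometryError(f"grid dimensions must be >= 8, got {(n_az, n_el)}")
        if not np.all(np.isfinite(self.coords)):
            raise GeometryError("non-finite coordinates")
        if self.age_days < 0:
            raise GeometryError("age_days must be non-negative")
        codes = set(np.unique(self.label).tolist())
        unknown = codes - {int(v) for v in VALID_LABELS}
        if unknown:
            raise GeometryError(f"unknown label codes: {sorted(unknown)}")
        base_rows = np.nonzero(self.label == Label.BASE_BOUNDARY)[1]
        if base_rows.size and base_rows.max() > 0:
            raise GeometryError("BASE_BOUNDARY labels off the lowest-elevation row")
        # Each suture present must form one connected band separating two bones.
        for s in self.sutures_present():
            if not _is_connected(self.label == s):
                raise GeometryError(f"suture {s.name} is not a connected band")
        bone_adjacency(self)  # raises if any suture does not separate exactly 2 bones


def _is_connected(mask: np.ndarray) -> bool:
    """Connectivity of a boolean grid mask, 8-connected with azimuth wrap."""
    idx = np.argwhere(mask)
    if idx.size == 0:
        return True
    n_az = mask.shape[0]
    cells = {tuple(c) for c in idx}
    stack = [tuple(idx[0])]
    seen = {stack[0]}
    while stack:
        i, j = stack.pop()
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                nb = ((i + di) % n_az, j + dj)
                if nb in cells and nb not in seen:
                    seen.add(nb)
                    stack.append(nb)
    return len(seen) == len(cells)


# ---------------------------------------------------------------------------
# Surface frames
# ---------------------------------------------------------------------------

@dataclass
class SurfaceFrames:
    """Per-grid-point orthonormal frame: outward normal and two tangents."""

    normal: np.ndarray    # (n_az, n_el, 3)
    tangent1: np.ndarray  # (n_az, n_el, 3), along increasing azimuth
    tangent2: np.ndarray  # (n_az, n_el, 3), completes right-handed frame


def _grid_partials(coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Central-difference partial derivatives of a (n_az, n_el, 3) field.

    Azimuth is periodic; elevation uses one-sided differences at the edges.
    Derivatives are with respect to the (unit) grid index.
    """
    d_az = 0.5 * (np.roll(coords, -1, axis=0) - np.roll(coords, 1, axis=0))
    d_el = np.empty_like(coords)
    d_el[:, 1:-1] = 0.5 * (coords[:, 2:] - coords[:, :-2])
    d_el[:, 0] = coords[:, 1] - coords[:, 0]
    d_el[:, -1] = coords[:, -1] - coords[:, -2]
    return d_az, d_el


def compute_surface_frames(smap: SphericalMap, *, degenerate_tol: float = 1e-12) -> SurfaceFrames:
    """Per-grid-point orthonormal frame (outward normal, two tangents).

    The normal is the unit cross product of the grid partial derivatives,
    oriented outward (positive dot product with the vector from the surface
    centroid).  ``tangent1`` follows the azimuth direction; ``tangent2``
    completes a right-handed orthonormal frame.
    """
    coords = smap.coords
    d_az, d_el = _grid_partials(coords)
    n = np.cross(d_az, d_el)
    nn = np.linalg.norm(n, axis=-1)
    bad = np.argwhere(nn <= degenerate_tol)
    if bad.size:
        i, j = bad[0]
        raise GeometryError(
            f"degenerate grid cell at (az={i}, el={j}): repeated or collinear coordinates"
        )
    n = n / nn[..., None]
    # orient outward w.r.t. the centroid
    centroid = coords.reshape(-1, 3).mean(axis=0)
    outward = coords - centroid
    flip = np.sum(n * outward, axis=-1) < 0
    n[flip] *= -1.0
    t1 = d_az / np.linalg.norm(d_az, axis=-1)[..., None]
    # re-orthogonalize t1 against n (exact up to rounding already)
    t1 = t1 - np.sum(t1 * n, axis=-1)[..., None] * n
    t1 = t1 / np.linalg.norm(t1, axis=-1)[..., None]
    t2 = np.cross(n, t1)
    return SurfaceFrames(normal=n, tangent1=t1, tangent2=t2)


# ---------------------------------------------------------------------------
# Suture anchors
# ---------------------------------------------------------------------------

@dataclass
class SutureAnchors:
    """Discretized suture control points.

    Arrays are aligned over the anchor axis (length A).  ``grid_index`` holds
    the (az, el) grid location of each anchor; anchor coordinates are always
    the coordinates of that grid point, so anchors advect with the surface.
    ``y`` is the unit outward surface normal for anchors adjacent to the
    cranial-base boundary ring and the zero vector elsewhere.
    """

    suture: np.ndarray       # (A,) uint8 label codes
    grid_index: np.ndarray   # (A, 2) int
    x: np.ndarray            # (A, 3) float64, positions at sampling time
    u: np.ndarray            # (A, 3) float64, unit growth directions
    y: np.ndarray            # (A, 3) float64, unit base-displacement directions or 0

    @property
    def n_anchors(self) -> int:
        return self.suture.size

    @property
    def base_mask(self) -> np.ndarray:
        """True for anchors that carry a base-displacement direction."""
        return np.linalg.norm(self.y, axis=1) > 0.5

    def flat_index(self, n_el: int) -> np.ndarray:
        """Flat grid index (C order over (az, el)) of each anchor."""
        return self.grid_index[:, 0] * n_el + self.grid_index[:, 1]

    def anchors_of(self, suture: Label) -> np.ndarray:
        return np.nonzero(self.suture == int(suture))[0]


def _suture_path(mask: np.ndarray) -> list[tuple[int, int]]:
    """Order the cells of a suture band along the band.

    Builds the 8-connected (azimuth-periodic) adjacency graph of band cells,
    finds the graph-diameter endpoints by double BFS, and returns the
    shortest path between them.  For 1-cell-wide bands this is the band
    itself in order; for wider bands it is a centerline-like traversal.
    """
    cells = [tuple(c) for c in np.argwhere(mask)]
    if not cells:
        return []
    if len(cells) == 1:
        return cells
    n_az = mask.shape[0]
    cellset = set(cells)

    def neighbors(c):
        i, j = c
        for di in (-1, 0, 1):
            for dj in (-1, 0, 1):
                if di == dj == 0:
                    continue
                nb = ((i + di) % n_az, j + dj)
                if nb in cellset:
                    yield nb

    def bfs(start):
        dist = {start: 0}
        parent = {start: None}
        queue = [start]
        while queue:
            nxt = []
            for c in queue:
                for nb in neighbors(c):
                    if nb not in dist:
                        dist[nb] = dist[c] + 1
                        parent[nb] = c
                        nxt.append(nb)
            queue = nxt
        far = max(dist, key=lambda c: (dist[c], c))
        return far, dist, parent

    a, _, _ = bfs(cells[0])
    b, _, parent = bfs(a)
    path = []
    c = b
    while c is not None:
        path.append(c)
        c = parent[c]
    return path[::-1]


def _local_suture_tangent(coords: np.ndarray, mask: np.ndarray,
                          cell: tuple[int, int], radius: int = 3) -> np.ndarray:
    """Suture tangent at ``cell``: leading PCA direction of the suture-labeled
    grid points within a Chebyshev grid radius (azimuth-periodic)."""
    n_az = mask.shape[0]
    i0, j0 = cell
    pts = []
    for i, j in np.argwhere(mask):
        di = min((i - i0) % n_az, (i0 - i) % n_az)
        if di <= radius and abs(j - j0) <= radius:
            pts.append(coords[i, j])
    pts = np.asarray(pts)
    if len(pts) < 2:
        raise GeometryError(f"cannot estimate suture tangent at {cell}: isolated point")
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    return vt[0]


def sample_suture_anchors(smap: SphericalMap, spacing_mm: float,
                          frames: SurfaceFrames | None = None,
                          *, tangent_radius: int = 3) -> SutureAnchors:
    """Uniformly sample anchor control points along every suture band.

    Anchors are placed at grid points of the band, spaced uniformly in arc
    length (band endpoints included).  Each anchor's growth direction ``u``
    lies in the tangent plane, perpendicular to the local suture direction;
    its sign is fixed by a per-suture reference axis so results are
    reproducible (the flow model is invariant to this sign).  ``y`` is the
    outward surface normal for anchors 8-adjacent to the base-boundary ring.
    """
    if spacing_mm <= 0:
        raise GeometryError("spacing_mm must be positive")
    if frames is None:
        frames = compute_surface_frames(smap)
    sutures = smap.sutures_present()
    if not sutures:
        raise GeometryError("map contains no suture-labeled band")

    n_az, _ = smap.grid_shape
    base_cells = set(map(tuple, np.argwhere(smap.label == Label.BASE_BOUNDARY)))

    all_sut, all_idx, all_x, all_u, all_y = [], [], [], [], []
    for s in sutures:
        mask = smap.label == s
        path = _suture_path(mask)
        if len(path) == 0:
            warnings.warn(f"suture {s.name} has no labeled grid points; skipped")
            continue
        pts = np.array([smap.coords[c] for c in path])
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        arclen = np.concatenate([[0.0], np.cumsum(seg)])
        total = arclen[-1]
        if total == 0.0 or total < spacing_mm:
            if total < spacing_mm and len(path) > 1:
                warnings.warn(
                    f"spacing {spacing_mm} mm exceeds suture {s.name} length "
                    f"{total:.2f} mm; placing a single midpoint anchor"
                )
            targets = np.array([0.5 * total])
        else:
            n = max(2, int(round(total / spacing_mm)) + 1)
            targets = np.linspace(0.0, total, n)
        # snap each target arc position to the nearest path cell, deduplicated
        chosen: list[int] = []
        for t in targets:
            kk = int(np.argmin(np.abs(arclen - t)))
            if kk not in chosen:
                chosen.append(kk)
        for kk in chosen:
            cell = path[kk]
            x_a = smap.coords[cell]
            n_a = frames.normal[cell]
            s_dir = _local_suture_tangent(smap.coords, mask, cell, tangent_radius)
            u = np.cross(s_dir, n_a)
            norm_u = np.linalg.norm(u)
            if norm_u < 1e-12:
                raise GeometryError(f"suture tangent parallel to normal at {cell}")
            u = u / norm_u
            # exact orthogonality to the normal (s_dir may have a small
            # out-of-plane component from the PCA neighborhood)
            u = u - np.dot(u, n_a) * n_a
            u = u / np.linalg.norm(u)
            # reproducible sign convention
            if s in _LATERAL_U_SUTURES:
                ref = np.array([1.0, 0.0, 0.0])
            else:
                ref = np.array([0.0, 1.0, 0.0])
            d = np.dot(u, ref)
            if d == 0.0:
                d = np.dot(u, np.array([0.0, 0.0, 1.0]))
            if d < 0:
                u = -u
            adjacent_base = any(
                ((cell[0] + di) % n_az, cell[1] + dj) in base_cells
                for di in (-1, 0, 1) for dj in (-1, 0, 1)
            )
            y = frames.normal[cell].copy() if adjacent_base else np.zeros(3)
            all_sut.append(int(s))
            all_idx.append(cell)
            all_x.append(x_a)
            all_u.append(u)
            all_y.append(y)

    return SutureAnchors(
        suture=np.array(all_sut, dtype=np.uint8),
        grid_index=np.array(all_idx, dtype=int),
        x=np.array(all_x, dtype=float),
        u=np.array(all_u, dtype=float),
        y=np.array(all_y, dtype=float),
    )


def personalize_anchors(anchors: SutureAnchors, smap: SphericalMap,
                        *, tangent_radius: int = 3) -> SutureAnchors:
    """Recompute anchor positions and direction frames on a subject's geometry.

    The anchor set (grid indices and suture assignment) comes from the
    standardized domain; only the Euclidean positions and the ``u``/``y``
    directions are personalized to the subject's own surface.
    """
    frames = compute_surface_frames(smap)
    x = np.empty_like(anchors.x)
    u = np.empty_like(anchors.u)
    y = np.zeros_like(anchors.y)
    base = anchors.base_mask
    for a in range(anchors.n_anchors):
        cell = tuple(anchors.grid_index[a])
        s = Label(int(anchors.suture[a]))
        mask = smap.label == s
        x[a] = smap.coords[cell]
        n_a = frames.normal[cell]
        s_dir = _local_suture_tangent(smap.coords, mask, cell, tangent_radius)
        ua = np.cross(s_dir, n_a)
        ua /= np.linalg.norm(ua)
        ua = ua - np.dot(ua, n_a) * n_a
        ua /= np.linalg.norm(ua)
        # keep the orientation closest to the standardized-domain direction
        if np.dot(ua, anchors.u[a]) < 0:
            ua = -ua
        u[a] = ua
        if base[a]:
            y[a] = n_a
    return SutureAnchors(suture=anchors.suture.copy(), grid_index=anchors.grid_index.copy(),
                         x=x, u=u, y=y)


# ---------------------------------------------------------------------------
# Bone adjacency
# ---------------------------------------------------------------------------

def bone_adjacency(smap: SphericalMap, *, min_contacts: int = 2) -> dict[Label, frozenset[Label]]:
    """Map each suture present to the pair of bone labels it separates.

    Adjacency is derived from 4-connected label contacts on the grid
    (azimuth-periodic).  Point contacts at suture junctions (fewer than
    ``min_contacts`` cell edges) are ignored.  A suture adjacent to a number
    of bones other than two is rejected.
    """
    lab = smap.label
    n_az, n_el = lab.shape
    result: dict[Label, frozenset[Label]] = {}
    bone_codes = {int(b) for b in BONE_LABELS}
    for s in smap.sutures_present():
        counts: dict[int, int] = {}
        cells = np.argwhere(lab == s)
        for i, j in cells:
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                ni, nj = (i + di) % n_az, j + dj
                if 0 <= nj < n_el:
                    code = int(lab[ni, nj])
                    if code in bone_codes:
                        counts[code] = counts.get(code, 0) + 1
        bones = sorted(c for c, n in counts.items() if n >= min_contacts)
        if len(bones) != 2:
            found = {Label(c).name: n for c, n in sorted(counts.items())}
            raise GeometryError(
                f"suture {s.name} adjacent to {len(bones)} bones "
                f"(need exactly 2); contacts found: {found}"
            )
        result[s] = frozenset(Label(b) for b in bones)
    return result


# ---------------------------------------------------------------------------
# Rigid transforms (shared helpers)
# ---------------------------------------------------------------------------

def rotation_matrix(rotvec: np.ndarray) -> np.ndarray:
    """Rotation matrix from an axis-angle (rotation-vector) parameterization."""
    return Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix()


def apply_rigid(coords: np.ndarray, rotvec: np.ndarray, translation: np.ndarray) -> np.ndarray:
    """Apply x -> R(rotvec) x + t to an (..., 3) coordinate array."""
    R = rotation_matrix(rotvec)
    return coords @ R.T + np.asarray(translation, float)
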