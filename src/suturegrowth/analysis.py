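"""Quantitative analysis of growth flows.

Local expansion is summarized by the trace of the Green-Lagrange strain of
the displacement field ``d`` from the reference (birth) surface,

    eps = tr( (grad d + grad d^T + grad d grad d^T) / 2 ),

evaluated intrinsically on the surface: the displacement gradient is formed
from central finite differences along the two grid-parametric directions
and contracted with the inverse first fundamental form of the reference
surface, so the trace sums the two tangential principal directions (normal
derivatives of a surface-sampled field are undefined).  Under a uniform
in-plane stretch by a factor ``s`` the trace equals ``s^2 - 1``.

The module also provides per-bone area-weighted averages, strain rates over
an age series, the cephalic index (lateral / antero-posterior extent), and
the point-wise Euclidean error metric used for fitting and prediction
evaluation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from .geometry import (BONE_LABELS, Label, SphericalMap, _grid_partials)

DAYS_PER_YEAR = 365.25


class AnalysisError(ValueError):
    pass


@dataclass
class StrainField:
    """Per-grid-point Green-Lagrange strain trace at one age."""

    values: np.ndarray          # (n_az, n_el), dimensionless; NaN where degenerate
    age_days: float = np.nan

    def per_bone(self, smap: SphericalMap) -> dict[Label, float]:
        return per_bone_average(self.values, smap)


@dataclass
class ErrorSummary:
    """Point-wise Euclidean distances between two corresponding surfaces."""

    distances: np.ndarray       # (n_az, n_el) or flat, mm
    mean: float
    sd: float
    aligned: bool = False
    subject_id: str = ""

    def __str__(self) -> str:
        return f"{self.mean:.2f} ± {self.sd:.2f} mm"


def strain_trace(ref_map: SphericalMap, deformed: np.ndarray,
                 *, degenerate_tol: float = 1e-12,
                 age_days: float = np.nan) -> StrainField:
    """Trace of the Green-Lagrange strain of ``deformed`` relative to the
    reference surface, computed intrinsically (two tangential directions).

    ``deformed`` must share the reference grid shape.  Zero-area reference
    cells yield NaN at that point.
    """
    deformed = np.asarray(deformed, float)
    if deformed.size != ref_map.coords.size:
        raise AnalysisError(
            f"reference and deformed grids do not match: "
            f"{ref_map.coords.shape} vs {deformed.shape}")
    deformed = deformed.reshape(ref_map.coords.shape)
    Xu, Xv = _grid_partials(ref_map.coords)
    Fu, Fv = _grid_partials(deformed)
    # first fundamental form of the reference
    E = np.einsum("ijk,ijk->ij", Xu, Xu)
    F = np.einsum("ijk,ijk->ij", Xu, Xv)
    G = np.einsum("ijk,ijk->ij", Xv, Xv)
    det = E * G - F * F
    # pulled-back metric of the deformed surface, as differences C - G_ref
    # (keeps the zero-displacement case exactly zero)
    de = np.einsum("ijk,ijk->ij", Fu, Fu) - E
    df = np.einsum("ijk,ijk->ij", Fu, Fv) - F
    dg = np.einsum("ijk,ijk->ij", Fv, Fv) - G
    # covariant strain S = 0.5 (C - G_ref); eps = tr(G^-1 S)
    with np.errstate(divide="ignore", invalid="ignore"):
        eps = 0.5 * (G * de - 2.0 * F * df + E * dg) / det
    eps = np.where(det <= degenerate_tol, np.nan, eps)
    return StrainField(values=eps, age_days=age_days)


def strain_rate(ages_days: np.ndarray, strain_series: np.ndarray) -> np.ndarray:
    """Temporal derivative of a strain series, in year^-1.

    ``strain_series`` has shape (n_ages, ...); central differences inside,
    one-sided at the series endpoints.  Ages must be strictly increasing.
    """
    ages = np.asarray(ages_days, float)
    series = np.asarray(strain_series, float)
    if ages.ndim != 1 or ages.size < 2 or series.shape[0] != ages.size:
        raise AnalysisError("need >= 2 ages matching the series' first axis")
    if np.any(np.diff(ages) <= 0):
        raise AnalysisError("ages must be strictly increasing")
    return np.gradient(series, ages / DAYS_PER_YEAR, axis=0)


def cell_areas(smap: SphericalMap) -> np.ndarray:
    """Per-grid-point surface area weight |X_u x X_v| from the reference metric."""
    Xu, Xv = _grid_partials(smap.coords)
    return np.linalg.norm(np.cross(Xu, Xv), axis=-1)


def per_bone_average(fieldvals: np.ndarray, smap: SphericalMap) -> dict[Label, float]:
    """Area-weighted mean of a per-grid-point field over each bone label.

    NaN field points are excluded; bones with no labeled points are absent
    from the result (reported missing, not zero).
    """
    fieldvals = np.asarray(fieldvals, float).reshape(smap.grid_shape)
    areas = cell_areas(smap)
    out: dict[Label, float] = {}
    for b in BONE_LABELS:
        mask = (smap.label == b) & np.isfinite(fieldvals)
        if not mask.any():
            continue
        w = areas[mask]
        out[b] = float(np.sum(w * fieldvals[mask]) / np.sum(w))
    return out


def cephalic_index(smap_or_coords) -> float:
    """Cephalic index: 100 x lateral extent / antero-posterior extent.

    Uses the standardized pose of the spherical maps (x lateral, y
    antero-posterior); extents are coordinate ranges.
    """
    coords = smap_or_coords.coords if isinstance(smap_or_coords, SphericalMap) \
        else np.asarray(smap_or_coords, float)
    flat = coords.reshape(-1, 3)
    lat = float(np.ptp(flat[:, 0]))
    ap = float(np.ptp(flat[:, 1]))
    if ap <= 0:
        raise AnalysisError("degenerate antero-posterior extent")
    return 100.0 * lat / ap


def _best_fit_rigid(moving: np.ndarray, target: np.ndarray):
    """Least-squares rigid alignment (Kabsch) of ``moving`` onto ``target``."""
    mc = moving.mean(axis=0)
    tc = target.mean(axis=0)
    rot, _ = Rotation.align_vectors(target - tc, moving - mc)
    R = rot.as_matrix()
    t = tc - mc @ R.T
    return R, t


def pointwise_error(pred, obs, *, align: bool = False,
                    subject_id: str = "") -> ErrorSummary:
    """Per-point Euclidean distance between corresponding surfaces.

    With ``align=True`` a best-fit rigid transform of the prediction onto
    the observation is removed first (the evaluation analogue of the rigid
    nuisance transform used during fitting); prediction errors are reported
    unaligned by default.
    """
    P = (pred.coords if isinstance(pred, SphericalMap) else np.asarray(pred, float))
    O = (obs.coords if isinstance(obs, SphericalMap) else np.asarray(obs, float))
    if P.shape != O.shape:
        raise AnalysisError(f"shape mismatch: {P.shape} vs {O.shape}")
    shape = P.shape[:-1]
    P = P.reshape(-1, 3)
    O = O.reshape(-1, 3)
    if align:
        R, t = _best_fit_rigid(P, O)
        P = P @ R.T + t
    d = np.linalg.norm(P - O, axis=1)
    return ErrorSummary(distances=d.reshape(shape), mean=float(d.mean()),
                        sd=float(d.std()), aligned=align, subject_id=subject_id)
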