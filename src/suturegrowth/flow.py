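"""Diffeomorphic cranial growth flow.

Rational velocity profiles and the discretized combined flow.  The local
suture growth rate at anchor ``a`` follows the temporal derivative of a
logarithmic growth curve,

    v_a(t) = 1 / (p0 + p1 t + p2 t^2)     [day^-1],

and the cranial-base displacement velocity ``z_a(t)`` has the same rational
form in mm/day (its sign is unrestricted; the denominator must only stay
away from zero).  The combined transformation is accumulated by explicit
forward Euler with a default step of 5 days:

    x <- x + dt * sum_a w_l^a(m) [ v_a(t) <x - x_a, u_a> u_a + z_a(t) y_a ],

where both the point and the anchor positions are the current (advected)
positions, the weights are the fixed material weights of the grid index
``m``, ``u_a``/``y_a`` are held at their reference-age values, and the
translation term acts only at anchors adjacent to the cranial-base boundary
(``y_a = 0`` elsewhere).  Craniosynostosis is simulated by forcing
``v_a = 0`` for all anchors of the fused sutures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .geometry import Label, SphericalMap, SutureAnchors
from .influence import WeightField

T_MAX_DAYS = 3650.0      # model span: birth to 10 years
EPS_DENOMINATOR = 1e-4   # positivity margin for rational-velocity denominators
DEFAULT_DT_DAYS = 5.0


class FlowError(ValueError):
    pass


def _poly(t, p):
    """Denominator q(t) = p0 + p1 t + p2 t^2 for scalar t, per anchor row."""
    t = float(t) if np.isscalar(t) else np.asarray(t, float)
    p = np.asarray(p, float)
    if p.ndim == 1:
        return p[0] + p[1] * t + p[2] * t * t
    return p[:, 0] + p[:, 1] * t + p[:, 2] * t * t


def growth_rate(t, p_v, *, eps_den: float = EPS_DENOMINATOR):
    """Suture growth rate v(t) = 1/(p0 + p1 t + p2 t^2), in day^-1.

    The denominator must stay above ``eps_den`` (growth rates are strictly
    positive); violation is rejected as an invariant breach.
    """
    q = _poly(t, p_v)
    if np.any(q < eps_den):
        raise FlowError(f"growth-rate denominator below {eps_den} at requested age")
    return 1.0 / q


def base_displacement_rate(t, p_z, *, eps_den: float = EPS_DENOMINATOR):
    """Base displacement velocity z(t) = 1/(p0 + p1 t + p2 t^2), in mm/day.

    Sign-unrestricted; the denominator must only stay away from zero.
    """
    q = _poly(t, p_z)
    if np.any(np.abs(q) < eps_den):
        raise FlowError(f"displacement-rate denominator within {eps_den} of zero")
    return 1.0 / q


@dataclass
class VelocityParams:
    """Per-anchor rational-velocity parameters.

    ``p_v`` has shape (A, 3); ``p_z`` has shape (A, 3) with rows of
    non-base anchors ignored (those anchors have ``y_a = 0``).  An all-zero
    coefficient row denotes an identically zero rate (the rational form
    itself cannot represent v = 0), so a fully static model is expressible.
    """

    p_v: np.ndarray
    p_z: np.ndarray

    def __post_init__(self):
        self.p_v = np.atleast_2d(np.asarray(self.p_v, float))
        self.p_z = np.atleast_2d(np.asarray(self.p_z, float))

    @property
    def n_anchors(self) -> int:
        return self.p_v.shape[0]

    @staticmethod
    def zero(n_anchors: int) -> "VelocityParams":
        """The static model: all growth and displacement rates identically 0."""
        return VelocityParams(p_v=np.zeros((n_anchors, 3)),
                              p_z=np.zeros((n_anchors, 3)))

    def rates_at(self, t: float, base_mask: np.ndarray | None = None):
        """Per-anchor (v, z) at age ``t``, honoring the zero-row convention
        and restricting z to base-adjacent anchors."""
        v = np.zeros(self.n_anchors)
        live = np.any(self.p_v != 0.0, axis=1)
        if live.any():
            v[live] = growth_rate(t, self.p_v[live])
        z = np.zeros(self.n_anchors)
        zrows = np.any(self.p_z != 0.0, axis=1)
        if base_mask is not None:
            zrows &= base_mask
        if zrows.any():
            z[zrows] = base_displacement_rate(t, self.p_z[zrows])
        return v, z

    def validate(self, base_mask: np.ndarray | None = None,
                 t_max: float = T_MAX_DAYS, *, eps_den: float = EPS_DENOMINATOR,
                 check_dt: float = 1.0) -> None:
        """Check denominator positivity on a dense time grid over [0, t_max].

        All-zero rows (identically zero rates) are exempt.
        """
        t = np.arange(0.0, t_max + check_dt, check_dt)
        live = np.any(self.p_v != 0.0, axis=1)
        qv = self.p_v[live, 0:1] + self.p_v[live, 1:2] * t + self.p_v[live, 2:3] * t * t
        if np.any(qv < eps_den):
            a = int(np.nonzero(live)[0][np.argwhere(np.any(qv < eps_den, axis=1))[0][0]])
            raise FlowError(f"growth-rate denominator of anchor {a} drops below "
                            f"{eps_den} within [0, {t_max}] days")
        rows = np.ones(self.p_z.shape[0], bool) if base_mask is None else base_mask.copy()
        rows &= np.any(self.p_z != 0.0, axis=1)
        if rows.any():
            pz = self.p_z[rows]
            qz = pz[:, 0:1] + pz[:, 1:2] * t + pz[:, 2:3] * t * t
            if np.any(np.abs(qz) < eps_den):
                raise FlowError("displacement-rate denominator approaches zero "
                                f"within [0, {t_max}] days")


@dataclass
class FlowSpec:
    """Integration interval, step, and the set of fused sutures."""

    t0: float
    T: float
    dt: float = DEFAULT_DT_DAYS
    fused_sutures: frozenset = field(default_factory=frozenset)

    def __post_init__(self):
        if self.dt <= 0:
            raise FlowError("dt must be positive")
        if self.t0 > self.T:
            raise FlowError("t0 must not exceed T")
        self.fused_sutures = frozenset(Label(s) for s in self.fused_sutures)

    def step_times(self) -> np.ndarray:
        """Left endpoints of the Euler steps and the per-step durations."""
        span = self.T - self.t0
        if span == 0.0:
            return np.empty((0, 2))
        if self.dt > span:
            warnings.warn("dt exceeds the integration span; taking one clamped step")
            return np.array([[self.t0, span]])
        n_full = int(np.floor(span / self.dt + 1e-9))
        times = self.t0 + self.dt * np.arange(n_full)
        steps = np.column_stack([times, np.full(n_full, self.dt)])
        covered = n_full * self.dt
        if span - covered > 1e-9:
            steps = np.vstack([steps, [self.t0 + covered, span - covered]])
        return steps


@dataclass
class FlowResult:
    """Final coordinates of a flow, with optional trajectory and snapshots."""

    final: np.ndarray                     # (n_az, n_el, 3)
    times: np.ndarray                     # step left endpoints
    snapshots: dict = field(default_factory=dict)   # step index -> (M, 3)
    trajectory: np.ndarray | None = None  # (n_steps+1, M, 3)


def _fused_mask(anchors: SutureAnchors, fused) -> np.ndarray:
    """Boolean anchor mask: True where v_a is forced to zero by suture fusion."""
    mask = np.zeros(anchors.n_anchors, dtype=bool)
    for s in fused:
        idx = anchors.anchors_of(Label(s))
        if idx.size == 0:
            raise FlowError(f"fused suture {Label(s).name} has no anchors in the map")
        mask[idx] = True
    return mask


def integrate_flow(smap: SphericalMap, anchors: SutureAnchors, weights: WeightField,
                   vel: VelocityParams, spec: FlowSpec, *,
                   start_coords: np.ndarray | None = None,
                   record_trajectory: bool = False,
                   snapshot_steps=None,
                   reverse: bool = False,
                   recompute_directions: bool = False) -> FlowResult:
    """Integrate the combined growth flow with explicit forward Euler.

    ``start_coords`` (default: the map's coordinates) are advanced from
    ``spec.t0`` to ``spec.T``.  With ``reverse=True`` the same step sequence
    is applied backward with negated velocities, starting from coordinates
    at ``spec.T`` and returning coordinates at ``spec.t0`` (the numerical
    inverse of the forward pass).  ``snapshot_steps`` collects intermediate
    coordinates after the given step counts (forward mode only).

    By default the anchor directions ``u_a``/``y_a`` stay at their
    reference-age values; ``recompute_directions=True`` re-derives them
    from the advected geometry at every step (a sensitivity-study option;
    slower, and no longer exactly reversible with ``reverse=True``).
    """
    n_az, n_el = smap.grid_shape
    X0 = smap.flat_coords() if start_coords is None else np.asarray(start_coords, float).reshape(-1, 3)
    if X0.shape[0] != smap.n_points:
        raise FlowError("start coordinates do not match the map grid")
    A = anchors.n_anchors
    if vel.n_anchors != A or weights.values.shape[1] != A:
        raise FlowError("anchors, weights and velocity parameters are inconsistent")

    W = weights.values
    U = anchors.u
    Y = anchors.y
    anchor_rows = anchors.flat_index(n_el)
    fused = _fused_mask(anchors, spec.fused_sutures)
    base = anchors.base_mask

    steps = spec.step_times()
    n_steps = steps.shape[0]
    X = X0.copy()
    snapshots = {}
    if snapshot_steps is not None:
        snapshot_steps = set(int(s) for s in snapshot_steps)
        if 0 in snapshot_steps:
            snapshots[0] = X.copy()
    traj = [X.copy()] if record_trajectory else None

    order = range(n_steps) if not reverse else range(n_steps - 1, -1, -1)
    sign = 1.0 if not reverse else -1.0
    for i in order:
        t, dt_i = steps[i]
        if recompute_directions:
            from .geometry import personalize_anchors
            current = smap.copy(coords=X.reshape(smap.coords.shape))
            pers = personalize_anchors(anchors, current)
            U, Y = pers.u, pers.y
        v, z = vel.rates_at(t, base)
        v = np.where(fused, 0.0, v)
        # projection <x - x_a, u_a> for every (point, anchor) pair
        s_proj = X @ U.T - np.einsum("aj,aj->a", X[anchor_rows], U)[None, :]
        disp = ((W * (v[None, :] * s_proj)) @ U) + ((W * z[None, :]) @ Y)
        X = X + sign * dt_i * disp
        if not np.all(np.isfinite(X)):
            raise FlowError(f"non-finite coordinates at integration step {i} (t={t})")
        if traj is not None:
            traj.append(X.copy())
        if snapshot_steps is not None and not reverse and (i + 1) in snapshot_steps:
            snapshots[i + 1] = X.copy()

    return FlowResult(
        final=X.reshape(n_az, n_el, 3),
        times=steps[:, 0],
        snapshots=snapshots,
        trajectory=np.array(traj) if traj is not None else None,
    )


def simulate_synostosis(smap: SphericalMap, anchors: SutureAnchors, weights: WeightField,
                        vel: VelocityParams, spec: FlowSpec, **kwargs) -> FlowResult:
    """Growth flow with the fused sutures' growth rates forced to zero.

    Identical to :func:`integrate_flow`; this entry point validates the
    fused suture labels against the map and flags lambdoid fusion, whose
    phenotype has no validated reference behavior in this model.
    """
    present = set(smap.sutures_present())
    for s in spec.fused_sutures:
        if Label(s) not in present:
            raise FlowError(f"unknown or absent fused suture: {Label(s).name}")
        if Label(s) in (Label.LL, Label.RL):
            warnings.warn("lambdoid fusion is mechanically supported but has no "
                          "validated phenotype reference in this model")
    return integrate_flow(smap, anchors, weights, vel, spec, **kwargs)


def invert_flow(smap: SphericalMap, anchors: SutureAnchors, weights: WeightField,
                vel: VelocityParams, spec: FlowSpec,
                final_coords: np.ndarray) -> FlowResult:
    """Integrate the negated velocity field backward from T to t0.

    Returns coordinates at ``spec.t0``; applied to the output of the forward
    flow this is the numerical inverse, with an error that vanishes at first
    order as ``dt -> 0`` (the diffeomorphism surrogate check).
    """
    return integrate_flow(smap, anchors, weights, vel, spec,
                          start_coords=final_coords, reverse=True)
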