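"""Statistical inference of the growth model from a cross-sectional cohort.

All model parameters -- the per-anchor rational-velocity coefficients
``p_v`` and ``p_z``, the weight-shape parameters ``k`` and ``Sigma_l``, and
one rigid nuisance transform per subject -- are estimated jointly by
minimizing the size-normalized discrepancy between the model's predicted
average development and every observed map:

    L = (1/N) sum_s (1/M) sum_m  || Phi(I0(m), t_s) - (R(theta_s) I_s(m) + tau_s) ||
                                 / || I_s(m) ||,

where ``Phi`` is the discretized growth flow started from the birth
template ``I0``.  Because the cohort is cross-sectional and every subject's
prediction starts from the same template, a single forward integration of
the flow (snapshotted at each subject's age) evaluates the whole objective.

Gradients are computed analytically by reverse-mode (adjoint)
differentiation of the forward-Euler recursion, including the chain through
the normalized anchor weights to ``k`` and the isotropic kernel scales, and
through the axis-angle parameterization of the rigid transforms; they are
validated against finite differences in the test suite.  Optimization uses
Adam with a preconditioning scale per parameter block (equivalent to
optimizing in nondimensionalized coordinates), an initial learning rate of
0.01, and denominator positivity enforced by a soft hinge penalty plus a
hard validity check on the returned parameters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .geometry import (Label, SphericalMap, SutureAnchors,
                       sample_suture_anchors, personalize_anchors,
                       rotation_matrix)
from .influence import (WeightShapeParams, WeightField, normalize_weights,
                        build_weight_field, isotropic_sigma,
                        DEFAULT_SUPPORT_THRESHOLD)
from .flow import (FlowSpec, FlowResult, VelocityParams, integrate_flow,
                   T_MAX_DAYS, EPS_DENOMINATOR, DEFAULT_DT_DAYS)

logger = logging.getLogger(__name__)


class InferenceError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Rigid transforms and their derivatives
# ---------------------------------------------------------------------------

def _hat(v: np.ndarray) -> np.ndarray:
    return np.array([[0.0, -v[2], v[1]],
                     [v[2], 0.0, -v[0]],
                     [-v[1], v[0], 0.0]])


def rotation_jacobian(rotvec: np.ndarray) -> np.ndarray:
    """d R / d rotvec for the axis-angle parameterization.

    Returns an array J with ``J[i] = dR/d rotvec_i`` (each 3x3), using the
    closed form of Gallego & Yezzi; the limit ``J[i] = hat(e_i)`` applies at
    the identity.
    """
    v = np.asarray(rotvec, float)
    n2 = float(v @ v)
    J = np.empty((3, 3, 3))
    if n2 < 1e-16:
        for i in range(3):
            e = np.zeros(3)
            e[i] = 1.0
            J[i] = _hat(e)
        return J
    R = rotation_matrix(v)
    I = np.eye(3)
    for i in range(3):
        e = np.zeros(3)
        e[i] = 1.0
        J[i] = (v[i] * _hat(v) + _hat(np.cross(v, (I - R) @ e))) @ R / n2
    return J


# ---------------------------------------------------------------------------
# Problem setup
# ---------------------------------------------------------------------------

@dataclass
class FitConfig:
    """Configuration of the model fit."""

    anchor_spacing_mm: float = 10.0
    dt_days: float = DEFAULT_DT_DAYS
    iters: int = 400
    lr: float = 0.02
    lr_decay: float = 0.1          # final/initial learning-rate ratio (exponential)
    seed: int = 0
    optimize_weights: bool = True
    optimize_rigid: bool = True
    optimize_base: bool = True   # fit the base-displacement profiles p_z
    freeze_weights_frac: float = 0.4  # fraction of the run with k, sigma held
                                      # at init while the velocities converge
    k_init: float = 0.5
    sigma_init_mm: float = 20.0
    init_v0: float = 0.1 / 365.0   # first-year integrated growth ~ 10% of size
    init_z0: float = 0.01          # mm/day
    penalty_weight: float = 1e-3
    penalty_margin: float = 50.0   # q(t) kept above this (caps rates at 1/50 per day)
    penalty_grid_days: float = 30.0
    grad_clip: float = 1.0         # max |preconditioned gradient| per coordinate
    eps_den: float = EPS_DENOMINATOR
    t_max: float = T_MAX_DAYS
    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD
    max_restarts: int = 3
    template_bandwidth_days: float = 90.0


@dataclass
class GrowthModelParams:
    """The fitted model: anchors of the standardized domain, weight-shape
    parameters, and per-anchor velocity parameters."""

    anchors: SutureAnchors
    shape: WeightShapeParams
    vel: VelocityParams
    weights: WeightField | None = None

    def weight_field(self, template: SphericalMap,
                     support_threshold: float = DEFAULT_SUPPORT_THRESHOLD) -> WeightField:
        if self.weights is None:
            self.weights = build_weight_field(template, self.anchors, self.shape,
                                              support_threshold)
        return self.weights


@dataclass
class FitReport:
    """Outcome of a model fit."""

    final_loss: float
    loss_trajectory: np.ndarray
    best_trajectory: np.ndarray     # running best-so-far (non-increasing)
    params: GrowthModelParams
    rigid: np.ndarray               # (S, 6) rotvec + translation per subject
    per_subject_error_mm: np.ndarray
    converged: bool
    n_restarts: int = 0
    config: FitConfig | None = None


class _Problem:
    """Precomputed quantities shared by objective and gradient evaluations."""

    def __init__(self, template: SphericalMap, cohort, config: FitConfig,
                 anchors: SutureAnchors | None = None):
        self.template = template
        self.config = config
        self.anchors = anchors if anchors is not None else sample_suture_anchors(
            template, config.anchor_spacing_mm)
        self.n_el = template.grid_shape[1]
        self.anchor_rows = self.anchors.flat_index(self.n_el)
        self.U = self.anchors.u
        self.Y = self.anchors.y
        self.base_mask = self.anchors.base_mask
        self.A = self.anchors.n_anchors
        self.M = template.n_points
        self.X0 = template.flat_coords()

        # cached weight-field ingredients (geometry is fixed during the fit)
        ref = build_weight_field(template, self.anchors,
                                 WeightShapeParams.isotropic(
                                     template.sutures_present(),
                                     k=config.k_init, sigma_mm=config.sigma_init_mm),
                                 config.support_threshold)
        self.D = ref.dist        # (M, A) suture distance per anchor column
        self.R2 = ref.sq_dist    # (M, A) squared distance to anchor

        self.suture_list = sorted(set(int(s) for s in self.anchors.suture))
        self.suture_of_anchor = np.array(
            [self.suture_list.index(int(s)) for s in self.anchors.suture])

        # observations
        self.N = cohort.n_subjects
        self.obs = np.stack([m.flat_coords() for m in cohort.maps])      # (S, M, 3)
        self.obs_norm = np.linalg.norm(self.obs, axis=2)                  # (S, M)
        zero = self.obs_norm <= 0.0
        if zero.any():
            logger.info("excluding %d zero-norm observation points", int(zero.sum()))
        self.alpha = np.zeros_like(self.obs_norm)
        self.alpha[~zero] = 1.0 / (self.N * self.M * self.obs_norm[~zero])
        ages = np.asarray(cohort.ages, float)
        if np.any(ages < 0) or np.any(ages > config.t_max):
            raise InferenceError("subject ages outside the model span")
        self.steps = np.rint(ages / config.dt_days).astype(int)           # (S,)
        self.n_steps = int(self.steps.max())
        self.dt = config.dt_days
        # subjects grouped by their snapshot step
        self.by_step: dict[int, np.ndarray] = {}
        for n in np.unique(self.steps):
            self.by_step[int(n)] = np.nonzero(self.steps == n)[0]
        # time grid of the penalty
        self.t_pen = np.arange(0.0, config.t_max + config.penalty_grid_days,
                               config.penalty_grid_days)

    # -- weights ------------------------------------------------------------

    def weight_field_values(self, log_k: float, log_sigma: np.ndarray):
        """Normalized weights and cached pieces for the shape-parameter chain."""
        k = math.exp(log_k)
        s_a = np.exp(-2.0 * log_sigma)[self.suture_of_anchor]       # (A,)
        raw = np.exp(-k * self.D - 0.5 * s_a[None, :] * self.R2)
        wf = normalize_weights(raw, self.config.support_threshold)
        return wf, raw, k, s_a

    def shape_params(self, log_k: float, log_sigma: np.ndarray) -> WeightShapeParams:
        sigma = {Label(s): isotropic_sigma(math.exp(log_sigma[j]))
                 for j, s in enumerate(self.suture_list)}
        return WeightShapeParams(k=math.exp(log_k), sigma=sigma)

    # -- rigid --------------------------------------------------------------

    def transformed_obs(self, theta: np.ndarray) -> np.ndarray:
        out = np.empty_like(self.obs)
        for s in range(self.N):
            R = rotation_matrix(theta[s, :3])
            out[s] = self.obs[s] @ R.T + theta[s, 3:]
        return out

    # -- forward + loss -----------------------------------------------------

    def _rates(self, t: float, p_v: np.ndarray, p_z: np.ndarray):
        qv = p_v[:, 0] + p_v[:, 1] * t + p_v[:, 2] * t * t
        v = 1.0 / qv
        z = np.zeros(self.A)
        qz = np.ones(self.A)
        if self.base_mask.any():
            b = self.base_mask
            qz_b = p_z[b, 0] + p_z[b, 1] * t + p_z[b, 2] * t * t
            z[b] = 1.0 / qz_b
            qz[b] = qz_b
        return v, z, qv, qz

    def all_rates(self, p_v, p_z):
        """Rates v_a(t), z_a(t) at every step's left endpoint, (n_steps, A)."""
        t = self.dt * np.arange(self.n_steps)[:, None]
        qv = p_v[None, :, 0] + p_v[None, :, 1] * t + p_v[None, :, 2] * t * t
        v = 1.0 / qv
        z = np.zeros((self.n_steps, self.A))
        b = self.base_mask
        if b.any():
            qz = p_z[None, b, 0] + p_z[None, b, 1] * t + p_z[None, b, 2] * t * t
            z[:, b] = 1.0 / qz
        return v, z, qv

    def forward(self, p_v, p_z, W, store: bool):
        """Forward-Euler integration from the template; optionally store the
        whole state trajectory for the adjoint pass."""
        X = self.X0.copy()
        states = [X] if store else None
        rows = self.anchor_rows
        U, Y = self.U, self.Y
        v_all, z_all, _ = self.all_rates(p_v, p_z)
        for i in range(self.n_steps):
            v, z = v_all[i], z_all[i]
            s_proj = X @ U.T - np.einsum("aj,aj->a", X[rows], U)[None, :]
            X = X + self.dt * (((W * (v[None, :] * s_proj)) @ U)
                               + ((W * z[None, :]) @ Y))
            if store:
                states.append(X)
        if not np.all(np.isfinite(X)):
            raise FloatingPointError("flow diverged (non-finite coordinates)")
        return X, states

    def loss_only(self, params: dict) -> float:
        W = self.weight_field_values(params["log_k"], params["log_sigma"])[0].values
        p_v, p_z = params["p_v"], params["p_z"]
        theta = params["theta"]
        X = self.X0.copy()
        rows, U, Y = self.anchor_rows, self.U, self.Y
        tobs = self.transformed_obs(theta)
        v_all, z_all, _ = self.all_rates(p_v, p_z)
        loss = 0.0
        if 0 in self.by_step:
            loss += self._loss_at(X, self.by_step[0], tobs)
        for i in range(self.n_steps):
            v, z = v_all[i], z_all[i]
            s_proj = X @ U.T - np.einsum("aj,aj->a", X[rows], U)[None, :]
            X = X + self.dt * (((W * (v[None, :] * s_proj)) @ U)
                               + ((W * z[None, :]) @ Y))
            if (i + 1) in self.by_step:
                loss += self._loss_at(X, self.by_step[i + 1], tobs)
        return loss + self._penalty(p_v, p_z)[0]

    def _loss_at(self, X, subj_idx, tobs) -> float:
        total = 0.0
        for s in subj_idx:
            r = X - tobs[s]
            total += float(np.sum(self.alpha[s] * np.linalg.norm(r, axis=1)))
        return total

    def _penalty(self, p_v, p_z):
        """Hinge penalty keeping rational-velocity denominators positive.

        The hinge fires once a denominator drops below ``penalty_margin``
        (well before the hard validity bound ``eps_den``), so the barrier
        engages while gradients are still moderate instead of after the
        rates have already blown up.
        """
        w = self.config.penalty_weight
        eps = self.config.penalty_margin
        t = self.t_pen
        qv = p_v[:, 0:1] + p_v[:, 1:2] * t + p_v[:, 2:3] * t * t   # (A, T)
        hv = np.maximum(0.0, eps - qv)
        g_pv = np.zeros_like(p_v)
        val = w * float(np.sum(hv ** 2))
        if hv.any():
            coef = -2.0 * w * hv                                   # dP/dq
            g_pv[:, 0] = coef.sum(axis=1)
            g_pv[:, 1] = (coef * t).sum(axis=1)
            g_pv[:, 2] = (coef * t * t).sum(axis=1)
        g_pz = np.zeros_like(p_z)
        b = self.base_mask
        if b.any():
            qz = p_z[b, 0:1] + p_z[b, 1:2] * t + p_z[b, 2:3] * t * t
            hz = np.maximum(0.0, eps - np.abs(qz))
            val += w * float(np.sum(hz ** 2))
            if hz.any():
                coef = -2.0 * w * hz * np.sign(qz)
                gz = np.zeros((int(b.sum()), 3))
                gz[:, 0] = coef.sum(axis=1)
                gz[:, 1] = (coef * t).sum(axis=1)
                gz[:, 2] = (coef * t * t).sum(axis=1)
                g_pz[b] = gz
        return val, g_pv, g_pz

    # -- loss + full analytic gradient --------------------------------------

    def loss_and_grad(self, params: dict):
        p_v, p_z, theta = params["p_v"], params["p_z"], params["theta"]
        log_k, log_sigma = params["log_k"], params["log_sigma"]
        wf, raw, k, s_a = self.weight_field_values(log_k, log_sigma)
        W = wf.values
        rows, U, Y = self.anchor_rows, self.U, self.Y
        dt = self.dt

        X_final, states = self.forward(p_v, p_z, W, store=True)
        tobs = self.transformed_obs(theta)

        # loss and the per-snapshot adjoint seeds dL/dX(step)
        loss = 0.0
        seeds: dict[int, np.ndarray] = {}
        g_theta = np.zeros_like(theta)
        for n, subj_idx in self.by_step.items():
            X = states[n]
            seed = np.zeros((self.M, 3))
            for s in subj_idx:
                r = X - tobs[s]
                nr = np.linalg.norm(r, axis=1)
                loss += float(np.sum(self.alpha[s] * nr))
                rh = np.zeros_like(r)
                nz = nr > 1e-12
                rh[nz] = r[nz] / nr[nz, None]
                dl_dpred = self.alpha[s][:, None] * rh
                seed += dl_dpred
                # rigid gradient: obs enters with a minus sign
                dl_dobs = -dl_dpred
                g_theta[s, 3:] = dl_dobs.sum(axis=0)
                dR = dl_dobs.T @ self.obs[s]                      # dL/dR (3,3)
                J = rotation_jacobian(theta[s, :3])
                for i3 in range(3):
                    g_theta[s, i3] = float(np.sum(J[i3] * dR))
            seeds[n] = seed

        # adjoint sweep
        lam = np.zeros((self.M, 3))
        g_pv = np.zeros_like(p_v)
        g_pz = np.zeros_like(p_z)
        G_W = np.zeros_like(W)
        v_all, z_all, qv_all = self.all_rates(p_v, p_z)
        for i in range(self.n_steps - 1, -1, -1):
            if (i + 1) in seeds:
                lam = lam + seeds[i + 1]
            X = states[i]
            t = i * dt
            v, z = v_all[i], z_all[i]
            s_proj = X @ U.T - np.einsum("aj,aj->a", X[rows], U)[None, :]
            udot = lam @ U.T                                       # (M, A)
            ydot = lam @ Y.T
            # parameter-side accumulations
            G_W += dt * (v[None, :] * s_proj * udot + z[None, :] * ydot)
            g_v_step = dt * np.einsum("ma,ma->a", W, s_proj * udot)
            dv_dq = -v * v
            for j3 in range(3):
                g_pv[:, j3] += g_v_step * dv_dq * t ** j3
            if self.base_mask.any():
                b = self.base_mask
                g_z_step = dt * np.einsum("ma,ma->a", W, ydot)[b]
                dz_dq = -(z[b] ** 2)
                for j3 in range(3):
                    g_pz[b, j3] += g_z_step * dz_dq * t ** j3
            # state adjoint
            wvu = W * (v[None, :] * udot)                          # (M, A)
            lam_new = lam + dt * (wvu @ U)
            c = v * np.einsum("ma,ma->a", W, udot)                 # (A,)
            np.subtract.at(lam_new, rows, dt * c[:, None] * U)
            lam = lam_new

        # chain through the weight normalization to (log_k, log_sigma)
        g_log_k = 0.0
        g_log_sigma = np.zeros_like(np.asarray(log_sigma, float))
        if self.config.optimize_weights:
            total = wf.raw.sum(axis=1)
            sup = ~wf.static
            dL_draw = np.zeros_like(raw)
            inner = np.einsum("ma,ma->m", G_W, W)
            dL_draw[sup] = (G_W[sup] - inner[sup, None]) / total[sup, None]
            dL_draw[wf.raw <= 0.0] = 0.0
            g_log_k = float(np.sum(dL_draw * raw * (-k * self.D)))
            per_anchor = np.einsum("ma,ma->a", dL_draw, raw * self.R2) * s_a
            np.add.at(g_log_sigma, self.suture_of_anchor, per_anchor)

        pen, pg_v, pg_z = self._penalty(p_v, p_z)
        loss += pen
        g_pv += pg_v
        g_pz += pg_z
        if not self.config.optimize_rigid:
            g_theta[:] = 0.0
        grads = {"p_v": g_pv, "p_z": g_pz, "theta": g_theta,
                 "log_k": g_log_k, "log_sigma": g_log_sigma}
        return loss, grads


# ---------------------------------------------------------------------------
# Public objective
# ---------------------------------------------------------------------------

def objective(vel: VelocityParams, shape: WeightShapeParams, rigid: np.ndarray,
              template: SphericalMap, cohort, *,
              anchors: SutureAnchors | None = None,
              config: FitConfig | None = None) -> float:
    """Evaluate the population objective at the given parameters.

    ``rigid`` is (S, 6) axis-angle + translation per subject.  The isotropic
    kernel scale of each suture is read off ``shape``; anisotropic ``Sigma``
    is supported through :func:`suturegrowth.influence.build_weight_field`
    but not through the fast fitting path.
    """
    cfg = config or FitConfig()
    prob = _Problem(template, cohort, cfg, anchors)
    params = _pack(prob, vel, shape, rigid)
    return prob.loss_only(params)


def _pack(prob: _Problem, vel: VelocityParams, shape: WeightShapeParams,
          rigid: np.ndarray) -> dict:
    log_sigma = np.empty(len(prob.suture_list))
    for j, s in enumerate(prob.suture_list):
        sig = shape.sigma[Label(s)]
        scale = float(np.mean(np.diag(sig)))
        log_sigma[j] = -0.5 * math.log(scale)   # Sigma = sigma_mm^-2 I
    return {
        "p_v": np.array(vel.p_v, float),
        "p_z": np.array(vel.p_z, float),
        "theta": np.array(rigid, float).reshape(prob.N, 6),
        "log_k": math.log(shape.k),
        "log_sigma": log_sigma,
    }


# ---------------------------------------------------------------------------
# Adam with per-block preconditioning
# ---------------------------------------------------------------------------

class _Adam:
    """Adam in preconditioned coordinates p/scale, with per-coordinate
    gradient clipping so rare penalty spikes cannot poison the second-moment
    state (which would freeze the affected parameters for the whole run)."""

    def __init__(self, shapes: dict, scales: dict, lr: float,
                 beta1=0.9, beta2=0.999, eps=1e-8, clip=1.0):
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.scales = scales
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.clip = clip
        self.t = 0

    def step(self, params: dict, grads: dict) -> dict:
        self.t += 1
        out = {}
        for key, p in params.items():
            g = np.asarray(grads[key], float) * self.scales[key]
            if self.clip:
                g = np.clip(g, -self.clip, self.clip)
            self.m[key] = self.b1 * self.m[key] + (1 - self.b1) * g
            self.v[key] = self.b2 * self.v[key] + (1 - self.b2) * g * g
            mh = self.m[key] / (1 - self.b1 ** self.t)
            vh = self.v[key] / (1 - self.b2 ** self.t)
            out[key] = p - self.lr * self.scales[key] * mh / (np.sqrt(vh) + self.eps)
        return out


def _copy_params(params: dict) -> dict:
    return {k: (v.copy() if isinstance(v, np.ndarray) else v) for k, v in params.items()}


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def initial_params(prob: _Problem, config: FitConfig) -> dict:
    """Documented initialization: flat growth at ``init_v0`` per day, flat
    base displacement at ``init_z0`` mm/day, k and sigma at their configured
    starting values, rigid transforms at the identity."""
    A = prob.A
    p_v = np.zeros((A, 3))
    p_v[:, 0] = 1.0 / config.init_v0
    p_z = np.zeros((A, 3))
    p_z[:, 0] = 1.0 / config.init_z0
    return {
        "p_v": p_v,
        "p_z": p_z,
        "theta": np.zeros((prob.N, 6)),
        "log_k": math.log(config.k_init),
        "log_sigma": np.full(len(prob.suture_list), math.log(config.sigma_init_mm)),
    }


def _scales(prob: _Problem, config: FitConfig) -> dict:
    """Per-block step scales: the characteristic magnitude of each parameter,
    so a unit Adam step moves every block by a comparable relative amount."""
    p0 = 1.0 / config.init_v0
    q0 = 1.0 / config.init_z0
    # characteristic time of the polynomial coefficients: long enough that a
    # single step cannot flip the sign of q(t) anywhere in [0, t_max]
    t_char = 1500.0
    sv = np.array([p0, p0 / t_char, p0 / t_char ** 2])
    sz = np.array([q0, q0 / t_char, q0 / t_char ** 2])
    if not config.optimize_base:
        sz[:] = 0.0
    theta_scale = np.concatenate([np.full(3, 0.05), np.full(3, 2.0)])
    if not config.optimize_rigid:
        theta_scale[:] = 0.0
    w_scale = 1.0 if config.optimize_weights else 0.0
    return {
        "p_v": np.broadcast_to(sv, (prob.A, 3)).copy(),
        "p_z": np.broadcast_to(sz, (prob.A, 3)).copy(),
        "theta": np.broadcast_to(theta_scale, (prob.N, 6)).copy(),
        "log_k": w_scale,
        "log_sigma": np.full(len(prob.suture_list), w_scale),
    }


def fit_model(cohort, template: SphericalMap, config: FitConfig | None = None,
              *, anchors: SutureAnchors | None = None,
              callback=None) -> FitReport:
    """Fit all model parameters to a cross-sectional cohort with Adam.

    Deterministic given the config (full-batch gradients, fixed
    initialization).  On numerical divergence (non-finite loss) the learning
    rate is halved and optimization restarts from the last valid state, at
    most ``config.max_restarts`` times.
    """
    cfg = config or FitConfig()
    if cohort.n_subjects < 2:
        raise InferenceError("cohort must contain at least 2 subjects")
    prob = _Problem(template, cohort, cfg, anchors)
    params = initial_params(prob, cfg)
    scales = _scales(prob, cfg)
    shapes = {k: np.shape(v) for k, v in params.items()}
    lr = cfg.lr
    adam = _Adam(shapes, scales, lr, clip=cfg.grad_clip)
    best_loss = np.inf
    best_params = _copy_params(params)
    last_valid = _copy_params(params)
    traj, best_traj = [], []
    restarts = 0
    it = 0
    while it < cfg.iters:
        try:
            loss, grads = prob.loss_and_grad(params)
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite loss")
        except FloatingPointError:
            restarts += 1
            if restarts > cfg.max_restarts:
                raise InferenceError(
                    f"optimization diverged after {restarts - 1} restarts; "
                    f"best loss {best_loss:.6g}")
            lr *= 0.5
            logger.warning("divergence: restarting from last valid state, lr=%g", lr)
            params = _copy_params(last_valid)
            adam = _Adam(shapes, scales, lr, clip=cfg.grad_clip)
            continue
        traj.append(loss)
        if loss < best_loss:
            best_loss = loss
            best_params = _copy_params(params)
        best_traj.append(best_loss)
        last_valid = _copy_params(params)
        if callback is not None:
            callback(it, loss, params)
        adam.lr = lr * cfg.lr_decay ** (it / max(cfg.iters - 1, 1))
        if cfg.optimize_weights and it < cfg.freeze_weights_frac * cfg.iters:
            grads = dict(grads)
            grads["log_k"] = 0.0
            grads["log_sigma"] = np.zeros_like(grads["log_sigma"])
        params = adam.step(params, grads)
        it += 1

    vel = VelocityParams(p_v=best_params["p_v"], p_z=best_params["p_z"])
    vel.validate(prob.base_mask, cfg.t_max, eps_den=cfg.eps_den)
    shape = prob.shape_params(best_params["log_k"], best_params["log_sigma"])
    wf = prob.weight_field_values(best_params["log_k"], best_params["log_sigma"])[0]
    model = GrowthModelParams(anchors=prob.anchors, shape=shape, vel=vel, weights=wf)

    # per-subject fitting error in mm at the best parameters
    X_final, states = prob.forward(best_params["p_v"], best_params["p_z"],
                                   wf.values, store=True)
    tobs = prob.transformed_obs(best_params["theta"])
    errs = np.empty(prob.N)
    for s in range(prob.N):
        errs[s] = float(np.mean(np.linalg.norm(states[prob.steps[s]] - tobs[s], axis=1)))

    return FitReport(
        final_loss=best_loss,
        loss_trajectory=np.array(traj),
        best_trajectory=np.array(best_traj),
        params=model,
        rigid=best_params["theta"],
        per_subject_error_mm=errs,
        converged=bool(np.isfinite(best_loss)),
        n_restarts=restarts,
        config=cfg,
    )


# ---------------------------------------------------------------------------
# Template estimation and personalized prediction
# ---------------------------------------------------------------------------

def estimate_template(cohort, bandwidth_days: float = 90.0) -> SphericalMap:
    """Average anatomical shape at birth: Nadaraya-Watson kernel average of
    the cohort's coordinates with a Gaussian kernel over age centered at 0."""
    ages = np.asarray(cohort.ages, float)
    if ages.min() > 3.0 * bandwidth_days:
        raise InferenceError(
            f"no subjects within 3 bandwidths ({3 * bandwidth_days:.0f} days) of birth")
    w = np.exp(-0.5 * (ages / bandwidth_days) ** 2)
    w /= w.sum()
    coords = np.tensordot(w, np.stack([m.coords for m in cohort.maps]), axes=1)
    youngest = int(np.argmin(ages))
    return SphericalMap(coords=coords, label=cohort.maps[youngest].label.copy(),
                        age_days=0.0, subject_id="template-estimate")


def predict_subject(subject: SphericalMap, model: GrowthModelParams,
                    target_age_days: float, template: SphericalMap | None = None,
                    fused_sutures=(), *, dt_days: float = DEFAULT_DT_DAYS,
                    personalize: bool = True) -> FlowResult:
    """Personalized growth prediction for one subject.

    By default the anchor directions ``u_a``/``y_a`` are recomputed on the
    subject's own geometry (personalization); the anchor set and the
    normalized weights live in the standardized 2D domain and are reused
    unchanged.  With ``personalize=False`` the standardized-domain
    directions are kept, which makes prediction the exact continuation of
    the population flow (useful for self-consistency checks; personalized
    directions drift slightly from the birth-frame directions the
    population model integrates with).  The flow runs from the subject's
    age to ``target_age_days`` (ages snapped to the integration grid),
    optionally with fused sutures.
    """
    if target_age_days < subject.age_days:
        raise InferenceError("target age precedes the subject's age")
    if target_age_days > T_MAX_DAYS:
        import warnings
        warnings.warn("target age beyond the model span; extrapolating")
    if personalize:
        pers = personalize_anchors(model.anchors, subject)
    else:
        pers = SutureAnchors(
            suture=model.anchors.suture.copy(),
            grid_index=model.anchors.grid_index.copy(),
            x=subject.coords[tuple(model.anchors.grid_index.T)],
            u=model.anchors.u.copy(), y=model.anchors.y.copy())
    if model.weights is None and template is None:
        raise InferenceError("need either cached weights or the standardized template")
    wf = model.weights if model.weights is not None else model.weight_field(template)
    t0 = round(subject.age_days / dt_days) * dt_days
    T = round(target_age_days / dt_days) * dt_days
    spec = FlowSpec(t0=t0, T=max(T, t0), dt=dt_days,
                    fused_sutures=frozenset(fused_sutures))
    return integrate_flow(subject, pers, wf, model.vel, spec)
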