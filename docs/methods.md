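# Methods

## Model

The calvarial surface of one subject at one age is a **spherical map**: a
2D grid (azimuth × elevation) of 3D Euclidean coordinates in mm with a
per-point anatomical label — five bone plates (left/right frontal,
left/right parietal, occipital), six suture bands (metopic, left/right
coronal, sagittal, left/right lambdoid) and a cranial-base boundary ring on
the lowest elevation row. The azimuth index is periodic; grid indices are
anatomically corresponding across subjects. All model mathematics operates
on this representation.

Growth is driven at **anchors**: control points sampled uniformly (by arc
length, endpoints included) along each suture band. Anchor `a` on suture
`l` carries

- a unit direction `u_a` tangential to the surface and perpendicular to the
  suture (the direction in which new bone is deposited),
- for anchors adjacent to the base ring, a unit outward surface normal
  `y_a` along which the cranial base displaces the calvaria,
- a growth rate `v_a(t) = 1/(p0 + p1 t + p2 t²)` in day⁻¹ (the temporal
  derivative of a logarithmic growth curve; the denominator must stay
  positive on the model span, and an all-zero coefficient row denotes an
  identically zero rate), and a base displacement rate `z_a(t)` of the same
  rational form in mm/day (sign-unrestricted).

Each anchor's affine velocity field is localized by a weight

    w_l^a(x) = exp(−k·d_l(x)) · exp(−½ (x − x_a)ᵀ Σ_l (x − x_a)),

where `d_l(x)` is the straight-line Euclidean distance from `x` to the
nearest grid point of either bone that suture `l` separates (or of `l`
itself), so the locality factor is exactly 1 on those bones, and `Σ_l`
(mm⁻²) is applied directly as a concentration matrix — we keep the formula
exactly as the model defines it even though the matrix is *called* a
variance; an isotropic `Σ_l = σ_l⁻² I` is the default and the fitting path,
a full SPD matrix is accepted by the weight builder. Per grid point the raw
weights of all anchors are normalized to sum to one; points whose total raw
weight falls below 1e-8 are flagged static and never move. Weights are
**material**: computed once on the reference geometry in the standardized
domain, attached to grid indices, and held fixed during integration (they
do not change between subjects).

The combined flow is integrated by explicit forward Euler with Δt = 5 days:

    x ← x + Δt Σ_a w_l^a(m) [ v_a(t) ⟨x − x_a, u_a⟩ u_a + z_a(t) y_a ],

with both the point and the anchor advected by the same combined flow (the
anchor is a grid point, so its position is just the corresponding row of
the current state). This is the standard locally-affine combination; with a
single anchor it reduces to the per-anchor affine flow. Craniosynostosis is
simulated by forcing `v_a ≡ 0` on the fused sutures (`z_a` unaffected).
Directions `u_a`, `y_a` are computed from the anatomy at the start age and
held constant over the interval.

The flow is numerically invertible: integrating the negated field backward
over the same step sequence returns the start coordinates up to a
first-order-in-Δt error (≈0.03 mm over one year at Δt = 5 days on the
default synthetic model, ≈5× smaller at Δt = 1).

## Inference

All parameters — per-anchor `p_v`, per-base-anchor `p_z`, the shared
locality decay `k`, the per-suture isotropic kernel scales `σ_l`, and one
rigid nuisance transform (axis-angle rotation + translation) per subject —
minimize the size-normalized population objective

    L = (1/N) Σ_s (1/M) Σ_m ‖Φ(I₀(m), t_s) − (R(θ_s) I_s(m) + τ_s)‖ / ‖I_s(m)‖.

The birth template `I₀` is estimated first (decoupled from the model fit)
as a Nadaraya–Watson average of the cohort's coordinates with a Gaussian
kernel over age centered at 0 (default bandwidth 90 days; rejected if no
subject lies within three bandwidths of birth).

Because the cohort is cross-sectional and every subject's prediction starts
from the same template, one forward integration of the flow — snapshotted
at each subject's age, rounded to the nearest Δt multiple — evaluates the
whole objective. Gradients are computed by reverse-mode (adjoint)
differentiation of the Euler recursion, hand-derived: the adjoint state is
seeded at every snapshot with the per-point loss gradients and swept
backward through the steps; the chain continues analytically through the
weight normalization to `k` and `log σ_l`, and through the Gallego–Yezzi
closed form for the derivative of an axis-angle rotation matrix. The test
suite checks every gradient block against central finite differences
(agreement ≲ 1e-4 relative).

Optimization is Adam (initial learning rate 0.01–0.02) in preconditioned
coordinates: each parameter block is divided by a characteristic scale
(`p_vj` by `p0_init/1500^j`, rotations by 0.05 rad, translations by 2 mm,
log-shape parameters by 1) so one Adam step moves every block by a
comparable relative amount. Two numerical safeguards matter in practice:

- **Gradient clipping** (per-coordinate, in preconditioned units): the
  denominator-positivity hinge penalty occasionally fires with enormous
  gradients; unclipped, a single spike inflates Adam's second-moment
  estimate so much that the affected parameters freeze for thousands of
  iterations.
- **Penalty margin**: the hinge `max(0, q_min − q(t))²` (on a 30-day grid)
  uses `q_min = 50` days, i.e. it engages once a rate exceeds 0.02/day —
  well before the hard validity bound (denominator ≥ 1e-4) at which the
  flow would already have blown up. The returned parameters are re-checked
  against the hard bound.

The learning rate decays exponentially to 10% of its initial value over the
run; on a non-finite loss the optimizer restarts from the last valid state
at half the rate (at most 3 times). Fitting is full-batch and fully
deterministic given the configuration.

Initialization: flat growth at `v₀ = 0.1/365` day⁻¹ (first-year integrated
growth ≈ 10% of template size), flat base displacement at 0.01 mm/day,
`k = 0.5` mm⁻¹, `σ_l = 20` mm, rigid transforms at the identity.

**Personalized prediction** starts from a subject's own map: the anchor set
and normalized weights are reused from the standardized domain (same grid
indices), while `u_a`, `y_a` are re-derived from the subject's geometry.
Re-derived directions rotate slightly relative to the birth-frame
directions the population flow integrates with, so personalized prediction
is not an exact continuation of the generating flow even on noise-free
synthetic pairs (~up to 2 mm over a year under default conditions);
`personalize=False` gives the exact continuation and isolates
discretization error.

## Strain analysis

Local expansion from birth to age `t` is the trace of the Green–Lagrange
strain `E = (∇d + ∇dᵀ + ∇d∇dᵀ)/2` of the displacement `d`. The gradient is
taken **intrinsically**: parametric central differences along the two grid
directions (azimuth periodic, one-sided at elevation edges) are contracted
with the inverse first fundamental form of the reference surface,
`ε = tr(G⁻¹ · ½(C − G))` with `C` the pulled-back metric of the deformed
surface. Normal derivatives of a surface-sampled field are undefined, so
the trace sums the two tangential directions; a uniform in-plane stretch by
`s` gives `ε = s² − 1`. Strain values are therefore comparable only within
this convention. Strain rates are reported in year⁻¹ (365.25 days/year);
per-bone summaries are area-weighted means using the reference metric.
The cephalic index is 100 × lateral / antero-posterior coordinate range in
the standardized pose; clinical practice measures landmark distances
(euryon–euryon / glabella–opisthocranion), so absolute values are
convention-dependent while trends are comparable.

## Synthetic data

Clinical calvaria surfaces are not redistributable, so the package
generates its own study material with known ground truth. The template is
the upper part of an ellipsoid with semi-axes (49, 60, 45) mm — birth
cephalic index 81.7% — sampled on a 32 × 24 grid up to 78° elevation (the
parameterization stops short of the pole, whose degenerate cells would
break the surface frames; the exported surface is topologically an
annulus). Label bands: metopic on the anterior midline, coronal columns at
±67.5° azimuth (behind the forehead, which makes the coronal growth
direction predominantly antero-posterior), sagittal on the upper posterior
midline, L-shaped lambdoid bands around the occipital region. Layout
fractions scale with the grid so every suture separates exactly its two
anatomical bones at any supported resolution.

True growth parameters (defaults): birth rates `v₀` of 2.0e-3 day⁻¹
(coronal), 8e-4 (lambdoid), 5e-4 (metopic, sagittal), each decaying 10×
over ten years via a linear denominator; base displacement 0.02 mm/day
decaying 10×; `k = 0.5` mm⁻¹, `σ = 60` mm. These values were calibrated
once, by forward simulation only, to reproduce the qualitative reference
behaviors of normative cranial growth: both extents grow ≈1.5× over ten
years, the cephalic index decreases with age (81.7 → 79.9 at 2 y → 78.4 at
10 y), and fusing the sagittal / metopic / one coronal suture produces the
scaphocephaly / trigonocephaly / plagiocephaly directions respectively.

Cohorts draw ages from a truncated exponential (mean 1100 days, young-
skewed, mirroring how pediatric imaging cohorts oversample early ages) or a
uniform distribution; each subject is the true flow snapshot at its age
(steps of 5 days) plus iid Gaussian coordinate noise (0.5 mm default),
observed under a random rigid perturbation (≤5°, ≤3 mm) whose ground truth
is recorded. Longitudinal cohorts reuse one trajectory and one rigid
perturbation per subject with independent noise per visit. What the
generator does **not** emulate: anatomical shape variability between
subjects (every subject follows the population trajectory), spatially
correlated segmentation noise, suture-width changes or closure with age,
and compensatory overdevelopment parallel to a fused suture — so passing
recovery tests demonstrates correctness of the estimation machinery under
the model, not robustness to model misspecification in real CT data.

## Problem sizes and defaults

Default experiments use the 32 × 24 grid (768 points), ~39 anchors, Δt = 5
days, and up to 730 Euler steps (10 years). The headline recovery
experiment fits 200 subjects with uniform ages over 0–10 years, 0.5 mm
noise and rigid perturbations, using 400 Adam iterations; it is given the
true birth template, because with uniform ages only a handful of subjects
lie near birth and the kernel template estimate carries a systematic size
bias (≈2 mm) that is a property of the sampling design, not of the
estimator under test. The estimated-template pipeline is exercised
end-to-end separately. Rigid nuisance recovery is reported per subject
after this choice; a global gauge (one common rigid transform shared by
the model trajectory and all nuisances) is only weakly identified when the
template itself is estimated.

## Known limitations

- Forward Euler is first order; invertibility is numerical, not exact.
- The intrinsic strain convention makes absolute strain values specific to
  this package's definition.
- Growth rates are per anchor but the synthetic truth is per suture;
  recovery is assessed on suture-averaged integrated growth curves, which
  is what the data constrain well. End anchors of a suture are weakly
  constrained individually.
- Joint optimization of weight-shape parameters with growth rates is
  non-convex; the learning-rate schedule and clipping above were chosen for
  robust convergence on the default conditions, and different conditions
  may need a different iteration budget.
- **Suture-specific rates need a long age span.** With cohort ages covering
  the full 0–10 y range, 60 subjects at 0.5 mm noise suffice to recover
  every suture's integrated growth within a few percent. When ages only
  reach ~3 y, the per-suture contrast in accumulated growth is small
  relative to noise and the optimizer settles into near-degenerate
  common-mode solutions (all sutures sharing one rate, kernel scales
  collapsing for the weakly-determined sutures) that fit the data almost
  as well; longer optimization does not escape. Cross-sectional designs
  for this model should therefore span the full growth period of interest.
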