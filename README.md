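# suturegrowth

A data-driven diffeomorphic model of cranial growth in which all calvarial
shape change is the consequence of bone deposition at the cranial sutures,
plus displacement of the calvaria–cranial-base boundary. It is aimed at
researchers studying pediatric skull development and craniosynostosis (the
premature fusion of one or more sutures) who need an *explainable* growth
model: one whose parameters are per-suture growth rates that can be
inferred from cross-sectional imaging cohorts, used to predict personalized
growth, and switched off to simulate suture fusion.

## Model

A calvaria is a standardized spherical map: an azimuth × elevation grid of
3D points with anatomical labels (5 bone plates, 6 sutures, a base ring),
with grid-index correspondence across subjects. Each suture *l* carries
uniformly-spaced anchor points *a* with a growth direction **u**ₐ
(tangential to the surface, perpendicular to the suture) and, at the base
ring, a displacement direction **y**ₐ (surface normal). Point trajectories
follow the combined locally-affine flow

&nbsp;&nbsp;&nbsp;&nbsp;Φ(x, T) = x + ∫ Σₐ wₗᵃ(x) [ vₐ(t) ⟨Φ(x,t) − Φ(xₐ,t), **u**ₐ⟩ **u**ₐ + zₐ(t) **y**ₐ ] dt,

integrated by forward Euler with Δt = 5 days, where the rates are rational
profiles vₐ(t) = 1/(p₀ + p₁t + p₂t²) (the derivative of logarithmic
growth) and the weights wₗᵃ(x) = e^(−k·dₗ(x)) · e^(−½(x−xₐ)ᵀΣₗ(x−xₐ)),
normalized per point, restrict each suture's influence to the bones it
separates. All parameters — rates, k, Σₗ, plus a rigid nuisance transform
per subject — are inferred from a cross-sectional cohort by minimizing the
size-normalized discrepancy

&nbsp;&nbsp;&nbsp;&nbsp;(1/N) Σₛ (1/M) Σₘ ‖Φ(I₀(m), tₛ) − R(θₛ)Iₛ(m)‖ / ‖Iₛ(m)‖

with Adam on hand-derived adjoint gradients. Craniosynostosis is simulated
by setting the fused suture's vₐ to zero. See `docs/methods.md` for the
full account, including the synthetic-data generator that stands in for
clinical cohorts (which are not redistributable).

## Worked example

```bash
python examples/02_craniosynostosis.py
```

prints (seeded, deterministic):

```
normative at 2 y:      CI  79.85 %
S fused (scaphocephaly): CI  76.36 %
M fused (trigonocephaly): CI  79.83 %; frontal strain 0.388 (normative 0.445)
RC fused (right plagiocephaly): CI  76.71 %; AP length left 138.8 mm vs right 126.7 mm
```

The cephalic index (CI, 100 × skull width / length) of the normative
simulation falls from 81.7% at birth to 79.9% at two years — the model's
coronal sutures grow fastest, elongating the skull. Fusing the sagittal
suture blocks widening (CI drops a further 3.5 points: scaphocephaly);
fusing the metopic suture leaves global proportions almost untouched but
reduces the frontal-bone strain by 13% (trigonocephaly is a *local*
anterior restriction); fusing one coronal suture shortens that side of the
skull by 12 mm (anterior plagiocephaly). The other examples cover forward
simulation, parameter recovery on a synthetic cohort, and strain analysis.

A thin command-line interface wraps the same library code:

```bash
suturegrowth synth cohort --config cfg.yaml --seed 1 --out run/
suturegrowth fit --cohort run/cohort.h5 --out model.h5 --seed 1
suturegrowth simulate --map run/template.h5 --params model.h5 \
    --t0 0 --t1 730 --fuse S --out pred.h5 --mesh pred.ply
suturegrowth evaluate --pred pred.h5 --obs obs.h5
```

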