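# mfdbp — myofibre-density age-breakpoint analysis

Histopathology of early Duchenne muscular dystrophy (DMD) lacks robust
quantitative markers of disease progression.  Myofibre density (*MFD*) —
the simple count of myofibres with identifiable contours per mm² of
cross-section — declines steeply with age in steroid-naïve biopsies and
then plateaus.  `mfdbp` is a statistical pipeline for locating and
characterising that transition from a patient cohort table: for
pathologists and biostatisticians asking *at what age does rapid myofibre
loss stop, and what MFD value says a biopsy is still on the steep limb?*

The core model is a two-slope segmented regression with an estimated knot,

    yᵢ = α + β₁ (xᵢ − ψ)₋ + β₂ (xᵢ − ψ)₊ + εᵢ,   εᵢ ~ N(0, σ²),

where x is age at biopsy, y is MFD, ψ the breakpoint age, and β₁/β₂ the
pre-/post-break slopes.  Around it the pipeline provides:

- Spearman screening of all morphometric variables against age, and a
  LOESS/moving-average initialiser for the knot;
- Muggeo-style iterative breakpoint estimation with a grid-search oracle,
  Wald CI, F-test against the single-slope model, LOOCV-RMSE and an
  initial-value robustness scan;
- Bayesian re-estimation on centred age with weakly informative priors
  (ensemble MCMC plus an exact quadrature posterior), a ROPE decision rule
  for the slopes, and PSIS-LOO model comparison;
- Monte Carlo power: the probability that a cohort of size n recovers the
  breakpoint within ±1–1.5 years;
- logistic inversion of MFD into probability-of-young-age cut-offs;
- effect-size analysis (Hedges' d / Cliff's δ with bootstrap CIs) across
  breakpoint-defined age bands;
- a calibrated synthetic-cohort generator so every stage is testable.

The 38-patient reference cohort ships with the package.  See
`docs/methods.md` for the models, priors, and numerical choices.

## Worked example

```python
import mfdbp

cohort = mfdbp.load_reference_cohort()          # 38 patients
young = mfdbp.subset_by_age(cohort, 11.0)       # analysis subset, n = 35

fit = mfdbp.fit_segmented(young.ages, young.mfd, psi0=6.0)
print(f"breakpoint {fit.psi:.2f} y, CI [{fit.ci_psi[0]:.2f}, {fit.ci_psi[1]:.2f}]")
print(f"pre-slope {fit.beta1:.1f}, post-slope {fit.beta2:.1f} fibres/mm2/year")
print(f"adjusted R2 {fit.adj_r2:.2f}")

logi = mfdbp.fit_age_logistic(young, round(fit.psi, 2))
print(f"MFD > {mfdbp.invert_probability(logi, 0.8):.1f} -> P(age < breakpoint) > 80%")
```

prints

```
breakpoint 6.30 y, CI [5.17, 7.43]
pre-slope -169.0, post-slope -27.7 fibres/mm2/year
adjusted R2 0.80
MFD > 595.5 -> P(age < breakpoint) > 80%
```

MFD falls by ~169 fibres/mm² per year until age 6.3, then the decline
flattens to −28 fibres/mm²/year (practically indistinguishable from
measurement noise); a biopsy with MFD above ~595 fibres/mm² most likely
precedes the transition.  The full pipeline, including the Bayesian
re-estimation and the power simulation, runs with

```sh
mfdbp run --seed 1 --out results/
```

and writes a JSON report bundle mirroring each stage's summary table.

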