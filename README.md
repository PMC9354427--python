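# twinpillars

Twin-pair analysis of how meeting five lifestyle "pillars" — ≥8 h
sleep, ≥5 daily fruit/vegetable servings, ≤2 h daily sedentary time,
≥150 min/week of moderate-to-vigorous physical activity, and
non-smoking — relates to BMI and depressive symptoms (PHQ-2).

The package is aimed at behavior-genetics and epidemiology researchers
working with same-sex MZ/DZ twin registry data.  It implements, end to
end:

* **Pillar coding** from raw survey items into tri-state indicators and
  a 0–5 pillar count (missing unless all five indicators are observed),
  plus the outcome transforms (log BMI, √PHQ-2).
* **Univariate ACE decomposition** by FIML: trait variance split into
  additive-genetic (A), shared-environment (C), and non-shared (E)
  components using the MZ/DZ correlation contrast
  (r_MZ = a² + c², r_DZ = ½a² + c²), for continuous traits and for
  ordinal traits under a liability-threshold model.
* **Quasi-causal co-twin models**: the bivariate twin SEM

      X_ij = μ_x + a_x A_xij + c_x C_xi + e_x E_xij
      Y_ij = μ_y + b_P (X_ij − μ_x) + b_A A_xij + b_C C_xi + U_ij

  where `b_P` is the within-person (phenotypic) path and `b_A = b_C`
  absorb between-family confounding; fitted as Model 1 (`b_A = b_C = 0`),
  Model 2 (confounds estimated), and Model 3 (`b_P` equated across
  sexes, Wald-testable), with optional covariates and either an
  observed-count or liability-ordinal predictor.
* **Regression trees** over the five binary pillars with ANOVA (SSE)
  splitting, surrogate splits for missing data, cost-complexity pruning
  by seeded 10-fold cross-validation, and summed-improvement variable
  importance scaled to 100.
* **Within-pair difference descriptives**: between-individual and
  discordant-co-twin outcome differences by pillar-count difference and
  zygosity.
* **A synthetic registry generator** that emulates the study
  conditions (pair counts, pillar prevalences, ACE-structured
  liabilities, item-level missingness) and back-converts latent draws
  to raw survey responses, so every stage is testable without the
  restricted registry data.

See `docs/methods.md` for the models, assumptions, and numerical
choices in detail.

## Worked example

Simulate a registry of 2,000 MZ + 2,000 DZ female pairs in which
meeting pillars lowers log-BMI both through a within-person path
(b_P = −0.02 per count-SD) and through between-family confounds
(b_A = b_C = −0.05), then decompose BMI variance and contrast the
phenotypic with the quasi-causal model:

```python
from twinpillars import (GeneratorConfig, OutcomeModel, generate_registry,
                         code_dataset, fit_ace_continuous, QuasiCausalSpec,
                         fit_model, percent_change_per_pillar)

cfg = GeneratorConfig(
    n_mz_pairs=2000, n_dz_pairs=2000, prop_female=1.0, seed=1,
    outcomes={
        "log_bmi": OutcomeModel(mean=3.25, resid_sd=0.19,
                                resid_ace=(0.6, 0.1, 0.3),
                                b_p=-0.02, b_a=-0.05, b_c=-0.05),
        "sqrt_phq": OutcomeModel(mean=0.62, resid_sd=0.6,
                                 resid_ace=(0.35, 0.05, 0.6)),
    },
)
coded = code_dataset(generate_registry(cfg))

est = fit_ace_continuous(coded, "log_bmi")
print(f"log-BMI ACE shares: a2={est.a2:.2f} c2={est.c2:.2f} e2={est.e2:.2f}")

kw = dict(outcome="log_bmi", pillars="all",
          predictor_mode="observed_count", groups=None)
f1 = fit_model(QuasiCausalSpec(model_level=1, **kw), coded)
f2 = fit_model(QuasiCausalSpec(model_level=2, **kw), coded)
print(f"Model 1 (phenotypic)   b_p = {f1['b_p']:+.4f} (SE {f1.se['b_p']:.4f})")
print(f"Model 2 (quasi-causal) b_p = {f2['b_p']:+.4f} (SE {f2.se['b_p']:.4f})")
print(f"percent BMI change per pillar, Model 1: "
      f"{percent_change_per_pillar(f1['b_p']):.1f}% decrease")
```

Output:

```
log-BMI ACE shares: a2=0.59 c2=0.17 e2=0.24
Model 1 (phenotypic)   b_p = -0.0449 (SE 0.0020)
Model 2 (quasi-causal) b_p = -0.0214 (SE 0.0026)
percent BMI change per pillar, Model 1: 4.4% decrease
```

The ACE shares recover the generating residual structure; the
phenotypic slope (−0.045 per pillar) is roughly twice the quasi-causal
slope (−0.021) because Model 1 absorbs the between-family confound into
`b_P` while Model 2 routes it through the confound paths — the
attenuation pattern that motivates the co-twin design.  A log-scale
slope `b` converts to a `100·(1 − e^b)` percent change in BMI per
additional pillar met.

The same stages are available from the shell:

```bash
twinpillars simulate --out registry.csv --seed 1
twinpillars code --data registry.csv --out coded.csv
twinpillars fit ace --trait log_bmi --data coded.csv --out ace.json
twinpillars fit quasicausal --outcome log_bmi --pillars all --model 2 \
    --data coded.csv --out fit.json
twinpillars tree --outcome bmi --data coded.csv --seed 1 --out tree.json
twinpillars diffs --outcome bmi --data coded.csv --out diffs.csv
twinpillars run --outdir results --seed 1     # full pipeline
```

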