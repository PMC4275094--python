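# ncii — quantitative genetics of North Carolina II crosses under crossed environments

`ncii` analyses (and simulates) blocked **North Carolina II breeding
designs**: every sire is mated to every dam within an experimental block,
each full-sib family is raised under a factorial set of environmental
treatments, and each family × treatment cell is replicated.  Designs of
this shape are the workhorse for asking whether *additive genetic
variation* exists for tolerance of environmental stressors — e.g. sea
urchin embryos raised under crossed warming × acidification treatments,
where a significant sire × environment interaction signals heritable
variation in stress tolerance and hence adaptive potential.

The package is aimed at quantitative geneticists and experimental
ecologists who have jar/tank-level records of the form
`(block, sire, dam, temperature, pH, replicate, n_scored, n_success)` —
or who need to simulate them — and want the full analysis chain:

* **Design algebra** (`ncii.design`) — model-term enumeration with
  nesting, balanced-design degrees of freedom, dataset validation.
* **Mixed-model ANOVA** (`ncii.anova`) — balanced sums of squares,
  Cornfield–Tukey expected mean squares (unrestricted convention by
  default, restricted available), exact or Satterthwaite-synthesized
  quasi-F ratios, and p-values by unrestricted permutation of the raw
  data: p = (1 + #{F\* ≥ F}) / (1 + n_perm).
* **Variance components** (`ncii.varcomp`) — average-information REML
  with EM fallback and zero bounds, plus the closed-form ANOVA
  (method-of-moments) estimator, fitted "in a single analysis" with
  block, sire(block), dam(block), sire × dam and all parent × environment
  interactions.
* **Cross-environment genetic correlations** — from the sire-associated
  components (σ²_s ↔ V_A in a half-sib design):

      r*_G      = σ²_s / D
      r*_G(T)   = (σ²_s + σ²_sT) / D        D = σ²_s + σ²_sT + σ²_spH + σ²_sTpH
      r*_G(pH)  = (σ²_s + σ²_spH) / D

* **Heritability & repeatability** (`ncii.heritability`) — intra-family
  (repeatability), sire, dam and animal models on the jar records, with a
  pedigree numerator-relationship matrix, delta-method standard errors,
  and per-treatment-cell estimates.
* **Cross-stage regression** (`ncii.stagelink`) — OLS of family mean
  performance at one developmental stage on another within each treatment.
* **Synthetic data** (`ncii.simulate`) — Gaussian-percent or
  latent-binomial jar records from user-specified variance components,
  with named random substreams and cross-stage parental correlation.
* **Carbonate chemistry** (`ncii.carbonate`) — seawater CO₂-system solver
  (Mehrbach constants refit by Dickson & Millero; total pH scale) for
  documenting culture conditions: any two of {TA, DIC, pH_T} → pCO₂, Ω.

## Worked example

Simulate the reference design (2 blocks × [4 sires × 2 dams] × 2
temperatures × 3 pH levels × 3 jars = 288 jars) and analyse it:

```python
from ncii import (DesignSpec, VarianceComponents, FixedEffects, SimOptions,
                  simulate_dataset, anova_table, reml_fit, eisen_saxton)

design = DesignSpec()                       # the layout above
vc = VarianceComponents(block=5, sire=20, dam=10, sire_dam=5,
                        sire_temperature=10, sire_ph=5,
                        sire_temperature_ph=5, dam_temperature=5,
                        dam_ph=5, residual=100)
fx = FixedEffects(mu=60, temperature=(-4, 4), ph=(6, 1, -7))
records = simulate_dataset(design, vc, fx, SimOptions(seed=20140))

table = anova_table(records, design, "percent", n_perm=999, seed=1)
print(table[["df", "MS", "F", "P"]].head(5).round(3))
```

```
        df        MS       F      P
Source
Bl       1  3714.342   1.760  0.075
Te       1  6118.245  38.898  0.114
pH       2  3349.807   6.413  0.127
Ma(Bl)   6   530.642   1.175  0.332
Fe(Bl)   2  1514.910   1.996  0.096
```

The `df` column is the balanced-design degrees of freedom (the full
column for this design is 1, 1, 2, 6, 2, … , 12, 192 and sums to 287);
`F` is the exact F where a single error mean square exists (`Te` uses
MS(Bl × Te)) and a Satterthwaite quasi-F otherwise (`Ma(Bl)`, whose
denominator combines four mean squares); `P` is the raw-data permutation
p-value, so with 999 permutations its smallest possible value is 0.001.

Variance components and genetic correlations for the same records:

```python
fit = reml_fit(records, design)             # AI-REML, 13 components + residual
gc = eisen_saxton(fit)
print(f"r_G={gc.r_G:.3f}  r_G(T)={gc.r_G_T:.3f}  r_G(pH)={gc.r_G_pH:.3f}")
```

```
r_G=0.248  r_G(T)=0.649  r_G(pH)=0.437
```

Here r\*_G is the proportion of sire-associated variance shared across
*both* environmental factors (low values mean genotypes that excel under
one stressor need not excel under the other), while r\*_G(T) and
r\*_G(pH) are the correlations within a temperature or pH class.

The same pipeline is available from the shell:

```bash
ncii run-all --config examples/config.yaml      # simulate → ANOVA → REML →
                                                # correlations → h² → stage link
ncii carb --ta 2258.1 --ph 7.64 --temp 25.14 --sal 34.1
```

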