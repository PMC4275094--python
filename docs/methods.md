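# Methods

This note records the statistical models implemented in `ncii`, the
conventions and numerical choices behind them, what the simulation studies
in the test suite do and do not demonstrate, and known limitations.

## The design and its model terms

A blocked NC II cross with `b` blocks, `s` sires and `d` dams per block
(parents never reused across blocks), environmental factors with `l_1, l_2,
…` levels and `r` replicate jars yields `N = b·s·d·Πl_i·r` experimental
units.  Model terms are all factor combinations in which no factor meets its
own nesting factor; degrees of freedom follow balanced-design rules —
`Π(levels−1)` over member factors times the level count of every nesting
factor not in the term — and zero-df terms (degenerate designs) are dropped.
For the default layout (b=2, s=4, d=2, 2×3 treatments, r=3; N=288) this
produces 19 terms plus residual with df summing to 287.  Jar-level records
are validated for completeness, key uniqueness, count sanity and parent
scoping before any ANOVA.

## ANOVA: sums of squares, EMS, quasi-F, permutation

Sums of squares use the classical balanced decomposition: for each term the
subclass-total quadratic `U` minus the correction factor minus the SS of all
contained terms; the residual is the within-cell remainder.  The
decomposition identity Σ SS = total corrected SS is property-tested at
1e−8 relative tolerance.

Expected mean squares follow the Cornfield–Tukey rules under the
**unrestricted** mixed-model convention: every random term whose subscripts
contain those of a row contributes its component, with integer multiplier
`N / (number of subclasses of the component)`; fixed-only terms contribute a
quadratic form to their own row.  The unrestricted convention matches how
REML defines variance components, which keeps the ANOVA and REML halves of
the package mutually consistent; the restricted (sum-constrained)
convention, under which e.g. the sire error term collapses to the
sire × dam mean square, is available via `restricted=True` for sensitivity.

F ratios are built by solving the square linear system over all mean
squares for the unique weight vector whose expectation isolates the tested
effect.  Because each term owns exactly one column (its component or its
quadratic form), the solution is unique: no heuristic tie-breaking between
candidate quasi-F combinations is ever needed.  Positive weights form the
numerator (always including the tested term with weight 1), negative
weights the denominator; degrees of freedom of each combination follow
Satterthwaite, `(Σ wᵢMSᵢ)² / Σ (wᵢMSᵢ)²/dfᵢ`, which reduces to the exact df
for single-MS combinations.

Significance uses unrestricted permutation of the raw response over all
jars, recomputing each term's (quasi-)F per permutation, with the add-one
estimate `p = (1 + #{F* ≥ F}) / (1 + n_perm)` so p is never zero.
Restricted schemes (within-block permutation, residual permutation under a
reduced model) were considered and deliberately not made the default: the
raw-data scheme is the simplest, is exact under the global null, and in the
type-I study below stays nominal for the sire term even with nonzero
block/dam nuisance variance because the quasi-F denominator tracks the
nuisance components.  For N ≤ 9 an exhaustive enumeration of all N!
orderings is available and is checked to reproduce partition-enumeration
p-values exactly.  Permutations are evaluated in vectorized batches
(group-indicator matrix products), making 999 permutations of all 19 terms
of the default design run in ~0.1 s.

## Variance components

Two estimators share the model structure (block, sire(block), dam(block),
sire × dam, and all parent × environment interactions, fitted jointly;
temperature, pH and their interaction are fixed):

* **ANOVA / method of moments** — solves `E[MS] = C·σ²` through the EMS
  coefficient matrix restricted to random rows; exactly unbiased on
  balanced data and allowed to go negative (a zero-truncated copy is
  reported alongside).  Used as the oracle for REML and for the
  recovery study, precisely because of its unbiasedness.
* **AI-REML** — average-information updates with step-halving line search
  (the restricted log-likelihood never decreases), monotone EM fallback,
  components bounded at zero with an active-set treatment, convergence
  when the relative log-likelihood change falls below `ll_tol` (default
  1e−8) and the free-gradient norm below `grad_tol·(1+|ll|)`.  Standard
  errors come from the inverse average-information matrix.  The linear
  algebra uses a dense covariance factorization when the total number of
  random levels exceeds the number of observations and a Woodbury
  representation otherwise, so both the 288-jar default design and
  several-thousand-record simulation designs fit in well under a second.
  The full 13-component fit is cross-checked against lme4 on a fixed
  simulated dataset (agreement to ~1% including boundary components) and
  against the moment estimator at interior optima (1e−6 relative).

Genetic correlations across the two environmental factors are ratios of
sire-associated components (`eisen_saxton`): r\*_G = σ²_s/D,
r\*_G(T) = (σ²_s+σ²_sT)/D, r\*_G(pH) = (σ²_s+σ²_spH)/D with
D = σ²_s+σ²_sT+σ²_spH+σ²_sTpH.  The exact algebraic identity of these
forms is r\*_G(T) + r\*_G(pH) − r\*_G = 1 − σ²_sTpH/D; it equals 1
precisely when the three-way sire component vanishes, which is also the
regime in which a reported correlation triple satisfying the sum-to-one check to two
decimals is internally consistent.  Dam-side and sire × dam components are
fitted but never enter these ratios, and block interacts with nothing in
the default random structure (block × environment terms exist as an option
for full-structure simulation studies).

## Heritability and repeatability

The experimental unit is a jar of one full-sib family, so the "genotype"
carrying repeated measures is the family and every jar is one observation
of it.  Jar percentages average over tens of embryos, which suppresses
Mendelian-sampling variance; the additive value of a family is therefore
the parental average `0.5(a_sire + a_dam)`.  The animal model carries one
additive effect per founder with incidence `0.5(Z_sire + Z_dam)` — the
numerator-relationship structure expressed at the family level (variance
0.5σ²_A per record, covariance 0.25σ²_A between half-sib families) — plus
a family permanent-environment effect and block.  An alternative encoding
sometimes seen (each family as a pedigree individual with self-relationship
1 and a PE effect absorbing the difference) was implemented first and
rejected: on family-mean records it demands a negative PE component, which
the zero bound forbids, deflating σ̂²_A and decoupling the animal model from
the sire model.  The pedigree machinery (`build_pedigree`, tabular-method
`amatrix`) is retained and verified against a recursive-coancestry oracle.

The sire and dam models both fit sire + dam + family + block and differ in
which parental component is quadrupled: fitting only one parent biases the
target component because the omitted parent's covariance leaks into block
and family (measured on simulations: true h²=0.4 recovered as ≈0.19 with
the dam term omitted).  σ²_P sums each fitted component's per-observation
variance contribution (0.5σ²_A for the additive term) plus the residual;
block can be excluded via a flag since conventions differ.  Ratio estimates
are reported raw and truncated to [0, 1]; SEs use the delta method.
Per-treatment-cell estimates refit the same models on one temperature × pH
cell with intercept-only fixed effects.

## The synthetic-data generator

The generator draws one iid Gaussian effect per level of every declared
random term, adds sum-to-zero fixed treatment effects to a grand mean on
the percent scale, and emits one record per design cell × replicate, with
`n_scored` uniform on the configured range (default 30–50).  Two response
models: `gaussian-percent` (default) reports the latent value clipped to
[0, 100] — matching an analysis that treats raw percentages as normal —
and counts clip events, warning when they occur since heavy clipping
invalidates the Gaussian theory; `latent-binomial` maps the latent percent
to a probability and draws `n_success` binomially, for robustness studies.
Each random term owns a named substream of the seed, so activating or
removing a term never perturbs the draws of the others, and replicate
datasets use `(seed, i)` substreams reproducible in isolation.  Cross-stage
dependence between two traits is induced only through the purely parental
effects (sire, dam, sire × dam), correlated at `rho_stage` with matched
marginals.

What the generator does *not* emulate: gamete-compatibility mechanisms
(bindin-type assortative fertilization), within-ejaculate sperm
heterogeneity, over-dispersed or spatially correlated jar effects, and any
nonlinearity between the latent scale and the percent scale other than
clipping.  Passing recovery tests therefore demonstrate correctness of the
estimators under the stated Gaussian model, not robustness to those
features of real data.  Shipped example components are illustrative round
numbers on the percent scale, not estimates from any dataset.

## Simulation studies in the acceptance suite (sizes and seeds)

All studies run with frozen seeds chosen before the studies were first run
at full size.

* **Type-I error** (seed 4001): 500 datasets of the default 288-jar design
  with every sire-containing component zero (block 5, dam 10, residual
  100); the sire-term permutation test (999 permutations) must reject at
  5% within the 99% binomial interval.
* **REML ≡ MoM** (seed 5001): balanced 720-jar design with all 17
  components truly positive; the first dataset whose moment solution is
  componentwise positive is fitted by REML at tight tolerances and must
  agree to 1e−6 relative.
* **Component recovery** (seed 6001): 200 replicates of the 288-jar
  design with sire-side components (20, 10, 5, 5) and residual 100,
  method-of-moments estimates.  Note the precision limit: the moment
  estimator of a component of size 5 has per-dataset standard deviation
  near 9 on this design, so the standard error of a 200-replicate mean is
  ~0.65 — of the same order as a 10%-of-truth band.
* **Heritability recovery** (seed 7001): 200 replicates of a sire-rich
  design (6 blocks × 8 sires × 4 dams, 6 treatments, 1 jar each; N=1152)
  with every true component interior (block 20, sire = dam = 20 so
  V_A = 80, sire × dam 50, residual 100; h² = 0.381, repeatability
  0.429).  The default 8-sire layout is deliberately not used here: the
  sire-component sampling distribution at 8 sires is so right-skewed that
  its zero-truncated mean exceeds the truth by ~35%, and with few blocks
  the truncation of the block component deflates the sire mean — the
  recovery premise (bias → 0 as sires grow) needs a design where it can
  hold.

## Carbonate system

All computation is on the total hydrogen-ion scale.  Constants: Weiss
(1974) K0; Mehrbach (1973) K1/K2 as refit by Dickson & Millero (1987)
(seawater scale, converted to total via the Dickson (1990) bisulfate and
Dickson & Riley (1979) fluoride constants); Dickson (1990) KB; Millero
(1995) KW; Mucci (1983) calcite/aragonite solubilities; salinity-
proportional totals from Uppström (boron), Morris & Riley (sulfate), Riley
(fluoride) and Riley & Tongudai (calcium).  Alkalinity includes carbonate,
borate, water and the free proton; phosphate and silicate are zero.  From
TA+DIC the pH root is bracketed on [2, 12] and solved by Brent's method to
1e−10; from pH the system is closed-form.  The test oracle re-derives the
solution through an independent closed form (every species linear in pCO₂
at fixed pH) with the same constants.  NIST-scale pH is accepted only with
an explicit user-supplied offset to the total scale, since the
liquid-junction correction is electrode-specific; no universal conversion
is pretended.  Saturation states use Ω = [Ca²⁺][CO₃²⁻]/Ksp at surface
pressure; no pressure corrections are implemented.

## Known limitations

* ANOVA requires balanced, complete data; imbalance is detected and
  refused, not accommodated (no Type-II/III SS, no
  Satterthwaite/Kenward-Roger df for unbalanced layouts).
* Permutation p-values for terms other than the global-null case are
  approximate (as with all raw-data permutation schemes); the type-I study
  covers the sire term, the primary inferential target.
* REML standard errors are asymptotic and optimistic near the zero bound;
  boundary components are flagged rather than corrected.
* The multi-trait generator correlates parental effects only; residual
  cross-stage correlation is not modelled, so stage regressions on
  simulated data understate within-jar coupling.
* The carbonate solver covers T ∈ [0, 45] °C, S ∈ [15, 45] at surface
  pressure with a fixed constant set; alternative constant choices are not
  currently selectable.
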