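# Methods

## Model

The data-generating model is a linear structural chain with four nodes:

```
X2 = β1·X1 + e2,    X3 = β2·X2 + e3,    Y = β3·X3 + e4
```

`X1` is the minor-allele count (0/1/2) at a biallelic causal SNP with
minor allele frequency `p ∈ (0, 0.5]`, drawn Binomial(2, p) under
Hardy–Weinberg equilibrium, so `var(X1) = 2p(1−p)`. The exogenous
errors `e2, e3, e4` are mutually independent, zero-mean Gaussian with
variances `σ²_e2, σ²_e3, σ²_e4` (default 1.0 each). Genotype enters
additively; dominance, epistasis, multiple causal SNPs, linkage
disequilibrium and covariates are out of scope.

Substituting each equation into the next shows the trait is linear in
every upstream node plus independent noise. The squared correlations
with the trait are products of the squared link ("mediate")
correlations `r_k²`:

| level   | squared correlation with trait |
|---------|--------------------------------|
| protein | `r3²`                          |
| RNA     | `r2² r3²`                      |
| SNP     | `r1² r2² r3² = h²`             |

Since each `r_k² < 1`, remoteness from the trait strictly attenuates
the correlation — the ordering that drives every power comparison in
the package.

## Parameters and defaults

| parameter | meaning | default | rationale |
|-----------|---------|---------|-----------|
| `maf` | minor allele frequency | 0.25 | common-variant setting used throughout the numerical studies |
| `β1, β2, β3` | structural slopes | (0.5744, 0.7183, 0.4564) | anchor giving h² = 1.0% with unit errors; the implied split r1² ≈ 11%, r2² ≈ 37%, r3² ≈ 25% sits inside the ranges reported for eQTL effect sizes (r1² up to ~15%), mRNA–protein correlations (r2² up to ~50%) and protein–trait correlations (r3² up to ~34%, i.e. a 5-fold EPS fold change) |
| `σ²_e2..e4` | exogenous error variances | 1.0 each | the convention under which the anchor slopes reproduce h² = 1% exactly; only correlations, not scales, affect power |
| `sig_level` | nominal significance | 2.5e-6 | 0.05 / 20,000 protein-coding genes, the usual genome-wide gene-based threshold |
| `sides` | sidedness | 2 | two-sided reproduces the published SRS sample-size cells within ~1–3%; one-sided does not |
| `trunc_alpha` | per-tail EPS fraction | 0.2 | a pool of n/(2α) screened subjects yields n assayed extremes; 0.1–0.2 is the range used in practice |
| `target_power` | for inversion | 0.8 | conventional design power |

Heritability sweeps move along a one-parameter path: all three squared
mediate correlations are scaled by the common factor
`(h²_target / h²_anchor)^(1/3)` so that their product lands exactly on
the target while the relative composition of the chain is preserved.
This common-scaling path is a modelling choice — the composition could
instead be varied link by link — adopted because it reproduces the
published sample-size table to within a few percent at both h² = 0.1%
and 1.0%; it should not be read as the only path consistent with a
given h².

## Power formulas

**SRS.** The slope t-test of a level against the trait at total sample
size n is treated as non-central t with df = n − 2 and non-centrality
`δ = √n·ρ/√(1−ρ²)`, where ρ² is the level–trait squared correlation.
This is the standard fixed-regressor approximation; for random
regressors it is accurate to O(10⁻³) in power (see *Accuracy* below).

**EPS.** With n/2 subjects per tail at per-tail fraction α, write
z = Φ⁻¹(1−α), λ = φ(z)/α (the tail mean of a standard normal, i.e. the
selection differential) and `tail_var = 1 + zλ − λ²` (the within-tail
trait variance). A standardised predictor with correlation ρ to the
trait then has conditional mean ±ρλ and conditional variance
`σ_tail² = 1 − ρ²(1 − tail_var)` in the upper/lower tail, so the pooled
two-sample t statistic is non-central t with df = n − 2 and
`δ = ρλ√n / σ_tail`. `DesignSpec(tail_shrinkage=False)` drops the
σ_tail factor (a cruder variant kept for comparison);
`normal_approx=True` replaces the non-central t with its large-sample
normal limit under both schemes.

Two-sided power is evaluated as
`nct.sf(tcrit, df, δ) + nct.sf(tcrit, df, −δ)`; the second term uses the
symmetry of the non-central t because the direct lower-tail evaluation
`nct.cdf(−tcrit, df, δ)` returns NaN at large df in scipy. At δ = 0 the
power equals the nominal level exactly and is returned as such.

**Fold-change conversion.** Protein intensity is modelled log-normal
with standardised log-intensity correlated ρ with the trait. The
expected between-tail difference in log intensity is 2ρλ(α), so a
reported fold change fc corresponds to `ρ = ln(fc)/(2λ(α))`. At
(fc = 5, α = 0.2) this gives r3² = 33.05%; the figure of 34% sometimes
quoted for the same setting is consistent to within rounding of the
modelling convention, and the conversion here is reported as computed
rather than adjusted toward it.

**Sample-size inversion.** Power is strictly increasing in n, so the
smallest admissible n (any integer under SRS, even under EPS) with
power ≥ target is found by doubling an upper bracket from n = 16 and
bisecting on the integer grid; termination at unit (or two-unit) width
makes the bracketing invariant exact: power(n_required) ≥ target >
power(n_required − step).

## Simulator

`simulate_cohort` draws genotypes Binomial(2, maf) and pushes Gaussian
errors down the chain; `eps_select` simulates a screening pool of
`ceil(n/(2α))` subjects (grown deterministically if integer rounding
leaves a tail short) and labels the n/2 most extreme trait values per
tail, ties broken by sample index. `empirical_power` generates
replicate-by-sample blocks from a single `numpy.random.Generator`
seeded with the user's seed and applies vectorised closed forms of the
same slope/pooled t statistics used by `mcmpower.assoc` (the two routes
are asserted equal in the test suite); identical seeds give identical
results. A hook accepts alternative error samplers for robustness
experiments; the analytic formulas assume Gaussian errors.

The generator emulates an idealised cohort: one causal SNP in
Hardy–Weinberg equilibrium, exact linearity, homoscedastic Gaussian
noise, no measurement error, batch effects or population structure.
Passing tests therefore demonstrate internal consistency of the
analytic machinery under the stated model, not robustness of the power
claims to the violations real multi-omics data exhibit.

## Accuracy and known limitations

* **Oracle agreement.** At (n = 200, anchor chain) and (n = 796, EPS,
  h² = 0.1%) the analytic power of the RNA and protein tests matches
  10⁴-replicate empirical power within 3 Monte-Carlo standard errors;
  the SNP test matches within 0.02 absolute (the genotype is discrete,
  so its two-sample statistic is only approximately t).
* **Extreme-power optimism.** Measured at 10⁵ replicates, the nct
  approximation for the SRS protein test at n = 200 (power ≈ 0.999)
  exceeds empirical power by ≈ 9×10⁻⁴ — a random-regressor
  approximation error that only becomes visible where the binomial
  noise floor collapses. It is documented rather than corrected.
* **Small-n EPS cells.** The non-central-t engine requires n = 136 for
  80% power of the EPS protein test at h² = 0.1%, while the published
  reference table lists 127. Simulation sides with the engine
  (empirical power 0.735 at n = 127 vs 0.799 at n = 136); n = 127 is
  recovered only by the large-sample normal approximation, which
  overstates power at df ≈ 130. The corresponding regression test is
  deliberately left failing at its ±5% tolerance rather than switching
  engines or widening the band; all other published cells reproduce
  within ±5% (SRS rows, EPS h² = 0.1% SNP/RNA) or ±15% (EPS h² = 1.0%
  row, where the reconstruction of the selection-based formula is
  known to deviate).
* **Odd EPS sizes.** EPS requires an even total n (equal tails); odd
  published values (e.g. 795) are compared against the nearest even
  solution.
* **Monte-Carlo problem sizes.** Moment contracts are checked at 10⁶
  samples and power oracles at 10⁴ replicates, sizes at which the
  3-standard-error bands are a few×10⁻³ wide — tight enough to detect
  any formula error that matters at design time.
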