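# Methods

## Model

A PRS is `PRS_i = Σ_{j=1..p} ω_j g_ij`, with fixed, known per-allele
weights `ω_j` and effect-allele counts `g_ij ∈ {0,1,2}` (dosages in
[0,2] are accepted). The calibration treats an individual's ancestral
makeup as a fixed characteristic and the sampled alleles as the source
of randomness. With K reference ancestries and ancestry-specific
frequencies `f_j^{a_k}`:

- **Homogeneous population.** `g_ij ~ Bin(2, f_j)` gives
  `E[PRS] = 2 Σ_j ω_j f_j` and, for independent variants,
  `Var(PRS) = Σ_j ω_j² · 2 f_j (1 − f_j)`.
- **Global ancestry (gePRS).** Allele counts follow a mixture over
  ancestries with weights `π_ik` (the genome-wide ancestry proportions):
  `gePRS_i = Σ_j ω_j Σ_k 2 f_j^{a_k} π_ik` and
  `Var(PRS_i) = Σ_j ω_j² Σ_k 2 f_j^{a_k}(1−f_j^{a_k}) π_ik`.
  Equivalently, the gePRS is the π-weighted combination of
  ancestry-specific expected PRSs.
- **Local ancestry (lePRS).** With known per-haplotype ancestry labels
  `a_ijm` and `g_ijm | a_ijm = a_k ~ Ber(f_j^{a_k})`, independent copies:
  `lePRS_i = Σ_j ω_j (f_j^{a_ij1} + f_j^{a_ij2})` and
  `Var(PRS_i) = Σ_j ω_j² [f^{a1}(1−f^{a1}) + f^{a2}(1−f^{a2})]_j`.

Derived metrics: `rPRS = PRS − ePRS` and
`qPRS = Φ(PRS; μ = ePRS, σ² = Var(PRS))`, a within-person percentile
under a central-limit normal approximation across variants.

**What the "global" variance is (and is not).** The global variance
formula is the π-average of the local (conditional) variance, i.e. the
allele-sampling variance *given* ancestry at each locus. It is not the
full dispersion of PRS among individuals sharing the same π, which is
larger by the variance contributed by local-ancestry sampling,
`2·Var_{k~π}(f_j^{a_k})` per haplotype (about 20% extra for generic
panels; we verified this numerically). Consequences:

- the local qPRS is exactly calibrated under the generative model (its
  empirical distribution is uniform, KS ≈ 0.006 at n = 10,000);
- the global qPRS is mildly over-dispersed (KS ≈ 0.019 at n = 10,000,
  above the 1% critical value 0.016): extreme percentiles are slightly
  over-called when only global proportions are available.

Calibration claims in the test suite therefore use the local model; the
global model is the pragmatic fallback when local calls are unavailable.

## Association models

The PRS–outcome effect `β1` is estimated with working models fit by OLS
(continuous outcomes) or maximum-likelihood logistic regression (binary
outcomes); Wald 95% intervals use ±1.959964·SE. The ePRS models regress
`Y ~ rPRS + ePRS`: since `PRS = rPRS + ePRS`, the rPRS coefficient
equals the PRS coefficient in the reparameterized fit `Y ~ PRS + ePRS`
(checked to 1e-8). Comparators adjust the raw PRS for an observed
confounder, global ancestry proportions (one column dropped against the
intercept), or 10/20 genotype PCs; the PC-adjusted-PRS comparator uses
the residual of PRS on the PCs as the exposure. PCs come from an SVD of
the column-centered, sample-SD-standardized dosage matrix of the PRS
variants, with a deterministic sign convention (largest-|loading| entry
positive); standardizing by `√(2f(1−f))` instead is a constructor
option away but not the default. Constant adjustment columns are
dropped with a warning; genuinely collinear designs raise.

## Simulator

Per replicate: `π_1 ~ U(0,1)`, `π_2 ~ U(0, 1−π_1)`, `π_3` the
remainder (ancestry a1 dominant on average, as for European ancestry in
three-way admixed American cohorts); local ancestry multinomial in
`π_i`, independent across variants and haplotypes; alleles Bernoulli at
the local ancestry's frequency; outcome
`Y = β0 + β1·PRS + γ·conf/sd(conf) + ε`, `ε ~ N(0,1)`, defaults
`β0 = 1`, `β1 = 1.5`, `γ ∈ {0.5, 1, 1.5}` (default 1), n = 10,000,
p = 100, 1000 replicates. A logistic link is available for binary
outcomes.

Fixed, dataset-level quantities — the weight set, frequency panels, and
confounder weights — are drawn once per scenario seed and reused across
replicates, standing in for the real GWAS weights and reference-panel
frequencies a study would hold fixed. Defaults: weights iid N(0, 0.05²)
(a hook accepts a real scoring file), generic panel frequencies iid
U(0.05, 0.95) per ancestry. Confounder designs:

- `conf_prs1`: a PRS over p new variants that reuse, variant-for-variant,
  the main PRS variants' local-ancestry draws (fresh generic
  frequencies, N(0,1) weights) — confounding through shared local
  ancestry;
- `conf_prs2`: 100 fresh variants common in a2 (U(0.4, 0.6)) and rare in
  a1 (U(0.01, 0.1)), N(0,1) weights — strong stratification confounding;
- `conf_pc_star`: 100 fresh generic variants, N(0,1) weights, also
  exposed as an *observed* covariate so the benchmark model M4 can
  adjust for the true confounder (it is not produced by a PCA);
- `single_variant` / `two_variant`: 1–2 enriched variants, unit weight.

Heterogeneous weighting replaces the base weight with 1.5 on the 10
variants most frequent in a2 (when the haplotype's local ancestry is
a2) and 2.0 on a3's top 10 (a2's picks excluded first; frequency ties
break by ascending variant index). Association models always use the
homogeneous PRS, so these scenarios probe model misspecification.

Ancestry-inference error is emulated by mixing each π row with a
Dirichlet(1,…,1) draw (global) or resampling each local label from
`π_i` with a given probability (local); both are our constructions for
sensitivity analysis, not estimates of any specific inference tool's
error process.

Seeding: one root seed; scenario fixtures and each replicate use
independent `SeedSequence` substreams keyed by replicate index, so any
replicate is reproducible in isolation and results are independent of
execution order.

### What the generator does *not* emulate

No linkage disequilibrium, recombination maps, or realistic ancestry
tract lengths (labels are iid across variants); no relatedness; no
genotyping/imputation error; frequencies are synthetic rather than
estimated from reference panels. Green simulation tests therefore
establish the statistical behaviour of the estimators under the stated
generative model — not performance on real cohorts with LD and inferred
(noisy) ancestries.

## Evaluation

Bias, empirical variance (population denominator, so
`MSE = bias² + variance` holds exactly), and MSE of `β̂1` are computed
over replicates, with the MC standard error of the MSE as
`SD((β̂1−β1)²)/√reps`. Desk-scale defaults are 200 replicates of
n = 5,000 (reduced from 1000 × 10,000); tolerances are expressed in MC
SEs so the reduction widens, never biases, the checks. Under the
strong-confounding design the unadjusted model's MSE grows roughly with
γ², driven by bias; the ePRS models stay unbiased, their MSE growing
only mildly through residual-variance inflation. Against the oracle
adjustment (M4) in the conf-pc* scenario the ePRS model is equally
unbiased but less efficient, with an MSE ratio that itself grows with γ
(≈1.8 at γ = 1, ≈2.8 at γ = 1.5 in our runs) because the oracle also
removes the confounder from the residual variance.

## Numerical and edge-case choices

- qPRS with zero variance (all frequencies 0/1) is undefined and
  returned as NaN, never clamped to 0/1; `risk_stratify` never flags
  NaN; ties at the threshold are flagged (≥ convention).
- qPRS warns below 30 variants (configurable) — the normal
  approximation is a CLT statement — and is refused entirely when the
  caller declares the weight set un-clumped, since the closed-form
  variance assumes independence.
- Missing genotypes: PRS, ePRS, and variance for an individual are all
  computed over that individual's non-missing variants, so rPRS always
  compares like with like.
- Harmonization: variants are matched by id; panel/genotype counted
  alleles are re-expressed as effect-allele counts (`f → 1−f`,
  `g → 2−g`); unresolvable allele mismatches are dropped and counted;
  strand-ambiguous (A/T, C/G) variants are kept with a warning — inputs
  are assumed to come from one build/panel, and no strand inference is
  attempted. The operation is idempotent. Multiallelic VCF records are
  skipped (the allele-count model is biallelic).
- msp intervals are 0-based half-open; a position on a boundary belongs
  to the interval that starts there; uncovered positions are an error.
- Q-table rows off unit sum by more than the tolerance (default 1e-3)
  are an error rather than silently renormalized.

## Known limitations

LD-aware variances (hence qPRS for genome-wide scores built from
correlated variants) are not supported. The global qPRS over-dispersion
described above is inherent to conditioning only on π. Logistic-link
simulation is provided for classification-style experiments, but no
claim is made that it reproduces any particular published figure.
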