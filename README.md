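# eprs — ancestry-aware calibration of polygenic risk scores

Polygenic risk scores (PRSs) are weighted sums of risk-allele counts,
`PRS_i = Σ_j ω_j g_ij`. Because allele frequencies differ between
ancestral populations, the *distribution* of a PRS shifts with an
individual's admixture pattern: two people can have different PRS values
purely because of their ancestry, and PRS–outcome association studies in
admixed cohorts are confounded by population stratification.

This package implements an expectation-based calibration of the PRS for
analysts working with admixed or multi-ancestry cohorts:

- **ePRS** — the expected PRS given an individual's ancestral makeup and
  ancestry-specific allele frequencies `f_j^{a_k}`. From global ancestry
  proportions `π_ik`:
  `gePRS_i = Σ_j ω_j Σ_k 2 f_j^{a_k} π_ik`,
  with allele-sampling variance (independent, clumped variants)
  `Var(PRS_i) = Σ_j ω_j² Σ_k 2 f_j^{a_k}(1 − f_j^{a_k}) π_ik`.
  From per-haplotype local ancestry calls `a_ijm`:
  `lePRS_i = Σ_j ω_j (f_j^{a_ij1} + f_j^{a_ij2})`, with the analogous
  per-haplotype variance.
- **rPRS = PRS − ePRS** — the ancestry-calibrated deviation; its
  distribution is centered at zero in every ancestry stratum, so it
  compares genetic risk across individuals of different ancestral makeup.
- **qPRS = Φ(PRS; μ = ePRS, σ² = Var(PRS))** — the individual's
  percentile within their own (normal-approximation) PRS distribution;
  an equitable basis for risk thresholds across ancestries.

In association analysis, fitting `Y ~ rPRS + ePRS` estimates the
PRS–outcome effect while the ePRS term blocks the ancestry "back-door
path" that otherwise biases the naive fit `Y ~ PRS` — playing the role
usually given to genetic principal components, but with a PRS-specific,
dataset-transferable interpretation.

The package also ships:

- an **admixture simulator** (3-way sequential-uniform global
  proportions → multinomial local ancestry → Bernoulli alleles →
  PRS/confounder → outcome) with ancestry-enriched genetic confounders
  of several designs (`conf_prs1`, `conf_prs2`, `conf_pc_star`,
  single/two-variant) and heterogeneous (ancestry-specific) true weights;
- the **working association models** M1–M7 (unadjusted; rPRS+gePRS;
  lrPRS+lePRS; observed-confounder benchmark; global-proportion
  adjustment; 10 or 20 genotype PCs) plus a PC-adjusted-PRS comparator;
- an **evaluation harness** computing bias, empirical variance, and MSE
  (with Monte-Carlo standard errors) of the estimated PRS effect over
  replicate grids and confounder-strength sweeps;
- readers/writers for PGS-Catalog-style scoring files, ancestry-specific
  frequency panels, ADMIXTURE/RFMix-style Q tables, RFMix msp local
  ancestry, VCF/dosage genotypes, and an allele **harmonizer** that
  aligns all inputs to count effect alleles.

## Worked example

Simulate one admixed cohort (n = 5,000, p = 100 clumped variants) with a
strong ancestry-enriched confounder, score everyone, and compare the
naive and calibrated association models:

```python
from eprs import core, models as assoc, simulate as sim

scen = sim.SimScenario(n=5000, p=100, seed=7, confounder="conf_prs2",
                       gamma=1.5, reps=1)
inputs = sim.scenario_inputs(scen)
rep = sim.simulate_replicate(scen, 0, inputs=inputs)

prof = core.build_profile(
    core.ProfileInputs(inputs.weights, inputs.panel, rep.genotypes, gam=rep.gam),
    eprs_kind="global",
)
print(prof.head(4).round(4).to_string(index=False))

fit1 = assoc.fit_working_model("M1_none", rep.outcome, prof)
fit2 = assoc.fit_working_model("M2_gePRS", rep.outcome, prof)
print(f"M1 (unadjusted)   beta1_hat = {fit1.prs_term_estimate:.3f}")
print(f"M2 (rPRS + gePRS) beta1_hat = {fit2.prs_term_estimate:.3f}   (truth 1.5)")
```

Output:

```
individual_id    prs   eprs  var_prs    rprs   qprs  n_variants_used eprs_kind
         ind1 1.7007 1.0979   0.1219  0.6028 0.9579              100    global
         ind2 0.3567 1.0385   0.1200 -0.6818 0.0246              100    global
         ind3 1.6001 1.2148   0.1196  0.3853 0.8674              100    global
         ind4 0.3483 0.9791   0.1204 -0.6307 0.0345              100    global
M1 (unadjusted)   beta1_hat = 1.794
M2 (rPRS + gePRS) beta1_hat = 1.484   (truth 1.5)
```

`ind1` and `ind3` have nearly the same ePRS (baseline genetic value
implied by their admixture), but `ind1` sits at the 96th percentile of
their personal PRS distribution and `ind2` at the 2nd — that is the
information the qPRS carries, independent of ancestral makeup. In the
association fits, the outcome was generated with a PRS effect of 1.5
plus an unobserved ancestry-correlated confounder: the naive model
over-estimates (1.79), while the ePRS-calibrated model recovers the
truth (1.48) on this single replicate.

Command-line equivalents: `eprs score`, `eprs simulate`,
`eprs associate`, `eprs evaluate` (see `--help` on each).

## Acceptance script

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch, the mean estimated PRS coefficients (and
intercept) of the working models over 200-replicate simulation grids
(n = 5,000, p = 100): the unadjusted model without confounding, the
global-ePRS-adjusted model under strong `conf_prs2` confounding, and the
local-ePRS-adjusted model under `conf_prs1` confounding, writing one
JSON entry per quantity. Runtime is roughly two minutes on one CPU.

## Scope notes

Variant weights are treated as fixed and known; the closed-form variance
assumes clumped (approximately independent) variants, so qPRS is
refused for weight sets declared un-clumped. Linkage disequilibrium,
kinship/mixed models, and local-ancestry *inference* are out of scope —
local ancestry and ancestry-specific frequencies are consumed as inputs.
See `docs/methods.md` for the model, its assumptions, and numerical
choices.
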