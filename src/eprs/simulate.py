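"""Generative model for synthetic admixed cohorts, PRSs, confounders, outcomes.

The data-generating mechanism proceeds in five steps per replicate:

1. global ancestry proportions per individual for a 3-way admixture,
   drawn sequentially: ``pi_1 ~ U(0,1)``, ``pi_2 ~ U(0, 1-pi_1)``,
   ``pi_3 = 1 - pi_1 - pi_2`` (so ancestry ``a1`` dominates on average,
   as for, e.g., European ancestry in Hispanic/Latino admixed cohorts);
2. local ancestry per variant and haplotype, multinomial with
   probabilities ``pi_i`` (variants and the two copies independent);
3. alleles per haplotype, Bernoulli at the local ancestry's
   ancestry-specific frequency;
4. PRS and an ancestry-correlated genetic confounder as weighted allele
   sums;
5. a continuous outcome
   ``Y = beta0 + beta1 * PRS + gamma * conf/sd(conf) + eps``,
   ``eps ~ N(0,1)`` (or a Bernoulli outcome through a logistic link).

Weight sets, frequency panels, and confounder definitions are drawn once
per scenario (they play the role of fixed real-world GWAS weights and
reference-panel frequencies); everything individual-level is redrawn per
replicate from a counter-based substream, so replicate ``r`` is
reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .io_formats import (
    AncestryFrequencyPanel,
    GenotypeMatrix,
    GlobalAncestryMatrix,
    LocalAncestryTensor,
    WeightSet,
)

ANCESTRY_LABELS = ("a1", "a2", "a3")

#: default weight scale for synthetic PRS weights (per-allele effects)
WEIGHT_SD = 0.05

_CONFOUNDERS = (
    "none", "conf_prs1", "conf_prs2", "conf_pc_star", "single_variant", "two_variant",
)


@dataclass
class SimScenario:
    """Configuration of one simulation setting.

    Defaults mirror the reference design: cohorts of 10,000 individuals,
    100 clumped PRS variants, 3-way admixture, PRS effect ``beta1 = 1.5``,
    intercept ``beta0 = 1``, confounder effect ``gamma`` in
    {0.5, 1, 1.5}, 1000 replicates.
    """

    n: int = 10_000
    p: int = 100
    n_ancestries: int = 3
    weighting: str = "homogeneous"
    confounder: str = "none"
    beta0: float = 1.0
    beta1: float = 1.5
    gamma: float = 1.0
    reps: int = 1000
    seed: int = 0
    ancestry_noise: tuple[str, float] | None = None
    outcome_family: str = "linear"
    weight_file: str | None = None  # hook to score with real GWAS weights

    def __post_init__(self) -> None:
        if min(self.n, self.p, self.reps) < 1:
            raise ValueError("n, p, reps must all be >= 1")
        if self.n_ancestries < 2:
            raise ValueError("admixture scenarios need at least 2 ancestries")
        if self.weighting not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown weighting {self.weighting!r}")
        if self.confounder not in _CONFOUNDERS:
            raise ValueError(f"unknown confounder {self.confounder!r}")
        if self.outcome_family not in ("linear", "logistic"):
            raise ValueError(f"unknown outcome family {self.outcome_family!r}")
        if self.ancestry_noise is not None:
            kind, level = self.ancestry_noise
            if kind not in ("global", "local") or not 0 <= level <= 1:
                raise ValueError("ancestry_noise must be ('global'|'local', level in [0,1])")


@dataclass
class ScenarioInputs:
    """Scenario-level fixtures: weights, panels, confounder definition."""

    weights: WeightSet
    panel: AncestryFrequencyPanel
    weight_table: np.ndarray | None  # (p, K) ancestry-specific weights, or None
    conf_weights: np.ndarray | None
    conf_panel: AncestryFrequencyPanel | None
    pcstar_weights: np.ndarray
    pcstar_panel: AncestryFrequencyPanel


@dataclass
class SimReplicate:
    """One simulated dataset plus the generative truth."""

    gam: GlobalAncestryMatrix
    lat: LocalAncestryTensor
    haplotypes: np.ndarray           # (n, p, 2) allele indicators
    genotypes: GenotypeMatrix
    prs_true: np.ndarray             # enters the outcome model
    prs_assoc: np.ndarray            # homogeneous-weighting PRS used by all models
    confounder_value: np.ndarray
    conf_pc_star: np.ndarray         # observed covariate for the benchmark model
    outcome: np.ndarray
    truth: tuple[float, float, float]
    gam_obs: GlobalAncestryMatrix = None
    lat_obs: LocalAncestryTensor = None


# ---------------------------------------------------------------------------
# RNG streams
# ---------------------------------------------------------------------------


def replicate_rng(seed: int, rep_index: int) -> np.random.Generator:
    """Independent substream for replicate ``rep_index`` under root ``seed``."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(0, rep_index)))


def scenario_rng(seed: int) -> np.random.Generator:
    """Substream for scenario-level fixtures (weights, panels)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(1,)))


# ---------------------------------------------------------------------------
# Sampling steps
# ---------------------------------------------------------------------------


def sample_global_proportions(n: int, rng: np.random.Generator) -> GlobalAncestryMatrix:
    """Sequential-uniform 3-way global proportions (see module docstring)."""
    pi1 = rng.uniform(0.0, 1.0, size=n)
    pi2 = rng.uniform(0.0, 1.0 - pi1)
    pi3 = 1.0 - pi1 - pi2
    props = np.column_stack([pi1, pi2, pi3])
    ids = np.asarray([f"ind{i + 1}" for i in range(n)], dtype=object)
    return GlobalAncestryMatrix(ids, list(ANCESTRY_LABELS), props)


def sample_local_ancestry(
    gam: GlobalAncestryMatrix,
    p: int,
    rng: np.random.Generator,
    variant_ids=None,
) -> LocalAncestryTensor:
    """Draw per-variant, per-haplotype ancestry labels, multinomial in ``pi_i``.

    Variants and the two chromosomal copies are sampled independently.
    """
    cum = np.cumsum(gam.props, axis=1)  # (n, K)
    u = rng.random((gam.n_individuals, p, 2))
    codes = (u[..., None] > cum[:, None, None, :]).sum(axis=-1).astype(np.int8)
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(p)]
    return LocalAncestryTensor(
        individual_id=gam.individual_id,
        variant_id=np.asarray(list(variant_ids), dtype=object),
        ancestries=list(gam.ancestries),
        codes=codes,
    )


def sample_haplotypes(
    lat: LocalAncestryTensor,
    panel: AncestryFrequencyPanel,
    rng: np.random.Generator,
) -> np.ndarray:
    """Bernoulli allele per haplotype at its local ancestry's frequency; (n, p, 2)."""
    if not set(lat.ancestries) <= set(panel.ancestries):
        raise ValueError("panel does not cover all local-ancestry labels")
    col_of = np.asarray([panel.ancestries.index(a) for a in lat.ancestries])
    jidx = np.arange(lat.n_variants)[None, :, None]
    f = panel.freq[jidx, col_of[lat.codes]]  # (n, p, 2)
    return (rng.random(f.shape) < f).astype(np.int8)


def sample_genotypes(
    lat: LocalAncestryTensor,
    panel: AncestryFrequencyPanel,
    rng: np.random.Generator,
) -> GenotypeMatrix:
    """Sum of the two haplotype alleles as a :class:`GenotypeMatrix`."""
    haps = sample_haplotypes(lat, panel, rng)
    return GenotypeMatrix(
        individual_id=lat.individual_id,
        variant_id=lat.variant_id,
        dosage=haps.sum(axis=2).astype(float),
    )


def synthesize_frequency_panel(
    p: int,
    n_ancestries: int = 3,
    profile: str = "generic",
    rng: np.random.Generator | None = None,
    variant_ids=None,
) -> AncestryFrequencyPanel:
    """Synthetic ancestry-specific frequency panel.

    ``generic`` draws every frequency iid Uniform(0.05, 0.95).
    ``conf_prs2_enriched`` mimics variants chosen to be common in one
    ancestry and rare in the dominant one — the recipe behind a strong
    ancestry confounder: ancestry ``a2`` frequencies ~ Uniform(0.4, 0.6),
    ``a1`` ~ Uniform(0.01, 0.1), remaining ancestries Uniform(0.05, 0.95).
    """
    if rng is None:
        rng = np.random.default_rng()
    freq = rng.uniform(0.05, 0.95, size=(p, n_ancestries))
    if profile == "conf_prs2_enriched":
        freq[:, 0] = rng.uniform(0.01, 0.1, size=p)
        freq[:, 1] = rng.uniform(0.4, 0.6, size=p)
    elif profile != "generic":
        raise ValueError(f"unknown panel profile {profile!r}")
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(p)]
    return AncestryFrequencyPanel(
        variant_id=np.asarray(list(variant_ids), dtype=object),
        counted_allele=np.asarray(["A"] * p, dtype=object),
        ancestries=list(ANCESTRY_LABELS[:n_ancestries]),
        freq=freq,
    )


def default_weights(p: int, rng: np.random.Generator, variant_ids=None) -> WeightSet:
    """Synthetic per-allele weights, iid N(0, 0.05^2)."""
    if variant_ids is None:
        variant_ids = [f"v{j + 1}" for j in range(p)]
    return WeightSet(
        variant_id=np.asarray(list(variant_ids), dtype=object),
        effect_allele=np.asarray(["A"] * p, dtype=object),
        other_allele=np.asarray(["G"] * p, dtype=object),
        weight=rng.normal(0.0, WEIGHT_SD, size=p),
    )


def make_heterogeneous_weights(
    weights: WeightSet, panel: AncestryFrequencyPanel
) -> tuple[np.ndarray, dict]:
    """Ancestry-specific weight table for the heterogeneous-weighting PRS.

    The 10 variants most frequent in ancestry ``a2`` get weight 1.5 when a
    haplotype's local ancestry is ``a2``; the top 10 in ``a3`` (after
    excluding ``a2``'s picks) get weight 2 under ``a3``.  Frequency ties
    break by ascending variant index; overlaps resolve ``a2``-first.

    Returns a ``(p, K)`` table (column k = weight applying under local
    ancestry k) and the selected index sets.
    """
    p, K = panel.freq.shape
    if p < 20:
        raise ValueError("heterogeneous weighting needs at least 20 variants")
    if K < 3:
        raise ValueError("heterogeneous weighting is defined for 3 ancestries")
    order_a2 = np.argsort(-panel.freq[:, 1], kind="stable")
    sel_a2 = np.sort(order_a2[:10])
    remaining = np.setdiff1d(np.arange(p), sel_a2)
    order_a3 = remaining[np.argsort(-panel.freq[remaining, 2], kind="stable")]
    sel_a3 = np.sort(order_a3[:10])
    table = np.tile(weights.weight[:, None], (1, K))
    table[sel_a2, 1] = 1.5
    table[sel_a3, 2] = 2.0
    return table, {"a2_top10": sel_a2, "a3_top10": sel_a3}


def heterogeneous_prs(
    haplotypes: np.ndarray, lat: LocalAncestryTensor, weight_table: np.ndarray
) -> np.ndarray:
    """True PRS under ancestry-specific weights, summed haplotype-wise."""
    jidx = np.arange(lat.n_variants)[None, :, None]
    w = weight_table[jidx, lat.codes]  # (n, p, 2)
    return (w * haplotypes).sum(axis=(1, 2))


# ---------------------------------------------------------------------------
# Confounders
# ---------------------------------------------------------------------------


def build_confounder(
    kind: str,
    gam: GlobalAncestryMatrix,
    lat_prs: LocalAncestryTensor | None,
    rng: np.random.Generator,
    conf_weights: np.ndarray | None = None,
    conf_panel: AncestryFrequencyPanel | None = None,
) -> tuple[np.ndarray, dict]:
    """Generate the unobserved ancestry-related genetic confounder U_G.

    Kinds
    -----
    ``none``
        zero vector.
    ``conf_prs1``
        a PRS over new variants that reuse, variant-for-variant, the
        local-ancestry draws of the main PRS variants; fresh generic
        frequencies; weights iid N(0,1).
    ``conf_prs2``
        a PRS over 100 fresh variants with frequencies enriched in
        ancestry ``a2`` (common) and depleted in ``a1`` (rare); weights
        iid N(0,1).  Creates strong stratification confounding.
    ``conf_pc_star``
        a PRS over 100 fresh generic variants with N(0,1) weights,
        standing in for a single "known" genetic PC (it is *not* computed
        by a PCA); the value doubles as an observed covariate.
    ``single_variant`` / ``two_variant``
        1 or 2 enriched variants with unit weight.

    Scenario-level pieces (``conf_weights``, ``conf_panel``) may be passed
    in to keep them fixed across replicates; fresh ones are drawn if
    omitted.
    """
    n = gam.n_individuals
    if kind == "none":
        return np.zeros(n), {}
    if kind == "conf_prs1":
        if lat_prs is None:
            raise ValueError("conf_prs1 requires the PRS local-ancestry tensor")
        m = lat_prs.n_variants
        if conf_panel is None:
            conf_panel = synthesize_frequency_panel(m, len(gam.ancestries), "generic", rng)
        if conf_weights is None:
            conf_weights = rng.normal(0.0, 1.0, size=m)
        lat_conf = LocalAncestryTensor(
            individual_id=lat_prs.individual_id,
            variant_id=np.asarray([f"c{j + 1}" for j in range(m)], dtype=object),
            ancestries=lat_prs.ancestries,
            codes=lat_prs.codes,  # shared local-ancestry intervals
        )
    else:
        if kind in ("conf_prs2", "single_variant", "two_variant"):
            profile = "conf_prs2_enriched"
            m = {"conf_prs2": 100, "single_variant": 1, "two_variant": 2}[kind]
            if conf_weights is None:
                conf_weights = (
                    rng.normal(0.0, 1.0, size=m) if kind == "conf_prs2" else np.ones(m)
                )
        elif kind == "conf_pc_star":
            profile, m = "generic", 100
            if conf_weights is None:
                conf_weights = rng.normal(0.0, 1.0, size=m)
        else:
            raise ValueError(f"unknown confounder kind {kind!r}")
        if conf_panel is None:
            conf_panel = synthesize_frequency_panel(m, len(gam.ancestries), profile, rng)
        lat_conf = sample_local_ancestry(
            gam, m, rng, variant_ids=[f"c{j + 1}" for j in range(m)]
        )
    haps = sample_haplotypes(lat_conf, conf_panel, rng)
    value = (haps.sum(axis=2) @ conf_weights).astype(float)
    return value, {"weights": conf_weights, "panel": conf_panel, "lat": lat_conf}


# ---------------------------------------------------------------------------
# Outcome and noise
# ---------------------------------------------------------------------------


def simulate_outcome(
    prs: np.ndarray,
    conf: np.ndarray | None,
    scenario: SimScenario,
    rng: np.random.Generator,
) -> np.ndarray:
    """Outcome per the generative model; the confounder is standardized to
    unit sample SD within the replicate so gamma is comparable across
    settings."""
    eta = scenario.beta0 + scenario.beta1 * np.asarray(prs, dtype=float)
    if conf is not None and scenario.gamma != 0 and scenario.confounder != "none":
        sd = np.std(conf, ddof=1)
        if sd == 0:
            raise ValueError("confounder has zero variance; cannot standardize")
        eta = eta + scenario.gamma * conf / sd
    if scenario.outcome_family == "linear":
        return eta + rng.normal(0.0, 1.0, size=len(eta))
    prob = 1.0 / (1.0 + np.exp(-eta))
    return (rng.random(len(eta)) < prob).astype(float)


def inject_ancestry_noise(obj, noise_level: float, rng: np.random.Generator, gam=None):
    """Perturb ancestry calls to emulate inference error.

    Global proportions: each row becomes the convex combination
    ``(1-level) * pi + level * Dirichlet(1,...,1)``.  Local labels: each
    label is independently resampled from the individual's ``pi`` with
    probability ``level`` (requires ``gam``).
    """
    if not 0 <= noise_level <= 1:
        raise ValueError("noise_level must lie in [0, 1]")
    if isinstance(obj, GlobalAncestryMatrix):
        if noise_level == 0:
            return obj
        dirich = rng.dirichlet(np.ones(len(obj.ancestries)), size=obj.n_individuals)
        props = (1.0 - noise_level) * obj.props + noise_level * dirich
        return GlobalAncestryMatrix(obj.individual_id, obj.ancestries, props)
    if isinstance(obj, LocalAncestryTensor):
        if noise_level == 0:
            return obj
        if gam is None:
            raise ValueError("local-label resampling requires global proportions")
        fresh = sample_local_ancestry(gam, obj.n_variants, rng, variant_ids=obj.variant_id)
        mask = rng.random(obj.codes.shape) < noise_level
        codes = np.where(mask, fresh.codes, obj.codes).astype(np.int8)
        return LocalAncestryTensor(obj.individual_id, obj.variant_id, obj.ancestries, codes)
    raise TypeError("expected GlobalAncestryMatrix or LocalAncestryTensor")


# ---------------------------------------------------------------------------
# Scenario assembly
# ---------------------------------------------------------------------------


def scenario_inputs(scenario: SimScenario) -> ScenarioInputs:
    """Draw the scenario-level fixtures (fixed across replicates)."""
    rng = scenario_rng(scenario.seed)
    if scenario.weight_file is not None:
        from .io_formats import read_weight_file

        weights = read_weight_file(scenario.weight_file)
        if weights.n_variants != scenario.p:
            raise ValueError("weight file size disagrees with scenario p")
    else:
        weights = default_weights(scenario.p, rng)
    panel = synthesize_frequency_panel(
        scenario.p, scenario.n_ancestries, "generic", rng
    )
    weight_table = None
    if scenario.weighting == "heterogeneous":
        weight_table, _ = make_heterogeneous_weights(weights, panel)

    conf_weights = conf_panel = None
    kind = scenario.confounder
    if kind == "conf_prs1":
        conf_panel = synthesize_frequency_panel(
            scenario.p, scenario.n_ancestries, "generic", rng
        )
        conf_weights = rng.normal(0.0, 1.0, size=scenario.p)
    elif kind == "conf_prs2":
        conf_panel = synthesize_frequency_panel(
            100, scenario.n_ancestries, "conf_prs2_enriched", rng
        )
        conf_weights = rng.normal(0.0, 1.0, size=100)
    elif kind in ("single_variant", "two_variant"):
        m = 1 if kind == "single_variant" else 2
        conf_panel = synthesize_frequency_panel(
            m, scenario.n_ancestries, "conf_prs2_enriched", rng
        )
        conf_weights = np.ones(m)
    # the conf-pc* covariate always exists (benchmark model M4)
    pcstar_panel = synthesize_frequency_panel(
        100, scenario.n_ancestries, "generic", rng
    )
    pcstar_weights = rng.normal(0.0, 1.0, size=100)
    if kind == "conf_pc_star":
        conf_panel, conf_weights = pcstar_panel, pcstar_weights
    return ScenarioInputs(
        weights=weights,
        panel=panel,
        weight_table=weight_table,
        conf_weights=conf_weights,
        conf_panel=conf_panel,
        pcstar_weights=pcstar_weights,
        pcstar_panel=pcstar_panel,
    )


def simulate_replicate(
    scenario: SimScenario,
    rep_index: int = 0,
    inputs: ScenarioInputs | None = None,
) -> SimReplicate:
    """Generate one full replicate of the scenario."""
    if inputs is None:
        inputs = scenario_inputs(scenario)
    rng = replicate_rng(scenario.seed, rep_index)
    gam = sample_global_proportions(scenario.n, rng)
    lat = sample_local_ancestry(gam, scenario.p, rng, variant_ids=inputs.weights.variant_id)
    haps = sample_haplotypes(lat, inputs.panel, rng)
    genotypes = GenotypeMatrix(
        individual_id=gam.individual_id,
        variant_id=lat.variant_id,
        dosage=haps.sum(axis=2).astype(float),
    )
    prs_assoc = genotypes.dosage @ inputs.weights.weight
    if scenario.weighting == "heterogeneous":
        prs_true = heterogeneous_prs(haps, lat, inputs.weight_table)
    else:
        prs_true = prs_assoc

    if scenario.confounder == "conf_pc_star":
        conf_value, _ = build_confounder(
            "conf_pc_star", gam, lat, rng,
            conf_weights=inputs.pcstar_weights, conf_panel=inputs.pcstar_panel,
        )
        pcstar_value = conf_value
    else:
        conf_value, _ = build_confounder(
            scenario.confounder, gam, lat, rng,
            conf_weights=inputs.conf_weights, conf_panel=inputs.conf_panel,
        )
        pcstar_value, _ = build_confounder(
            "conf_pc_star", gam, lat, rng,
            conf_weights=inputs.pcstar_weights, conf_panel=inputs.pcstar_panel,
        )

    outcome = simulate_outcome(prs_true, conf_value, scenario, rng)

    gam_obs, lat_obs = gam, lat
    if scenario.ancestry_noise is not None:
        kind, level = scenario.ancestry_noise
        if kind == "global":
            gam_obs = inject_ancestry_noise(gam, level, rng)
        else:
            lat_obs = inject_ancestry_noise(lat, level, rng, gam=gam)

    return SimReplicate(
        gam=gam,
        lat=lat,
        haplotypes=haps,
        genotypes=genotypes,
        prs_true=prs_true,
        prs_assoc=prs_assoc,
        confounder_value=conf_value,
        conf_pc_star=pcstar_value,
        outcome=outcome,
        truth=(scenario.beta0, scenario.beta1, scenario.gamma),
        gam_obs=gam_obs,
        lat_obs=lat_obs,
    )
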