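"""The admixed-cohort generative model: sampling steps, confounders, outcomes."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import stats

from eprs import simulate as sim

from conftest import make_gam, make_panel, make_weights


# ---------------------------------------------------------------------------
# global proportions
# ---------------------------------------------------------------------------


def test_global_proportions_reproducible_and_valid():
    a = sim.sample_global_proportions(50, np.random.default_rng(1))
    b = sim.sample_global_proportions(50, np.random.default_rng(1))
    np.testing.assert_array_equal(a.props, b.props)
    assert np.all(a.props >= 0)
    np.testing.assert_allclose(a.props.sum(axis=1), 1.0, atol=1e-12)


def test_global_proportion_marginal_means(rng):
    """pi_1 ~ U(0,1) has mean 1/2; pi_2 ~ U(0, 1-pi_1) has mean 1/4."""
    gam = sim.sample_global_proportions(100_000, rng)
    n = gam.n_individuals
    se1 = gam.props[:, 0].std(ddof=1) / np.sqrt(n)
    se2 = gam.props[:, 1].std(ddof=1) / np.sqrt(n)
    assert abs(gam.props[:, 0].mean() - 0.5) < 4 * se1
    assert abs(gam.props[:, 1].mean() - 0.25) < 4 * se2


# ---------------------------------------------------------------------------
# local ancestry
# ---------------------------------------------------------------------------


def test_local_ancestry_degenerate_and_frequency_match(rng):
    gam = make_gam([[1.0, 0.0, 0.0]])
    lat = sim.sample_local_ancestry(gam, 20, rng)
    assert np.all(lat.codes == 0)

    pi = np.array([0.6, 0.3, 0.1])
    gam2 = make_gam([pi])
    lat2 = sim.sample_local_ancestry(gam2, 10_000, rng)
    counts = np.bincount(lat2.codes.ravel(), minlength=3)
    m = lat2.codes.size
    for k in range(3):
        se = np.sqrt(pi[k] * (1 - pi[k]) / m)
        assert abs(counts[k] / m - pi[k]) < 4 * se


def test_local_ancestry_haplotypes_independent(rng):
    """Empirical joint of the two copies' labels matches the product of
    marginals (chi-square on the 3x3 table)."""
    gam = make_gam([[0.5, 0.3, 0.2]])
    lat = sim.sample_local_ancestry(gam, 20_000, rng)
    table = np.zeros((3, 3))
    for h1, h2 in lat.codes[0]:
        table[h1, h2] += 1
    res = stats.chi2_contingency(table)
    assert res.pvalue > 0.001


# ---------------------------------------------------------------------------
# genotypes / panels
# ---------------------------------------------------------------------------


def test_sample_genotypes_degenerate_frequencies(rng):
    gam = make_gam(np.tile([0.4, 0.4, 0.2], (5, 1)))
    lat = sim.sample_local_ancestry(gam, 8, rng)
    panel0 = make_panel(np.zeros((8, 3)))
    assert np.all(sim.sample_genotypes(lat, panel0, rng).dosage == 0)
    panel1 = make_panel(np.ones((8, 3)))
    assert np.all(sim.sample_genotypes(lat, panel1, rng).dosage == 2)


def test_genotype_mean_conditional_on_local_ancestry(rng):
    p = 5
    panel = make_panel(rng.uniform(0.1, 0.9, size=(p, 3)))
    gam = make_gam(np.tile([1 / 3, 1 / 3, 1 / 3], (4000, 1)))
    lat = sim.sample_local_ancestry(gam, p, rng)
    haps = sim.sample_haplotypes(lat, panel, rng)
    f1 = panel.freq[np.arange(p)[None, :], lat.codes[:, :, 0]]
    f2 = panel.freq[np.arange(p)[None, :], lat.codes[:, :, 1]]
    g = haps.sum(axis=2)
    resid = g - (f1 + f2)  # mean-zero given local ancestry
    se = resid.std(ddof=1) / np.sqrt(resid.size)
    assert abs(resid.mean()) < 4 * se


def test_synthesize_frequency_panel_profiles():
    rng = np.random.default_rng(3)
    generic = sim.synthesize_frequency_panel(200, 3, "generic", rng)
    assert np.all((generic.freq > 0.05) & (generic.freq < 0.95))

    enriched = sim.synthesize_frequency_panel(200, 3, "conf_prs2_enriched", rng)
    assert np.all((enriched.freq[:, 1] >= 0.4) & (enriched.freq[:, 1] <= 0.6))
    assert np.all(enriched.freq[:, 0] <= 0.1)

    again = sim.synthesize_frequency_panel(200, 3, "generic", np.random.default_rng(3))
    np.testing.assert_array_equal(again.freq, generic.freq)

    with pytest.raises(ValueError):
        sim.synthesize_frequency_panel(10, 3, "bogus", rng)


# ---------------------------------------------------------------------------
# heterogeneous weights
# ---------------------------------------------------------------------------


def test_heterogeneous_weights_selection_rules():
    p = 25
    weights = make_weights(np.full(p, 0.1))
    freq = np.full((p, 3), 0.5)
    # a2 frequency: tie between many variants at 0.9 -> lowest indices win
    freq[:12, 1] = 0.9
    # a3 top values partially overlap a2's winners
    freq[5:18, 2] = 0.8
    panel = make_panel(freq)
    table, meta = sim.make_heterogeneous_weights(weights, panel)
    # ties at 0.9 broken by ascending index: variants 0..9
    np.testing.assert_array_equal(meta["a2_top10"], np.arange(10))
    # a2 winners excluded from a3 candidates: 10..17 qualify, padded by
    # the next-highest (ties at 0.5 -> ascending index)
    assert set(range(10, 18)) <= set(meta["a3_top10"])
    assert len(meta["a3_top10"]) == 10

    np.testing.assert_array_equal(table[meta["a2_top10"], 1], 1.5)
    np.testing.assert_array_equal(table[meta["a3_top10"], 2], 2.0)
    # outside the selections the table equals the base weights
    mask = np.ones(p, bool)
    mask[meta["a2_top10"]] = False
    np.testing.assert_array_equal(table[mask, 1], weights.weight[mask])
    assert np.all(table[:, 0] == weights.weight)

    with pytest.raises(ValueError, match="20"):
        sim.make_heterogeneous_weights(make_weights(np.ones(10)),
                                       make_panel(np.full((10, 3), 0.5)))


# ---------------------------------------------------------------------------
# confounders
# ---------------------------------------------------------------------------


def test_confounder_none_and_unknown(rng):
    gam = make_gam(np.tile([0.5, 0.3, 0.2], (10, 1)))
    value, _ = sim.build_confounder("none", gam, None, rng)
    assert np.all(value == 0)
    with pytest.raises(ValueError):
        sim.build_confounder("bogus", gam, None, rng)


def test_conf_prs1_shares_prs_local_ancestry(rng):
    gam = sim.sample_global_proportions(30, rng)
    lat = sim.sample_local_ancestry(gam, 40, rng)
    _, meta = sim.build_confounder("conf_prs1", gam, lat, rng)
    np.testing.assert_array_equal(meta["lat"].codes, lat.codes)
    assert meta["lat"].n_variants == lat.n_variants


def test_conf_prs2_correlates_with_a2_proportion(rng):
    """Variants common in a2 and rare in a1 make the confounder track the
    a2 global proportion."""
    gam = sim.sample_global_proportions(10_000, rng)
    conf_w = np.abs(np.random.default_rng(0).normal(size=100))  # positive weights
    value, _ = sim.build_confounder("conf_prs2", gam, None, rng, conf_weights=conf_w)
    r, pval = stats.pearsonr(value, gam.props[:, 1])
    assert r > 0 and pval < 0.01


# ---------------------------------------------------------------------------
# outcomes
# ---------------------------------------------------------------------------


def test_outcome_moments_and_recovery(rng):
    n = 20_000
    scen = sim.SimScenario(n=n, p=100, seed=0, confounder="conf_prs2", gamma=1.5, reps=1)
    prs = rng.normal(size=n)
    conf = rng.normal(loc=2.0, scale=3.0, size=n)
    y = sim.simulate_outcome(prs, conf, scen, rng)
    resid = y - (scen.beta0 + scen.beta1 * prs + scen.gamma * conf / conf.std(ddof=1))
    assert abs(resid.var(ddof=1) - 1.0) < 4 * np.sqrt(2 / (n - 1))

    # OLS on the true regressors recovers (beta0, beta1, gamma) within 4 SEs
    X = sm.add_constant(np.column_stack([prs, conf / conf.std(ddof=1)]))
    fit = sm.OLS(y, X).fit()
    for est, se, truth in zip(fit.params, fit.bse, [1.0, 1.5, 1.5]):
        assert abs(est - truth) < 4 * se


def test_outcome_constant_confounder_errors(rng):
    scen = sim.SimScenario(n=10, p=30, confounder="single_variant", gamma=1.0, reps=1)
    with pytest.raises(ValueError, match="zero variance"):
        sim.simulate_outcome(np.zeros(10), np.ones(10), scen, rng)


def test_logistic_outcome_is_binary(rng):
    scen = sim.SimScenario(n=500, p=30, outcome_family="logistic", reps=1)
    y = sim.simulate_outcome(rng.normal(size=500), None, scen, rng)
    assert set(np.unique(y)) <= {0.0, 1.0}


# ---------------------------------------------------------------------------
# ancestry noise
# ---------------------------------------------------------------------------


def test_inject_ancestry_noise_global(rng):
    gam = sim.sample_global_proportions(2000, rng)
    same = sim.inject_ancestry_noise(gam, 0.0, rng)
    np.testing.assert_array_equal(same.props, gam.props)

    noisy = sim.inject_ancestry_noise(gam, 0.3, rng)
    np.testing.assert_allclose(noisy.props.sum(axis=1), 1.0, atol=1e-9)
    assert np.all(noisy.props >= 0)

    # level 1 -> rows ~ Dirichlet(1,1,1), mean 1/3 per component
    full = sim.inject_ancestry_noise(gam, 1.0, rng)
    se = full.props[:, 0].std(ddof=1) / np.sqrt(full.n_individuals)
    assert abs(full.props[:, 0].mean() - 1 / 3) < 4 * se


def test_inject_ancestry_noise_local(rng):
    gam = sim.sample_global_proportions(200, rng)
    lat = sim.sample_local_ancestry(gam, 50, rng)
    same = sim.inject_ancestry_noise(lat, 0.0, rng, gam=gam)
    np.testing.assert_array_equal(same.codes, lat.codes)
    noisy = sim.inject_ancestry_noise(lat, 0.5, rng, gam=gam)
    frac_changed = (noisy.codes != lat.codes).mean()
    assert 0 < frac_changed < 0.5  # resampling only changes a label sometimes
    with pytest.raises(ValueError, match="proportions"):
        sim.inject_ancestry_noise(lat, 0.5, rng)


# ---------------------------------------------------------------------------
# replicate assembly
# ---------------------------------------------------------------------------


def test_replicate_determinism_and_truth():
    scen = sim.SimScenario(n=300, p=40, seed=42, confounder="conf_prs2", gamma=1.0, reps=2)
    a = sim.simulate_replicate(scen, 1)
    b = sim.simulate_replicate(scen, 1)
    np.testing.assert_array_equal(a.genotypes.dosage, b.genotypes.dosage)
    np.testing.assert_array_equal(a.outcome, b.outcome)
    assert a.truth == (1.0, 1.5, 1.0)

    c = sim.simulate_replicate(scen, 0)
    assert not np.array_equal(a.outcome, c.outcome)


def test_heterogeneous_replicate_prs_differs_from_homogeneous():
    scen = sim.SimScenario(n=200, p=40, seed=7, weighting="heterogeneous", reps=1)
    rep = sim.simulate_replicate(scen, 0)
    assert not np.allclose(rep.prs_true, rep.prs_assoc)
    # haplotype-wise recomputation oracle
    inputs = sim.scenario_inputs(scen)
    expected = np.zeros(scen.n)
    for i in range(scen.n):
        for j in range(scen.p):
            for m in range(2):
                w = inputs.weight_table[j, rep.lat.codes[i, j, m]]
                expected[i] += w * rep.haplotypes[i, j, m]
    np.testing.assert_allclose(rep.prs_true, expected, atol=1e-10)
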