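"""Scenario x model grids over replicates, with bias/variance/MSE summaries.

For each simulated replicate every requested working model is fitted and
its PRS-role coefficient collected; summaries report, per model,

* ``bias = mean(beta1_hat) - beta1``
* ``empirical_variance`` (population denominator, matching the MSE)
* ``mse = mean((beta1_hat - beta1)^2) = bias^2 + empirical_variance``
* ``mse_mc_se`` — the Monte-Carlo standard error of the MSE,
  ``SD((beta1_hat - beta1)^2) / sqrt(reps)``.

All association models score individuals with the homogeneous-weighting
PRS, even when the outcome was generated under heterogeneous weights, so
heterogeneous scenarios probe robustness to PRS misspecification.
Expected PRSs are computed from the generative (true) frequencies and
ancestry calls — or from their noise-perturbed versions in sensitivity
scenarios.
"""

from __future__ import annotations

import logging
from dataclasses import replace as dc_replace

import numpy as np
import pandas as pd

from . import core, models as assoc, simulate

logger = logging.getLogger(__name__)

#: models that need genotype PCs
_PC_MODELS = {"M6_PC10", "M7_PC20", "PCadjPRS"}

#: desk-scale defaults; the reference design is reps=1000, n=10,000
DESK_REPS = 200
DESK_N = 5000


def _replicate_fits(rep, inputs, scenario, model_labels, family):
    """Fit the requested models on one replicate."""
    w, panel = inputs.weights, inputs.panel
    prs = rep.prs_assoc
    base = pd.DataFrame({"prs": prs})

    profiles = {}
    if "M2_gePRS" in model_labels:
        ge, _ = core.global_eprs(w, panel, rep.gam_obs)
        profiles["M2_gePRS"] = base.assign(eprs=ge, rprs=prs - ge)
    if "M3_lePRS" in model_labels:
        le, _ = core.local_eprs(w, panel, rep.lat_obs)
        profiles["M3_lePRS"] = base.assign(eprs=le, rprs=prs - le)

    extras = {"conf_pc_star": rep.conf_pc_star, "gam": rep.gam_obs}
    if _PC_MODELS & set(model_labels):
        n_pcs = 20 if ("M7_PC20" in model_labels or "PCadjPRS" in model_labels) else 10
        extras["pcs"] = assoc.compute_pcs(rep.genotypes, n_pcs)

    fits = {}
    for label in model_labels:
        profile = profiles.get(label, base)
        fits[label] = assoc.fit_working_model(
            label, rep.outcome, profile, extras=extras, family=family
        )
    return fits


def run_scenario(
    scenario: simulate.SimScenario,
    model_labels=("M1_none", "M2_gePRS", "M3_lePRS"),
    reps: int | None = None,
    family: str | None = None,
) -> list[dict]:
    """Simulate ``reps`` replicates and fit every requested model on each.

    Returns a list (one entry per successful replicate) of dicts mapping
    model label to :class:`~eprs.models.AssociationFit`.  Individual
    replicate failures are logged and skipped; more than 1% failures
    aborts with diagnostics.
    """
    reps = scenario.reps if reps is None else reps
    family = family or ("logistic" if scenario.outcome_family == "logistic" else "linear")
    inputs = simulate.scenario_inputs(scenario)
    results, failures = [], []
    for r in range(reps):
        try:
            rep = simulate.simulate_replicate(scenario, r, inputs=inputs)
            results.append(_replicate_fits(rep, inputs, scenario, model_labels, family))
        except Exception as exc:  # noqa: BLE001 - replicate-level containment
            logger.warning("replicate %d failed: %s", r, exc)
            failures.append((r, repr(exc)))
    if len(failures) > 0.01 * reps:
        raise RuntimeError(
            f"{len(failures)}/{reps} replicates failed; first failures: {failures[:5]}"
        )
    if failures:
        logger.warning("%d/%d replicates excluded", len(failures), reps)
    return results


def summarize(fits: list[dict], truth: float) -> pd.DataFrame:
    """Per-model bias/variance/MSE summary of the PRS-role coefficient.

    ``empirical_variance`` uses the population denominator so that
    ``mse = bias**2 + empirical_variance`` holds exactly.
    """
    if not fits:
        raise ValueError("no replicate fits to summarize")
    rows = []
    for label in fits[0]:
        est = np.asarray([f[label].prs_term_estimate for f in fits])
        err2 = (est - truth) ** 2
        bias = est.mean() - truth
        var = est.var(ddof=0)
        rows.append(
            {
                "model_label": label,
                "reps_used": len(est),
                "mean_beta1_hat": est.mean(),
                "bias": bias,
                "empirical_variance": var,
                "mse": err2.mean(),
                "mse_mc_se": err2.std(ddof=1) / np.sqrt(len(est)) if len(est) > 1 else np.nan,
                "mean_beta1_se": float(np.mean([f[label].coef["se"].iloc[1] for f in fits])),
            }
        )
    return pd.DataFrame(rows)


def gamma_sweep(
    scenario_base: simulate.SimScenario,
    gammas=(0.5, 1.0, 1.5),
    model_labels=("M1_none", "M2_gePRS", "M3_lePRS"),
    reps: int | None = None,
) -> pd.DataFrame:
    """Summaries across confounder strengths; one row per (gamma, model)."""
    if not len(tuple(gammas)):
        raise ValueError("gammas must be nonempty")
    frames = []
    for g in gammas:
        scen = dc_replace(scenario_base, gamma=float(g))
        fits = run_scenario(scen, model_labels, reps=reps)
        summ = summarize(fits, truth=scen.beta1)
        summ.insert(0, "gamma", float(g))
        frames.append(summ)
    return pd.concat(frames, ignore_index=True)
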