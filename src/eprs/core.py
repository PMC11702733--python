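"""Expected, residual, and quantile polygenic risk scores.

A PRS is the weighted sum of effect-allele counts,
``PRS_i = sum_j w_j g_ij``.  Because allele frequencies differ between
ancestral populations, the distribution of a PRS shifts with an
individual's admixture pattern.  This module computes, per individual:

* ``ePRS`` — the expectation of the PRS given the individual's ancestral
  makeup and ancestry-specific allele frequencies.  With global ancestry
  proportions ``pi_ik`` the expectation is
  ``sum_j w_j * sum_k 2 f_jk pi_ik`` (gePRS); with per-haplotype local
  ancestry labels it is ``sum_j w_j (f_j^{a1} + f_j^{a2})`` (lePRS).
* ``Var(PRS)`` — the allele-sampling variance conditional on ancestry,
  assuming the variants are independent (clumped) and the two
  chromosomal copies are independent.
* ``rPRS = PRS - ePRS`` — the ancestry-calibrated deviation.
* ``qPRS = Phi((PRS - ePRS)/sd)`` — the individual's percentile within
  their personal (normal-approximation) PRS distribution.

Missing genotypes are handled by computing each individual's PRS, ePRS,
and variance over the *same* subset of non-missing variants, so rPRS
always compares like with like.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import (
    AncestryFrequencyPanel,
    GenotypeMatrix,
    GlobalAncestryMatrix,
    LocalAncestryTensor,
    WeightSet,
)

logger = logging.getLogger(__name__)

#: below this many variants the normal approximation behind qPRS is dubious
DEFAULT_NORMALITY_GUARD = 30


def compute_prs(genotypes: GenotypeMatrix, weights: WeightSet) -> np.ndarray:
    """Weighted sum of allele counts per individual.

    Inputs must be harmonized (same variants, same order, effect-allele
    counts).  Missing genotypes are excluded from the sum.
    """
    _check_aligned(genotypes.variant_id, weights.variant_id)
    contrib = genotypes.dosage * weights.weight[None, :]
    return np.nansum(contrib, axis=1)


def homogeneous_eprs(weights: WeightSet, freqs: np.ndarray) -> tuple[float, float]:
    """Expected PRS and variance for a homogeneous population.

    With a single frequency ``f_j`` per variant, allele counts are
    Bin(2, f_j), giving expectation ``2 sum_j w_j f_j`` and (independent
    variants) variance ``sum_j w_j^2 * 2 f_j (1 - f_j)``.
    """
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != weights.weight.shape:
        raise ValueError(
            f"{len(freqs)} frequencies for {weights.n_variants} variants"
        )
    eprs = 2.0 * float(weights.weight @ freqs)
    var = float((weights.weight**2) @ (2.0 * freqs * (1.0 - freqs)))
    return eprs, var


def global_eprs(
    weights: WeightSet,
    panel: AncestryFrequencyPanel,
    gam: GlobalAncestryMatrix,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual expected PRS and variance from global ancestry proportions.

    Treating each variant's allele count as a mixture over ancestries with
    weights ``pi_ik``:

    * ``gePRS_i  = sum_j w_j sum_k 2 f_jk pi_ik`` — equivalently a
      pi-weighted combination of ancestry-specific expected PRSs;
    * ``Var_i    = sum_j w_j^2 sum_k 2 f_jk (1-f_jk) pi_ik`` — the
      pi-averaged allele-sampling variance, conditional on ancestry.
    """
    _check_aligned(panel.variant_id, weights.variant_id)
    if list(panel.ancestries) != list(gam.ancestries):
        raise ValueError(
            f"ancestry mismatch: panel {panel.ancestries} vs proportions {gam.ancestries}"
        )
    mean_f = gam.props @ panel.freq.T                       # (n, p)
    var_g = gam.props @ (panel.freq * (1.0 - panel.freq)).T  # (n, p)
    eprs = 2.0 * mean_f @ weights.weight
    var = 2.0 * var_g @ (weights.weight**2)
    return eprs, var


def local_eprs(
    weights: WeightSet,
    panel: AncestryFrequencyPanel,
    lat: LocalAncestryTensor,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-individual expected PRS and variance from local ancestry calls.

    Local ancestry is treated as known and fixed: each haplotype copy
    contributes a Bernoulli draw at its own ancestry's frequency, so

    * ``lePRS_i = sum_j w_j (f_j^{a_ij1} + f_j^{a_ij2})``
    * ``Var_i   = sum_j w_j^2 [f^{a1}(1-f^{a1}) + f^{a2}(1-f^{a2})]``
    """
    _check_aligned(lat.variant_id, weights.variant_id)
    if not set(lat.ancestries) <= set(panel.ancestries):
        extra = set(lat.ancestries) - set(panel.ancestries)
        raise ValueError(f"local-ancestry labels missing from panel: {sorted(extra)}")
    # map tensor codes onto panel columns
    col_of = np.asarray([panel.ancestries.index(a) for a in lat.ancestries])
    p = lat.n_variants
    jidx = np.arange(p)[None, :]
    f1 = panel.freq[jidx, col_of[lat.codes[:, :, 0]]]
    f2 = panel.freq[jidx, col_of[lat.codes[:, :, 1]]]
    w = weights.weight
    eprs = (f1 + f2) @ w
    var = (f1 * (1.0 - f1) + f2 * (1.0 - f2)) @ (w**2)
    return eprs, var


def residual_prs(prs: np.ndarray, eprs: np.ndarray) -> np.ndarray:
    """rPRS = PRS - ePRS, elementwise."""
    prs = np.asarray(prs, dtype=float)
    eprs = np.asarray(eprs, dtype=float)
    if prs.shape != eprs.shape:
        raise ValueError("prs and eprs must have equal length")
    return prs - eprs


def quantile_prs(prs: np.ndarray, eprs: np.ndarray, var: np.ndarray) -> np.ndarray:
    """Percentile of each PRS within its personal normal approximation.

    ``qPRS_i = Phi(PRS_i; mean=ePRS_i, sd=sqrt(Var_i))``.  Rows with zero
    variance (all frequencies 0 or 1) are undefined and returned as NaN.
    """
    prs = np.asarray(prs, dtype=float)
    eprs = np.asarray(eprs, dtype=float)
    var = np.asarray(var, dtype=float)
    if np.any(var < 0):
        raise ValueError("negative PRS variance")
    out = np.full(prs.shape, np.nan)
    ok = var > 0
    out[ok] = stats.norm.cdf((prs[ok] - eprs[ok]) / np.sqrt(var[ok]))
    return out


def risk_stratify(qprs: np.ndarray, threshold: float) -> np.ndarray:
    """Flag individuals whose qPRS meets or exceeds ``threshold``.

    Because qPRS is a within-person percentile, roughly ``1 - threshold``
    of individuals are flagged in every ancestry-composition stratum.
    NaN (undefined) qPRS values are never flagged.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must lie in (0, 1)")
    qprs = np.asarray(qprs, dtype=float)
    with np.errstate(invalid="ignore"):
        return np.where(np.isnan(qprs), False, qprs >= threshold)


@dataclass
class ProfileInputs:
    """Bundle of harmonized inputs for :func:`build_profile`."""

    weights: WeightSet
    panel: AncestryFrequencyPanel
    genotypes: GenotypeMatrix
    gam: GlobalAncestryMatrix | None = None
    lat: LocalAncestryTensor | None = None


def build_profile(
    inputs: ProfileInputs,
    eprs_kind: str = "global",
    clumped: bool = True,
    normality_guard: int = DEFAULT_NORMALITY_GUARD,
) -> pd.DataFrame:
    """Compute the full per-individual PRS profile.

    Returns a DataFrame with columns ``individual_id, prs, eprs, var_prs,
    rprs, qprs, n_variants_used, eprs_kind``.  Missing genotypes are
    excluded from PRS, ePRS, and variance alike, per individual.

    The closed-form variance (hence qPRS) assumes independent variants;
    when ``clumped=False`` the weight set is declared un-clumped and qPRS
    is refused (NaN) with a warning.
    """
    w = inputs.weights
    geno = inputs.genotypes
    panel = inputs.panel
    _check_aligned(geno.variant_id, w.variant_id)
    n, p = geno.dosage.shape

    # per-variant expectation / variance contributions, shape (n, p)
    if eprs_kind == "global":
        if inputs.gam is None:
            raise ValueError("global ePRS requires global ancestry proportions")
        mean_f = inputs.gam.props @ panel.freq.T
        var_f = inputs.gam.props @ (panel.freq * (1 - panel.freq)).T
        e_contrib = 2.0 * mean_f * w.weight[None, :]
        v_contrib = 2.0 * var_f * (w.weight**2)[None, :]
    elif eprs_kind == "local":
        if inputs.lat is None:
            raise ValueError("local ePRS requires a local-ancestry tensor")
        lat = inputs.lat
        col_of = np.asarray([panel.ancestries.index(a) for a in lat.ancestries])
        jidx = np.arange(p)[None, :]
        f1 = panel.freq[jidx, col_of[lat.codes[:, :, 0]]]
        f2 = panel.freq[jidx, col_of[lat.codes[:, :, 1]]]
        e_contrib = (f1 + f2) * w.weight[None, :]
        v_contrib = (f1 * (1 - f1) + f2 * (1 - f2)) * (w.weight**2)[None, :]
    elif eprs_kind == "homogeneous":
        # panel must carry a single frequency column
        if panel.n_ancestries != 1:
            raise ValueError("homogeneous ePRS requires a single-column panel")
        f = panel.freq[:, 0]
        e_contrib = np.broadcast_to(2.0 * f * w.weight, (n, p)).copy()
        v_contrib = np.broadcast_to(
            2.0 * f * (1 - f) * (w.weight**2), (n, p)
        ).copy()
    else:
        raise ValueError(f"unknown eprs_kind {eprs_kind!r}")

    observed = ~np.isnan(geno.dosage)
    prs = np.nansum(geno.dosage * w.weight[None, :], axis=1)
    eprs = np.where(observed, e_contrib, 0.0).sum(axis=1)
    var = np.where(observed, v_contrib, 0.0).sum(axis=1)
    n_used = observed.sum(axis=1)

    rprs = residual_prs(prs, eprs)
    if not clumped:
        warnings.warn(
            "weight set declared un-clumped: the independence-based variance "
            "does not apply, qPRS withheld",
            stacklevel=2,
        )
        qprs = np.full(n, np.nan)
    else:
        if np.any(n_used < normality_guard):
            warnings.warn(
                f"qPRS normal approximation dubious: some individuals use "
                f"fewer than {normality_guard} variants",
                stacklevel=2,
            )
        qprs = quantile_prs(prs, eprs, var)

    return pd.DataFrame(
        {
            "individual_id": geno.individual_id,
            "prs": prs,
            "eprs": eprs,
            "var_prs": var,
            "rprs": rprs,
            "qprs": qprs,
            "n_variants_used": n_used,
            "eprs_kind": eprs_kind,
        }
    )


def _check_aligned(a: np.ndarray, b: np.ndarray) -> None:
    if len(a) == 0 or len(b) == 0 or len(a) != len(b) or not np.array_equal(a, b):
        raise ValueError(
            "inputs are not harmonized: variant ids differ in content or order"
        )
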