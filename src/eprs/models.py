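"""Working association models for estimating the PRS-outcome effect.

Seven model specifications are compared for estimating ``beta1``, the
per-unit PRS effect, under population stratification:

========  ==========================================================
label     linear predictor (intercept implicit)
========  ==========================================================
M1_none        PRS
M2_gePRS       global rPRS + global ePRS
M3_lePRS       local rPRS + local ePRS
M4_conf_pc_star  PRS + observed conf-pc* covariate (benchmark)
M5_gaProp      PRS + global ancestry proportions (one column dropped)
M6_PC10        PRS + 10 genotype PCs
M7_PC20        PRS + 20 genotype PCs
PCadjPRS       PC-adjusted PRS + the PCs themselves
========  ==========================================================

In every model the reported ``prs_term_estimate`` is the coefficient of
the model's PRS-role term (PRS, rPRS, or PC-adjusted PRS).  Fits are
plain OLS for continuous outcomes and maximum-likelihood logistic
regression for binary ones; simulated individuals are unrelated, so no
kinship random effect is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .io_formats import GenotypeMatrix, GlobalAncestryMatrix

Z_975 = 1.959964  # two-sided 95% normal quantile

MODEL_LABELS = (
    "M1_none", "M2_gePRS", "M3_lePRS", "M4_conf_pc_star",
    "M5_gaProp", "M6_PC10", "M7_PC20", "PCadjPRS",
)


@dataclass
class PCSet:
    """Principal-component scores of the PRS variant genotypes.

    Columns are ordered by descending singular value with a deterministic
    sign (the largest-|loading| element of each right-singular vector is
    positive).
    """

    scores: np.ndarray            # (n, J)
    singular_values: np.ndarray   # (J,)
    loadings: np.ndarray          # (p_kept, J)
    kept_columns: np.ndarray      # indices of non-constant genotype columns


@dataclass
class AssociationFit:
    """One fitted working model."""

    model_label: str
    family: str
    coef: pd.DataFrame            # term, estimate, se, ci_low, ci_high
    prs_term: str
    prs_term_estimate: float
    n_used: int

    @property
    def intercept(self) -> float:
        return float(self.coef.loc[self.coef["term"] == "const", "estimate"].iloc[0])

    def term(self, name: str) -> float:
        return float(self.coef.loc[self.coef["term"] == name, "estimate"].iloc[0])


def compute_pcs(genotypes, n_components: int) -> PCSet:
    """PCs via SVD of the column-centered, column-standardized dosage matrix.

    Standardization uses the sample SD of each dosage column (not the
    binomial ``sqrt(2f(1-f))``).  Zero-variance columns are dropped with
    a warning.
    """
    X = genotypes.dosage if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes, float)
    n, p = X.shape
    sd = X.std(axis=0, ddof=1)
    keep = np.flatnonzero(sd > 0)
    if len(keep) < p:
        import warnings

        warnings.warn(f"dropping {p - len(keep)} zero-variance genotype columns",
                      stacklevel=2)
    if n_components > min(n, len(keep)):
        raise ValueError("n_components exceeds matrix rank bound")
    Z = (X[:, keep] - X[:, keep].mean(axis=0)) / sd[keep]
    U, s, Vt = np.linalg.svd(Z, full_matrices=False)
    # sign convention: largest-|loading| entry of each component positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    U = U * flip[None, :]
    Vt = Vt * flip[:, None]
    J = n_components
    return PCSet(
        scores=U[:, :J] * s[:J][None, :],
        singular_values=s[:J],
        loadings=Vt[:J].T,
        kept_columns=keep,
    )


def pc_adjust_prs(prs: np.ndarray, pcs: PCSet) -> np.ndarray:
    """Residuals of the PRS regressed on the PCs (with intercept).

    This is the "ancestry-adjusted PRS" comparator: the returned vector
    is orthogonal to every PC column and has SD no larger than the raw
    PRS.
    """
    X = sm.add_constant(pcs.scores)
    beta, *_ = np.linalg.lstsq(X, np.asarray(prs, float), rcond=None)
    return np.asarray(prs, float) - X @ beta


def standardize_per_sd(x: np.ndarray) -> np.ndarray:
    """Scale to unit sample SD (denominator n-1); errors on constant input."""
    x = np.asarray(x, dtype=float)
    sd = np.std(x, ddof=1)
    if sd == 0:
        raise ValueError("cannot standardize a constant vector")
    return x / sd


def fit_working_model(
    label: str,
    outcome: np.ndarray,
    profile: pd.DataFrame,
    extras: dict | None = None,
    covariates: np.ndarray | None = None,
    family: str = "linear",
) -> AssociationFit:
    """Fit one working model and report its PRS-role coefficient.

    Parameters
    ----------
    label : one of :data:`MODEL_LABELS`
    outcome : response vector.
    profile : PRS profile frame with ``prs`` (and ``rprs``/``eprs`` for the
        ePRS models — pass the *global* profile for M2 and the *local*
        profile for M3).
    extras : per-label requirements: ``conf_pc_star`` (M4), ``gam`` (M5),
        ``pcs`` (M6/M7/PCadjPRS, a :class:`PCSet` with enough columns).
    covariates : optional additional design columns.
    family : "linear" (OLS) or "logistic" (MLE; Wald CIs).
    """
    extras = extras or {}
    y = np.asarray(outcome, dtype=float)
    n = len(y)
    prs = profile["prs"].to_numpy()

    if label == "M1_none":
        terms, cols, prs_term = ["prs"], [prs], "prs"
    elif label in ("M2_gePRS", "M3_lePRS"):
        terms = ["rprs", "eprs"]
        cols = [profile["rprs"].to_numpy(), profile["eprs"].to_numpy()]
        prs_term = "rprs"
    elif label == "M4_conf_pc_star":
        conf = extras.get("conf_pc_star")
        if conf is None:
            raise ValueError("M4 requires extras['conf_pc_star']")
        terms, cols, prs_term = ["prs", "conf_pc_star"], [prs, np.asarray(conf, float)], "prs"
    elif label == "M5_gaProp":
        gam: GlobalAncestryMatrix = extras.get("gam")
        if gam is None:
            raise ValueError("M5 requires extras['gam']")
        # proportions sum to 1: drop the last column to keep the intercept
        terms = ["prs"] + [f"prop_{a}" for a in gam.ancestries[:-1]]
        cols = [prs] + [gam.props[:, k] for k in range(len(gam.ancestries) - 1)]
        prs_term = "prs"
    elif label in ("M6_PC10", "M7_PC20"):
        pcs: PCSet = extras.get("pcs")
        if pcs is None:
            raise ValueError(f"{label} requires extras['pcs']")
        J = 10 if label == "M6_PC10" else 20
        if pcs.scores.shape[1] < J:
            raise ValueError(f"{label} needs {J} PCs, got {pcs.scores.shape[1]}")
        terms = ["prs"] + [f"PC{j + 1}" for j in range(J)]
        cols = [prs] + [pcs.scores[:, j] for j in range(J)]
        prs_term = "prs"
    elif label == "PCadjPRS":
        pcs = extras.get("pcs")
        if pcs is None:
            raise ValueError("PCadjPRS requires extras['pcs']")
        adj = pc_adjust_prs(prs, pcs)
        J = pcs.scores.shape[1]
        terms = ["pc_adj_prs"] + [f"PC{j + 1}" for j in range(J)]
        cols = [adj] + [pcs.scores[:, j] for j in range(J)]
        prs_term = "pc_adj_prs"
    else:
        raise ValueError(f"unknown model label {label!r}")

    # constant adjustment columns carry no information beyond the intercept;
    # drop them (the PRS-role term itself must vary)
    keep_terms, keep_cols = [], []
    for t, c in zip(terms, cols):
        c = np.asarray(c, dtype=float)
        if t != prs_term and np.ptp(c) == 0:
            import warnings

            warnings.warn(f"dropping constant term {t!r} from {label}", stacklevel=2)
            continue
        keep_terms.append(t)
        keep_cols.append(c)
    terms, cols = keep_terms, keep_cols

    X = np.column_stack(cols)
    if covariates is not None:
        covariates = np.atleast_2d(np.asarray(covariates, float))
        if covariates.shape[0] != n:
            covariates = covariates.T
        X = np.column_stack([X, covariates])
        terms = terms + [f"x{j + 1}" for j in range(covariates.shape[1])]
    X = sm.add_constant(X, has_constant="add")
    terms = ["const"] + terms

    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError(
            f"design matrix for {label} is rank deficient "
            f"(rank {rank} < {X.shape[1]} columns: {terms})"
        )

    if family == "linear":
        res = sm.OLS(y, X).fit()
    elif family == "logistic":
        res = sm.Logit(y, X).fit(disp=0, maxiter=200)
        if not res.mle_retvals.get("converged", True):
            raise RuntimeError(f"logistic fit for {label} did not converge")
    else:
        raise ValueError(f"unknown family {family!r}")

    est = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    coef = pd.DataFrame(
        {
            "term": terms,
            "estimate": est,
            "se": se,
            "ci_low": est - Z_975 * se,
            "ci_high": est + Z_975 * se,
        }
    )
    return AssociationFit(
        model_label=label,
        family=family,
        coef=coef,
        prs_term=prs_term,
        prs_term_estimate=float(est[terms.index(prs_term)]),
        n_used=n,
    )
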