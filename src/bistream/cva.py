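"""Canonical variate analysis (CVA) of class labels against features.

CVA tests for any linear mapping between a categorical design (here the two
percepts) and a multivariate feature set via the generalized eigenvalues of
the treatment (between-class) against the residual (within-class)
sums-of-squares-and-products matrices of a general linear model.  Wilks'
Lambda is Prod_i 1/(1+lambda_i) = det(W)/det(W+B); inference uses Bartlett's
chi-squared approximation ``-(n - 1 - (p+q+1)/2) ln(Lambda)`` with p*q
degrees of freedom, or (for a single contrast, q = 1) Rao's exact F
transform, which reduces to Hotelling's T^2 / the pooled two-sample t-test
when p = 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = ["CvaResult", "cva", "cva_screen"]


@dataclass
class CvaResult:
    canonical_values: np.ndarray  # generalized eigenvalues, descending
    wilks_lambda: float
    chi2: float
    df: int
    p: float  # primary p-value (per `stat` used)
    p_chi2: float  # Bartlett approximation
    p_f: float | None  # Rao's exact F (q = 1 only)
    canonical_vectors: np.ndarray  # feature-space directions (columns)
    n: int
    p_features: int
    extras: dict = field(default_factory=dict)


def cva(X: np.ndarray, y: np.ndarray, stat: str = "bartlett") -> CvaResult:
    """CVA of an n x p feature matrix against binary labels.

    Builds the within-class (residual, W) and between-class (treatment, B)
    SSP matrices from the GLM of X on the class indicator (with intercept),
    solves the generalized eigenproblem of W^{-1} B, and converts Wilks'
    Lambda to a p-value via Bartlett's chi-squared (``stat="bartlett"``) or
    Rao's exact F for q = 1 (``stat="f"``).  A singular W is
    ridge-regularized by eps*trace/p with a warning.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    n, p = X.shape
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    if n <= p + 2:
        raise ValueError(
            f"n = {n} too small for p = {p} features; reduce the number of modes"
        )
    q = len(classes) - 1

    grand = X.mean(axis=0)
    W = np.zeros((p, p))
    B = np.zeros((p, p))
    for c in classes:
        Xi = X[y == c]
        mi = Xi.mean(axis=0)
        R = Xi - mi
        W += R.T @ R
        d = (mi - grand)[:, None]
        B += Xi.shape[0] * (d @ d.T)

    # guard against singular within-class scatter
    try:
        cond = np.linalg.cond(W)
    except np.linalg.LinAlgError:  # pragma: no cover
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        ridge = 1e-10 * np.trace(W) / p
        if ridge <= 0:
            ridge = 1e-10
        logger.warning("singular residual SSP; ridge-regularizing by %.3g", ridge)
        W = W + ridge * np.eye(p)

    vals, vecs = np.linalg.eig(np.linalg.solve(W, B))
    order = np.argsort(vals.real)[::-1]
    vals = np.clip(vals.real[order], 0.0, None)
    vecs = vecs.real[:, order]
    m = min(p, q)  # at most one nonzero canonical value for two classes
    canonical = vals[:m]

    wilks = float(np.prod(1.0 / (1.0 + canonical)))
    df = p * q
    factor = n - 1 - (p + q + 1) / 2.0
    chi2 = -factor * np.log(wilks)
    p_chi2 = float(stats.chi2.sf(chi2, df))

    p_f = None
    if q == 1:
        df2 = n - p - 1
        if df2 > 0 and wilks > 0:
            F = (1.0 - wilks) / wilks * df2 / p
            p_f = float(stats.f.sf(F, p, df2))
    if stat == "bartlett":
        p_primary = p_chi2
    elif stat == "f":
        if p_f is None:
            raise ValueError("exact F transform unavailable (q != 1 or df <= 0)")
        p_primary = p_f
    else:
        raise ValueError(f"unknown stat {stat!r}")

    return CvaResult(
        canonical_values=canonical,
        wilks_lambda=wilks,
        chi2=float(chi2),
        df=df,
        p=p_primary,
        p_chi2=p_chi2,
        p_f=p_f,
        canonical_vectors=vecs[:, :m],
        n=n,
        p_features=p,
    )


def cva_screen(
    feature_sets: dict, alpha: float = 0.05, stat: str = "bartlett"
) -> dict:
    """Apply CVA to a named collection of feature matrices (per subject, per
    ROI, ...) and count significant sets at ``alpha`` (uncorrected, matching
    per-subject reporting conventions).

    Values may be FeatureMatrix objects or (X, y) tuples.  Returns
    {"results": name -> CvaResult, "significant": name -> bool,
    "n_significant": int, "alpha": alpha}.
    """
    results: dict = {}
    flags: dict = {}
    for name, fm in feature_sets.items():
        X, y = (fm.X, fm.y) if hasattr(fm, "X") else fm
        res = cva(X, y, stat=stat)
        results[name] = res
        flags[name] = bool(res.p < alpha)
    return {
        "results": results,
        "significant": flags,
        "n_significant": int(sum(flags.values())),
        "alpha": alpha,
    }
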