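"""Marker-wise association screening of fold change against SF2.

Pearson and Spearman correlations are computed per marker, tested for
significance, corrected for multiple testing with the Benjamini-Hochberg
step-up procedure (Pearson and Spearman families corrected separately),
and the candidate pool for regression is drawn from the markers with the
strongest linear (Pearson) association.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cohort import CohortMatrix

#: Unadjusted Pearson p-value threshold for the regression candidate pool.
CANDIDATE_ALPHA = 1e-5

#: Largest sample count for which the Spearman null is enumerated exactly.
EXACT_SPEARMAN_N = 9


def _columnwise_pearson(X: np.ndarray, y: np.ndarray):
    """Pearson r of each column of X against y, with zero-variance columns NaN."""
    n = len(y)
    Xc = X - X.mean(axis=0)
    yc = y - y.mean()
    sxx = (Xc**2).sum(axis=0)
    syy = (yc**2).sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc.T @ yc) / np.sqrt(sxx * syy)
    r = np.clip(r, -1.0, 1.0)
    undefined = (sxx == 0) | (syy == 0)
    r[undefined] = np.nan
    return r, undefined


def _pearson_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t distribution with n-2 degrees of freedom."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[np.isnan(r)] = np.nan
    return np.minimum(p, 1.0)


def pearson_screen(cohort: CohortMatrix) -> pd.DataFrame:
    """Pearson correlation of each marker's FC with SF2.

    Returns a DataFrame with columns ``marker_id, r_pearson, p_pearson,
    n_used, defined``.  Markers with zero FC variance are flagged
    undefined (NaN coefficient, no p-value) and are excluded from any
    later multiple-testing correction.  Requires at least 3 samples.
    """
    n = cohort.n_samples
    if n < 3:
        raise ValueError("Pearson screen requires at least 3 samples")
    r, undefined = _columnwise_pearson(cohort.fc, cohort.sf2)
    p = _pearson_pvalues(r, n)
    return pd.DataFrame(
        {
            "marker_id": list(cohort.marker_ids),
            "r_pearson": r,
            "p_pearson": p,
            "n_used": n,
            "defined": ~undefined,
        }
    )


def _exact_spearman_pvalues(xranks: np.ndarray, yrank: np.ndarray, rho: np.ndarray):
    """Exact permutation p-values for Spearman rho at small n.

    Enumerates all n! permutations of the SF2 ranks and counts the
    fraction with |rho| at least as extreme as observed (midranks are
    used throughout, so ties are handled consistently).
    """
    n = len(yrank)
    perms = np.array(list(itertools.permutations(yrank)), dtype=float)
    pc = perms - perms.mean(axis=1, keepdims=True)
    pnorm = np.sqrt((pc**2).sum(axis=1))
    xc = xranks - xranks.mean(axis=0)
    xnorm = np.sqrt((xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        null = (pc @ xc) / np.outer(pnorm, xnorm)
    p = np.full(len(rho), np.nan)
    ok = ~np.isnan(rho)
    thresh = np.abs(rho[ok]) - 1e-12
    p[ok] = (np.abs(null[:, ok]) >= thresh).mean(axis=0)
    return p


def spearman_screen(cohort: CohortMatrix) -> pd.DataFrame:
    """Spearman rank correlation of each marker's FC with SF2.

    Ranks use midranks (average ranks on ties); the coefficient is the
    Pearson correlation of the rank vectors.  Significance is assessed by
    exact permutation enumeration for n <= 9 and by the t approximation
    for larger n (the approximation is routine for n > 20 and is also
    applied for 10 <= n <= 20).
    """
    n = cohort.n_samples
    if n < 3:
        raise ValueError("Spearman screen requires at least 3 samples")
    xranks = stats.rankdata(cohort.fc, axis=0, method="average")
    yrank = stats.rankdata(cohort.sf2, method="average")
    rho, undefined = _columnwise_pearson(xranks, yrank)
    if n <= EXACT_SPEARMAN_N:
        p = _exact_spearman_pvalues(xranks, yrank, rho)
    else:
        p = _pearson_pvalues(rho, n)
    return pd.DataFrame(
        {
            "marker_id": list(cohort.marker_ids),
            "rho_spearman": rho,
            "p_spearman": p,
            "n_used": n,
            "defined": ~undefined,
        }
    )


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adj_(i) = min_{j>=i} (p_(j) * m / j)`` on the ascending sort,
    capped at 1 and mapped back to the input order.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(~np.isfinite(p)) or np.any(p < 0) or np.any(p > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_table(cohort: CohortMatrix) -> pd.DataFrame:
    """Joint screening record per marker.

    Combines the Pearson and Spearman screens and appends BH-adjusted
    q-values (``q_pearson``, ``q_spearman``), each family corrected
    separately over its defined markers only.
    """
    pe = pearson_screen(cohort)
    sp = spearman_screen(cohort).drop(columns=["n_used"])
    out = pe.merge(sp, on="marker_id", suffixes=("", "_sp"))
    out["defined"] = out["defined"] & out["defined_sp"]
    out = out.drop(columns=["defined_sp"])
    for pcol, qcol in (("p_pearson", "q_pearson"), ("p_spearman", "q_spearman")):
        q = np.full(len(out), np.nan)
        ok = out[pcol].notna().to_numpy()
        if ok.any():
            q[ok] = benjamini_hochberg(out.loc[ok, pcol].to_numpy())
        out[qcol] = q
    return out


def select_candidates(
    records: pd.DataFrame, alpha: float = CANDIDATE_ALPHA, basis: str = "pearson_p"
) -> list:
    """Candidate markers for regression: unadjusted Pearson p < ``alpha``.

    ``records`` is a screening table (from :func:`pearson_screen` or
    :func:`correlation_table`) computed on the training set.  Returns
    marker ids ordered by ascending p-value (stable on ties); this order
    is also the deterministic tie-break priority used downstream by
    forward selection.
    """
    if basis != "pearson_p":
        raise ValueError(f"unsupported selection basis {basis!r}")
    mask = records["p_pearson"].notna() & (records["p_pearson"] < alpha)
    hits = records.loc[mask].sort_values("p_pearson", kind="stable")
    return list(hits["marker_id"])
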