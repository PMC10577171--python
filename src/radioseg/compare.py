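"""Marker-wise comparison of radio-sensitive vs radio-resistant groups.

For each marker the fold changes of the RS and RR sample groups are
compared with the Mann-Whitney U test and summarised with the Glass
rank-biserial correlation, a non-parametric effect size
``r = 2*(meanrank_A - meanrank_B)/n`` over the pooled midranks --
algebraically identical to ``2*U_A/(n_A*n_B) - 1``.  Absolute effects are
categorised as negligible / small / medium / large / very large at the
0.1 / 0.3 / 0.5 / 0.7 thresholds.

Sign convention: effects are computed as RR minus RS, so a positive
rank-biserial correlation means the copy number is higher in the
radio-resistant group than in the radio-sensitive one.

Groups may be defined from the utmost segments of a fitted segmentation
(DP-based) or from the SF2 quartiles (Q-based); :func:`overlap_summary`
quantifies the agreement between the two marker hit sets.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import CohortMatrix
from .screen import benjamini_hochberg

#: Pooled-sample size up to which the exact U null distribution is enumerated.
EXACT_MWU_N = 12

#: |r| thresholds for small / medium / large / very large effects.
EFFECT_THRESHOLDS = (0.1, 0.3, 0.5, 0.7)
EFFECT_LABELS = ("negligible", "small", "medium", "large", "very large")


def _check_groups(a, b):
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    return a, b


def _u_statistic(a: np.ndarray, b: np.ndarray) -> float:
    """U for group a, via pooled midranks (ties share average ranks)."""
    na = len(a)
    ranks = stats.rankdata(np.concatenate([a, b]), method="average")
    return float(ranks[:na].sum() - na * (na + 1) / 2.0)


def _exact_mwu_p(u: float, na: int, nb: int) -> float:
    """Two-sided p by full enumeration of rank assignments (no ties)."""
    n = na + nb
    offset = na * (na + 1) / 2.0
    values = [sum(c) - offset for c in itertools.combinations(range(1, n + 1), na)]
    total = len(values)
    le = sum(1 for v in values if v <= u + 1e-9)
    ge = sum(1 for v in values if v >= u - 1e-9)
    return min(1.0, 2.0 * min(le, ge) / total)


def _normal_mwu_p(u: float, na: int, nb: int, pooled: np.ndarray) -> float:
    """Two-sided normal approximation with tie correction and continuity."""
    n = na + nb
    mu = na * nb / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float((counts**3 - counts).sum())
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return 1.0
    diff = u - mu
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    return min(1.0, 2.0 * stats.norm.sf(abs(z)))


def mann_whitney_u(group_a, group_b) -> tuple:
    """Mann-Whitney U (for ``group_a``) and a two-sided p-value.

    Ties are handled with midranks.  When the pooled sample holds at most
    12 values and is tie-free, the p-value comes from full enumeration of
    all rank assignments; otherwise from the normal approximation with
    tie correction and continuity correction.
    """
    a, b = _check_groups(group_a, group_b)
    na, nb = len(a), len(b)
    u = _u_statistic(a, b)
    pooled = np.concatenate([a, b])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if na + nb <= EXACT_MWU_N and not has_ties:
        p = _exact_mwu_p(u, na, nb)
    else:
        p = _normal_mwu_p(u, na, nb, pooled)
    return u, p


def glass_rank_biserial(group_a, group_b) -> float:
    """Glass rank-biserial correlation ``r = 2*(meanrank_a - meanrank_b)/n``.

    Mean midranks are taken over the pooled sample of size
    ``n = n_a + n_b``; the result lies in [-1, 1], with -1 when every
    ``a`` value ranks below every ``b`` value.
    """
    a, b = _check_groups(group_a, group_b)
    na, nb = len(a), len(b)
    ranks = stats.rankdata(np.concatenate([a, b]), method="average")
    mean_a = ranks[:na].mean()
    mean_b = ranks[na:].mean()
    return float(2.0 * (mean_a - mean_b) / (na + nb))


def effect_category(r) -> str:
    """Category label for a rank-biserial effect by its absolute value."""
    r_arr = np.asarray(r, dtype=float)
    if np.any(np.abs(r_arr) > 1 + 1e-12):
        raise ValueError("|r| must not exceed 1")
    idx = np.searchsorted(EFFECT_THRESHOLDS, np.abs(r_arr), side="right")
    out = np.take(EFFECT_LABELS, idx)
    return str(out) if out.ndim == 0 else out


def quartile_groups(cohort: CohortMatrix) -> tuple:
    """Quartile-based RS/RR groups (Q-based definition).

    RS = samples with SF2 at or below the lower quartile, RR = samples at
    or above the upper quartile; quartiles are linear-interpolation
    empirical quantiles, and samples tied exactly at a quartile are
    included on their side.  Requires at least 8 samples.
    """
    if cohort.n_samples < 8:
        raise ValueError("quartile grouping requires at least 8 samples")
    q1, q3 = np.quantile(cohort.sf2, [0.25, 0.75])
    rs = [s for s, v in zip(cohort.sample_ids, cohort.sf2) if v <= q1]
    rr = [s for s, v in zip(cohort.sample_ids, cohort.sf2) if v >= q3]
    return rs, rr


@dataclass(frozen=True)
class ComparisonSummary:
    n_markers: int
    n_significant: int
    n_significant_adjusted: int
    category_counts: dict


def compare_groups(
    cohort: CohortMatrix,
    rs_ids: Sequence[str],
    rr_ids: Sequence[str],
    alpha: float = 1e-5,
) -> tuple:
    """Marker-by-marker RS-vs-RR comparison.

    Returns ``(records, summary)`` where ``records`` is a DataFrame with
    one row per marker (``u_statistic`` and ``rank_biserial`` computed as
    RR minus RS, so positive r means CNV higher in RR), the two-sided
    Mann-Whitney p, its BH adjustment, and the effect category;
    ``summary`` counts markers below ``alpha`` and per category.  Both
    groups must be disjoint subsets of the cohort with at least 2 samples.
    """
    rs_ids, rr_ids = list(rs_ids), list(rr_ids)
    if set(rs_ids) & set(rr_ids):
        raise ValueError("RS and RR groups overlap")
    if len(rs_ids) < 2 or len(rr_ids) < 2:
        raise ValueError("each group needs at least 2 samples")
    index = {s: i for i, s in enumerate(cohort.sample_ids)}
    missing = [s for s in rs_ids + rr_ids if s not in index]
    if missing:
        raise KeyError(f"samples not in cohort: {missing}")
    # group A = RR so that positive effects mean higher CNV in RR
    a_idx = [index[s] for s in rr_ids]
    b_idx = [index[s] for s in rs_ids]
    na, nb = len(a_idx), len(b_idx)
    n = na + nb
    sub = cohort.fc[a_idx + b_idx, :]
    ranks = stats.rankdata(sub, axis=0, method="average")
    ra = ranks[:na].sum(axis=0)
    u = ra - na * (na + 1) / 2.0
    mean_a = ranks[:na].mean(axis=0)
    mean_b = ranks[na:].mean(axis=0)
    r = 2.0 * (mean_a - mean_b) / n

    m = cohort.n_markers
    p = np.empty(m)
    if n <= EXACT_MWU_N:
        for j in range(m):
            col = sub[:, j]
            if len(np.unique(col)) == len(col):
                p[j] = _exact_mwu_p(u[j], na, nb)
            else:
                p[j] = _normal_mwu_p(u[j], na, nb, col)
    else:
        mu = na * nb / 2.0
        var = np.empty(m)
        for j in range(m):
            _, counts = np.unique(sub[:, j], return_counts=True)
            tie_term = float((counts**3 - counts).sum())
            var[j] = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
        diff = u - mu
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
        p = np.where(var > 0, 2.0 * stats.norm.sf(np.abs(z)), 1.0)
        p = np.minimum(p, 1.0)

    q = benjamini_hochberg(p)
    categories = effect_category(r)
    direction = np.where(r > 0, "higher_in_RR",
                         np.where(r < 0, "higher_in_RS", "none"))
    records = pd.DataFrame(
        {
            "marker_id": list(cohort.marker_ids),
            "u_statistic": u,
            "p_value": p,
            "q_value": q,
            "rank_biserial": r,
            "category": categories,
            "direction": direction,
        }
    )
    counts = {lab: int((categories == lab).sum()) for lab in EFFECT_LABELS}
    summary = ComparisonSummary(
        n_markers=m,
        n_significant=int((p < alpha).sum()),
        n_significant_adjusted=int((q < alpha).sum()),
        category_counts=counts,
    )
    return records, summary


def overlap_summary(markers_q, markers_dp) -> tuple:
    """Set overlap of two marker hit sets.

    Returns ``(only_q, only_dp, common, common_fraction_of_union)``;
    an empty union yields fraction 0.
    """
    q, dp = set(markers_q), set(markers_dp)
    common = q & dp
    union = q | dp
    frac = len(common) / len(union) if union else 0.0
    return len(q - dp), len(dp - q), len(common), frac
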