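"""Multiple-input single-output (MISO) linear regression of SF2 on marker FCs.

Ordinary least squares with greedy forward feature selection driven by a
Bayes factor: at each step the candidate marker with the highest Bayes
factor over the current model is added, provided the factor clears the
"strong evidence" threshold (10 by default) and the model stays within the
sample-to-feature cap of at least ``ratio`` (default 10) observations per
independent variable.  The Bayes factor uses the BIC approximation
(unit-information prior): ``BF = exp((BIC_current - BIC_candidate)/2)``
with ``BIC = n*ln(RSS/n) + k*ln(n)``.

Model quality is summarised by the relative error ``RE = |pred - obs|/|obs|``
per sample, its arithmetic mean (MRE) and the RMSE.  The relative error is
preferred over squared error here because it does not discount prediction
mistakes on the low-SF2 (radio-sensitive) samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import linalg as sla
from scipy import stats

from .cohort import CohortMatrix

#: Bayes-factor threshold read as "at least strong evidence".
BF_STRONG = 10.0

#: Minimum observations required per independent variable.
SAMPLES_PER_FEATURE = 10

# An RSS at or below this fraction of the total sum of squares is treated
# as a numerically perfect fit (BF reported as +inf; selection stops).
# Gram-based RSS is computed by subtraction and carries cancellation noise
# of order machine-eps * TSS, so the threshold sits well above that.
_PERFECT_RSS_REL = 1e-12


@dataclass(frozen=True)
class LinearModel:
    """An intercept plus selected-marker OLS model.

    ``terms`` is an ordered list of ``(marker_id, coefficient, p_value)``
    tuples in selection order; ``rss`` is the residual sum of squares on
    the fitting samples and ``sigma2_hat`` the unbiased residual variance.
    """

    intercept: float
    terms: tuple
    fitted_on: tuple
    rss: float
    sigma2_hat: float

    @property
    def markers(self) -> list:
        return [t[0] for t in self.terms]

    @property
    def n_features(self) -> int:
        return len(self.terms)

    def predict(self, cohort: CohortMatrix) -> np.ndarray:
        """Predicted SF2 for every sample of ``cohort``.

        Raises ``KeyError`` if a model marker is missing from the cohort.
        """
        X = cohort.marker_columns(self.markers)
        coefs = np.array([t[1] for t in self.terms])
        return self.intercept + X @ coefs


@dataclass(frozen=True)
class SelectionTrace:
    """Record of a forward-selection run.

    ``steps`` holds ``(step, added_marker_id, bayes_factor)`` for every
    accepted addition; ``stop_reason`` is one of ``bf_below_threshold``,
    ``feature_cap``, ``pool_exhausted``.
    """

    steps: tuple
    stop_reason: str


@dataclass(frozen=True)
class FitMetrics:
    mre: float
    rmse: float
    per_sample_re: np.ndarray


def max_features(n_samples: int, ratio: int = SAMPLES_PER_FEATURE) -> int:
    """Feature cap from the observations-per-variable rule: floor(n/ratio).

    E.g. 116 training samples at 10 observations per variable allow at
    most 11 marker features (the intercept is not counted).
    """
    if n_samples < 0:
        raise ValueError("n_samples must be non-negative")
    if ratio < 1:
        raise ValueError("ratio must be >= 1")
    return n_samples // ratio


def relative_error(predicted, observed):
    """``RE = |predicted - observed| / |observed|`` (observed must be nonzero).

    Dimensionless and scale-free: a prediction of 0.2 for an observed 0.1
    scores RE = 1, while 0.8 for 0.7 scores only ~0.143 -- unlike squared
    error, the same absolute miss is penalised harder on sensitive (low
    SF2) samples.
    """
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if np.any(observed == 0):
        raise ValueError("observed value must be nonzero")
    out = np.abs(predicted - observed) / np.abs(observed)
    return float(out) if out.ndim == 0 else out


def _collinear_markers(design: np.ndarray, marker_ids: Sequence[str]) -> list:
    """Markers involved in a rank deficiency of the design matrix."""
    full_rank = np.linalg.matrix_rank(design)
    involved = []
    for j, mid in enumerate(marker_ids):
        reduced = np.delete(design, j + 1, axis=1)  # column 0 is the intercept
        if np.linalg.matrix_rank(reduced) == full_rank:
            involved.append(mid)
    return involved


def fit_ols(
    X: np.ndarray,
    y: np.ndarray,
    marker_ids: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence] = None,
) -> LinearModel:
    """Least-squares fit of ``y`` on an intercept plus the columns of ``X``.

    Per-coefficient two-sided p-values come from the t distribution with
    ``n - k - 1`` degrees of freedom.  A rank-deficient design raises a
    ``ValueError`` naming the collinear markers.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, k = X.shape
    if marker_ids is None:
        marker_ids = [f"x{j}" for j in range(k)]
    if len(marker_ids) != k:
        raise ValueError("marker_ids length does not match predictor count")
    if n <= k + 1:
        raise ValueError(
            f"need more than {k + 1} samples to fit {k} predictors; got {n}"
        )
    design = np.column_stack([np.ones(n), X])
    p = k + 1
    if np.linalg.matrix_rank(design) < p:
        bad = _collinear_markers(design, marker_ids)
        raise ValueError(f"design matrix is rank deficient; collinear markers: {bad}")
    beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    rss = float(resid @ resid)
    dof = n - p
    sigma2 = rss / dof
    xtx_inv = np.linalg.inv(design.T @ design)
    se = np.sqrt(np.maximum(sigma2 * np.diag(xtx_inv), 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, beta / se, np.inf * np.sign(beta))
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df=dof)
    terms = tuple(
        (str(marker_ids[j]), float(beta[j + 1]), float(pvals[j + 1]))
        for j in range(k)
    )
    fitted_on = tuple(sample_ids) if sample_ids is not None else tuple(range(n))
    return LinearModel(
        intercept=float(beta[0]),
        terms=terms,
        fitted_on=fitted_on,
        rss=rss,
        sigma2_hat=float(sigma2),
    )


def _bic(rss: float, n: int, k: int) -> float:
    return n * math.log(rss / n) + k * math.log(n)


def bayes_factor(candidate_model: LinearModel, current_model: LinearModel, n: int) -> float:
    """Bayes factor of the candidate over the current model (BIC approximation).

    ``BF = exp((BIC_current - BIC_candidate)/2)`` with
    ``BIC = n*ln(RSS/n) + k*ln(n)`` and ``k`` counting all estimated
    coefficients including the intercept.  A zero-RSS candidate (perfect
    fit) is reported as ``+inf``; a zero-RSS current model with an
    imperfect candidate as ``0``.
    """
    if n < 1:
        raise ValueError("n must be positive")
    k_cand = candidate_model.n_features + 1
    k_cur = current_model.n_features + 1
    if candidate_model.rss <= 0 and current_model.rss <= 0:
        return 1.0
    if candidate_model.rss <= 0:
        return math.inf
    if current_model.rss <= 0:
        return 0.0
    delta = _bic(current_model.rss, n, k_cur) - _bic(candidate_model.rss, n, k_cand)
    try:
        return math.exp(delta / 2.0)
    except OverflowError:
        return math.inf


def _subset_rss(G: np.ndarray, cols: list, y_idx: int):
    """RSS and coefficients of the OLS fit defined by Gram-matrix columns.

    ``G`` is the Gram matrix of ``[1, candidates..., y]``; ``cols`` indexes
    the design columns (intercept first).  Returns ``(None, None)`` when
    the sub-Gram is not positive definite (collinear design).
    """
    A = G[np.ix_(cols, cols)]
    b = G[cols, y_idx]
    try:
        c, low = sla.cho_factor(A, check_finite=False)
    except (np.linalg.LinAlgError, sla.LinAlgError, ValueError):
        return None, None
    beta = sla.cho_solve((c, low), b, check_finite=False)
    rss = float(G[y_idx, y_idx] - beta @ b)
    return max(rss, 0.0), beta


def _greedy_gram(
    G: np.ndarray,
    n: int,
    cap: int,
    bf_threshold: float,
):
    """Forward selection on a precomputed Gram matrix.

    ``G`` is the Gram matrix of ``[1, x_1..x_c, y]``.  Returns
    ``(selected candidate positions, accepted (step, pos, bf) list,
    stop_reason, final_rss)``.  Candidates are tried in order; ties in the
    step-winning Bayes factor keep the earliest candidate, so the caller's
    ordering (ascending screening p-value) is the tie-break rule.
    """
    d = G.shape[0]
    y_idx = d - 1
    remaining = list(range(1, d - 1))
    cur_cols = [0]
    rss_cur, _ = _subset_rss(G, cur_cols, y_idx)
    if rss_cur is None:  # cannot happen for n >= 1: A = [[n]]
        raise RuntimeError("intercept-only fit failed")
    tss = max(float(G[y_idx, y_idx]), 1.0)
    perfect = _PERFECT_RSS_REL * tss
    selected: list = []
    steps: list = []
    log_n = math.log(n)
    while True:
        if not remaining:
            return selected, steps, "pool_exhausted", rss_cur
        if len(selected) >= cap:
            return selected, steps, "feature_cap", rss_cur
        if rss_cur <= perfect:
            return selected, steps, "bf_below_threshold", rss_cur
        best_pos, best_bf, best_rss = None, -math.inf, None
        for pos in remaining:
            rss_new, _ = _subset_rss(G, cur_cols + [pos], y_idx)
            if rss_new is None:
                continue  # collinear with the current design; inadmissible
            if rss_new <= perfect:
                bf = math.inf
            else:
                try:
                    bf = math.exp(0.5 * (n * math.log(rss_cur / rss_new) - log_n))
                except OverflowError:
                    bf = math.inf
            if bf > best_bf:
                best_pos, best_bf, best_rss = pos, bf, rss_new
        if best_pos is None:
            return selected, steps, "pool_exhausted", rss_cur
        if best_bf < bf_threshold:
            return selected, steps, "bf_below_threshold", rss_cur
        cur_cols.append(best_pos)
        remaining.remove(best_pos)
        selected.append(best_pos - 1)  # candidate position
        steps.append((len(selected), best_pos - 1, best_bf))
        rss_cur = best_rss


def forward_select(
    cohort: CohortMatrix,
    candidates: Sequence[str],
    bf_threshold: float = BF_STRONG,
    ratio: int = SAMPLES_PER_FEATURE,
) -> tuple:
    """Greedy Bayes-factor forward selection over a candidate marker pool.

    At each step, the model extended by each unused candidate is fitted
    and the candidate with the highest Bayes factor over the current model
    wins; it is accepted iff its BF clears ``bf_threshold`` and the
    feature count stays within ``max_features(n, ratio)``.  Candidate
    order (ascending screening p-value from
    :func:`radioseg.screen.select_candidates`) breaks BF ties.

    Returns ``(LinearModel, SelectionTrace)``.  The intercept is always
    included and never counted against the cap.
    """
    if cohort.n_samples == 0:
        raise ValueError("empty cohort subset")
    candidates = list(candidates)
    X = cohort.marker_columns(candidates)
    y = cohort.sf2
    n = cohort.n_samples
    cap = max_features(n, ratio)
    Z = np.column_stack([np.ones(n), X, y])
    G = Z.T @ Z
    sel, steps, stop, _ = _greedy_gram(G, n, cap, bf_threshold)
    chosen = [candidates[i] for i in sel]
    if chosen:
        model = fit_ols(X[:, sel], y, chosen, sample_ids=cohort.sample_ids)
    else:
        resid = y - y.mean()
        rss = float(resid @ resid)
        model = LinearModel(
            intercept=float(y.mean()),
            terms=(),
            fitted_on=tuple(cohort.sample_ids),
            rss=rss,
            sigma2_hat=rss / (n - 1) if n > 1 else float("nan"),
        )
    trace = SelectionTrace(
        steps=tuple((s, candidates[i], bf) for s, i, bf in steps),
        stop_reason=stop,
    )
    return model, trace


def evaluate(model: LinearModel, cohort: CohortMatrix) -> FitMetrics:
    """Prediction quality of a model on a cohort: per-sample RE, MRE, RMSE."""
    pred = model.predict(cohort)
    re = relative_error(pred, cohort.sf2)
    rmse = float(np.sqrt(np.mean((pred - cohort.sf2) ** 2)))
    return FitMetrics(mre=float(np.mean(re)), rmse=rmse, per_sample_re=re)
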