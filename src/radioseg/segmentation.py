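"""Dynamic-programming segmentation of the SF2 range.

Samples are sorted by SF2 and partitioned into K contiguous batches so as
to minimise the overall weighted mean relative error (MRE): each candidate
batch gets its own forward-selected local MISO model, the batch cost is the
sum of the per-sample relative errors under that model, and an exact DP
over cut positions finds the globally cost-minimal K-segmentation.  The
overall MRE equals both the size-weighted mean of batch MREs and the plain
mean of all per-sample REs.

A batch must hold at least ``min_size`` samples (default 10, reflecting the
requirement of at least 10 observations per independent variable); each
batch's feature cap is derived from its own size.  The breakpoint of a
segment is the highest SF2 value among its members.  The lowest-SF2 segment
is labelled radio-sensitive (RS), the highest radio-resistant (RR), any in
between normally-sensitive (NS).  The number of segments is chosen as the
smallest K >= 3 whose utmost breakpoints coincide exactly with those of the
(K+1)-segmentation ("utmost-border stabilisation").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .cohort import CohortMatrix
from .regression import (
    BF_STRONG,
    SAMPLES_PER_FEATURE,
    LinearModel,
    _greedy_gram,
    fit_ols,
    relative_error,
)

logger = logging.getLogger(__name__)

#: Minimal batch size: one independent variable needs >= 10 observations.
MIN_BATCH = 10

LABEL_RS = "RS"
LABEL_NS = "NS"
LABEL_RR = "RR"


@dataclass(frozen=True)
class Segmentation:
    """An ordered partition of SF2-sorted samples into contiguous segments.

    ``boundaries`` are the K-1 end-exclusive cut positions in the sorted
    order (segment k spans ``sorted[boundaries[k-1]:boundaries[k]]``);
    ``breakpoints`` are the K-1 corresponding SF2 values, each the highest
    SF2 of its lower segment.  ``sample_ids`` and ``sf2`` are stored in
    ascending-SF2 order; ``labels`` aligns with them.
    """

    K: int
    boundaries: tuple
    breakpoints: tuple
    segment_models: tuple
    segment_mre: tuple
    overall_mre: float
    labels: tuple
    sample_ids: tuple
    sf2: np.ndarray
    per_sample_re: np.ndarray

    @property
    def segment_sizes(self) -> tuple:
        edges = (0,) + self.boundaries + (len(self.sample_ids),)
        return tuple(edges[i + 1] - edges[i] for i in range(self.K))

    @property
    def segment_slices(self) -> tuple:
        edges = (0,) + self.boundaries + (len(self.sample_ids),)
        return tuple(slice(edges[i], edges[i + 1]) for i in range(self.K))

    def label_map(self) -> dict:
        return dict(zip(self.sample_ids, self.labels))


@dataclass(frozen=True)
class ValidationMetrics:
    """Segment-wise evaluation of held-out samples.

    Validation samples are assigned to a segment by their observed SF2
    against the breakpoints (lower-exclusive / upper-inclusive); samples
    outside the training SF2 range fall into the nearest utmost segment
    and are flagged.
    """

    weighted_mre: float
    rmse: float
    segment_mre: tuple
    segment_sizes: tuple
    assignments: tuple
    flagged: tuple
    per_sample_re: np.ndarray


class SegmentCostTable:
    """Memoised per-window forward-selected models and RE costs.

    For a cohort already sorted by ascending SF2 and a fixed candidate
    pool, ``cost(i, j)`` fits a forward-selected local model on the sorted
    samples ``i..j-1`` (half-open window) and returns the sum of their
    relative errors.  Cross-product prefix sums make each window's Gram
    matrix O(d^2), so the DP can probe thousands of windows cheaply.
    Identical calls are served from the cache.
    """

    def __init__(
        self,
        sorted_cohort: CohortMatrix,
        candidates: Sequence[str],
        min_size: int = MIN_BATCH,
        bf_threshold: float = BF_STRONG,
        ratio: int = SAMPLES_PER_FEATURE,
    ):
        if np.any(np.diff(sorted_cohort.sf2) < 0):
            raise ValueError("cohort must be sorted by ascending SF2")
        self.cohort = sorted_cohort
        self.candidates = list(candidates)
        self.min_size = int(min_size)
        self.bf_threshold = float(bf_threshold)
        self.ratio = int(ratio)
        self._X = sorted_cohort.marker_columns(self.candidates)
        self._y = sorted_cohort.sf2
        n = sorted_cohort.n_samples
        Z = np.column_stack([np.ones(n), self._X, self._y])
        # prefix[j] = sum of outer products of the first j rows
        outer = Z[:, :, None] * Z[:, None, :]
        self._prefix = np.concatenate(
            [np.zeros((1,) + outer.shape[1:]), np.cumsum(outer, axis=0)]
        )
        self._cache: dict = {}

    @property
    def n_samples(self) -> int:
        return self.cohort.n_samples

    def _window(self, i: int, j: int):
        key = (i, j)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        n = j - i
        if n < self.min_size:
            raise ValueError(f"window [{i}, {j}) smaller than min_size={self.min_size}")
        G = self._prefix[j] - self._prefix[i]
        cap = n // self.ratio
        sel, steps, stop, _ = _greedy_gram(G, n, cap, self.bf_threshold)
        y = self._y[i:j]
        if sel:
            Xw = self._X[i:j][:, sel]
            design = np.column_stack([np.ones(n), Xw])
            beta, _, _, _ = np.linalg.lstsq(design, y, rcond=None)
            pred = design @ beta
        else:
            pred = np.full(n, y.mean())
        re = relative_error(pred, y)
        cost = float(re.sum())
        entry = (tuple(sel), cost, tuple(steps), stop, re)
        self._cache[key] = entry
        return entry

    def cost(self, i: int, j: int) -> float:
        """Sum of per-sample REs of the local model on window ``[i, j)``."""
        return self._window(i, j)[1]

    def model(self, i: int, j: int) -> LinearModel:
        """Fully refit local model (with p-values) for window ``[i, j)``."""
        sel = self._window(i, j)[0]
        y = self._y[i:j]
        ids = self.cohort.sample_ids[i:j]
        if sel:
            chosen = [self.candidates[s] for s in sel]
            return fit_ols(self._X[i:j][:, list(sel)], y, chosen, sample_ids=ids)
        resid = y - y.mean()
        rss = float(resid @ resid)
        n = j - i
        return LinearModel(
            intercept=float(y.mean()),
            terms=(),
            fitted_on=tuple(ids),
            rss=rss,
            sigma2_hat=rss / (n - 1) if n > 1 else float("nan"),
        )


def segment_cost(
    sorted_cohort: CohortMatrix,
    i: int,
    j: int,
    candidates: Sequence[str],
    min_size: int = MIN_BATCH,
    bf_threshold: float = BF_STRONG,
    ratio: int = SAMPLES_PER_FEATURE,
    table: Optional[SegmentCostTable] = None,
) -> tuple:
    """Local model and RE cost of sorted samples ``i..j`` inclusive.

    Convenience wrapper over :class:`SegmentCostTable` (pass ``table`` to
    reuse its cache across calls).  Returns ``(LinearModel, cost)``.
    """
    if table is None:
        table = SegmentCostTable(
            sorted_cohort, candidates, min_size=min_size,
            bf_threshold=bf_threshold, ratio=ratio,
        )
    return table.model(i, j + 1), table.cost(i, j + 1)


def classify_labels(K: int, sizes: Sequence[int]) -> tuple:
    """Per-sample labels for a K-segmentation: RS lowest, RR highest, NS between."""
    if K < 2:
        raise ValueError("classification requires at least 2 segments")
    labels = []
    for k, size in enumerate(sizes):
        if k == 0:
            lab = LABEL_RS
        elif k == K - 1:
            lab = LABEL_RR
        else:
            lab = LABEL_NS
        labels.extend([lab] * size)
    return tuple(labels)


def classify_samples(segmentation: Segmentation) -> tuple:
    """Labels of a fitted segmentation (ascending-SF2 order); requires K >= 2."""
    return classify_labels(segmentation.K, segmentation.segment_sizes)


def compute_breakpoints(boundaries: Sequence[int], sorted_sf2: np.ndarray) -> tuple:
    """SF2 breakpoints: the highest member SF2 of each lower segment."""
    return tuple(float(sorted_sf2[b - 1]) for b in boundaries)


def _build_segmentation(
    table: SegmentCostTable, boundaries: Sequence[int]
) -> Segmentation:
    cohort = table.cohort
    N = cohort.n_samples
    edges = [0] + list(boundaries) + [N]
    K = len(edges) - 1
    models, mres, res = [], [], []
    for k in range(K):
        i, j = edges[k], edges[k + 1]
        entry = table._window(i, j)
        models.append(table.model(i, j))
        mres.append(entry[1] / (j - i))
        res.append(entry[4])
    per_re = np.concatenate(res)
    overall = float(per_re.mean())
    labels = (
        classify_labels(K, [edges[k + 1] - edges[k] for k in range(K)])
        if K >= 2
        else tuple([LABEL_NS] * N)
    )
    return Segmentation(
        K=K,
        boundaries=tuple(int(b) for b in boundaries),
        breakpoints=compute_breakpoints(boundaries, cohort.sf2),
        segment_models=tuple(models),
        segment_mre=tuple(float(m) for m in mres),
        overall_mre=overall,
        labels=labels,
        sample_ids=cohort.sample_ids,
        sf2=cohort.sf2.copy(),
        per_sample_re=per_re,
    )


def optimal_segmentation(
    cohort: CohortMatrix,
    K: int,
    candidates: Sequence[str],
    min_size: int = MIN_BATCH,
    bf_threshold: float = BF_STRONG,
    ratio: int = SAMPLES_PER_FEATURE,
    table: Optional[SegmentCostTable] = None,
) -> Segmentation:
    """Exact DP minimisation of the overall weighted MRE over K-partitions.

    Samples are sorted by ascending SF2 (stable on ties); the DP recurrence
    ``D[k][j] = min_i D[k-1][i] + cost(i, j)`` over feasible last-cut
    positions yields the globally cost-minimal K-segmentation.  Ties are
    broken toward the earliest cut for determinism.  ``table`` may carry a
    shared cost cache (it must wrap the same sorted cohort).
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if table is None:
        table = SegmentCostTable(
            cohort.sorted_by_sf2(), candidates, min_size=min_size,
            bf_threshold=bf_threshold, ratio=ratio,
        )
    N = table.n_samples
    m = table.min_size
    if K * m > N:
        raise ValueError(f"infeasible: K={K} segments of >= {m} need > {N} samples")
    INF = float("inf")
    D = np.full((K + 1, N + 1), INF)
    D[0, 0] = 0.0
    back = np.zeros((K + 1, N + 1), dtype=int)
    for k in range(1, K + 1):
        j_lo = k * m
        j_hi = N - (K - k) * m
        for j in range(j_lo, j_hi + 1):
            best, best_i = INF, -1
            for i in range((k - 1) * m, j - m + 1):
                prev = D[k - 1, i]
                if prev == INF:
                    continue
                total = prev + table.cost(i, j)
                if total < best:
                    best, best_i = total, i
            D[k, j] = best
            back[k, j] = best_i
    cuts = []
    j = N
    for k in range(K, 0, -1):
        i = back[k, j]
        if k > 1:
            cuts.append(int(i))
        j = i
    cuts.reverse()
    return _build_segmentation(table, cuts)


@dataclass(frozen=True)
class StabilityResult:
    """Segmentations across a K range with the stabilisation-based choice."""

    segmentations: dict
    recommended_K: int
    stabilized: bool


def stability_scan(
    cohort: CohortMatrix,
    candidates: Sequence[str],
    K_min: int = 2,
    K_max: int = 6,
    min_size: int = MIN_BATCH,
    bf_threshold: float = BF_STRONG,
    ratio: int = SAMPLES_PER_FEATURE,
) -> StabilityResult:
    """Segment for each K and pick the smallest K whose utmost borders hold.

    The recommended K is the smallest K >= 3 such that both the lowest and
    the highest breakpoint equal -- exactly, as realized SF2 values --
    their counterparts at K+1.  If no K stabilises (or the scan cannot
    look ahead), ``K_max`` is returned with ``stabilized=False``.
    """
    if K_min > K_max:
        raise ValueError("K_min must not exceed K_max")
    sorted_cohort = cohort.sorted_by_sf2()
    if K_max * min_size > sorted_cohort.n_samples:
        raise ValueError("K_max infeasible for this cohort and min_size")
    table = SegmentCostTable(
        sorted_cohort, candidates, min_size=min_size,
        bf_threshold=bf_threshold, ratio=ratio,
    )
    segs = {
        K: optimal_segmentation(cohort, K, candidates, min_size=min_size,
                                bf_threshold=bf_threshold, ratio=ratio, table=table)
        for K in range(K_min, K_max + 1)
    }
    for K in range(max(3, K_min), K_max):
        bp, bp_next = segs[K].breakpoints, segs[K + 1].breakpoints
        if bp and bp_next and bp[0] == bp_next[0] and bp[-1] == bp_next[-1]:
            return StabilityResult(segmentations=segs, recommended_K=K, stabilized=True)
    return StabilityResult(segmentations=segs, recommended_K=K_max, stabilized=False)


def mean_split_baseline(
    cohort: CohortMatrix,
    candidates: Sequence[str],
    bf_threshold: float = BF_STRONG,
    ratio: int = SAMPLES_PER_FEATURE,
) -> Segmentation:
    """Fixed 2-segmentation at the cohort's mean SF2 (non-optimised baseline).

    Samples with SF2 strictly below the mean form the lower (RS) side;
    the rest the upper side.  Local models and MREs are fitted exactly as
    in the DP workflow, so the weighted MRE is directly comparable with
    the DP 2-segment solution.
    """
    sorted_cohort = cohort.sorted_by_sf2()
    mean = float(cohort.sf2.mean())
    n_low = int(np.sum(sorted_cohort.sf2 < mean))
    N = sorted_cohort.n_samples
    if n_low < 2 or N - n_low < 2:
        raise ValueError("degenerate mean split: a side has fewer than 2 samples")
    table = SegmentCostTable(
        sorted_cohort, candidates, min_size=2,
        bf_threshold=bf_threshold, ratio=ratio,
    )
    return _build_segmentation(table, [n_low])


def evaluate_validation(
    segmentation: Segmentation, validation: CohortMatrix
) -> ValidationMetrics:
    """Evaluate a fitted segmentation on held-out samples.

    Each validation sample is assigned to a segment by its observed SF2
    against the training breakpoints (half-open intervals,
    lower-exclusive / upper-inclusive at the breakpoint); the segment's
    local model predicts its SF2.  Samples whose SF2 falls outside the
    training SF2 range are assigned to the nearest utmost segment and
    flagged.
    """
    bps = np.asarray(segmentation.breakpoints, dtype=float)
    sf2 = validation.sf2
    assign = np.searchsorted(bps, sf2, side="left")
    lo, hi = float(segmentation.sf2[0]), float(segmentation.sf2[-1])
    flagged = tuple(
        sid for sid, v in zip(validation.sample_ids, sf2) if v < lo or v > hi
    )
    if flagged:
        logger.warning(
            "%d validation samples outside the training SF2 range", len(flagged)
        )
    per_re = np.empty(validation.n_samples)
    pred_all = np.empty(validation.n_samples)
    seg_mre, seg_sizes = [], []
    for k in range(segmentation.K):
        mask = assign == k
        seg_sizes.append(int(mask.sum()))
        if not mask.any():
            seg_mre.append(float("nan"))
            continue
        sub = validation.take_samples(np.flatnonzero(mask))
        pred = segmentation.segment_models[k].predict(sub)
        pred_all[mask] = pred
        re = relative_error(pred, sub.sf2)
        per_re[mask] = re
        seg_mre.append(float(re.mean()))
    rmse = float(np.sqrt(np.mean((pred_all - sf2) ** 2)))
    return ValidationMetrics(
        weighted_mre=float(per_re.mean()),
        rmse=rmse,
        segment_mre=tuple(seg_mre),
        segment_sizes=tuple(seg_sizes),
        assignments=tuple(int(a) for a in assign),
        flagged=flagged,
        per_sample_re=per_re,
    )
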