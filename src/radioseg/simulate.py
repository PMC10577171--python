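"""Synthetic cohorts with planted segment-wise FC -> SF2 structure.

The generator emulates the statistical shape the segmentation method
assumes: SF2 drawn from an approximately normal distribution on a
realistic range, a small set of informative markers whose fold changes are
linearly linked to SF2 -- with the link exact inside each marker's own SF2
regime -- and a large majority of null markers with pure Gaussian fold
changes.  Full ground truth (regime boundaries, per-regime supports and
coefficients, per-sample regime membership) is returned for recovery
testing.

Construction of informative markers inverts the linear link so that the
regime model ``SF2 = a + sum_m b_m FC_m + e`` holds exactly inside each
regime (``e`` is Gaussian noise in SF2 units).  For a singleton support the
single marker carries the whole signal, ``FC = (SF2 - a - e)/b``.  For a
multi-marker support the first ``m-1`` markers get a shared linear trend
plus independent scatter (``fc_within_sd``) and the last marker closes the
identity; the within-regime residual left by any partial fit is therefore
spanned by the support itself, never by unrelated markers.  Outside its
own regime a marker keeps the same mean linear trend plus extra scatter
(``fc_carryover_sd``): the marker stays strongly correlated with SF2
across the whole cohort -- so it survives genome-wide screening, as real
segment markers must -- while no single model fits it well across a
regime boundary, which is precisely the contrast the DP segmentation
exploits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .cohort import CohortMatrix

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Regime:
    """One SF2 segment of the planted model.

    ``upper`` is the regime's upper SF2 bound (lower-exclusive /
    upper-inclusive against the previous regime's bound); ``support`` are
    the informative marker column indices, with nonzero ``coefficients``
    and the regime ``intercept`` defining the local linear model.
    """

    upper: float
    support: tuple
    coefficients: tuple
    intercept: float

    def __post_init__(self):
        object.__setattr__(self, "support", tuple(int(s) for s in self.support))
        object.__setattr__(
            self, "coefficients", tuple(float(c) for c in self.coefficients)
        )
        if len(self.support) != len(self.coefficients):
            raise ValueError("support and coefficients must have equal length")
        if any(c == 0 for c in self.coefficients):
            raise ValueError("regime coefficients must be nonzero")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterisation of a synthetic cohort.

    ``sf2_distribution`` is ``"uniform"`` on ``sf2_range`` or
    ``"truncated-normal"`` with ``sf2_mean``/``sf2_sd`` truncated to
    ``sf2_range``.  ``regimes`` (possibly empty for a pure-null cohort)
    must have strictly increasing upper bounds ending at the top of
    ``sf2_range``.  ``fc_null_sd`` scales null-marker fold changes,
    ``fc_carryover_sd`` the out-of-regime scatter of informative markers,
    ``noise_sd`` the SF2-unit regression noise.
    """

    n_samples: int
    n_markers: int
    sf2_range: tuple = (0.14, 0.49)
    sf2_distribution: str = "truncated-normal"
    sf2_mean: float = 0.3273
    sf2_sd: float = 0.0868
    regimes: tuple = ()
    fc_null_sd: float = 0.2
    fc_carryover_sd: float = 0.6
    fc_within_sd: float = 0.02
    noise_sd: float = 0.005
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.sf2_range
        if not (0 < lo < hi <= 1):
            raise ValueError("sf2_range must satisfy 0 < low < high <= 1")
        if self.sf2_distribution not in {"uniform", "truncated-normal"}:
            raise ValueError(f"unknown sf2_distribution {self.sf2_distribution!r}")
        if min(self.noise_sd, self.fc_null_sd, self.fc_carryover_sd,
               self.fc_within_sd) < 0:
            raise ValueError("standard deviations must be non-negative")
        uppers = [r.upper for r in self.regimes]
        if uppers:
            if any(u2 <= u1 for u1, u2 in zip(uppers, uppers[1:])):
                raise ValueError("regime upper bounds must be strictly increasing")
            if not np.isclose(uppers[-1], hi):
                raise ValueError("last regime bound must equal sf2_range high")
            for r in self.regimes:
                if any(not 0 <= s < self.n_markers for s in r.support):
                    raise ValueError("regime support outside marker range")

    @property
    def true_breakpoints(self) -> tuple:
        """Planted segment boundaries (upper bounds of all but the last regime)."""
        return tuple(r.upper for r in self.regimes[:-1])


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually planted, for recovery tests."""

    true_breakpoints: tuple
    true_models: tuple  # (intercept, support, coefficients) per regime
    sample_regime: np.ndarray  # regime index per sample; -1 if no regimes
    noise_sd: float

    def sorted_cut_positions(self, sf2: np.ndarray) -> tuple:
        """True cut positions in the ascending-SF2 sample order."""
        order = np.argsort(sf2, kind="stable")
        reg_sorted = self.sample_regime[order]
        n_regimes = int(self.sample_regime.max()) + 1
        return tuple(int(np.sum(reg_sorted <= r)) for r in range(n_regimes - 1))


def _draw_sf2(spec: SyntheticSpec, rng: np.random.Generator) -> np.ndarray:
    lo, hi = spec.sf2_range
    if spec.sf2_distribution == "uniform":
        return rng.uniform(lo, hi, spec.n_samples)
    a = (lo - spec.sf2_mean) / spec.sf2_sd
    b = (hi - spec.sf2_mean) / spec.sf2_sd
    return stats.truncnorm.rvs(
        a, b, loc=spec.sf2_mean, scale=spec.sf2_sd,
        size=spec.n_samples, random_state=rng,
    )


def generate(spec: SyntheticSpec, seed: Optional[int] = None) -> tuple:
    """Generate ``(CohortMatrix, GroundTruth)`` from a spec.

    Deterministic for a fixed seed (``spec.seed`` unless overridden by the
    ``seed`` argument).  Regimes left without any assigned sample are
    reported with a warning.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    n, m = spec.n_samples, spec.n_markers
    y = _draw_sf2(spec, rng)
    fc = rng.normal(0.0, spec.fc_null_sd, size=(n, m))
    noise = rng.normal(0.0, spec.noise_sd, size=n)

    if spec.regimes:
        uppers = np.array([r.upper for r in spec.regimes])
        sample_regime = np.searchsorted(uppers, y, side="left")
        sample_regime = np.minimum(sample_regime, len(spec.regimes) - 1)
    else:
        sample_regime = np.full(n, -1, dtype=int)

    for r_idx, regime in enumerate(spec.regimes):
        idx = np.flatnonzero(sample_regime == r_idx)
        if idx.size == 0:
            logger.warning("regime %d received no samples", r_idx)
        m_r = len(regime.support)
        signal = y - regime.intercept - noise  # exact only used inside the regime
        outside = np.setdiff1d(np.arange(n), idx, assume_unique=True)
        # first m_r - 1 support markers: shared trend + independent scatter;
        # the last one closes SF2 = a + sum b*FC + e exactly inside the regime
        remainder = signal[idx].copy()
        for t, (col, coef) in enumerate(zip(regime.support, regime.coefficients)):
            if t < m_r - 1:
                fc[idx, col] = signal[idx] / (m_r * coef) + rng.normal(
                    0.0, spec.fc_within_sd, size=idx.size
                )
                remainder -= coef * fc[idx, col]
            else:
                fc[idx, col] = remainder / coef
            trend = (y[outside] - regime.intercept) / (m_r * coef)
            fc[outside, col] = trend + rng.normal(
                0.0, spec.fc_carryover_sd, size=outside.size
            )

    sample_ids = tuple(f"S{i + 1:03d}" for i in range(n))
    marker_ids = tuple(f"M{j + 1:05d}" for j in range(m))
    cohort = CohortMatrix(sample_ids=sample_ids, marker_ids=marker_ids, fc=fc, sf2=y)
    truth = GroundTruth(
        true_breakpoints=spec.true_breakpoints,
        true_models=tuple(
            (r.intercept, r.support, r.coefficients) for r in spec.regimes
        ),
        sample_regime=sample_regime,
        noise_sd=spec.noise_sd,
    )
    return cohort, truth


def default_study_spec(
    seed: int = 0, n_null_markers: int = 10_000
) -> SyntheticSpec:
    """The reference study-scale cohort: 129 samples, 5 regimes, 10k nulls.

    SF2 follows a truncated normal with mean 0.3273 and SD 0.0868 on
    [0.1384, 0.4860], matching the observed moments and range of the
    fibroblast cohort the method was developed on.  Five SF2 regimes carry
    1-3 informative markers each, with intercepts and coefficient
    magnitudes of the order reported for fitted segment models; the
    regime boundaries are placed so that under the truncated normal every
    segment comfortably exceeds the minimal batch size of 10.
    """
    hi = 0.4860
    regimes = (
        Regime(upper=0.2300, support=(0,), coefficients=(0.1821,), intercept=0.1713),
        Regime(
            upper=0.2835, support=(1, 2),
            coefficients=(0.1293, 0.1330), intercept=0.2790,
        ),
        Regime(
            upper=0.3613, support=(3, 4, 5),
            coefficients=(-0.1305, -0.0934, 0.0744), intercept=0.3285,
        ),
        Regime(
            upper=0.4100, support=(6, 7, 8),
            coefficients=(0.0780, 0.1105, 0.0835), intercept=0.3776,
        ),
        Regime(upper=hi, support=(9,), coefficients=(-0.1035,), intercept=0.4412),
    )
    n_informative = sum(len(r.support) for r in regimes)
    return SyntheticSpec(
        n_samples=129,
        n_markers=n_informative + n_null_markers,
        sf2_range=(0.1384, hi),
        sf2_distribution="truncated-normal",
        sf2_mean=0.3273,
        sf2_sd=0.0868,
        regimes=regimes,
        seed=seed,
    )


def null_spec(
    n_samples: int = 129, n_markers: int = 10_000, seed: int = 0
) -> SyntheticSpec:
    """A pure-null cohort: no planted regimes, all markers Gaussian noise."""
    return SyntheticSpec(
        n_samples=n_samples,
        n_markers=n_markers,
        sf2_range=(0.1384, 0.4860),
        regimes=(),
        seed=seed,
    )


def with_seed(spec: SyntheticSpec, seed: int) -> SyntheticSpec:
    """Copy of ``spec`` with a different seed."""
    return replace(spec, seed=seed)
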