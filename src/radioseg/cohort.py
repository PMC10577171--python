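"""Cohort data model and I/O.

The central container is :class:`CohortMatrix`: a samples x markers matrix of
copy-number fold changes (FC, the log2 ratio of a sample's microarray signal
to the reference genome signal) joined to a per-sample radiosensitivity
phenotype, the surviving fraction at 2 Gy (SF2).  Every downstream stage --
marker screening, regression, segmentation, group comparison -- consumes this
container.

Also provided here: the linear-quadratic cell-survival utility, an SF2
range-spanning train/validation splitter, and a left-join of user-supplied
marker annotations (chromosome, position, gene, region class).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Fixed vocabulary for the genomic region class of a marker.
REGION_CLASSES = frozenset(
    {"intron", "exon", "3'-UTR", "5'-UTR", "intergenic", "unknown"}
)


@dataclass(frozen=True)
class CohortMatrix:
    """Samples x markers fold-change matrix joined to a per-sample SF2 vector.

    Parameters
    ----------
    sample_ids
        Ordered, unique sample identifiers (length ``n``).
    marker_ids
        Ordered, unique marker identifiers (length ``m``).
    fc
        ``(n, m)`` array of fold changes, i.e. log2(sample / reference)
        signal ratios.  Positive values indicate copy-number gain relative
        to the reference genome, negative values a loss.
    sf2
        Length-``n`` vector of surviving fractions at 2 Gy; strictly
        positive proportions (relative errors divide by the observed SF2).
    """

    sample_ids: tuple
    marker_ids: tuple
    fc: np.ndarray
    sf2: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "sample_ids", tuple(str(s) for s in self.sample_ids))
        object.__setattr__(self, "marker_ids", tuple(str(m) for m in self.marker_ids))
        object.__setattr__(self, "fc", np.asarray(self.fc, dtype=float))
        object.__setattr__(self, "sf2", np.asarray(self.sf2, dtype=float))
        n, m = len(self.sample_ids), len(self.marker_ids)
        if self.fc.shape != (n, m):
            raise ValueError(
                f"fc shape {self.fc.shape} does not match "
                f"{n} samples x {m} markers"
            )
        if self.sf2.shape != (n,):
            raise ValueError("sf2 length does not match sample count")
        if len(set(self.sample_ids)) != n:
            raise ValueError("duplicate sample ids")
        if len(set(self.marker_ids)) != m:
            raise ValueError("duplicate marker ids")
        if not np.all(np.isfinite(self.sf2)):
            raise ValueError("SF2 contains non-finite values")
        if np.any(self.sf2 <= 0):
            bad = [self.sample_ids[i] for i in np.flatnonzero(self.sf2 <= 0)]
            raise ValueError(f"SF2 must be strictly positive; offending samples: {bad}")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_markers(self) -> int:
        return len(self.marker_ids)

    def fc_frame(self) -> pd.DataFrame:
        """Fold changes as a DataFrame indexed by sample id."""
        return pd.DataFrame(
            self.fc, index=list(self.sample_ids), columns=list(self.marker_ids)
        )

    def marker_columns(self, marker_ids: Sequence[str]) -> np.ndarray:
        """Return the ``(n, len(marker_ids))`` FC sub-matrix for the given markers.

        Raises ``KeyError`` for a marker absent from the cohort.
        """
        index = {m: j for j, m in enumerate(self.marker_ids)}
        cols = []
        for m in marker_ids:
            if m not in index:
                raise KeyError(f"marker {m!r} not present in cohort")
            cols.append(index[m])
        if not cols:
            return np.empty((self.n_samples, 0))
        return self.fc[:, cols]

    def take_samples(self, indices: Sequence[int]) -> "CohortMatrix":
        """Sub-cohort restricted to ``indices`` (in the given order)."""
        idx = np.asarray(indices, dtype=int)
        return CohortMatrix(
            sample_ids=tuple(self.sample_ids[i] for i in idx),
            marker_ids=self.marker_ids,
            fc=self.fc[idx],
            sf2=self.sf2[idx],
        )

    def sorted_by_sf2(self) -> "CohortMatrix":
        """Cohort re-ordered by ascending SF2 (stable on ties)."""
        order = np.argsort(self.sf2, kind="stable")
        return self.take_samples(order)


@dataclass(frozen=True)
class SplitResult:
    """A disjoint train/validation partition of a cohort."""

    train: CohortMatrix
    validation: CohortMatrix
    seed: int

    def __post_init__(self):
        train_set = set(self.train.sample_ids)
        val_set = set(self.validation.sample_ids)
        if train_set & val_set:
            raise ValueError("train and validation sets overlap")


def _read_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = "\t" if path.suffix.lower() in {".tsv", ".bed", ".txt"} else ","
    return pd.read_csv(path, sep=sep)


def load_cohort(fc_path, phenotype_path) -> CohortMatrix:
    """Load a cohort from an FC matrix file and a phenotype table.

    The FC file has a header row of marker ids and one row per sample, the
    first column holding the sample id.  The phenotype file has columns
    ``sample_id`` and ``sf2``.  The returned cohort is restricted to the
    intersection of sample ids present in both files, preserving
    phenotype-file order; samples present in only one file are dropped with
    a logged warning.  Markers whose column contains any non-numeric cell
    are rejected (logged).
    """
    fc_df = _read_table(fc_path)
    pheno = _read_table(phenotype_path)

    fc_df = fc_df.set_index(fc_df.columns[0])
    fc_df.index = fc_df.index.astype(str)
    if fc_df.index.duplicated().any():
        raise ValueError("duplicate sample ids in FC file")
    if pd.Index(fc_df.columns).duplicated().any():
        raise ValueError("duplicate marker ids in FC file")

    cols = {c.lower(): c for c in pheno.columns}
    if "sample_id" not in cols or "sf2" not in cols:
        raise ValueError("phenotype file must have columns 'sample_id' and 'sf2'")
    pheno = pheno.rename(columns={cols["sample_id"]: "sample_id", cols["sf2"]: "sf2"})
    pheno["sample_id"] = pheno["sample_id"].astype(str)
    if pheno["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in phenotype file")

    # reject markers with any non-numeric (or missing) cell
    numeric = fc_df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.columns[numeric.isna().any(axis=0)]
    if len(bad):
        logger.warning("rejecting %d markers with non-numeric cells", len(bad))
        numeric = numeric.drop(columns=bad)

    in_fc = set(numeric.index)
    keep = pheno[pheno["sample_id"].isin(in_fc)]
    dropped = len(pheno) - len(keep)
    if dropped:
        logger.warning("%d phenotype samples absent from FC file; dropped", dropped)
    extra = in_fc - set(keep["sample_id"])
    if extra:
        logger.warning("%d FC samples absent from phenotype file; dropped", len(extra))
    if keep.empty:
        raise ValueError("no overlapping samples between FC and phenotype files")

    sf2 = keep["sf2"].astype(float).to_numpy()
    fc = numeric.loc[keep["sample_id"]].to_numpy(dtype=float)
    return CohortMatrix(
        sample_ids=tuple(keep["sample_id"]),
        marker_ids=tuple(str(c) for c in numeric.columns),
        fc=fc,
        sf2=sf2,
    )


def lq_surviving_fraction(alpha: float, beta: float, dose: float):
    """Linear-quadratic cell survival: ``SF = exp(-alpha*D - beta*D**2)``.

    ``alpha`` (1/Gy) and ``beta`` (1/Gy^2) are the linear and quadratic
    radiosensitivity rates; ``dose`` is in Gy and must be non-negative.
    With non-negative rates the result lies in (0, 1].  SF2 is this
    quantity evaluated at D = 2 Gy.
    """
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-alpha * dose - beta * dose**2)
    return float(out) if out.ndim == 0 else out


def split_train_validation(
    cohort: CohortMatrix, n_validation: int, seed: int
) -> SplitResult:
    """Split off an SF2 range-spanning validation set.

    Samples are sorted by SF2, the sorted order is divided into
    ``n_validation`` contiguous bins of (near-)equal size, and one
    validation sample is drawn uniformly at random (seeded) from each bin,
    so that the validation set spans the whole SF2 range.  Deterministic
    for a fixed seed.  Train and validation cohorts preserve the original
    sample order of the input cohort.
    """
    n = cohort.n_samples
    if not 0 <= n_validation < n:
        raise ValueError(f"n_validation must be in [0, {n}); got {n_validation}")
    if n_validation == 0:
        empty = cohort.take_samples([])
        return SplitResult(train=cohort, validation=empty, seed=seed)
    rng = np.random.default_rng(seed)
    order = np.argsort(cohort.sf2, kind="stable")
    bins = np.array_split(order, n_validation)
    val_idx = sorted(int(rng.choice(b)) for b in bins)
    val_set = set(val_idx)
    train_idx = [i for i in range(n) if i not in val_set]
    return SplitResult(
        train=cohort.take_samples(train_idx),
        validation=cohort.take_samples(sorted(val_set)),
        seed=seed,
    )


def read_annotation(path) -> pd.DataFrame:
    """Read a BED-like marker annotation table.

    Expected tab-separated columns: ``chrom, start, marker_id, gene,
    region_class, regulatory`` (columns beyond ``marker_id`` optional).
    Start coordinates are 1-based inclusive.  Malformed rows (too few
    columns, non-positive or non-integer start, region class outside the
    fixed vocabulary) are skipped with a logged count.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    names = ["chrom", "start", "marker_id", "gene", "region_class", "regulatory"]
    rows, skipped = [], 0
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                skipped += 1
                continue
            parts = parts[:6] + [""] * (6 - len(parts))
            chrom, start, marker_id, gene, region_class, regulatory = parts
            try:
                start_i = int(start)
            except ValueError:
                skipped += 1
                continue
            if start_i < 1:
                skipped += 1
                continue
            if region_class and region_class not in REGION_CLASSES:
                skipped += 1
                continue
            rows.append(
                dict(
                    chrom=chrom,
                    start=start_i,
                    marker_id=marker_id,
                    gene=gene,
                    region_class=region_class or "unknown",
                    regulatory=regulatory,
                )
            )
    if skipped:
        logger.warning("skipped %d malformed annotation rows", skipped)
    return pd.DataFrame(rows, columns=names)


def annotate_markers(marker_ids: Sequence[str], annotation: pd.DataFrame) -> pd.DataFrame:
    """Left-join marker ids onto an annotation table.

    Unmatched markers get ``region_class='unknown'``.  When a marker has
    several annotation rows, their fields are concatenated with ``';'`` in
    input order (documented tie rule).
    """
    marker_ids = [str(m) for m in marker_ids]
    base = pd.DataFrame({"marker_id": marker_ids})
    if annotation is None or annotation.empty:
        out = base.copy()
        for col in ("chrom", "start", "gene", "region_class", "regulatory"):
            out[col] = ""
        out["region_class"] = "unknown"
        return out

    ann = annotation.copy()
    ann["marker_id"] = ann["marker_id"].astype(str)

    def _join(series):
        vals = [str(v) for v in series if str(v) != ""]
        return ";".join(vals)

    agg = ann.groupby("marker_id", sort=False).agg(
        chrom=("chrom", _join),
        start=("start", lambda s: _join(s.astype(str))),
        gene=("gene", _join),
        region_class=("region_class", _join),
        regulatory=("regulatory", _join),
    )
    out = base.merge(agg, how="left", left_on="marker_id", right_index=True)
    out["region_class"] = out["region_class"].fillna("unknown").replace("", "unknown")
    for col in ("chrom", "start", "gene", "regulatory"):
        out[col] = out[col].fillna("")
    return out
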