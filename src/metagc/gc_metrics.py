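"""Per-read GC-content and its aggregation into sample x phylum matrices.

The central container is :class:`GCMatrix`: rows are samples, columns are
phyla, and each cell holds the arithmetic mean GC (in percent), the SD and
the number of contributing reads. Cells supported by fewer than
``min_reads`` reads are marked missing (NaN mean/SD) — a mean over a
handful of reads is noise, not a community property.

GC is reported as a proportion (0-1) at read level and as percent (0-100)
in matrices. Ambiguous bases (N) are excluded from both numerator and
denominator of the GC computation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

from .sequence_io import ReadRecord

__all__ = [
    "DegenerateSequenceError",
    "GCMatrix",
    "read_gc",
    "build_gc_matrix",
    "relative_abundance",
    "iqr_filter",
    "iqr_filter_reads",
]


class DegenerateSequenceError(ValueError):
    """Raised when GC-content is undefined (no unambiguous base)."""


def read_gc(sequence: str) -> float:
    """GC proportion of a sequence: (#G + #C) / (#A + #C + #G + #T).

    N's are excluded from numerator and denominator. Raises
    :class:`DegenerateSequenceError` if no unambiguous base remains.
    """
    if not sequence:
        raise DegenerateSequenceError("empty sequence")
    s = sequence.upper()
    gc = s.count("G") + s.count("C")
    at = s.count("A") + s.count("T")
    if gc + at == 0:
        raise DegenerateSequenceError("sequence has no unambiguous base")
    return gc / (gc + at)


@dataclass
class GCMatrix:
    """Samples x phyla table of (mean GC %, SD %, n reads).

    ``mean`` and ``sd`` are float DataFrames (NaN marks a missing cell),
    ``n`` an int DataFrame, all sharing index (sample ids) and columns
    (phylum labels).
    """

    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame
    min_reads: int = 10

    def __post_init__(self) -> None:
        for name in ("sd", "n"):
            df = getattr(self, name)
            if not df.index.equals(self.mean.index) or not df.columns.equals(
                self.mean.columns
            ):
                raise ValueError(f"GCMatrix: {name} not aligned with mean")
        if self.mean.index.has_duplicates or self.mean.columns.has_duplicates:
            raise ValueError("GCMatrix: duplicate sample or phylum labels")
        with np.errstate(invalid="ignore"):
            vals = self.mean.to_numpy(dtype=float)
        if np.any((vals < 0) | (vals > 100)):
            raise ValueError("GCMatrix: mean GC outside [0, 100]")

    @property
    def samples(self) -> list[str]:
        return list(self.mean.index)

    @property
    def phyla(self) -> list[str]:
        return list(self.mean.columns)

    def subset(self, sample_ids: Iterable[str]) -> "GCMatrix":
        ids = [s for s in self.mean.index if s in set(sample_ids)]
        return GCMatrix(
            self.mean.loc[ids], self.sd.loc[ids], self.n.loc[ids], self.min_reads
        )

    def to_tsv(self, prefix: str | Path) -> None:
        """Write mean/sd/n as ``<prefix>_{mean,sd,n}.tsv`` (missing = NA)."""
        prefix = str(prefix)
        self.mean.to_csv(prefix + "_mean.tsv", sep="\t", na_rep="NA", float_format="%.6f")
        self.sd.to_csv(prefix + "_sd.tsv", sep="\t", na_rep="NA", float_format="%.6f")
        self.n.to_csv(prefix + "_n.tsv", sep="\t")

    @classmethod
    def from_tsv(cls, prefix: str | Path, min_reads: int = 10) -> "GCMatrix":
        prefix = str(prefix)
        mean = pd.read_csv(prefix + "_mean.tsv", sep="\t", index_col=0, na_values="NA")
        sd = pd.read_csv(prefix + "_sd.tsv", sep="\t", index_col=0, na_values="NA")
        n = pd.read_csv(prefix + "_n.tsv", sep="\t", index_col=0)
        return cls(mean, sd, n.astype(int), min_reads)


def build_gc_matrix(
    reads: Sequence[ReadRecord],
    min_reads: int = 10,
    phyla: Sequence[str] | None = None,
) -> GCMatrix:
    """Aggregate screened reads into a per-sample, per-phylum GC matrix.

    The cell mean is the plain arithmetic mean of per-read GC (x100) over
    that sample x phylum; cells with fewer than ``min_reads`` reads are
    marked missing (their count is still recorded).
    """
    rows = [
        (r.sample_id, r.phylum, read_gc(r.sequence) * 100.0)
        for r in reads
        if r.phylum is not None
    ]
    df = pd.DataFrame(rows, columns=["sample_id", "phylum", "gc"])
    if df.empty:
        empty = pd.DataFrame(dtype=float)
        return GCMatrix(empty, empty.copy(), empty.copy().astype(int), min_reads)
    grouped = df.groupby(["sample_id", "phylum"])["gc"]
    mean = grouped.mean().unstack()
    sd = grouped.std(ddof=1).unstack()
    n = grouped.size().unstack(fill_value=0)
    if phyla is not None:
        mean = mean.reindex(columns=phyla)
        sd = sd.reindex(columns=phyla)
        n = n.reindex(columns=phyla, fill_value=0)
    n = n.reindex(index=mean.index, columns=mean.columns, fill_value=0).astype(int)
    sd = sd.reindex(index=mean.index, columns=mean.columns)
    low = n < min_reads
    mean = mean.mask(low)
    sd = sd.mask(low)
    return GCMatrix(mean, sd, n, min_reads)


def relative_abundance(
    reads: Sequence[ReadRecord], phyla: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-sample relative abundance of each phylum over classified reads.

    Rows are samples, columns phyla; each row sums to 1 over the retained
    phyla (reads without a phylum label are ignored).
    """
    rows = [(r.sample_id, r.phylum) for r in reads if r.phylum is not None]
    df = pd.DataFrame(rows, columns=["sample_id", "phylum"])
    if df.empty:
        return pd.DataFrame(dtype=float)
    counts = df.groupby(["sample_id", "phylum"]).size().unstack(fill_value=0)
    if phyla is not None:
        counts = counts.reindex(columns=phyla, fill_value=0)
    return counts.div(counts.sum(axis=1), axis=0)


IqrMode = Literal["literal", "tukey"]


def iqr_filter(
    values: Sequence[float] | np.ndarray, mode: IqrMode = "literal"
) -> np.ndarray:
    """Interquartile outlier filter over a pool of GC values.

    Quartiles use linear-interpolation quantiles. Mode "literal" keeps
    values inside [Q1, Q3]; mode "tukey" keeps values inside the fences
    [Q1 - 1.5*IQR, Q3 + 1.5*IQR]. Boundaries are inclusive. Fewer than 4
    values: the filter is skipped with a warning and everything is kept.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 4:
        warnings.warn(
            f"iqr_filter: only {arr.size} value(s), filter skipped", stacklevel=2
        )
        return arr.copy()
    q1, q3 = np.quantile(arr, [0.25, 0.75])
    if mode == "literal":
        lo, hi = q1, q3
    elif mode == "tukey":
        iqr = q3 - q1
        lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    else:
        raise ValueError(f"unknown IQR mode {mode!r}")
    return arr[(arr >= lo) & (arr <= hi)]


def iqr_filter_reads(
    reads: Sequence[ReadRecord], mode: IqrMode = "literal"
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Remove reads whose GC falls outside the per-phylum interquartile band.

    Quartiles are computed per phylum pooled across all samples; reads
    surviving the band are returned (order preserved) together with
    per-phylum removal counts, ready for a rebuild of the GC matrix.
    """
    by_phylum: dict[str, list[float]] = {}
    gcs: list[float] = []
    for r in reads:
        g = read_gc(r.sequence) * 100.0
        gcs.append(g)
        if r.phylum is not None:
            by_phylum.setdefault(r.phylum, []).append(g)

    bounds: dict[str, tuple[float, float]] = {}
    for phylum, vals in by_phylum.items():
        arr = np.asarray(vals)
        if arr.size < 4:
            warnings.warn(
                f"iqr_filter_reads: phylum {phylum!r} has {arr.size} read(s), "
                "filter skipped for it",
                stacklevel=2,
            )
            continue
        q1, q3 = np.quantile(arr, [0.25, 0.75])
        if mode == "literal":
            bounds[phylum] = (q1, q3)
        elif mode == "tukey":
            iqr = q3 - q1
            bounds[phylum] = (q1 - 1.5 * iqr, q3 + 1.5 * iqr)
        else:
            raise ValueError(f"unknown IQR mode {mode!r}")

    kept: list[ReadRecord] = []
    removed: dict[str, int] = {}
    for r, g in zip(reads, gcs):
        if r.phylum in bounds:
            lo, hi = bounds[r.phylum]
            if not (lo <= g <= hi):
                removed[r.phylum] = removed.get(r.phylum, 0) + 1
                continue
        kept.append(r)
    return kept, removed
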