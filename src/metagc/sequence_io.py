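"""Input/output for reads, labels, annotations and sample metadata.

Shotgun reads arrive as multi-FASTA (one file per sample by convention,
but any grouping works); taxonomic labels, gene annotations and sample
metadata arrive as TSV tables with mandatory headers:

* labels:       read_id, sample_id, phylum, genus, confidence
* annotations:  read_id, start, end, strand, frame_offset
* samples:      sample_id, environment

Coordinates are 0-based half-open on the read; strand is "+"/"-"; an
annotation on "-" is interpreted after reverse-complementing the interval.
Screening implements the study's read filters: minimum length 100 bp and
phylum-level classification confidence of at least 0.80, both inclusive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "ReadRecord",
    "GeneAnnotation",
    "SampleMeta",
    "FastaParseError",
    "LabelJoinError",
    "parse_fasta",
    "parse_reads",
    "screen_reads",
    "read_labels",
    "read_annotations",
    "read_samples",
    "write_labels",
    "write_annotations",
    "write_samples",
]

VALID_BASES = frozenset("ACGTN")

LABEL_COLUMNS = ["read_id", "sample_id", "phylum", "genus", "confidence"]
ANNOTATION_COLUMNS = ["read_id", "start", "end", "strand", "frame_offset"]
SAMPLE_COLUMNS = ["sample_id", "environment"]


class FastaParseError(ValueError):
    """Malformed FASTA input; carries the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class LabelJoinError(ValueError):
    """FASTA records without a label row (or vice versa)."""


@dataclass(frozen=True)
class ReadRecord:
    """One shotgun read with its sample of origin and taxonomic call."""

    read_id: str
    sequence: str
    sample_id: str
    phylum: str | None = None
    genus: str | None = None
    confidence: float = 1.0

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"read {self.read_id!r}: empty sequence")
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ValueError(
                f"read {self.read_id!r}: invalid characters {sorted(bad)!r}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"read {self.read_id!r}: confidence {self.confidence} not in [0,1]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneAnnotation:
    """A coding interval on a read: 0-based half-open, with codon phase.

    ``frame_offset`` is the phase of ``start`` on the coding strand: the
    number of bases to drop from the coding-strand sequence before the
    first complete codon.
    """

    read_id: str
    start: int
    end: int
    strand: str
    frame_offset: int = 0

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(
                f"annotation on {self.read_id!r}: bad strand {self.strand!r}"
            )
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"annotation on {self.read_id!r}: bad interval "
                f"[{self.start}, {self.end})"
            )
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(
                f"annotation on {self.read_id!r}: frame_offset "
                f"{self.frame_offset} not in 0..2"
            )


@dataclass(frozen=True)
class SampleMeta:
    sample_id: str
    environment: str


def parse_fasta(source: str | Path) -> list[tuple[str, str]]:
    """Parse a (possibly wrapped) FASTA file into (id, upper-cased seq) pairs.

    Sequence characters outside {A,C,G,T,N} and structural problems are
    rejected with the offending line number.
    """
    path = Path(source)
    # Pre-scan for structure and character validity so errors carry line
    # numbers; Bio.SeqIO then does the actual record assembly.
    seen_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped:
                continue
            if stripped.startswith(">"):
                seen_header = True
                continue
            if not seen_header:
                raise FastaParseError(
                    f"{path.name}: sequence data before first header", lineno
                )
            bad = set(stripped.upper()) - VALID_BASES
            if bad:
                raise FastaParseError(
                    f"{path.name}: invalid sequence characters {sorted(bad)!r}",
                    lineno,
                )
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaParseError(f"{path.name}: record {rec.id!r} has no sequence")
        records.append((rec.id, seq))
    return records


def _as_paths(fasta_source: str | Path | Iterable[str | Path]) -> list[Path]:
    if isinstance(fasta_source, (str, Path)):
        p = Path(fasta_source)
        if p.is_dir():
            return sorted(p.glob("*.fasta")) + sorted(p.glob("*.fa"))
        return [p]
    return [Path(p) for p in fasta_source]


def parse_reads(
    fasta_source: str | Path | Iterable[str | Path],
    labels: pd.DataFrame,
) -> list[ReadRecord]:
    """Join FASTA records with the label table into ReadRecords.

    Every FASTA record must have exactly one label row; orphan records are
    a hard error listing the ids. Label rows without a FASTA record are
    reported as a warning (they may belong to another file of the set).
    """
    missing_cols = set(LABEL_COLUMNS) - set(labels.columns)
    if missing_cols:
        raise ValueError(f"label table missing columns: {sorted(missing_cols)}")
    if labels["read_id"].duplicated().any():
        dupes = labels.loc[labels["read_id"].duplicated(), "read_id"].tolist()
        raise LabelJoinError(f"duplicate label rows for read ids: {dupes[:10]}")

    by_id = labels.set_index("read_id")
    reads: list[ReadRecord] = []
    seen: set[str] = set()
    orphans: list[str] = []
    for path in _as_paths(fasta_source):
        for rid, seq in parse_fasta(path):
            if rid not in by_id.index:
                orphans.append(rid)
                continue
            row = by_id.loc[rid]
            phylum = row["phylum"] if pd.notna(row["phylum"]) else None
            genus = row["genus"] if pd.notna(row["genus"]) else None
            reads.append(
                ReadRecord(
                    read_id=rid,
                    sequence=seq,
                    sample_id=str(row["sample_id"]),
                    phylum=phylum,
                    genus=genus,
                    confidence=float(row["confidence"]),
                )
            )
            seen.add(rid)
    if orphans:
        raise LabelJoinError(
            f"{len(orphans)} FASTA record(s) without a label row: {orphans[:10]}"
        )
    unmatched = set(by_id.index) - seen
    if unmatched:
        warnings.warn(
            f"{len(unmatched)} label row(s) without a FASTA record "
            f"(e.g. {sorted(unmatched)[:5]})",
            stacklevel=2,
        )
    return reads


def screen_reads(
    reads: Sequence[ReadRecord],
    min_len: int = 100,
    min_conf: float = 0.80,
) -> tuple[list[ReadRecord], dict[str, int]]:
    """Apply the read-screening filters; thresholds are inclusive.

    Keeps reads with length >= ``min_len`` AND confidence >= ``min_conf``
    AND a phylum label, preserving order. Returns the kept list and
    per-filter removal counts with first-failing-filter attribution
    (length, then confidence, then missing phylum), so that
    ``len(input) == len(kept) + sum(removals.values())``.
    """
    kept: list[ReadRecord] = []
    removals = {"length": 0, "confidence": 0, "unclassified": 0}
    for read in reads:
        if len(read) < min_len:
            removals["length"] += 1
        elif read.confidence < min_conf:
            removals["confidence"] += 1
        elif read.phylum is None:
            removals["unclassified"] += 1
        else:
            kept.append(read)
    return kept, removals


def _read_table(path: str | Path, columns: list[str], kind: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"read_id": str, "sample_id": str})
    missing = set(columns) - set(df.columns)
    if missing:
        raise ValueError(f"{kind} table {path}: missing columns {sorted(missing)}")
    return df[columns]


def read_labels(path: str | Path) -> pd.DataFrame:
    return _read_table(path, LABEL_COLUMNS, "label")


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = _read_table(path, ANNOTATION_COLUMNS, "annotation")
    return df.astype({"start": int, "end": int, "frame_offset": int})


def read_samples(path: str | Path) -> list[SampleMeta]:
    df = _read_table(path, SAMPLE_COLUMNS, "sample")
    if df["sample_id"].duplicated().any():
        raise ValueError(f"sample table {path}: duplicate sample_id")
    return [
        SampleMeta(sample_id=str(r.sample_id), environment=str(r.environment))
        for r in df.itertuples()
    ]


def write_labels(df: pd.DataFrame, path: str | Path) -> None:
    df[LABEL_COLUMNS].to_csv(path, sep="\t", index=False)


def write_annotations(df: pd.DataFrame, path: str | Path) -> None:
    df[ANNOTATION_COLUMNS].to_csv(path, sep="\t", index=False)


def write_samples(samples: Iterable[SampleMeta] | pd.DataFrame, path: str | Path) -> None:
    if not isinstance(samples, pd.DataFrame):
        samples = pd.DataFrame(
            [(s.sample_id, s.environment) for s in samples], columns=SAMPLE_COLUMNS
        )
    samples[SAMPLE_COLUMNS].to_csv(path, sep="\t", index=False)


def write_fasta(records: Iterable[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    """Write (id, seq) pairs as wrapped FASTA."""
    with open(path, "w") as fh:
        for rid, seq in records:
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")
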