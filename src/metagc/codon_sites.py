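"""Extraction of 4-fold degenerate third-codon positions (GC4).

A codon box is 4-fold degenerate when the four codons sharing its first
two bases all encode the same amino acid; the third position is then
silent, so its nucleotide composition is shielded from selection on the
protein sequence. Under the standard bacterial/archaeal code (translation
table 11) exactly eight amino acids own such a box — Ala (GCN), Arg (CGN),
Gly (GGN), Leu (CTN), Pro (CCN), Ser (TCN), Thr (ACN) and Val (GTN). The
6-fold amino acids Leu/Ser/Arg contribute only through their 4-fold box:
their 2-fold codons (TTR, AGY, AGR) never yield a silent third position
and are never extracted here.

Gene calling is out of scope: coding intervals arrive as annotations
(0-based half-open, strand, codon phase of the interval start).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from .gc_metrics import GCMatrix, read_gc
from .sequence_io import GeneAnnotation, ReadRecord

__all__ = [
    "GeneticCode",
    "FourfoldSites",
    "AnnotationError",
    "fourfold_third_positions",
    "extract_sites",
    "gc4_matrix",
]

BASES = "ACGT"


class AnnotationError(ValueError):
    """Annotation inconsistent with its read (out of bounds, bad strand)."""


class GeneticCode:
    """A codon -> amino acid mapping plus its derived 4-fold boxes."""

    def __init__(self, forward_table: Mapping[str, str], name: str = "custom"):
        self.name = name
        # Normalize: stops may be absent from a forward table; map them to "*".
        self.codon_to_aa = {
            c1 + c2 + c3: forward_table.get(c1 + c2 + c3, "*")
            for c1 in BASES
            for c2 in BASES
            for c3 in BASES
        }
        self.fourfold_prefixes = frozenset(
            p
            for p in (b1 + b2 for b1 in BASES for b2 in BASES)
            if len({self.codon_to_aa[p + b3] for b3 in BASES}) == 1
            and self.codon_to_aa[p + "A"] != "*"
        )

    @classmethod
    def from_ncbi_id(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        return cls(table.forward_table, name=table.names[0])

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneticCode":
        """Load a code from a 64-line ``CODON<tab>AA`` table (stop = ``*``)."""
        mapping: dict[str, str] = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                codon, aa = line.split()
                mapping[codon.upper()] = aa
        if len(mapping) != 64:
            raise ValueError(f"codon table {path}: expected 64 codons, got {len(mapping)}")
        return cls(mapping, name=str(path))


#: Standard bacterial/archaeal code, the default for prokaryotic data.
BACTERIAL_CODE = GeneticCode.from_ncbi_id(11)


@dataclass(frozen=True)
class FourfoldSites:
    """Third positions of 4-fold degenerate codons found on one read."""

    read_id: str
    thirds: str
    n_codons_scanned: int

    @property
    def n_fourfold(self) -> int:
        return len(self.thirds)

    def __post_init__(self) -> None:
        if self.n_fourfold > self.n_codons_scanned:
            raise ValueError("more 4-fold sites than codons scanned")


def fourfold_third_positions(
    read: ReadRecord,
    ann: GeneAnnotation,
    code: GeneticCode = BACTERIAL_CODE,
) -> FourfoldSites:
    """Extract silent third positions from an annotated coding interval.

    The coding-strand sequence is the interval itself ("+") or its reverse
    complement ("-"); the first ``frame_offset`` bases and any trailing
    partial codon are dropped. A codon contributes its third base iff its
    first two bases form a 4-fold box; codons with N in the first two
    positions are skipped (an N in the third position of a 4-fold codon is
    kept and later excluded by the GC computation).
    """
    if ann.read_id != read.read_id:
        raise AnnotationError(
            f"annotation read_id {ann.read_id!r} != read {read.read_id!r}"
        )
    if ann.end > len(read.sequence):
        raise AnnotationError(
            f"annotation [{ann.start}, {ann.end}) outside read "
            f"{read.read_id!r} of length {len(read.sequence)}"
        )
    segment = read.sequence[ann.start : ann.end]
    if ann.strand == "-":
        segment = reverse_complement(segment)
    coding = segment[ann.frame_offset :]
    thirds: list[str] = []
    n_codons = len(coding) // 3
    for i in range(n_codons):
        codon = coding[3 * i : 3 * i + 3]
        if codon[:2] in code.fourfold_prefixes:
            thirds.append(codon[2])
    return FourfoldSites(
        read_id=read.read_id, thirds="".join(thirds), n_codons_scanned=n_codons
    )


def extract_sites(
    reads: Sequence[ReadRecord],
    annotations: pd.DataFrame | Iterable[GeneAnnotation],
    code: GeneticCode = BACTERIAL_CODE,
) -> list[FourfoldSites]:
    """Run 4-fold extraction for every annotation with a matching read."""
    if isinstance(annotations, pd.DataFrame):
        anns = [
            GeneAnnotation(
                read_id=str(r.read_id),
                start=int(r.start),
                end=int(r.end),
                strand=str(r.strand),
                frame_offset=int(r.frame_offset),
            )
            for r in annotations.itertuples()
        ]
    else:
        anns = list(annotations)
    by_id = {r.read_id: r for r in reads}
    sites = []
    for ann in anns:
        read = by_id.get(ann.read_id)
        if read is None:
            continue  # read was screened out
        sites.append(fourfold_third_positions(read, ann, code))
    return sites


def sites_to_frame(sites: Sequence[FourfoldSites]) -> pd.DataFrame:
    return pd.DataFrame(
        [(s.read_id, s.thirds, s.n_codons_scanned, s.n_fourfold) for s in sites],
        columns=["read_id", "thirds", "n_codons_scanned", "n_fourfold"],
    )


def gc4_matrix(
    sites: Sequence[FourfoldSites],
    reads: Sequence[ReadRecord],
    min_sites: int = 10,
    phyla: Sequence[str] | None = None,
) -> GCMatrix:
    """GC4 per sample x phylum: GC of the pooled silent third positions.

    Third-position bases are concatenated per group and a single GC value
    is computed; the cell count is the number of unambiguous pooled sites,
    and groups with fewer than ``min_sites`` are marked missing. SD is not
    defined for a pooled single value and is reported as NaN.
    """
    by_id = {r.read_id: r for r in reads}
    pooled: dict[tuple[str, str], list[str]] = {}
    for s in sites:
        read = by_id.get(s.read_id)
        if read is None or read.phylum is None:
            continue
        pooled.setdefault((read.sample_id, read.phylum), []).append(s.thirds)

    rows = []
    for (sample, phylum), chunks in pooled.items():
        thirds = "".join(chunks)
        n_unambig = sum(thirds.count(b) for b in BASES)
        gc = read_gc(thirds) * 100.0 if n_unambig else float("nan")
        rows.append((sample, phylum, gc, n_unambig))
    df = pd.DataFrame(rows, columns=["sample_id", "phylum", "gc4", "n_sites"])
    if df.empty:
        empty = pd.DataFrame(dtype=float)
        return GCMatrix(empty, empty.copy(), empty.copy().astype(int), min_sites)
    mean = df.pivot(index="sample_id", columns="phylum", values="gc4")
    n = (
        df.pivot(index="sample_id", columns="phylum", values="n_sites")
        .fillna(0)
        .astype(int)
    )
    if phyla is not None:
        mean = mean.reindex(columns=phyla)
        n = n.reindex(columns=phyla, fill_value=0)
    mean = mean.mask(n < min_sites)
    sd = pd.DataFrame(float("nan"), index=mean.index, columns=mean.columns)
    return GCMatrix(mean, sd, n, min_sites)
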