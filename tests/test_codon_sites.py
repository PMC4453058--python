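"""4-fold degenerate third-position extraction and GC4."""

import itertools

import numpy as np
import pytest
from Bio.Data import CodonTable
from Bio.Seq import reverse_complement

from metagc.codon_sites import (
    BACTERIAL_CODE,
    AnnotationError,
    GeneticCode,
    extract_sites,
    fourfold_third_positions,
    gc4_matrix,
)
from metagc.sequence_io import GeneAnnotation, ReadRecord

BASES = "ACGT"


def _read(seq, rid="r1", sample="s1", phylum="A"):
    return ReadRecord(rid, seq, sample, phylum=phylum, confidence=0.9)


class TestGeneticCode:
    def test_table11_has_exactly_the_eight_fourfold_boxes(self):
        expected = {"GC", "CG", "GG", "CT", "CC", "TC", "AC", "GT"}
        assert BACTERIAL_CODE.fourfold_prefixes == expected

    def test_fourfold_boxes_by_brute_force_over_all_64_codons(self):
        """Independent oracle: group the 64 codons by prefix via Biopython's
        table and keep prefixes whose 4 completions share one amino acid."""
        table = CodonTable.unambiguous_dna_by_id[11]
        fwd = table.forward_table
        oracle = set()
        for p in ("".join(t) for t in itertools.product(BASES, repeat=2)):
            aas = {fwd.get(p + b, "*") for b in BASES}
            if len(aas) == 1 and "*" not in aas:
                oracle.add(p)
        assert BACTERIAL_CODE.fourfold_prefixes == oracle

    def test_sixfold_two_fold_codons_never_extracted(self):
        # TTR (Leu), AGY (Ser), AGR (Arg): 2-fold boxes of 6-fold amino acids
        for codon in ("TTA", "TTG", "AGT", "AGC", "AGA", "AGG"):
            read = _read(codon)
            ann = GeneAnnotation("r1", 0, 3, "+")
            assert fourfold_third_positions(read, ann).thirds == ""

    def test_roundtrip_through_codon_table_file(self, tmp_path):
        path = tmp_path / "code.tsv"
        lines = [
            f"{c1}{c2}{c3}\t{BACTERIAL_CODE.codon_to_aa[c1 + c2 + c3]}"
            for c1 in BASES
            for c2 in BASES
            for c3 in BASES
        ]
        path.write_text("\n".join(lines) + "\n")
        loaded = GeneticCode.from_file(path)
        assert loaded.fourfold_prefixes == BACTERIAL_CODE.fourfold_prefixes


class TestFourfoldThirdPositions:
    def test_glycine_run_yields_all_thirds(self):
        read = _read("GGAGGCGGG")
        sites = fourfold_third_positions(read, GeneAnnotation("r1", 0, 9, "+"))
        assert sites.thirds == "ACG"
        assert sites.n_fourfold == 3
        assert sites.n_codons_scanned == 3

    def test_twofold_codons_yield_nothing(self):
        read = _read("TTAAGT")
        sites = fourfold_third_positions(read, GeneAnnotation("r1", 0, 6, "+"))
        assert sites.thirds == ""
        assert sites.n_codons_scanned == 2

    def test_reverse_strand_reads_through_reverse_complement(self):
        read = _read("TGCGGC")  # revcomp = GCCGCA: two Ala (GCN) codons
        sites = fourfold_third_positions(read, GeneAnnotation("r1", 0, 6, "-"))
        assert sites.thirds == "CA"

    def test_phase_trimming_drops_leading_bases_and_partial_codon(self):
        # offset 1: skip "G", codons GGA GGC, trailing "GG" dropped
        read = _read("GGGAGGCGG")
        sites = fourfold_third_positions(read, GeneAnnotation("r1", 0, 9, "+", 1))
        assert sites.thirds == "AC"
        assert sites.n_codons_scanned == 2

    def test_n_in_prefix_skips_codon_n_in_third_kept(self):
        read = _read("GNAGGN")
        sites = fourfold_third_positions(read, GeneAnnotation("r1", 0, 6, "+"))
        assert sites.thirds == "N"  # GNA skipped, GGN contributes its third
        assert sites.n_codons_scanned == 2

    def test_out_of_bounds_annotation_rejected(self):
        with pytest.raises(AnnotationError):
            fourfold_third_positions(_read("ACGACG"), GeneAnnotation("r1", 0, 9, "+"))

    def test_frame_shift_by_one_codon_removes_first_contribution(self, rng):
        seq = "".join(rng.choice(list(BASES)) for _ in range(30))
        read = _read(seq)
        full = fourfold_third_positions(read, GeneAnnotation("r1", 0, 30, "+"))
        shifted = fourfold_third_positions(read, GeneAnnotation("r1", 3, 30, "+"))
        first = seq[:2] in BACTERIAL_CODE.fourfold_prefixes
        assert shifted.thirds == (full.thirds[1:] if first else full.thirds)

    def test_minus_strand_equals_plus_on_reverse_complemented_read(self, rng):
        seq = "".join(rng.choice(list(BASES)) for _ in range(24))
        start, end = 3, 21
        minus = fourfold_third_positions(
            _read(seq), GeneAnnotation("r1", start, end, "-")
        )
        rc = reverse_complement(seq)
        mirrored = fourfold_third_positions(
            _read(rc), GeneAnnotation("r1", len(seq) - end, len(seq) - start, "+")
        )
        assert minus.thirds == mirrored.thirds


class TestGC4Matrix:
    def test_pooled_thirds_gc(self):
        reads = [_read("GGAGGCGGG", "r1"), _read("GGAGGCGGG", "r2")]
        anns = [GeneAnnotation("r1", 0, 9, "+"), GeneAnnotation("r2", 0, 9, "+")]
        sites = extract_sites(reads, anns)
        m = gc4_matrix(sites, reads, min_sites=1)
        # pooled thirds "ACGACG": GC4 = 4/6
        assert m.mean.loc["s1", "A"] == pytest.approx(4 / 6 * 100)
        assert m.n.loc["s1", "A"] == 6

    def test_group_below_min_sites_is_missing(self):
        reads = [_read("GGAGGCGGG", "r1")]
        sites = extract_sites(reads, [GeneAnnotation("r1", 0, 9, "+")])
        m = gc4_matrix(sites, reads, min_sites=10)
        assert np.isnan(m.mean.loc["s1", "A"])

    def test_generator_gc4_recovers_target_gc(self):
        from metagc.synthetic_community import (
            EnvironmentProfile,
            PhylumProfile,
            SyntheticConfig,
            generate_collection,
        )

        cfg = SyntheticConfig(
            phyla=[PhylumProfile("P", 62.1, 0.0, coding_fraction=1.0)],
            environments=[EnvironmentProfile("e", n_samples=1)],
            reads_per_sample=300,
            read_length=120,
            confidence_noise=0.0,
            seed=9,
        )
        col = generate_collection(cfg)
        sites = extract_sites(col.reads, col.annotations)
        m = gc4_matrix(sites, col.reads)
        n_sites = int(m.n.iloc[0, 0])
        se = np.sqrt(0.621 * 0.379 / n_sites) * 100
        assert m.mean.iloc[0, 0] == pytest.approx(62.1, abs=4 * se)

    def test_extreme_offset_saturates_target_gc_at_cap(self):
        from metagc.synthetic_community import (
            EnvironmentProfile,
            PhylumProfile,
            SyntheticConfig,
            generate_collection,
        )

        cfg = SyntheticConfig(
            phyla=[PhylumProfile("P", 99.0, 0.0, coding_fraction=1.0)],
            environments=[EnvironmentProfile("e", n_samples=1, gc_offset=50.0)],
            reads_per_sample=20,
            read_length=120,
            confidence_noise=0.0,
            seed=2,
        )
        # offset pushes the target to the 99% cap; thirds are then G/C
        # with probability 0.99 — not a hard guarantee, so force the cap:
        col = generate_collection(cfg)
        truth = col.truth.reads
        assert (truth["target_gc"] == 0.99).all()
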