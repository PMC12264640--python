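"""Genome parsing, quadripartite detection and CDS extraction tests."""

import numpy as np
import pytest

from plastcodon import (
    CdsSimSpec,
    Feature,
    FormatError,
    GenomeSimSpec,
    PlastcodonError,
    SequenceRecord,
    detect_quadripartite,
    extract_cds,
    read_fasta,
    read_genbank,
    region_gc,
    revcomp,
    simulate_cds_set,
    simulate_quadripartite_genome,
    structure_report_rows,
    write_fixture,
)
from plastcodon.codon_metrics import STANDARD_PLASTID_CODE as CODE


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestReadFasta:
    def test_single_record(self, tmp_path):
        path = tmp_path / "one.fasta"
        path.write_text(">rec1 desc\n" + "ACGT" * 15 + "\n")
        records = read_fasta(path)
        assert len(records) == 1
        assert records[0].id == "rec1"
        assert len(records[0].seq) == 60

    def test_two_records_in_order(self, tmp_path):
        path = tmp_path / "two.fasta"
        path.write_text(">a\nACGT\n>b\nTTTT\n")
        assert [r.id for r in read_fasta(path)] == ["a", "b"]

    def test_invalid_character_names_position(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text(">a\nACGXA\n")
        with pytest.raises(FormatError, match="position 4"):
            read_fasta(path)

    def test_duplicate_id_named_in_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(FormatError, match="'a'"):
            read_fasta(path)

    def test_empty_file_is_format_error(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(FormatError):
            read_fasta(path)

    def test_lowercase_uppercased(self, tmp_path):
        path = tmp_path / "lc.fasta"
        path.write_text(">a\nacgt\n")
        assert read_fasta(path)[0].seq == "ACGT"


# ---------------------------------------------------------------------------
# GenBank
# ---------------------------------------------------------------------------

_GB_FIXTURE = """LOCUS       TESTREC                  120 bp    DNA     circular PLN 01-JAN-2024
DEFINITION  synthetic two-exon fixture.
ACCESSION   TESTREC
FEATURES             Location/Qualifiers
     CDS             complement(join(10..30,40..60))
                     /gene="demo"
     CDS             join(111..120,1..21)
                     /gene="wrap"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


class TestReadGenbank:
    def test_minus_strand_two_exon_splice(self, tmp_path):
        path = tmp_path / "fix.gb"
        path.write_text(_GB_FIXTURE)
        record = read_genbank(path)
        demo = [f for f in record.features if f.gene_name == "demo"][0]
        assert len(demo.location) == 2
        assert all(strand == "-" for *_, strand in demo.location)
        # hand check: reverse-complement of the joined plus-strand exons
        expected = revcomp(record.seq[9:30] + record.seq[39:60])
        assert record.splice(demo) == expected

    def test_circular_topology_from_locus(self, tmp_path):
        path = tmp_path / "fix.gb"
        path.write_text(_GB_FIXTURE)
        assert read_genbank(path).circular is True

    def test_origin_wrapping_cds(self, tmp_path):
        path = tmp_path / "fix.gb"
        path.write_text(_GB_FIXTURE)
        record = read_genbank(path)
        wrap = [f for f in record.features if f.gene_name == "wrap"][0]
        assert record.splice(wrap) == record.seq[110:120] + record.seq[0:21]

    def test_location_beyond_length_is_error(self, tmp_path):
        bad = _GB_FIXTURE.replace("join(111..120,1..21)", "join(111..150,1..21)")
        path = tmp_path / "bad.gb"
        path.write_text(bad)
        with pytest.raises(FormatError, match="exceeds"):
            read_genbank(path)

    def test_missing_origin_is_error(self, tmp_path):
        head, _, _ = _GB_FIXTURE.partition("ORIGIN")
        path = tmp_path / "noorigin.gb"
        path.write_text(head + "ORIGIN\n//\n")
        with pytest.raises(FormatError):
            read_genbank(path)


# ---------------------------------------------------------------------------
# Quadripartite detection
# ---------------------------------------------------------------------------


def oracle_has_inverted_repeat(seq: str, min_len: int) -> bool:
    """Brute-force scan for any inverted repeat pair >= min_len (circular)."""
    n = len(seq)
    doubled = seq + seq
    rc = revcomp(doubled)
    for i in range(n):
        block = doubled[i : i + min_len]
        # search reverse complement elsewhere, excluding overlap with block
        start = 0
        while True:
            j = rc.find(block, start)
            if j == -1:
                break
            # rc index j maps to forward position 2n - j - min_len
            fwd = (2 * n - j - min_len) % n
            offsets = {(fwd + k) % n for k in range(min_len)}
            own = {(i + k) % n for k in range(min_len)}
            if offsets.isdisjoint(own):
                return True
            start = j + 1
    return False


class TestDetectQuadripartite:
    def test_planted_lengths_recovered_exactly(self, planted_genome):
        structure = detect_quadripartite(planted_genome)
        assert structure is not None
        assert structure.lsc.length == 10000
        assert structure.ssc.length == 1000
        assert structure.ira.length == structure.irb.length == 2000

    def test_regions_tile_the_genome(self, planted_genome):
        s = detect_quadripartite(planted_genome)
        assert s.genome_length == len(planted_genome)
        assert s.lsc.length >= s.ssc.length

    def test_ir_copies_are_reverse_complements(self, planted_genome):
        s = detect_quadripartite(planted_genome)
        ira = planted_genome.slice(s.ira.start, s.ira.length)
        irb = planted_genome.slice(s.irb.start, s.irb.length)
        assert revcomp(ira) == irb

    def test_random_sequence_has_no_structure(self):
        rng = np.random.default_rng(123)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=20000)])
        record = SequenceRecord(id="rand", seq=seq, circular=True)
        assert not oracle_has_inverted_repeat(seq, 1000)  # independent check
        assert detect_quadripartite(record, min_ir_len=1000) is None

    def test_requires_circular(self):
        record = SequenceRecord(id="lin", seq="ACGT" * 100, circular=False)
        with pytest.raises(PlastcodonError):
            detect_quadripartite(record)

    def test_detection_invariant_to_rotation(self, planted_genome):
        n = len(planted_genome)
        rotated = SequenceRecord(
            id="rot",
            seq=planted_genome.seq[n // 3 :] + planted_genome.seq[: n // 3],
            circular=True,
        )
        s = detect_quadripartite(rotated)
        assert (s.lsc.length, s.ssc.length, s.ira.length) == (10000, 1000, 2000)

    def test_structure_report_rows(self, planted_genome):
        s = detect_quadripartite(planted_genome)
        rows = structure_report_rows(planted_genome, s)
        assert [r["region"] for r in rows] == ["LSC", "IRb", "SSC", "IRa"]
        assert sum(r["length"] for r in rows) == len(planted_genome)
        for r in rows:
            assert 1 <= r["start"] <= len(planted_genome)

    def test_na_row_without_structure(self):
        record = SequenceRecord(id="x", seq="AT" * 200, circular=True)
        rows = structure_report_rows(record, None)
        assert rows[0]["region"] == "NA"


class TestRegionGc:
    def test_extremes(self):
        genome = simulate_quadripartite_genome(GenomeSimSpec(seed=3))
        s = detect_quadripartite(genome)
        gc = region_gc(genome, s)
        assert 0.0 <= gc["lsc"] <= 100.0
        assert gc["ira"] == pytest.approx(gc["irb"])  # identical copies

    def test_planted_gc_recovered(self):
        genome = simulate_quadripartite_genome(
            GenomeSimSpec(lsc_len=20000, ssc_len=2000, ir_len=20000, gc_ir=0.44, seed=9)
        )
        s = detect_quadripartite(genome)
        assert abs(s.gc_ir / 100.0 - 0.44) < 0.02

    def test_all_at_region_is_zero(self):
        record = SequenceRecord(id="at", seq="ATATATAT", circular=False)
        from plastcodon.genome_io import Region, region_gc_regions

        assert region_gc_regions(record, {"r": Region(0, 8)})["r"] == 0.0

    def test_all_gc_region_is_hundred(self):
        record = SequenceRecord(id="gc", seq="GGCC", circular=False)
        from plastcodon.genome_io import Region, region_gc_regions

        assert region_gc_regions(record, {"r": Region(0, 4)})["r"] == 100.0


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def _record_with_cds(seqs, circular=True):
    genome = "".join(seqs)
    features = []
    pos = 0
    for i, s in enumerate(seqs):
        features.append(Feature(f"g{i}", "CDS", [(pos, pos + len(s), "+")]))
        pos += len(s)
    return SequenceRecord(id="toy", seq=genome, circular=circular, features=features)


def _valid_cds(n_codons: int) -> str:
    return "ATG" + "GCA" * (n_codons - 2) + "TAA"


class TestExtractCds:
    def test_length_boundary_at_300(self):
        record = _record_with_cds(
            [_valid_cds(100), _valid_cds(101)]  # 300 and 303 nt
        )
        # shrink one below 300 by hand: 299 nt cannot be a whole-codon CDS,
        # so model the boundary with 297 (99 codons) instead of 299
        record.features.append(Feature("short", "CDS", [(0, 297, "+")]))
        record.seq = record.seq  # unchanged; 'short' reuses a 297 nt prefix
        out = extract_cds(record)
        names = out.gene_names()
        assert "g0" in names and "g1" in names
        assert "short" not in names  # fails stop-codon and length filters

    def test_non_atg_start_excluded(self):
        bad = "GTG" + "GCA" * 99 + "TAA"
        record = _record_with_cds([bad, _valid_cds(100)])
        assert extract_cds(record).gene_names() == ["g1"]

    def test_internal_stop_excluded(self):
        bad = "ATG" + "GCA" * 50 + "TAA" + "GCA" * 48 + "TAA"
        record = _record_with_cds([bad, _valid_cds(100)])
        assert extract_cds(record).gene_names() == ["g1"]

    def test_ir_duplicate_deduplicated(self):
        cds = _valid_cds(100)
        genome = cds + "ACGT" * 10 + cds
        features = [
            Feature("rps19", "CDS", [(0, 300, "+")]),
            Feature("rps19", "CDS", [(340, 640, "+")]),
        ]
        record = SequenceRecord(id="dup", seq=genome, circular=True, features=features)
        out = extract_cds(record)
        assert out.gene_names() == ["rps19"]

    def test_same_name_different_sequence_suffixed(self):
        a = "ATG" + "GCA" * 99 + "TAA"
        b = "ATG" + "GCT" * 99 + "TAA"
        record = SequenceRecord(
            id="two",
            seq=a + b,
            circular=True,
            features=[
                Feature("psbA", "CDS", [(0, len(a), "+")]),
                Feature("psbA", "CDS", [(len(a), len(a) + len(b), "+")]),
            ],
        )
        assert extract_cds(record).gene_names() == ["psbA", "psbA_2"]

    def test_empty_set_warns(self):
        record = _record_with_cds(["GTG" + "GCA" * 99 + "TAA"])
        with pytest.warns(UserWarning):
            out = extract_cds(record)
        assert len(out) == 0

    def test_rotation_invariance(self, planted_genome):
        baseline = extract_cds(planted_genome)
        n = len(planted_genome)
        shift = 4567
        rotated_seq = planted_genome.seq[shift:] + planted_genome.seq[:shift]
        feats = []
        for f in planted_genome.features:
            loc = []
            for start, end, strand in f.location:
                s2, e2 = (start - shift) % n, (end - shift) % n
                if s2 < e2:
                    loc.append((s2, e2, strand))
                else:  # feature now crosses the origin: split, splice order
                    parts = [(s2, n, strand), (0, e2, strand)]
                    loc.extend(parts if strand == "+" else parts[::-1])
            feats.append(Feature(f.gene_name, f.feature_type, loc))
        rotated = SequenceRecord(id="rot", seq=rotated_seq, circular=True, features=feats)
        assert sorted(extract_cds(rotated).genes) == sorted(baseline.genes)

    def test_all_simulated_genes_pass(self):
        cds_set, _ = simulate_cds_set(CdsSimSpec(n_genes=30, seed=1))
        for _, seq in cds_set.genes:
            assert len(seq) >= 300 and len(seq) % 3 == 0
            assert seq.startswith("ATG") and seq[-3:] in CODE.stop_codons
            body = [seq[i : i + 3] for i in range(3, len(seq) - 3, 3)]
            assert not any(c in CODE.stop_codons for c in body)

    def test_every_retained_cds_translates(self, planted_genome):
        for _, seq in extract_cds(planted_genome).genes:
            from Bio.Seq import Seq

            protein = str(Seq(seq).translate(table=11))
            assert protein.endswith("*") and "*" not in protein[:-1]
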