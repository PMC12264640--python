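"""Genome records, annotation parsing, quadripartite structure, CDS extraction.

Reads FASTA and GenBank flat files (via Biopython behind a validated
surface), detects the canonical plastome quadripartite architecture
(LSC + IRb + SSC + IRa) by maximal inverted-repeat search on the
circular sequence, and extracts the filtered coding-sequence set that
all downstream codon statistics consume.

Coordinates are 0-based half-open internally; user-facing reports use
1-based inclusive coordinates (GenBank convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import SeqIO
from Bio.Seq import UndefinedSequenceError

from .codon_metrics import BASES, GeneticCode, STANDARD_PLASTID_CODE, STOP_CODONS
from .errors import FormatError, PlastcodonError

__all__ = [
    "Feature",
    "SequenceRecord",
    "Region",
    "QuadripartiteStructure",
    "CdsSet",
    "read_fasta",
    "read_genbank",
    "detect_quadripartite",
    "extract_cds",
    "region_gc",
    "structure_report_rows",
    "revcomp",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the A/C/G/T/N alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass
class Feature:
    """One annotated feature: a list of exon intervals in splice order.

    ``location`` holds (start, end, strand) triples, 0-based half-open,
    already ordered for extraction: concatenating each interval's
    sequence (reverse-complemented when its strand is '-') yields the
    spliced product. This matches how GenBank ``join``/``complement``
    locations are resolved.
    """

    gene_name: str
    feature_type: str  # CDS, tRNA, rRNA or other
    location: List[Tuple[int, int, str]]
    pseudo: bool = False


@dataclass
class SequenceRecord:
    """A named nucleotide sequence with topology and annotated features."""

    id: str
    seq: str
    circular: bool = False
    features: List[Feature] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.seq)

    def slice(self, start: int, length: int) -> str:
        """Extract ``length`` bases from ``start``, wrapping for circular records."""
        n = len(self.seq)
        if length > n:
            raise PlastcodonError("slice longer than sequence")
        end = start + length
        if end <= n:
            return self.seq[start:end]
        if not self.circular:
            raise PlastcodonError("interval outside a linear record")
        return self.seq[start:] + self.seq[: end - n]

    def splice(self, feature: Feature) -> str:
        """Spliced (strand-resolved) sequence of a feature."""
        parts = []
        n = len(self.seq)
        for start, end, strand in feature.location:
            if not (0 <= start < end <= n):
                raise FormatError(
                    f"feature {feature.gene_name!r} interval ({start}, {end}) "
                    f"outside sequence of length {n}"
                )
            part = self.seq[start:end]
            parts.append(revcomp(part) if strand == "-" else part)
        return "".join(parts)


@dataclass(frozen=True)
class Region:
    """A (possibly origin-wrapping) arc of a circular genome."""

    start: int  # 0-based
    length: int

    def end(self, genome_length: int) -> int:
        """0-based exclusive end, modulo genome length (0 means the origin)."""
        return (self.start + self.length) % genome_length


@dataclass
class QuadripartiteStructure:
    """LSC/SSC/IRa/IRb partition of a circular plastome with per-region GC%.

    The four regions tile the circle in the order LSC, IRb, SSC, IRa;
    the IRb arc equals the reverse complement of the IRa arc, so IR GC
    is reported once.
    """

    lsc: Region
    ssc: Region
    ira: Region
    irb: Region
    gc_lsc: float
    gc_ssc: float
    gc_ir: float

    @property
    def genome_length(self) -> int:
        return self.lsc.length + self.ssc.length + self.ira.length + self.irb.length


@dataclass
class CdsSet:
    """The filtered coding sequences of one species/record.

    Every sequence has length >= 300 and a multiple of 3, starts ATG,
    ends with a stop codon and has no internal stop; gene names are
    unique within the set.
    """

    species_label: str
    genes: List[Tuple[str, str]]
    provenance: str = ""

    def __len__(self) -> int:
        return len(self.genes)

    def gene_names(self) -> List[str]:
        return [name for name, _ in self.genes]

    def sequence_of(self, gene_name: str) -> str:
        for name, seq in self.genes:
            if name == gene_name:
                return seq
        raise KeyError(gene_name)


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------


def read_fasta(path) -> List[SequenceRecord]:
    """Read a (multi-record) FASTA file into uppercase A/C/G/T/N records."""
    path = Path(path)
    records: List[SequenceRecord] = []
    seen: Dict[str, int] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        for pos, base in enumerate(seq):
            if base not in "ACGTN":
                raise FormatError(
                    f"record {rec.id!r}: invalid character {base!r} at "
                    f"position {pos + 1}"
                )
        if rec.id in seen:
            raise FormatError(f"duplicate record id {rec.id!r}")
        seen[rec.id] = 1
        records.append(SequenceRecord(id=rec.id, seq=seq, circular=False))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def _feature_type(gb_type: str) -> str:
    return gb_type if gb_type in ("CDS", "tRNA", "rRNA") else "other"


def read_genbank(path) -> SequenceRecord:
    """Read one GenBank flat file, resolving join/complement locations.

    Circular topology is taken from the LOCUS line; coordinates are
    converted to 0-based half-open intervals stored in splice order.
    """
    path = Path(path)
    try:
        rec = SeqIO.read(str(path), "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: {exc}") from exc
    try:
        seq = str(rec.seq).upper()
    except UndefinedSequenceError as exc:
        raise FormatError(f"{path}: missing ORIGIN sequence") from exc
    if not seq:
        raise FormatError(f"{path}: empty sequence")

    circular = rec.annotations.get("topology", "linear") == "circular"
    n = len(seq)
    features: List[Feature] = []
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "gene"):
            continue
        if feat.type == "gene":
            continue  # gene features duplicate CDS/tRNA/rRNA spans
        name = (
            feat.qualifiers.get("gene", [None])[0]
            or feat.qualifiers.get("locus_tag", [None])[0]
            or f"{feat.type}_{int(feat.location.start)}"
        )
        location: List[Tuple[int, int, str]] = []
        for part in feat.location.parts:
            start, end = int(part.start), int(part.end)
            if end > n or start < 0:
                raise FormatError(
                    f"{path}: feature {name!r} location ({start}, {end}) "
                    f"exceeds sequence length {n}"
                )
            location.append((start, end, "-" if part.strand == -1 else "+"))
        features.append(
            Feature(
                gene_name=name,
                feature_type=_feature_type(feat.type),
                location=location,
                pseudo="pseudo" in feat.qualifiers or "pseudogene" in feat.qualifiers,
            )
        )
    return SequenceRecord(id=rec.id or rec.name, seq=seq, circular=circular, features=features)


# ---------------------------------------------------------------------------
# Quadripartite detection
# ---------------------------------------------------------------------------


def _find_inverted_repeats(seq: str, k: int, min_len: int) -> List[Tuple[int, int, int]]:
    """Maximal exact inverted repeats on the circular sequence.

    Returns (a, b, length) triples: seq_circ[a:a+length] equals the
    reverse complement of seq_circ[b:b+length], blocks disjoint on the
    circle. Seeds are k-mers; extension is exact and maximal. Along one
    repeat, a + b + length is invariant, which lets whole anti-diagonals
    be marked as covered after a single extension.
    """
    n = len(seq)
    if n < 2 * k:
        return []
    doubled = seq + seq[: k - 1]
    kmer_pos: Dict[str, List[int]] = {}
    for i in range(n):
        kmer_pos.setdefault(doubled[i : i + k], []).append(i)

    comp = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "#"}
    covered: Dict[int, List[Tuple[int, int]]] = {}
    repeats: Dict[Tuple[int, int], int] = {}

    def base(x: int) -> str:
        return seq[x % n]

    for i in range(n):
        rc = revcomp(doubled[i : i + k])
        for j in kmer_pos.get(rc, ()):
            if j < i:
                continue  # pair handled from the smaller index
            diag = (i + j + k) % n
            skip = False
            for lo, hi in covered.get(diag, ()):
                if lo <= i < hi:
                    skip = True
                    break
            if skip:
                continue
            a, b, length = i, j, k
            # grow left end of block A / right end of block B
            while length < n:
                na, nb = a - 1, b + length
                if na % n == nb % n or (nb - a + 1) >= n:
                    break
                if base(na) != comp.get(base(nb), "?"):
                    break
                a, length = na, length + 1
            # grow right end of block A / left end of block B
            while length < n:
                na, nb = a + length, b - 1
                if na % n == nb % n or (na - nb + 1) >= n:
                    break
                if base(na) != comp.get(base(nb), "?"):
                    break
                b, length = nb, length + 1
            covered.setdefault(diag, []).append((a, a + length))
            if length < min_len:
                continue
            a0, b0 = a % n, b % n
            # disjointness of the two arcs on the circle
            if _arcs_overlap(a0, length, b0, length, n):
                continue
            key = tuple(sorted((a0, b0)))
            if repeats.get(key, 0) < length:
                repeats[key] = length
    return [(a, b, l) for (a, b), l in repeats.items()]


def _arcs_overlap(s1: int, l1: int, s2: int, l2: int, n: int) -> bool:
    def points(s, l):
        return set(range(s, s + l))

    p1 = {x % n for x in range(s1, s1 + l1)}
    # cheap check first: compare interval arithmetic on the circle
    for x in (s2 % n, (s2 + l2 - 1) % n):
        if x in p1:
            return True
    p2 = {x % n for x in range(s2, s2 + l2)}
    return not p1.isdisjoint(p2)


def detect_quadripartite(
    record: SequenceRecord,
    min_ir_len: int = 1000,
    max_mismatch: int = 0,
    k: int = 25,
) -> Optional[QuadripartiteStructure]:
    """Locate the LSC/SSC/IR partition of a circular plastome.

    Finds the maximal-length pair of disjoint exact inverted repeats
    (>= ``min_ir_len``); the two single-copy gaps between the copies are
    labelled LSC (longer) and SSC (shorter). Returns None when no
    qualifying repeat pair exists — a valid outcome for non-plastome
    input, distinct from a parse error. Ties on repeat length break to
    the smallest start coordinate. Only exact repeats are supported
    (``max_mismatch`` must be 0): plastome IR copies are identical in
    practice.
    """
    if not record.circular:
        raise PlastcodonError("quadripartite detection requires a circular record")
    if min_ir_len < 100:
        raise PlastcodonError("min_ir_len must be >= 100")
    if max_mismatch != 0:
        raise NotImplementedError("only exact inverted repeats (max_mismatch=0) are supported")

    candidates = _find_inverted_repeats(record.seq, k=k, min_len=min_ir_len)
    if not candidates:
        return None
    best = max(candidates, key=lambda t: (t[2], -min(t[0], t[1])))
    a, b, length = best
    if b < a:
        a, b = b, a

    n = len(record.seq)
    gap1_start, gap1_len = (a + length) % n, (b - (a + length)) % n
    gap2_start, gap2_len = (b + length) % n, (a - (b + length)) % n
    if gap1_len == 0 or gap2_len == 0:
        return None  # repeats adjacent: no single-copy regions
    if gap1_len >= gap2_len:
        lsc, ssc = Region(gap1_start, gap1_len), Region(gap2_start, gap2_len)
        irb_start, ira_start = b, a
    else:
        lsc, ssc = Region(gap2_start, gap2_len), Region(gap1_start, gap1_len)
        irb_start, ira_start = a, b
    # order around the circle is LSC, IRb, SSC, IRa
    irb, ira = Region(irb_start, length), Region(ira_start, length)

    gc = region_gc_regions(record, {"lsc": lsc, "ssc": ssc, "ir": irb})
    return QuadripartiteStructure(
        lsc=lsc,
        ssc=ssc,
        ira=ira,
        irb=irb,
        gc_lsc=gc["lsc"],
        gc_ssc=gc["ssc"],
        gc_ir=gc["ir"],
    )


def _gc_percent(seq: str) -> float:
    atgc = sum(seq.count(b) for b in BASES)
    if atgc == 0:
        raise PlastcodonError("region contains no unambiguous bases")
    return 100.0 * (seq.count("G") + seq.count("C")) / atgc


def region_gc_regions(record: SequenceRecord, regions: Dict[str, Region]) -> Dict[str, float]:
    """GC percent per named region; N excluded from the denominator."""
    out = {}
    for name, region in regions.items():
        if region.length > len(record.seq):
            raise PlastcodonError(f"region {name!r} exceeds record length")
        out[name] = _gc_percent(record.slice(region.start, region.length))
    return out


def region_gc(record: SequenceRecord, structure: QuadripartiteStructure) -> Dict[str, float]:
    """Per-region GC percents (full precision) for a detected structure."""
    if structure.genome_length != len(record.seq):
        raise PlastcodonError("structure does not tile this record")
    return region_gc_regions(
        record,
        {
            "lsc": structure.lsc,
            "ssc": structure.ssc,
            "ira": structure.ira,
            "irb": structure.irb,
        },
    )


def structure_report_rows(
    record: SequenceRecord, structure: Optional[QuadripartiteStructure]
) -> List[Dict[str, object]]:
    """Rows for the structure TSV: region, start, end, length, gc_percent.

    Coordinates are 1-based inclusive; GC is rounded to 2 decimals. A
    missing structure yields a single NA row.
    """
    if structure is None:
        return [
            {
                "region": "NA",
                "start": "NA",
                "end": "NA",
                "length": len(record.seq),
                "gc_percent": round(_gc_percent(record.seq), 2),
            }
        ]
    n = structure.genome_length
    gc = {
        "LSC": structure.gc_lsc,
        "IRb": structure.gc_ir,
        "SSC": structure.gc_ssc,
        "IRa": structure.gc_ir,
    }
    regions = {
        "LSC": structure.lsc,
        "IRb": structure.irb,
        "SSC": structure.ssc,
        "IRa": structure.ira,
    }
    rows = []
    for name in ("LSC", "IRb", "SSC", "IRa"):
        region = regions[name]
        rows.append(
            {
                "region": name,
                "start": region.start + 1,
                "end": ((region.start + region.length - 1) % n) + 1,
                "length": region.length,
                "gc_percent": round(gc[name], 2),
            }
        )
    return rows


# ---------------------------------------------------------------------------
# CDS extraction
# ---------------------------------------------------------------------------


def _drop_n_codons(seq: str) -> Tuple[str, float]:
    """Remove codons containing N; return (cleaned sequence, dropped fraction)."""
    codons = [seq[i : i + 3] for i in range(0, len(seq), 3)]
    kept = [c for c in codons if "N" not in c]
    dropped = len(codons) - len(kept)
    frac = dropped / len(codons) if codons else 0.0
    return "".join(kept), frac


def _passes_filters(seq: str, code: GeneticCode, min_len: int) -> bool:
    if len(seq) < min_len or len(seq) % 3 != 0:
        return False
    if not seq.startswith("ATG"):
        return False
    if seq[-3:] not in code.stop_codons:
        return False
    for i in range(3, len(seq) - 3, 3):
        if seq[i : i + 3] in code.stop_codons:
            return False
    return True


def extract_cds(
    record: SequenceRecord,
    code: GeneticCode = STANDARD_PLASTID_CODE,
    min_len: int = 300,
    max_ambiguous_fraction: float = 0.05,
) -> CdsSet:
    """Splice and filter the CDS features of a record.

    Filters (all must pass): length >= ``min_len`` after ambiguous-codon
    removal, multiple of 3, ATG start, stop-codon end, no internal stop.
    Codons containing N are dropped before the length test; a CDS losing
    more than ``max_ambiguous_fraction`` of its codons is discarded.
    IR-duplicated genes (identical name and sequence) are deduplicated
    keeping the first copy; same-named genes with different sequences
    are kept under suffixed names.
    """
    kept: List[Tuple[str, str]] = []
    seen: Dict[Tuple[str, str], bool] = {}
    name_counts: Dict[str, int] = {}
    for feature in record.features:
        if feature.feature_type != "CDS" or feature.pseudo:
            continue
        seq = record.splice(feature)
        if len(seq) % 3 != 0:
            continue
        seq, dropped = _drop_n_codons(seq)
        if dropped > max_ambiguous_fraction:
            continue
        if not _passes_filters(seq, code, min_len):
            continue
        key = (feature.gene_name, seq)
        if key in seen:
            continue  # IR duplicate
        seen[key] = True
        count = name_counts.get(feature.gene_name, 0)
        name = feature.gene_name if count == 0 else f"{feature.gene_name}_{count + 1}"
        name_counts[feature.gene_name] = count + 1
        kept.append((name, seq))
    if not kept:
        warnings.warn(f"no CDS features of {record.id!r} survived filtering")
    return CdsSet(species_label=record.id, genes=kept, provenance=record.id)
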