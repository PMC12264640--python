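"""Seeded generators for every input the pipeline consumes.

Two generators cover the pipeline end to end without downloads:

* :func:`simulate_cds_set` emits gene sets with controllable
  codon-usage structure — a *mutation* regime in which synonymous
  choice is driven only by a target third-position GC (genes land near
  the ENCexp curve), a *selection* regime in which a planted set of
  preferred codons is favoured with tunable strength ``s`` (decoupling
  ENC from GC3), and a *mixed* regime layering selection on the
  mutation baseline.
* :func:`simulate_quadripartite_genome` emits circular genomes built as
  LSC + IRb + SSC + IRa with exact planted region lengths, per-region
  GC targets, and valid planted CDS features (including IR-duplicated
  gene copies).

Every generated CDS passes the extraction filters by construction
(ATG start, stop end, no internal stop, length >= 300 nt). Randomness
flows from one root seed; per-gene child seeds are derived
deterministically and recorded in the returned ground truth.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import FeatureLocation, CompoundLocation, SeqFeature
from Bio.SeqRecord import SeqRecord

from .codon_metrics import BASES, GeneticCode, STANDARD_PLASTID_CODE
from .errors import PlastcodonError
from .genome_io import CdsSet, Feature, SequenceRecord, revcomp

__all__ = [
    "CdsSimSpec",
    "GenomeSimSpec",
    "simulate_cds_set",
    "simulate_quadripartite_genome",
    "write_fixture",
    "PLASTID_AA_PROFILE",
]

# Fixed plausible plastid-like amino-acid usage profile (fractions,
# normalized at load). Populates every degeneracy class; configurable
# through CdsSimSpec.aa_profile. Stops excluded (appended separately).
PLASTID_AA_PROFILE: Dict[str, float] = {
    "L": 0.105, "S": 0.079, "I": 0.084, "G": 0.071, "A": 0.062,
    "V": 0.064, "T": 0.052, "P": 0.045, "K": 0.051, "R": 0.051,
    "N": 0.046, "D": 0.039, "E": 0.046, "Q": 0.037, "F": 0.051,
    "Y": 0.035, "H": 0.022, "C": 0.011, "M": 0.024, "W": 0.018,
}


@dataclass
class CdsSimSpec:
    """Specification for a simulated coding-sequence set.

    ``gc3`` may be a single target (every gene) or a (lo, hi) range,
    in which case per-gene targets are evenly spaced across the set.
    ``length_codons`` bounds the total gene length in codons including
    start and stop (uniform draw; minimum 100 codons = 300 nt).
    ``strength`` is the selection weight s in [0, 1]: the synonymous
    choice is (1 - s) * baseline + s * point mass on the preferred
    codon of each family that contains one.
    """

    n_genes: int = 50
    length_codons: Tuple[int, int] = (150, 450)
    regime: str = "mutation"  # mutation | selection | mixed
    gc3: Union[float, Tuple[float, float]] = 0.30
    preferred_codons: Sequence[str] = ()
    strength: float = 0.0
    seed: int = 0
    species_label: str = "synthetic"
    aa_profile: Dict[str, float] = field(default_factory=lambda: dict(PLASTID_AA_PROFILE))


@dataclass
class GenomeSimSpec:
    """Specification for a circular genome with planted quadripartite layout."""

    lsc_len: int = 10000
    ssc_len: int = 1000
    ir_len: int = 2000
    gc_lsc: float = 0.37
    gc_ssc: float = 0.33
    gc_ir: float = 0.44
    n_cds_lsc: int = 0
    n_cds_ssc: int = 0
    n_cds_ir: int = 0
    seed: int = 0
    record_id: str = "synthetic_plastome"


def _gene_gc3_targets(spec: CdsSimSpec) -> List[float]:
    if isinstance(spec.gc3, tuple):
        lo, hi = spec.gc3
        if spec.n_genes == 1:
            return [(lo + hi) / 2.0]
        return list(np.linspace(lo, hi, spec.n_genes))
    return [float(spec.gc3)] * spec.n_genes


def _third_base_weights(family: Sequence[str], g: float) -> np.ndarray:
    """Codon weights within a family from an internal third-base GC rate.

    Probability ``g`` is split uniformly over the family's G/C-ending
    codons and ``1 - g`` over its A/T-ending codons, so every
    multi-codon family hits third-position GC ``g`` exactly in
    expectation regardless of subset sizes.
    """
    n_gc = sum(1 for c in family if c[2] in "GC")
    n_at = len(family) - n_gc
    if n_gc == 0 or n_at == 0:  # single-codon families (Met, Trp)
        return np.full(len(family), 1.0 / len(family))
    probs = np.array(
        [g / n_gc if c[2] in "GC" else (1.0 - g) / n_at for c in family]
    )
    return probs


def _calibrated_gc_rate(spec: CdsSimSpec, gc3_target: float, code: GeneticCode) -> float:
    """Internal synonymous GC rate that yields the overall GC3 target.

    Met and Trp codons (and the ATG start) always carry G at position
    3, inflating overall GC3 above the synonymous rate; solving
    g = (target - f) / (1 - f), with f the profile mass on fixed-G
    families, makes the realized whole-gene GC3 track the target.
    Targets below f are unreachable under the genetic code.
    """
    profile = spec.aa_profile
    total = sum(v for aa, v in profile.items() if aa in code.families and aa != "*")
    fixed = sum(
        profile.get(aa, 0.0) for aa in code.single_codon_families() if aa != "*"
    )
    f = fixed / total
    g = (gc3_target - f) / (1.0 - f)
    if not 0.0 <= g <= 1.0:
        raise PlastcodonError(
            f"gc3 target {gc3_target} unreachable: fixed-G codons (Met/Trp) "
            f"contribute {f:.3f} at minimum"
        )
    return g


def _codon_sampler(
    spec: CdsSimSpec, g: float, strength: float, code: GeneticCode
) -> Dict[str, Tuple[List[str], np.ndarray]]:
    """Per-amino-acid (codons, probabilities) under the spec's regime.

    ``g`` is the calibrated synonymous third-base GC rate; ``strength``
    the per-gene selection weight mixing the baseline with a point mass
    on the preferred codon of each family that contains one.
    """
    preferred = {c.upper().replace("U", "T") for c in spec.preferred_codons}
    samplers: Dict[str, Tuple[List[str], np.ndarray]] = {}
    for aa, family in code.families.items():
        fam = list(family)
        if spec.regime == "mutation":
            probs = _third_base_weights(fam, g)
        else:
            if spec.regime == "selection":
                baseline = np.full(len(fam), 1.0 / len(fam))
            elif spec.regime == "mixed":
                baseline = _third_base_weights(fam, g)
            else:
                raise PlastcodonError(f"unknown regime {spec.regime!r}")
            hits = [c in preferred for c in fam]
            if any(hits):
                point = np.array([1.0 if h else 0.0 for h in hits])
                point /= point.sum()
                probs = (1.0 - strength) * baseline + strength * point
            else:
                probs = baseline
        samplers[aa] = (fam, probs)
    return samplers


def simulate_cds_set(
    spec: CdsSimSpec, code: GeneticCode = STANDARD_PLASTID_CODE
) -> Tuple[CdsSet, Dict]:
    """Generate a CDS set plus the ground truth needed for recovery tests.

    Returns (cds_set, truth) where truth records the regime, preferred
    set, selection strength and per-gene GC3 targets and child seeds.
    """
    if spec.n_genes < 1:
        raise PlastcodonError("n_genes must be >= 1")
    lo, hi = spec.length_codons
    if lo < 100:
        raise PlastcodonError("minimum gene length is 100 codons (300 nt)")
    if not 0.0 <= spec.strength <= 1.0:
        raise PlastcodonError("strength must lie in [0, 1]")

    root = np.random.default_rng(spec.seed)
    child_seeds = [int(s) for s in root.integers(0, 2**31 - 1, size=spec.n_genes)]
    gc3_targets = _gene_gc3_targets(spec)

    # Under selection/mixed regimes the selection weight ramps linearly
    # across genes from 0 to ``strength``: strongly selected genes end
    # up in the low-ENC tail, emulating expression-correlated selection
    # — the structure the ENC-tail library contrast is designed to
    # detect. Per-gene weights are recorded in the ground truth.
    if spec.regime == "mutation" or spec.n_genes == 1:
        strengths = [spec.strength if spec.regime != "mutation" else 0.0] * spec.n_genes
    else:
        strengths = [
            spec.strength * idx / (spec.n_genes - 1) for idx in range(spec.n_genes)
        ]

    profile_aas = [aa for aa in spec.aa_profile if aa in code.families and aa != "*"]
    profile_p = np.array([spec.aa_profile[aa] for aa in profile_aas], dtype=float)
    profile_p /= profile_p.sum()

    genes: List[Tuple[str, str]] = []
    truth_genes: Dict[str, Dict] = {}
    width = len(str(spec.n_genes))
    for idx in range(spec.n_genes):
        rng = np.random.default_rng(child_seeds[idx])
        gc3 = gc3_targets[idx]
        g_rate = _calibrated_gc_rate(spec, gc3, code)
        samplers = _codon_sampler(spec, g_rate, strengths[idx], code)
        n_codons = int(rng.integers(lo, hi + 1))
        body_len = n_codons - 2  # minus start and stop
        aas = rng.choice(profile_aas, size=body_len, p=profile_p)
        codons = ["ATG"]
        for aa in aas:
            fam, probs = samplers[aa]
            codons.append(fam[int(rng.choice(len(fam), p=probs))])
        stop_fam, stop_p = samplers["*"]
        codons.append(stop_fam[int(rng.choice(len(stop_fam), p=stop_p))])
        name = f"gene{idx + 1:0{width}d}"
        genes.append((name, "".join(codons)))
        truth_genes[name] = {
            "gc3_target": float(gc3),
            "strength": float(strengths[idx]),
            "seed": child_seeds[idx],
        }

    cds_set = CdsSet(
        species_label=spec.species_label, genes=genes, provenance=f"simulated(seed={spec.seed})"
    )
    truth = {
        "regime": spec.regime,
        "preferred_codons": sorted(
            c.upper().replace("U", "T") for c in spec.preferred_codons
        ),
        "strength": spec.strength,
        "seed": spec.seed,
        "genes": truth_genes,
    }
    return cds_set, truth


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list(BASES))[rng.choice(4, size=length, p=p)])


def _plant_genes(
    region_seq: str,
    n_genes: int,
    rng: np.random.Generator,
    gc: float,
    name_prefix: str,
) -> Tuple[str, List[Tuple[str, int, int]]]:
    """Overwrite non-overlapping stretches of a region with valid CDSs.

    Returns the edited region and (name, start, end) placements local
    to the region. Placement keeps a margin from the region edges so
    boundary-base adjustments never touch planted genes.
    """
    if n_genes == 0:
        return region_seq, []
    spec = CdsSimSpec(
        n_genes=n_genes,
        length_codons=(100, 140),
        regime="mutation",
        gc3=gc,
        seed=int(rng.integers(0, 2**31 - 1)),
        species_label=name_prefix,
    )
    cds_set, _ = simulate_cds_set(spec)
    margin = 10
    seq = list(region_seq)
    placements: List[Tuple[str, int, int]] = []
    cursor = margin
    for gene_name, gene_seq in cds_set.genes:
        if cursor + len(gene_seq) + margin > len(region_seq):
            raise PlastcodonError(
                f"region too short to plant {n_genes} genes of ~300-420 nt"
            )
        gap = int(rng.integers(5, 50))
        start = cursor + gap
        if start + len(gene_seq) + margin > len(region_seq):
            raise PlastcodonError("planted features would overlap the region edge")
        seq[start : start + len(gene_seq)] = gene_seq
        placements.append((f"{name_prefix}_{gene_name}", start, start + len(gene_seq)))
        cursor = start + len(gene_seq)
    return "".join(seq), placements


def simulate_quadripartite_genome(spec: GenomeSimSpec) -> SequenceRecord:
    """Build a circular genome as LSC + IRb + SSC + IRa (IRa = revcomp IRb).

    Region lengths are exact by construction; background composition
    tracks the per-region GC targets. CDS features planted in the IR
    appear in both copies under the same gene name (minus strand in the
    second copy), exercising downstream deduplication. Edge bases of
    the single-copy regions are adjusted so chance matches can never
    extend the inverted repeat beyond its planted bounds.
    """
    if spec.ir_len < 1000:
        raise PlastcodonError("ir_len must be >= 1000")
    if spec.lsc_len < 1 or spec.ssc_len < 1:
        raise PlastcodonError("single-copy regions must be non-empty")
    rng = np.random.default_rng(spec.seed)

    lsc = _random_seq(rng, spec.lsc_len, spec.gc_lsc)
    ssc = _random_seq(rng, spec.ssc_len, spec.gc_ssc)
    irb = _random_seq(rng, spec.ir_len, spec.gc_ir)

    lsc, lsc_placements = _plant_genes(lsc, spec.n_cds_lsc, rng, spec.gc_lsc, "lsc")
    ssc, ssc_placements = _plant_genes(ssc, spec.n_cds_ssc, rng, spec.gc_ssc, "ssc")
    irb, ir_placements = _plant_genes(irb, spec.n_cds_ir, rng, spec.gc_ir, "ir")

    # Stop chance extension of the IR pair past its planted bounds.
    # With genome order LSC, IRb, SSC, IRa on a circle, extending the
    # pair leftwards of IRb wraps to pair LSC[0] with complement(LSC[-1]),
    # and rightwards of IRb pairs SSC[-1] with complement(SSC[0]).
    # Setting an edge base equal to its partner breaks the pairing:
    # no DNA base equals its own complement.
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if lsc[0] == comp[lsc[-1]]:
        lsc = lsc[-1] + lsc[1:]
    if ssc[0] == comp[ssc[-1]]:
        ssc = ssc[-1] + ssc[1:]

    ira = revcomp(irb)
    genome = lsc + irb + ssc + ira
    n = len(genome)

    features: List[Feature] = []
    for name, start, end in lsc_placements:
        features.append(Feature(name, "CDS", [(start, end, "+")]))
    irb_offset = spec.lsc_len
    ssc_offset = spec.lsc_len + spec.ir_len
    ira_offset = spec.lsc_len + spec.ir_len + spec.ssc_len
    for name, start, end in ssc_placements:
        features.append(Feature(name, "CDS", [(ssc_offset + start, ssc_offset + end, "+")]))
    for name, start, end in ir_placements:
        features.append(Feature(name, "CDS", [(irb_offset + start, irb_offset + end, "+")]))
        # mirrored copy in IRa, minus strand
        m_start = ira_offset + (spec.ir_len - end)
        m_end = ira_offset + (spec.ir_len - start)
        features.append(Feature(name, "CDS", [(m_start, m_end, "-")]))
    features.sort(key=lambda f: f.location[0][0])

    return SequenceRecord(id=spec.record_id, seq=genome, circular=True, features=features)


# ---------------------------------------------------------------------------
# Fixture writing
# ---------------------------------------------------------------------------


def _to_seqrecord(record: SequenceRecord) -> SeqRecord:
    rec = SeqRecord(Seq(record.seq), id=record.id, description="")
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = "circular" if record.circular else "linear"
    for feature in record.features:
        parts = [
            FeatureLocation(start, end, strand=-1 if strand == "-" else 1)
            for start, end, strand in feature.location
        ]
        loc = parts[0] if len(parts) == 1 else CompoundLocation(parts)
        rec.features.append(
            SeqFeature(loc, type=feature.feature_type, qualifiers={"gene": [feature.gene_name]})
        )
    return rec


def write_fixture(obj: Union[SequenceRecord, CdsSet], path, fmt: str) -> Path:
    """Write a record or CDS set to fasta / genbank / tsv.

    Emitted files are re-readable by the genome_io readers with a
    lossless round trip of sequence, features and topology.
    """
    path = Path(path)
    if fmt == "fasta":
        if isinstance(obj, SequenceRecord):
            records = [SeqRecord(Seq(obj.seq), id=obj.id, description="")]
        else:
            records = [
                SeqRecord(Seq(seq), id=name, description="") for name, seq in obj.genes
            ]
        SeqIO.write(records, str(path), "fasta")
    elif fmt == "genbank":
        if not isinstance(obj, SequenceRecord):
            raise PlastcodonError("genbank output requires a SequenceRecord")
        SeqIO.write([_to_seqrecord(obj)], str(path), "genbank")
    elif fmt == "tsv":
        if not isinstance(obj, CdsSet):
            raise PlastcodonError("tsv output requires a CdsSet")
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
            writer.writerow(["gene", "length", "sequence"])
            for name, seq in obj.genes:
                writer.writerow([name, len(seq), seq])
    else:
        raise PlastcodonError(f"unknown fixture format {fmt!r}")
    return path


def read_cds_tsv(path, species_label: Optional[str] = None) -> CdsSet:
    """Read a CDS set from the gene/length/sequence TSV written above."""
    path = Path(path)
    genes: List[Tuple[str, str]] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or "gene" not in reader.fieldnames:
            raise PlastcodonError(f"{path}: expected columns gene, length, sequence")
        for row in reader:
            genes.append((row["gene"], row["sequence"].upper()))
    return CdsSet(
        species_label=species_label or path.stem, genes=genes, provenance=str(path)
    )


def write_ground_truth(truth: Dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return path
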