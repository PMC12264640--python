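"""Per-gene and pooled codon-usage statistics.

Implements the metrics underlying plastid codon-usage-bias analysis:
codon counting, positional GC content (GC1/GC2/GC3/GC12), relative
synonymous codon usage (RSCU), Wright's effective number of codons
(observed ENC and the mutation-pressure expectation ENCexp), the ENC
ratio, the codon adaptation index (CAI), and parity-rule-2 (PR2)
coordinates from fourfold-degenerate third positions.

Conventions
-----------
* Codons are handled internally as DNA triplets (T, not U); reports may
  render them as RNA via :func:`to_rna`.
* The default genetic code is NCBI translation table 11
  (bacterial/archaeal/plant plastid), whose codon->amino-acid map equals
  the standard code; only start-codon sets differ, which are irrelevant
  here.
* Positional GC is computed over every counted codon of the CDS,
  including the terminal stop, mirroring the whole-sequence convention
  of EMBOSS ``cusp``; pass ``include_stop=False`` for the alternative.
* Statistics are carried at full precision; rounding happens only in
  report writers.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from Bio.Data import CodonTable

from .errors import PlastcodonError, UndefinedMetricError

__all__ = [
    "BASES",
    "CODONS",
    "STOP_CODONS",
    "GeneticCode",
    "CodonCounts",
    "GeneMetrics",
    "RscuTable",
    "to_rna",
    "to_dna",
    "count_codons",
    "positional_gc",
    "rscu",
    "enc_observed",
    "enc_expected",
    "enc_ratio",
    "cai",
    "cai_weights",
    "pr2_point",
    "gene_metrics",
]

BASES = "ACGT"
CODONS: Tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP_CODONS: Tuple[str, ...] = ("TAA", "TAG", "TGA")

_STOP_FAMILY = "*"


def to_rna(codon: str) -> str:
    """Render a DNA codon as RNA (T -> U)."""
    return codon.upper().replace("T", "U")


def to_dna(codon: str) -> str:
    """Normalize an RNA or DNA codon to DNA (U -> T)."""
    return codon.upper().replace("U", "T")


# ---------------------------------------------------------------------------
# Genetic code
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneticCode:
    """A codon->amino-acid map with synonymous families and degeneracy classes.

    Families partition the 64 codons: one family per amino acid plus the
    stop family ``"*"`` (TAA/TAG/TGA in the default code). Degeneracy
    class is the family size (1, 2, 3, 4 or 6 in the standard/plastid
    code).
    """

    table_id: int
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, Tuple[str, ...]]

    @classmethod
    def from_ncbi_table(cls, table_id: int = 11) -> "GeneticCode":
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa: Dict[str, str] = {}
        for codon in CODONS:
            if codon in table.stop_codons:
                codon_to_aa[codon] = _STOP_FAMILY
            else:
                codon_to_aa[codon] = table.forward_table[codon]
        families: Dict[str, List[str]] = {}
        for codon, aa in codon_to_aa.items():
            families.setdefault(aa, []).append(codon)
        frozen = {aa: tuple(sorted(cods)) for aa, cods in families.items()}
        return cls(table_id=table_id, codon_to_aa=codon_to_aa, families=frozen)

    def family_of(self, codon: str) -> str:
        return self.codon_to_aa[to_dna(codon)]

    def degeneracy(self, aa: str) -> int:
        return len(self.families[aa])

    @property
    def stop_codons(self) -> Tuple[str, ...]:
        return self.families[_STOP_FAMILY]

    def is_stop(self, codon: str) -> bool:
        return self.codon_to_aa[to_dna(codon)] == _STOP_FAMILY

    def single_codon_families(self) -> Tuple[str, ...]:
        return tuple(aa for aa, fam in self.families.items() if len(fam) == 1)

    def fourfold_families(self) -> Tuple[str, ...]:
        """Strictly fourfold-degenerate amino acids (Val, Pro, Thr, Ala, Gly).

        Excludes the fourfold subsets of the sixfold families (Leu, Ser,
        Arg): PR2 analysis reads "four-codon degenerate amino acid"
        literally.
        """
        return tuple(
            aa
            for aa, fam in sorted(self.families.items())
            if len(fam) == 4 and aa != _STOP_FAMILY
        )


STANDARD_PLASTID_CODE = GeneticCode.from_ncbi_table(11)


# ---------------------------------------------------------------------------
# Codon counting
# ---------------------------------------------------------------------------


@dataclass
class CodonCounts:
    """Counts over the 64 codons for one gene or a pooled gene set."""

    label: str
    counts: Counter = field(default_factory=Counter)

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, codon: str) -> int:
        return self.counts.get(to_dna(codon), 0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = Counter(self.counts)
        merged.update(other.counts)
        return CodonCounts(label=f"{self.label}+{other.label}", counts=merged)

    @classmethod
    def pool(cls, items: Iterable["CodonCounts"], label: str = "pool") -> "CodonCounts":
        merged: Counter = Counter()
        for item in items:
            merged.update(item.counts)
        return cls(label=label, counts=merged)


def _codons_of(cds: str) -> List[str]:
    seq = cds.upper()
    if len(seq) % 3 != 0:
        raise PlastcodonError(
            f"CDS length {len(seq)} is not a multiple of 3"
        )
    return [seq[i : i + 3] for i in range(0, len(seq), 3)]


def count_codons(cds: str, label: str = "") -> CodonCounts:
    """Tally frame-0 codons of a coding sequence.

    Codons containing any base outside A/C/G/T (e.g. N) are skipped, so
    ``total`` reflects only unambiguous codons.
    """
    counts: Counter = Counter()
    for codon in _codons_of(cds):
        if all(b in BASES for b in codon):
            counts[codon] += 1
    return CodonCounts(label=label, counts=counts)


def positional_gc(cds: str, include_stop: bool = True) -> Tuple[float, float, float, float]:
    """GC fraction at codon positions 1, 2, 3 plus GC12 = (GC1+GC2)/2.

    Computed over every unambiguous codon of the sequence; with
    ``include_stop=False`` the terminal stop codon is dropped first.
    """
    codons = _codons_of(cds)
    if not include_stop and codons and codons[-1] in STOP_CODONS:
        codons = codons[:-1]
    codons = [c for c in codons if all(b in BASES for b in c)]
    if not codons:
        raise UndefinedMetricError("no unambiguous codons to compute GC over")
    n = len(codons)
    gc = [0, 0, 0]
    for codon in codons:
        for pos in range(3):
            if codon[pos] in "GC":
                gc[pos] += 1
    gc1, gc2, gc3 = (g / n for g in gc)
    return gc1, gc2, gc3, (gc1 + gc2) / 2.0


# ---------------------------------------------------------------------------
# RSCU
# ---------------------------------------------------------------------------


@dataclass
class RscuTable:
    """Per-codon relative synonymous codon usage.

    ``values[codon]`` = observed count divided by the equal-usage
    expectation within its synonymous family; families with zero total
    get RSCU 0 for every member and are listed in ``absent_families`` so
    downstream logic (e.g. optimal-codon calls) can treat them as
    missing rather than maximally avoided.
    """

    label: str
    values: Dict[str, float]
    absent_families: frozenset

    def __getitem__(self, codon: str) -> float:
        return self.values[to_dna(codon)]


def rscu(counts: CodonCounts, code: GeneticCode = STANDARD_PLASTID_CODE) -> RscuTable:
    """Relative synonymous codon usage for every codon, stop family included."""
    values: Dict[str, float] = {}
    absent: set = set()
    for aa, family in code.families.items():
        family_total = sum(counts[c] for c in family)
        if family_total == 0:
            absent.add(aa)
            for c in family:
                values[c] = 0.0
            continue
        expected = family_total / len(family)
        for c in family:
            values[c] = counts[c] / expected
    return RscuTable(label=counts.label, values=values, absent_families=frozenset(absent))


# ---------------------------------------------------------------------------
# ENC (effective number of codons)
# ---------------------------------------------------------------------------


def enc_observed(counts: CodonCounts, code: GeneticCode = STANDARD_PLASTID_CODE) -> float:
    """Wright's effective number of codons for one gene (or pool).

    Per synonymous family with degeneracy k >= 2 and n >= 2 codons
    counted, the homozygosity estimator is

        F = (n * sum(p_i^2) - 1) / (n - 1)

    with p_i the within-family codon frequencies. Families with F <= 0
    are unusable. Class means F2/F3/F4/F6 average usable families of
    each degeneracy; ENC = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6, capped at 61.
    Missing classes are imputed as in CodonW: F3 <- (F2+F4)/2,
    F6 <- F4. Stop and single-codon families never enter.

    Raises
    ------
    UndefinedMetricError
        If no usable twofold or no usable fourfold family exists, the
        imputations are impossible and ENC is undefined for the gene.
    """
    class_f: Dict[int, List[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, family in code.families.items():
        k = len(family)
        if aa == _STOP_FAMILY or k < 2 or k not in class_f:
            continue
        n = sum(counts[c] for c in family)
        if n < 2:
            continue
        sum_p2 = sum((counts[c] / n) ** 2 for c in family)
        f_hat = (n * sum_p2 - 1.0) / (n - 1.0)
        if f_hat > 0:
            class_f[k].append(f_hat)

    means: Dict[int, float] = {
        k: sum(v) / len(v) for k, v in class_f.items() if v
    }
    if 2 not in means or 4 not in means:
        raise UndefinedMetricError(
            f"ENC undefined for {counts.label!r}: missing usable "
            "twofold or fourfold families"
        )
    if 3 not in means:
        means[3] = (means[2] + means[4]) / 2.0
    if 6 not in means:
        means[6] = means[4]

    enc = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(enc, 61.0)


def enc_expected(gc3: float) -> float:
    """Expected ENC under pure mutation pressure at third-position GC ``gc3``.

    Closed form: ENCexp = 2 + GC3 + 29 / (GC3^2 + (1 - GC3)^2), with
    GC3 on the fraction scale.
    """
    if not 0.0 <= gc3 <= 1.0:
        raise PlastcodonError(f"gc3 must lie in [0, 1], got {gc3}")
    return 2.0 + gc3 + 29.0 / (gc3 ** 2 + (1.0 - gc3) ** 2)


def enc_ratio(enc_exp: float, enc_obs: float) -> float:
    """(ENCexp - ENCobs) / ENCexp; near 0 means mutation-dominated usage."""
    if enc_exp <= 0:
        raise PlastcodonError("enc_exp must be positive")
    return (enc_exp - enc_obs) / enc_exp


# ---------------------------------------------------------------------------
# CAI
# ---------------------------------------------------------------------------


def cai_weights(
    reference: CodonCounts, code: GeneticCode = STANDARD_PLASTID_CODE
) -> Dict[str, float]:
    """Relative adaptiveness w_ij from a reference (highly expressed) set.

    w = RSCU / max RSCU within the synonymous family. Codons unobserved
    in the reference but whose family is present get the conventional
    floor w = 0.01; codons of families absent from the reference are
    omitted (undefined weight, excluded from CAI scoring). Stop and
    single-codon families carry no weight.
    """
    table = rscu(reference, code)
    weights: Dict[str, float] = {}
    for aa, family in code.families.items():
        if aa == _STOP_FAMILY or len(family) < 2 or aa in table.absent_families:
            continue
        max_rscu = max(table.values[c] for c in family)
        for c in family:
            w = table.values[c] / max_rscu
            weights[c] = w if w > 0 else 0.01
    return weights


def cai(
    counts: CodonCounts,
    weights: Mapping[str, float],
    code: GeneticCode = STANDARD_PLASTID_CODE,
) -> float:
    """Codon adaptation index: geometric mean of relative adaptiveness.

    Scored over counted codons excluding stop codons, single-codon
    families (Met, Trp) and codons without a defined weight.
    """
    log_sum = 0.0
    n = 0
    for codon, count in counts.counts.items():
        aa = code.codon_to_aa[codon]
        if aa == _STOP_FAMILY or len(code.families[aa]) < 2:
            continue
        w = weights.get(codon)
        if w is None:
            continue
        log_sum += count * math.log(w)
        n += count
    if n == 0:
        raise UndefinedMetricError(f"CAI undefined for {counts.label!r}: no scorable codons")
    return math.exp(log_sum / n)


# ---------------------------------------------------------------------------
# PR2
# ---------------------------------------------------------------------------


def pr2_point(
    counts: CodonCounts, code: GeneticCode = STANDARD_PLASTID_CODE
) -> Tuple[float, float]:
    """Parity-rule-2 coordinates (x, y) = (G3/(G3+C3), A3/(A3+T3)).

    Third-position base counts are restricted to the five strictly
    fourfold-degenerate families (Val, Pro, Thr, Ala, Gly), where parity
    rule 2 predicts A=T and G=C in the absence of strand-specific
    mutation or selection asymmetry. The centre point is (0.5, 0.5).
    """
    third = Counter()
    for aa in code.fourfold_families():
        for codon in code.families[aa]:
            third[codon[2]] += counts[codon]
    gc_den = third["G"] + third["C"]
    at_den = third["A"] + third["T"]
    if gc_den == 0 or at_den == 0:
        raise UndefinedMetricError(
            f"PR2 undefined for {counts.label!r}: empty third-position pool"
        )
    return third["G"] / gc_den, third["A"] / at_den


def third_position_counts(
    counts: CodonCounts, code: GeneticCode = STANDARD_PLASTID_CODE
) -> Dict[str, int]:
    """A3/T3/G3/C3 counts over the strictly fourfold families."""
    third = Counter()
    for aa in code.fourfold_families():
        for codon in code.families[aa]:
            third[codon[2]] += counts[codon]
    return {b: third[b] for b in BASES}


# ---------------------------------------------------------------------------
# Per-gene metric bundle
# ---------------------------------------------------------------------------


@dataclass
class GeneMetrics:
    """All per-gene statistics behind the bias diagnostics.

    GC values are fractions in [0, 1]; ``enc_obs`` lies in [20, 61] when
    defined (NaN otherwise, with ``enc_defined`` False); ``pr2_x``/
    ``pr2_y`` are NaN when the fourfold third-position pool is empty.
    """

    gene_name: str
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    enc_obs: float
    enc_exp: float
    enc_ratio: float
    cai: float
    a3: int
    t3: int
    g3: int
    c3: int
    pr2_x: float
    pr2_y: float
    category: str = "unknown"
    enc_defined: bool = True
    pr2_defined: bool = True
    cai_defined: bool = True


def gene_metrics(
    gene_name: str,
    cds: str,
    code: GeneticCode = STANDARD_PLASTID_CODE,
    weights: Optional[Mapping[str, float]] = None,
    include_stop: bool = True,
    category: str = "unknown",
) -> GeneMetrics:
    """Compute the full :class:`GeneMetrics` row for one coding sequence.

    Undefined statistics are flagged and reported as NaN rather than
    raising, so table assembly over heterogeneous gene sets is total.
    """
    counts = count_codons(cds, label=gene_name)
    gc1, gc2, gc3, gc12 = positional_gc(cds, include_stop=include_stop)
    exp = enc_expected(gc3)

    enc_defined = True
    try:
        obs = enc_observed(counts, code)
    except UndefinedMetricError:
        obs = float("nan")
        enc_defined = False
    ratio = enc_ratio(exp, obs) if enc_defined else float("nan")

    cai_defined = weights is not None
    cai_value = float("nan")
    if weights is not None:
        try:
            cai_value = cai(counts, weights, code)
        except UndefinedMetricError:
            cai_defined = False

    third = third_position_counts(counts, code)
    pr2_defined = True
    try:
        x, y = pr2_point(counts, code)
    except UndefinedMetricError:
        x = y = float("nan")
        pr2_defined = False

    return GeneMetrics(
        gene_name=gene_name,
        gc1=gc1,
        gc2=gc2,
        gc3=gc3,
        gc12=gc12,
        enc_obs=obs,
        enc_exp=exp,
        enc_ratio=ratio,
        cai=cai_value,
        a3=third["A"],
        t3=third["T"],
        g3=third["G"],
        c3=third["C"],
        pr2_x=x,
        pr2_y=y,
        category=category,
        enc_defined=enc_defined,
        pr2_defined=pr2_defined,
        cai_defined=cai_defined,
    )
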