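"""Optimal-codon determination from ENC-tail expression libraries.

Genes are ranked by observed ENC; the lowest-ENC 10% (strongest bias,
taken as the putative high-expression library) and the highest-ENC 10%
(low-expression library) are pooled, RSCU is computed for each pool,
and ΔRSCU = RSCU_high − RSCU_low. A codon is *high-expression* when
ΔRSCU >= 0.08, *high-frequency* when its whole-set RSCU > 1, and
*optimal* when both hold. Optimal-codon sets from several species can
be intersected to find shared favoured codons.

A "table-reproduction mode" applies the thresholds to values rounded to
2 decimals so results computed from published, rounded RSCU/ΔRSCU
tables are exactly recomputable; the package ships one such reference
table for four Oryza plastomes (see :func:`load_published_rscu_table`).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import pandas as pd

from .codon_metrics import (
    CodonCounts,
    GeneticCode,
    STANDARD_PLASTID_CODE,
    count_codons,
    rscu,
    to_rna,
)
from .errors import PlastcodonError
from .genome_io import CdsSet

__all__ = [
    "ExpressionLibraries",
    "build_expression_libraries",
    "delta_rscu",
    "build_optimal_codon_report",
    "optimal_codon_set",
    "shared_optimal_codons",
    "third_base_composition",
    "load_published_rscu_table",
    "optimal_set_from_published",
]

DELTA_RSCU_THRESHOLD = 0.08
PUBLISHED_SPECIES = ("O_rufipogon", "O_officinalis", "O_granulata", "O_sativa")


@dataclass
class ExpressionLibraries:
    """Gene names of the two ENC tails used as expression proxies.

    ``high`` is the strong-bias (low-ENC) tail, treated as the
    high-expression library; ``low`` the weak-bias (high-ENC) tail.
    Tail size is max(1, floor(fraction * n)) over ENC-defined genes.
    """

    high: List[str]
    low: List[str]
    fraction: float
    tail_size: int


def build_expression_libraries(
    table: pd.DataFrame, fraction: float = 0.10
) -> ExpressionLibraries:
    """Split the gene table into low-/high-ENC tails.

    Ties on ENC break by gene name so the split is deterministic.
    """
    if not 0.0 < fraction < 0.5:
        raise PlastcodonError("fraction must lie in (0, 0.5)")
    defined = table[table["enc_defined"]]
    if len(defined) < 2:
        raise PlastcodonError("need at least 2 genes with defined ENC")
    ranked = defined.sort_values(["enc_obs", "gene_name"])
    tail = max(1, math.floor(fraction * len(ranked)))
    names = list(ranked["gene_name"])
    return ExpressionLibraries(
        high=names[:tail], low=names[-tail:], fraction=fraction, tail_size=tail
    )


def pooled_counts(cds_set: CdsSet, gene_names: Iterable[str], label: str) -> CodonCounts:
    """Sum codon counts over the named genes of a set."""
    return CodonCounts.pool(
        (count_codons(cds_set.sequence_of(name), label=name) for name in gene_names),
        label=label,
    )


def delta_rscu(
    rscu_high: Mapping[str, float], rscu_low: Mapping[str, float]
) -> Dict[str, float]:
    """Elementwise ΔRSCU = RSCU_high − RSCU_low at full precision."""
    return {codon: rscu_high[codon] - rscu_low[codon] for codon in rscu_high}


def build_optimal_codon_report(
    cds_set: CdsSet,
    table: pd.DataFrame,
    code: GeneticCode = STANDARD_PLASTID_CODE,
    fraction: float = 0.10,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
    rounded: bool = False,
) -> pd.DataFrame:
    """Per-codon RSCU/ΔRSCU report with optimal-codon flags for one species.

    Columns: codon (RNA rendering), amino_acid, rscu_all, rscu_high,
    rscu_low, delta_rscu, high_frequency, high_expression, optimal,
    absent. The high-frequency test uses the whole-gene-set RSCU;
    ``rounded=True`` evaluates both thresholds on 2-decimal values
    (table-reproduction mode). Absent families are never optimal.
    """
    libraries = build_expression_libraries(table, fraction=fraction)
    all_counts = pooled_counts(cds_set, cds_set.gene_names(), label="all")
    high_counts = pooled_counts(cds_set, libraries.high, label="high")
    low_counts = pooled_counts(cds_set, libraries.low, label="low")

    rscu_all = rscu(all_counts, code)
    rscu_high = rscu(high_counts, code)
    rscu_low = rscu(low_counts, code)
    delta = delta_rscu(rscu_high.values, rscu_low.values)

    rows = []
    for codon in sorted(rscu_all.values):
        aa = code.codon_to_aa[codon]
        r_all, d = rscu_all.values[codon], delta[codon]
        r_test = round(r_all, 2) if rounded else r_all
        d_test = round(d, 2) if rounded else d
        absent = aa in rscu_all.absent_families
        high_freq = (not absent) and r_test > 1.0
        high_expr = (not absent) and d_test >= delta_threshold
        rows.append(
            {
                "codon": to_rna(codon),
                "amino_acid": aa,
                "rscu_all": r_all,
                "rscu_high": rscu_high.values[codon],
                "rscu_low": rscu_low.values[codon],
                "delta_rscu": d,
                "high_frequency": high_freq,
                "high_expression": high_expr,
                "optimal": high_freq and high_expr,
                "absent": absent,
            }
        )
    report = pd.DataFrame(rows)
    report.attrs["species_label"] = cds_set.species_label
    report.attrs["libraries"] = libraries
    return report


def optimal_codon_set(report: pd.DataFrame) -> Set[str]:
    """The codons flagged optimal in a report (RNA rendering)."""
    return set(report.loc[report["optimal"], "codon"])


def shared_optimal_codons(sets: Sequence[Set[str]]) -> Set[str]:
    """Plain intersection of per-species optimal-codon sets."""
    if not sets:
        raise PlastcodonError("need at least one optimal-codon set")
    shared = set(sets[0])
    for s in sets[1:]:
        shared &= set(s)
    return shared


def third_base_composition(codons: Iterable[str]) -> Dict[str, int]:
    """Counts of third-base endings (A/U/G/C) over a codon collection."""
    comp = Counter(to_rna(c)[2] for c in codons)
    return {b: comp.get(b, 0) for b in "AUGC"}


# ---------------------------------------------------------------------------
# Published reference table (table-reproduction mode input)
# ---------------------------------------------------------------------------


def load_published_rscu_table() -> pd.DataFrame:
    """Published per-codon RSCU and ΔRSCU for four Oryza plastomes.

    Long-format columns: codon (RNA), species (one of
    ``PUBLISHED_SPECIES``), delta_rscu, rscu — values as printed
    (2 decimals), the whole-set RSCU alongside the high/low-library
    ΔRSCU for each species.
    """
    with resources.files("plastcodon.data").joinpath("oryza_rscu_table.tsv").open() as fh:
        wide = pd.read_csv(fh, sep="\t")
    frames = []
    for sp in PUBLISHED_SPECIES:
        frames.append(
            pd.DataFrame(
                {
                    "codon": wide["codon"],
                    "species": sp,
                    "delta_rscu": wide[f"{sp}_delta"],
                    "rscu": wide[f"{sp}_rscu"],
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def optimal_set_from_published(
    table: pd.DataFrame,
    species: str,
    delta_threshold: float = DELTA_RSCU_THRESHOLD,
) -> Set[str]:
    """Optimal codons of one species from a printed RSCU/ΔRSCU table.

    Values in such tables are already rounded to 2 decimals, so the
    thresholds apply to them directly (table-reproduction mode).
    """
    sub = table[table["species"] == species]
    if sub.empty:
        raise PlastcodonError(f"species {species!r} not present in table")
    mask = (sub["delta_rscu"] >= delta_threshold) & (sub["rscu"] > 1.0)
    return set(sub.loc[mask, "codon"])
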