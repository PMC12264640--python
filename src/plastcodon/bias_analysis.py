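"""Per-gene analysis table and the four codon-usage-bias diagnostics.

Assembles the gene-level metrics table (positional GC, observed and
expected ENC, ENC ratio, CAI, PR2 coordinates, functional category) and
derives from it:

1. the Pearson correlation matrix among GC1/GC2/GC3/ENC/CAI,
2. the ENC-plot companion statistics (ENC-ratio histogram with the
   mutation-dominated central band [-0.05, 0.05]),
3. the PR2 quadrant summary, and
4. the neutrality regression of GC12 on GC3.

All fits run on the fraction scale; percent conversion belongs to
report writers. Raw two-sided Pearson p-values with 0.05/0.01
significance tiers, no multiplicity correction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .codon_metrics import (
    CodonCounts,
    GeneticCode,
    STANDARD_PLASTID_CODE,
    cai_weights,
    count_codons,
    enc_observed,
    gene_metrics,
)
from .errors import PlastcodonError, UndefinedMetricError
from .genome_io import CdsSet

__all__ = [
    "CorrelationMatrix",
    "NeutralityFit",
    "EncRatioHistogram",
    "Pr2Summary",
    "gene_metrics_table",
    "species_summary",
    "correlate_metrics",
    "neutrality_fit",
    "enc_ratio_histogram",
    "pr2_summary",
    "classify_gene_function",
    "default_cai_weights",
]

DEFAULT_CORRELATION_METRICS = ("gc1", "gc2", "gc3", "enc_obs", "cai")

_CATEGORY_PREFIXES: List[Tuple[str, str]] = [
    ("psa", "photosynthesis"),
    ("psb", "photosynthesis"),
    ("ndh", "photosynthesis"),
    ("pet", "photosynthesis"),
    ("atp", "photosynthesis"),
    ("rbcl", "photosynthesis"),
    ("rpl", "self-replication"),
    ("rps", "self-replication"),
    ("rpo", "self-replication"),
    ("rrn", "self-replication"),
    ("trn", "self-replication"),
    ("matk", "other"),
    ("clpp", "other"),
    ("cema", "other"),
    ("accd", "other"),
    ("ccsa", "other"),
    ("infa", "other"),
    ("ycf", "unknown"),
    ("lhba", "unknown"),
]


def classify_gene_function(gene_name: str) -> str:
    """Functional category of a plastid gene from its name prefix.

    Categories: photosynthesis (psa/psb/ndh/pet/atp/rbcL),
    self-replication (rpl/rps/rpo/rrn/trn), other
    (matK/clpP/cemA/accD/ccsA/infA), unknown (ycf/lhba and anything
    unrecognized). Matching is case-insensitive on the prefix before
    the locus suffix.
    """
    lowered = gene_name.lower()
    for prefix, category in _CATEGORY_PREFIXES:
        if lowered.startswith(prefix):
            return category
    return "unknown"


def default_cai_weights(
    cds_set: CdsSet,
    code: GeneticCode = STANDARD_PLASTID_CODE,
    fraction: float = 0.10,
) -> Mapping[str, float]:
    """CAI reference weights from the strong-bias (low-ENC) tail.

    The reference set is the pooled codon counts of the lowest-ENC
    ``fraction`` of genes — the same tail used as the high-expression
    library in optimal-codon analysis. Genes with undefined ENC are
    ignored when ranking.
    """
    ranked: List[Tuple[float, str, CodonCounts]] = []
    for name, seq in cds_set.genes:
        counts = count_codons(seq, label=name)
        try:
            ranked.append((enc_observed(counts, code), name, counts))
        except UndefinedMetricError:
            continue
    if not ranked:
        raise PlastcodonError("no gene with defined ENC to build a CAI reference from")
    ranked.sort(key=lambda t: (t[0], t[1]))
    tail = max(1, math.floor(fraction * len(ranked)))
    pooled = CodonCounts.pool((c for _, _, c in ranked[:tail]), label="cai-reference")
    return cai_weights(pooled, code)


def gene_metrics_table(
    cds_set: CdsSet,
    code: GeneticCode = STANDARD_PLASTID_CODE,
    weights: Optional[Mapping[str, float]] = None,
    include_stop: bool = True,
) -> pd.DataFrame:
    """One row of gene-level statistics per gene.

    When no CAI weight table is supplied, weights are derived from the
    low-ENC 10% of this same set. Genes with undefined statistics are
    flagged (``enc_defined``/``pr2_defined``/``cai_defined``) and carry
    NaN; they stay in the table but are excluded from summaries.
    """
    if len(cds_set) == 0:
        raise PlastcodonError("empty CDS set")
    if weights is None:
        weights = default_cai_weights(cds_set, code)
    rows = []
    for name, seq in cds_set.genes:
        gm = gene_metrics(
            name,
            seq,
            code=code,
            weights=weights,
            include_stop=include_stop,
            category=classify_gene_function(name),
        )
        rows.append(vars(gm))
    table = pd.DataFrame(rows)
    table.attrs["species_label"] = cds_set.species_label
    return table


def species_summary(table: pd.DataFrame) -> Dict[str, float]:
    """Species-level means of GC1/GC2/GC3, ENC and CAI over defined genes."""
    enc_ok = table[table["enc_defined"]]
    cai_ok = table[table["cai_defined"]]
    return {
        "n_genes": int(len(table)),
        "gc1": float(table["gc1"].mean()),
        "gc2": float(table["gc2"].mean()),
        "gc3": float(table["gc3"].mean()),
        "enc_obs": float(enc_ok["enc_obs"].mean()) if len(enc_ok) else float("nan"),
        "cai": float(cai_ok["cai"].mean()) if len(cai_ok) else float("nan"),
    }


# ---------------------------------------------------------------------------
# Correlations
# ---------------------------------------------------------------------------


@dataclass
class CorrelationMatrix:
    """Pearson r, two-sided p and significance tiers for metric pairs.

    ``tier`` holds "ns", "0.05" or "0.01" (the finest level passed);
    undefined correlations (a constant metric) are NaN with tier
    "undefined".
    """

    r: pd.DataFrame
    p: pd.DataFrame
    tier: pd.DataFrame


def _tier(p: float) -> str:
    if math.isnan(p):
        return "undefined"
    if p < 0.01:
        return "0.01"
    if p < 0.05:
        return "0.05"
    return "ns"


def correlate_metrics(
    table: pd.DataFrame, metrics: Sequence[str] = DEFAULT_CORRELATION_METRICS
) -> CorrelationMatrix:
    """Pairwise Pearson correlations among per-gene metrics.

    Rows with NaN in either member of a pair are dropped for that pair.
    Requires at least 3 genes; a constant metric yields NaN r for its
    pairs, flagged "undefined".
    """
    if len(table) < 3:
        raise PlastcodonError("correlation analysis needs at least 3 genes")
    k = len(metrics)
    r = np.eye(k)
    p = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[metrics[i], metrics[j]]].dropna()
            x, y = sub[metrics[i]].to_numpy(), sub[metrics[j]].to_numpy()
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rij, pij = float("nan"), float("nan")
            else:
                res = stats.pearsonr(x, y)
                rij, pij = float(res.statistic), float(res.pvalue)
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    index = list(metrics)
    r_df = pd.DataFrame(r, index=index, columns=index)
    p_df = pd.DataFrame(p, index=index, columns=index)
    tier_df = p_df.map(_tier)
    for m in index:
        tier_df.loc[m, m] = "self"
    return CorrelationMatrix(r=r_df, p=p_df, tier=tier_df)


# ---------------------------------------------------------------------------
# Neutrality regression
# ---------------------------------------------------------------------------


@dataclass
class NeutralityFit:
    """OLS of GC12 on GC3 across genes (fraction scale).

    Slope near 1 indicates mutation dominance; slope near 0 indicates
    selection decoupling positions 1-2 from position 3.
    """

    slope: float
    intercept: float
    r: float
    r_squared: float
    p: float
    n: int


def neutrality_fit(table: pd.DataFrame) -> NeutralityFit:
    sub = table[["gc3", "gc12"]].dropna()
    if len(sub) < 3:
        raise PlastcodonError("neutrality fit needs at least 3 genes")
    x, y = sub["gc3"].to_numpy(), sub["gc12"].to_numpy()
    if np.ptp(x) == 0:
        raise UndefinedMetricError("neutrality fit undefined: GC3 has zero variance")
    res = stats.linregress(x, y)
    return NeutralityFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r=float(res.rvalue),
        r_squared=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        n=len(sub),
    )


# ---------------------------------------------------------------------------
# ENC-ratio histogram
# ---------------------------------------------------------------------------


@dataclass
class EncRatioHistogram:
    """Gene counts over ENC-ratio bins around the central band.

    The central band (default [-0.05, 0.05], inclusive on both edges)
    collects mutation-dominated genes; outer bins of width 0.1 aligned
    to the band edges cover the observed range. ``bin_edges[i]``/
    ``bin_edges[i+1]`` delimit ``counts[i]``.
    """

    bin_edges: List[float]
    counts: List[int]
    central_count: int
    central_fraction: float
    n_genes: int


def enc_ratio_histogram(
    table: pd.DataFrame, band: Tuple[float, float] = (-0.05, 0.05), width: float = 0.1
) -> EncRatioHistogram:
    lo, hi = band
    ratios = table["enc_ratio"].dropna().to_numpy()
    n = len(ratios)
    if n == 0:
        return EncRatioHistogram(
            bin_edges=[lo, hi], counts=[0], central_count=0,
            central_fraction=0.0, n_genes=0,
        )
    below = max(0, math.ceil((lo - ratios.min()) / width)) if ratios.min() < lo else 0
    above = max(0, math.ceil((ratios.max() - hi) / width)) if ratios.max() > hi else 0
    edges = (
        [lo - width * m for m in range(below, 0, -1)]
        + [lo, hi]
        + [hi + width * m for m in range(1, above + 1)]
    )
    counts = [0] * (len(edges) - 1)
    central_idx = below
    for r in ratios:
        if lo <= r <= hi:
            counts[central_idx] += 1
        elif r < lo:
            m = math.ceil((lo - r) / width)  # bins (lo-mw, lo-(m-1)w]
            counts[central_idx - m] += 1
        else:
            m = math.ceil((r - hi) / width)
            counts[central_idx + m] += 1
    central = counts[central_idx]
    return EncRatioHistogram(
        bin_edges=[float(e) for e in edges],
        counts=counts,
        central_count=central,
        central_fraction=central / n,
        n_genes=n,
    )


# ---------------------------------------------------------------------------
# PR2 quadrants
# ---------------------------------------------------------------------------


@dataclass
class Pr2Summary:
    """Gene counts per PR2 quadrant plus genes with undefined coordinates.

    Quadrants around the parity centre (0.5, 0.5): I x>0.5,y>0.5;
    II x<0.5,y>0.5; III x<0.5,y<0.5; IV x>0.5,y<0.5. Points on a
    boundary go to the bordering quadrant with the lowest numeral
    (deterministic tie-break).
    """

    quadrants: Dict[str, int]
    undefined: int

    @property
    def n_genes(self) -> int:
        return sum(self.quadrants.values()) + self.undefined


def _pr2_quadrant(x: float, y: float) -> str:
    candidates = []
    if x >= 0.5 and y >= 0.5:
        candidates.append(1)
    if x <= 0.5 and y >= 0.5:
        candidates.append(2)
    if x <= 0.5 and y <= 0.5:
        candidates.append(3)
    if x >= 0.5 and y <= 0.5:
        candidates.append(4)
    return {1: "I", 2: "II", 3: "III", 4: "IV"}[min(candidates)]


def pr2_summary(table: pd.DataFrame) -> Pr2Summary:
    quadrants = {"I": 0, "II": 0, "III": 0, "IV": 0}
    undefined = 0
    for _, row in table.iterrows():
        x, y = row["pr2_x"], row["pr2_y"]
        if math.isnan(x) or math.isnan(y):
            undefined += 1
        else:
            quadrants[_pr2_quadrant(x, y)] += 1
    return Pr2Summary(quadrants=quadrants, undefined=undefined)
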