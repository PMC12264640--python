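# Methods

This note documents the models, estimators, conventions and design
choices behind `plastcodon`, in the order the pipeline runs.

## Genome model and quadripartite detection

A genome record is a circular (or linear) A/C/G/T/N sequence with
annotated features; feature locations are lists of 0-based half-open
exon intervals stored in splice order, so extraction concatenates each
interval (reverse-complemented when its strand is `-`). User-facing
reports convert to 1-based inclusive coordinates, the GenBank
convention.

The quadripartite detector searches for the maximal-length pair of
disjoint **exact** inverted repeats on the circular sequence. Seeds are
25-mers whose reverse complement occurs elsewhere; each seed is
extended to maximality in both directions. Along one repeat the sum
(start of copy A) + (end of copy B) is invariant, so after one maximal
extension the whole anti-diagonal is marked covered, making the scan
effectively linear for plastome-scale inputs (a 135 kb genome with
20 kb IRs takes well under a second). Exactness is the default because
assembled plastome IR copies are identical in practice; the
`max_mismatch` parameter is reserved (only 0 is implemented). Ties on
repeat length break to the smallest start coordinate; the longer
single-copy gap is labelled LSC. Absence of any repeat ≥ `min_ir_len`
(default 1000 bp, minimum 100) returns `None` — a valid outcome for
non-plastome input, which report writers render as an `NA` row.

Region GC is (G+C)/(A+C+G+T) per region, with N excluded from the
denominator; values are carried at full precision and rounded to two
decimals only in reports.

## CDS extraction filters

A CDS is retained iff, after removing codons containing N: length
≥ 300 nt and a multiple of 3, ATG start, TAA/TAG/TGA stop, no internal
stop under the plastid/bacterial code (NCBI table 11). A CDS losing
more than 5% of its codons to ambiguity is discarded entirely —
dropping a few codons leaves the statistics unbiased, while heavy
ambiguity suggests an unreliable sequence. IR-duplicated genes
(identical name and sequence) keep one copy so pooled counts are not
double-weighted; same-named genes with different sequences are kept
under suffixed names. Trans-spliced genes are assembled per annotated
location and silently excluded if the assembly fails the filters.

## Codon statistics

**Positional GC** is computed over every unambiguous codon including
the terminal stop (the whole-sequence convention of EMBOSS `cusp`);
`include_stop=False` flips to the alternative. GC12 is the arithmetic
mean of GC1 and GC2.

**RSCU** follows the family-normalized definition with the stop
triplet treated as a 3-codon family. A family with zero total yields
RSCU 0 for all members plus an `absent` flag, so downstream ΔRSCU
arithmetic is total while absent families can never be called optimal.

**Observed ENC** is the Wright-style estimator as implemented by
CodonW: per family of degeneracy k ≥ 2 with n ≥ 2 counted codons,
F̂ = (nΣp̂² − 1)/(n − 1); families with F̂ ≤ 0 are unusable; class
means F̄₂, F̄₃, F̄₄, F̄₆ average usable families;
ENC = 2 + 9/F̄₂ + 1/F̄₃ + 5/F̄₄ + 3/F̄₆, capped at 61. A missing
threefold class is imputed as (F̄₂ + F̄₄)/2 and a missing sixfold
class as F̄₄. Without a usable twofold or fourfold family, ENC is
undefined: the gene stays in the table, flagged, excluded from
summaries and tail libraries. Stop and single-codon families never
enter. F̂ ≤ 1 always, so ENC ≥ 20 by construction; the cap at 61
handles finite-sample F̂ < 1/k.

**Expected ENC** is the closed form 2 + GC3 + 29/(GC3² + (1−GC3)²)
on the fraction scale, and the **ENC ratio** is
(ENCexp − ENCobs)/ENCexp (negative values allowed). The closed form is
a smooth approximation to the class-structured estimator, so even
idealized mutation-pressure genes sit within about one ENC unit of the
curve rather than exactly on it (see *Synthetic data* below).

**CAI** is the geometric mean of relative adaptiveness
w = RSCU/RSCU_max over counted codons, excluding stops, the
single-codon families (Met, Trp), and codons without a defined weight.
The default reference set is the pooled counts of the species' own
low-ENC 10% tail — the same strong-bias library used for optimal-codon
analysis — because no external reference is universally appropriate
for plastomes; an explicit weight table can be supplied instead.
Codons unobserved in a present reference family receive the
conventional floor w = 0.01; absent families carry no weight. CAI
values are therefore comparable within a species but depend on the
reference choice, and cross-study CAI magnitudes should not be
compared without fixing the reference.

**PR2** coordinates are restricted to the five strictly fourfold
families (Val, Pro, Thr, Ala, Gly) — the fourfold subsets of Leu, Ser
and Arg are excluded because their third-position composition is
confounded with first-position usage. Zero denominators mark the gene
undefined for PR2.

## Diagnostics

Correlations are raw two-sided Pearson tests among GC1/GC2/GC3/ENC/CAI
with 0.05/0.01 significance tiers and no multiplicity correction,
matching the star conventions of published correlation figures. The
neutrality fit is an ordinary least-squares regression of GC12 on GC3
on the fraction scale. The ENC-ratio histogram centres an inclusive
band [−0.05, 0.05] with outer bins of width 0.1 aligned to the band
edges. PR2 quadrants are numbered I (x>0.5, y>0.5), II, III, IV
counter-clockwise; boundary points go deterministically to the
bordering quadrant with the lowest numeral. Functional categories come
from a built-in case-insensitive prefix map (psa/psb/ndh/pet/atp/rbcL →
photosynthesis; rpl/rps/rpo/rrn/trn → self-replication;
matK/clpP/cemA/accD/ccsA/infA → other; ycf/lhba and anything
unrecognized → unknown).

## Optimal codons

Tail size is max(1, ⌊fraction·n⌋) with fraction 0.10 by default; ties
on ENC break by gene name. The low-ENC tail is the putative
high-expression library (stronger bias under translational selection).
A codon is optimal when ΔRSCU ≥ 0.08 (inclusive) and its
whole-gene-set RSCU exceeds 1; both thresholds are evaluated at full
precision by default, or on 2-decimal rounded values in
table-reproduction mode, which makes results computed from published
rounded tables exactly recomputable. The bundled reference table for
four *Oryza* plastomes reproduces a 14-codon shared optimal set under
this mode; note that recounting the per-species columns of such
rounded tables can disagree with per-species totals quoted alongside
them — the intersection is robust, the per-species counts are not.

ΔRSCU between two 10%-tail pools is a noisy statistic: for a 50-gene
species each pool holds ~5 genes, and an unselected twofold family
contributes only tens of codons per pool, giving ΔRSCU a standard
deviation around 0.2. Occasional false admissions from unselected
families are therefore expected from the method itself, which is why
shared sets across species are more trustworthy than any single
species' list.

## Synthetic data

The generator emulates the statistical structure the diagnostics are
designed to detect, not real plastome sequences.

* **Mutation regime** — amino acids are drawn from a fixed plastid-like
  usage profile; within each synonymous family the third base is G/C
  with probability g and A/T otherwise (uniform within each subset).
  Because Met, Trp and the ATG start always carry G at position 3, the
  internal rate g is calibrated as g = (target − f)/(1 − f), with f
  the profile mass on fixed-G families, so the realized whole-gene GC3
  tracks the requested target; targets below f (~0.04) are unreachable
  under the code and rejected. Genes then fall near the ENCexp curve:
  at GC3 = 0.30 with 200 genes of 150–450 codons, the mean signed
  deviation of ENCobs from ENCexp is ≈ −0.9 ENC units (the intrinsic
  offset between the closed-form curve and the class-structured
  estimator), while the mean absolute deviation is ≈ 2.0, dominated by
  Wright-estimator sampling noise on rare twofold families (Cys occurs
  ~3 times in a 300-codon gene).
* **Selection regime** — synonymous choice mixes a uniform baseline
  with a point mass on the planted preferred codon of each family; the
  mixing weight ramps linearly from 0 to s across genes, so strongly
  selected genes populate the low-ENC tail, emulating
  expression-correlated selection and decoupling ENC from GC3. The
  **mixed** regime uses the mutation baseline instead of uniform.
* **Genomes** — LSC + IRb + SSC + IRa with IRa the exact reverse
  complement of IRb, per-region GC targets, and valid planted CDSs
  (IR genes annotated in both copies, minus-strand in the second).
  Single-copy edge bases are adjusted so chance matches can never
  extend the repeat past its planted bounds, making round-trip
  detection exact.

Randomness derives from one root seed; per-gene child seeds are
deterministic and recorded in the returned ground truth, so identical
specs reproduce byte-identical outputs.

What passing synthetic tests do **not** show: real plastomes have
heterogeneous amino-acid usage across genes, length-dependent
composition, context effects (dinucleotide and codon-pair bias), and
IR copies that may differ at a handful of positions; the generator
models none of these. Accession-level validation against a deposited
*Oryza sativa* plastome record is wired into the test suite but needs
the record supplied locally.

## Default problem sizes

Tests and the acceptance script run at desk scale: simulated sets of
50–200 genes of 150–450 codons, genomes of 15–132 kb, 100-instance
oracle sweeps. These sizes are large enough for every statistical
check's stated margin while keeping a full run in seconds.

## Known limitations

* Only exact IR pairs are detected; a plastome with diverged IR copies
  (rare) yields truncated IR calls or `None`.
* CAI depends on the reference-set choice (see above); no attempt is
  made to reproduce any particular published CAI magnitude.
* The ENCexp closed form and the class-structured estimator differ by
  up to ~1 ENC unit even under pure mutation pressure; ENC-ratio bands
  should be read with that offset in mind.
* No correspondence analysis, codon-pair or tRNA-adaptation metrics.
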