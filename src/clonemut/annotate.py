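"""Genic-feature annotation, gene length/expression association, strand bias.

Feature precedence when intervals overlap: exonic (with UTR refined before
generic exonic) > intronic > upstream/downstream (1 kb flanks) > intergenic.
Every position receives exactly one class.

Transcription strand convention: the coding (untranscribed) strand of a
gene is the strand carrying the mRNA sequence; the template (transcribed)
strand is its complement.  After pyrimidine collapse, a mutation whose
pyrimidine lies on the coding strand is assigned to the untranscribed
strand.  Strand bias per six-type is the exact conditional binomial test of
the two strand counts under equal Poisson rates (Binomial(n_u + n_t, 1/2)).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .filtering import CallSet, VariantCall
from .genome import GeneModel, GenomeModel

FEATURE_CLASSES = (
    "exonic",
    "utr5",
    "utr3",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
SIX_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

UNTRANSCRIBED = "untranscribed"
TRANSCRIBED = "transcribed"
AMBIGUOUS = "ambiguous"
NONE = "none"


@dataclass(frozen=True)
class FeatureCall:
    call: VariantCall
    feature: str
    gene_id: str | None
    strand_relation: str  # transcribed / untranscribed / ambiguous / none

    def __post_init__(self) -> None:
        if (self.gene_id is None) != (self.feature == "intergenic"):
            raise ValueError("gene id present iff feature is genic")


class GeneIndex:
    """Sorted per-chromosome gene lookup over gene-body + flank intervals."""

    def __init__(self, genes: list[GeneModel]):
        self.by_chrom: dict[str, list[GeneModel]] = {}
        for g in genes:
            self.by_chrom.setdefault(g.chrom, []).append(g)
        self._starts: dict[str, list[int]] = {}
        for chrom, gs in self.by_chrom.items():
            gs.sort(key=lambda g: g.start)
            self._starts[chrom] = [g.start - g.flank for g in gs]

    def overlapping(self, chrom: str, pos: int) -> list[GeneModel]:
        """Genes whose flank-extended span contains pos."""
        gs = self.by_chrom.get(chrom, [])
        if not gs:
            return []
        i = bisect.bisect_right(self._starts[chrom], pos)
        hits = []
        # genes are near-sorted by end as well; scan a bounded window back
        for g in gs[max(0, i - 50) : i]:
            if g.start - g.flank <= pos <= g.end + g.flank:
                hits.append(g)
        return hits


def _classify_within(gene: GeneModel, pos: int) -> str:
    if gene.start <= pos <= gene.end:
        for s, e in gene.utr5:
            if s <= pos <= e:
                return "utr5"
        for s, e in gene.utr3:
            if s <= pos <= e:
                return "utr3"
        for s, e in gene.exons:
            if s <= pos <= e:
                return "exonic"
        return "intronic"
    if pos < gene.start:
        return "upstream" if gene.strand == "+" else "downstream"
    return "downstream" if gene.strand == "+" else "upstream"


_PRECEDENCE = {
    "exonic": 0,
    "utr5": 1,
    "utr3": 1,
    "intronic": 2,
    "upstream": 3,
    "downstream": 3,
}


def annotate_feature(
    call: VariantCall,
    index: GeneIndex,
    genome: GenomeModel | None = None,
) -> FeatureCall:
    """Locate a call in the genic-feature hierarchy."""
    if genome is not None and call.chrom not in genome:
        raise ValueError(f"unknown chromosome {call.chrom}")
    hits = index.overlapping(call.chrom, call.pos)
    if not hits:
        return FeatureCall(call, "intergenic", None, NONE)
    best: tuple[int, str, GeneModel] | None = None
    for g in hits:
        feat = _classify_within(g, call.pos)
        rank = _PRECEDENCE[feat]
        if best is None or rank < best[0]:
            best = (rank, feat, g)
    _, feature, gene = best
    strand_rel = NONE
    if call.var_class == "SNV" and gene.start <= call.pos <= gene.end:
        strand_rel = strand_of_mutation(call, [g for g in hits if g.start <= call.pos <= g.end])
    return FeatureCall(call, feature, gene.gene_id, strand_rel)


def annotate_calls(
    calls: CallSet, genes: list[GeneModel], genome: GenomeModel | None = None
) -> list[FeatureCall]:
    index = GeneIndex(genes)
    return [annotate_feature(c, index, genome) for c in calls]


def feature_fractions(annotated: list[FeatureCall]) -> dict[str, float]:
    """Proportion of calls per feature class (sums to 1)."""
    if not annotated:
        raise ValueError("no annotated calls")
    counts = {f: 0 for f in FEATURE_CLASSES}
    for fc in annotated:
        counts[fc.feature] += 1
    n = len(annotated)
    return {f: counts[f] / n for f in FEATURE_CLASSES}


def _mw_effect(values_hit: np.ndarray, values_all: np.ndarray) -> tuple[float, float]:
    if len(values_hit) < 3 or len(values_all) < 3:
        raise ValueError("need n >= 3 on each side")
    res = stats.mannwhitneyu(values_hit, values_all, alternative="two-sided")
    pooled_sd = float(np.std(np.concatenate([values_hit, values_all]), ddof=1))
    effect = (
        abs(float(np.mean(values_hit)) - float(np.mean(values_all))) / pooled_sd
        if pooled_sd > 0
        else 0.0
    )
    return float(res.pvalue), effect


def compare_gene_length(
    genes_hit: list[GeneModel], all_genes: list[GeneModel]
) -> tuple[float, float]:
    """Mann-Whitney p and effect size (|mean diff| / pooled SD) on log10
    gene length, mutated genes vs the full gene universe."""
    if not genes_hit:
        raise ValueError("empty hit set")
    return _mw_effect(
        np.log10([g.length for g in genes_hit]),
        np.log10([g.length for g in all_genes]),
    )


def compare_expression(
    genes_hit: list[GeneModel],
    all_genes: list[GeneModel],
    expression: dict[str, float],
) -> tuple[float, float]:
    """As :func:`compare_gene_length` on log10 FPKM; zero-FPKM genes are
    excluded from both sides (log undefined / not expressed)."""
    if not genes_hit:
        raise ValueError("empty hit set")
    hit = [expression[g.gene_id] for g in genes_hit if expression.get(g.gene_id, 0) > 0]
    uni = [expression[g.gene_id] for g in all_genes if expression.get(g.gene_id, 0) > 0]
    return _mw_effect(np.log10(hit), np.log10(uni))


def strand_of_mutation(call: VariantCall, genes_at_pos: list[GeneModel]) -> str:
    """Strand relation of an SNV within one or more gene bodies.

    The collapsed representation places the pyrimidine of the mutated pair
    on the reference strand iff ref is C or T.  For a +-strand gene the
    coding strand is the reference strand, so a pyrimidine ref means the
    substitution sits on the untranscribed (coding) strand; for a --strand
    gene the roles swap.  Overlapping genes on both strands give
    'ambiguous'.
    """
    if call.var_class != "SNV":
        raise ValueError("strand assignment applies to SNVs only")
    if not genes_at_pos:
        return NONE
    strands = {g.strand for g in genes_at_pos}
    if len(strands) > 1:
        return AMBIGUOUS
    gene_strand = strands.pop()
    pyr_on_reference = call.ref.upper() in "CT"
    pyr_on_coding = pyr_on_reference == (gene_strand == "+")
    return UNTRANSCRIBED if pyr_on_coding else TRANSCRIBED


@dataclass
class StrandBiasResult:
    counts: dict[str, tuple[int, int]]  # six-type -> (untranscribed, transcribed)
    p_values: dict[str, float | None]
    n_ambiguous: int
    bonferroni: bool = False


def strand_bias_counts(annotated: list[FeatureCall]) -> tuple[dict[str, tuple[int, int]], int]:
    from .spectra import collapse_substitution

    counts = {t: [0, 0] for t in SIX_TYPES}
    ambiguous = 0
    for fc in annotated:
        if fc.strand_relation in (NONE,):
            continue
        if fc.strand_relation == AMBIGUOUS:
            ambiguous += 1
            continue
        six, _, _ = collapse_substitution(fc.call.ref, fc.call.alt)
        if fc.strand_relation == UNTRANSCRIBED:
            counts[six][0] += 1
        else:
            counts[six][1] += 1
    return {t: (c[0], c[1]) for t, c in counts.items()}, ambiguous


def strand_bias_test(
    counts: dict[str, tuple[int, int]],
    n_ambiguous: int = 0,
    bonferroni: bool = False,
) -> StrandBiasResult:
    """Exact two-sided test per six-type of untranscribed vs transcribed
    counts under equal Poisson rates, via the conditional Binomial(n, 1/2).

    No multiple-testing correction by default; Bonferroni across the six
    types is available as an option.
    """
    p_values: dict[str, float | None] = {}
    for t, (n_u, n_t) in counts.items():
        n = n_u + n_t
        if n == 0:
            p_values[t] = None
            continue
        p = stats.binomtest(n_u, n, 0.5, alternative="two-sided").pvalue
        if bonferroni:
            p = min(1.0, p * len(counts))
        p_values[t] = float(p)
    return StrandBiasResult(dict(counts), p_values, n_ambiguous, bonferroni)
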