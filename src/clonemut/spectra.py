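"""Substitution spectra, 96-context signatures, and INDEL statistics.

Complementary substitutions are collapsed so the reported reference base is
a pyrimidine (G>T on the reference strand is counted as C>A, with the
flanking context reverse-complemented).  The 96-context index follows the
widespread alphabetical convention — substitution blocks C>A, C>G, C>T,
T>A, T>C, T>G, flanks ordered A, C, G, T — so vectors line up with
published signature catalogs supplied in the same layout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .filtering import CallSet, VariantCall
from .genome import BASES, GenomeModel

SIX_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: canonical 96-context labels, e.g. "A[C>A]A"
CONTEXT96_LABELS = tuple(
    f"{f5}[{sub}]{f3}" for sub in SIX_TYPES for f5 in BASES for f3 in BASES
)
_CONTEXT96_INDEX = {lab: i for i, lab in enumerate(CONTEXT96_LABELS)}


def collapse_substitution(
    ref: str, alt: str, ctx5: str = "", ctx3: str = ""
) -> tuple[str, str, str]:
    """Pyrimidine-collapsed (six-type, 5' base, 3' base).

    Purine-reference substitutions are mapped to the opposite strand: ref,
    alt and both flanks are complemented and the flank order is swapped.
    """
    ref, alt = ref.upper(), alt.upper()
    if len(ref) != 1 or len(alt) != 1 or ref == alt:
        raise ValueError(f"not a substitution: {ref}>{alt}")
    if ref not in "ACGT" or alt not in "ACGT":
        raise ValueError(f"ambiguous base in {ref}>{alt}")
    if ref in "AG":
        ref, alt = _COMP[ref], _COMP[alt]
        ctx5, ctx3 = (
            _COMP.get(ctx3.upper(), "") if ctx3 else "",
            _COMP.get(ctx5.upper(), "") if ctx5 else "",
        )
    else:
        ctx5, ctx3 = ctx5.upper(), ctx3.upper()
    return f"{ref}>{alt}", ctx5, ctx3


@dataclass
class SpectrumProfile:
    """Six-type substitution counts with the C>T class split by CpG status."""

    counts: dict[str, int]
    cpg_split: dict[str, int]  # {'CpG': ..., 'other': ..., 'unknown': ...}
    n_excluded: int  # ambiguous base or non-SNV

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def proportions(self) -> dict[str, float]:
        t = self.total
        return {k: (v / t if t else 0.0) for k, v in self.counts.items()}


def _call_context(call: VariantCall, genome: GenomeModel | None) -> tuple[str, str, bool]:
    """Flanking bases for a call: actual sequence when available, otherwise
    the generator-assigned flanks carried on the call."""
    if genome is not None and call.chrom in genome:
        ctx = genome.context_at(call.chrom, call.pos)
        if ctx is not None:
            return ctx[0], ctx[1], True
    return call.ctx5, call.ctx3, call.context_real


def spectrum6(calls: CallSet, genome: GenomeModel | None = None) -> SpectrumProfile:
    """Six-type spectrum over SNV calls.

    Calls without sequence-derived context still contribute to the six-type
    counts (type is determined by ref/alt alone); the CpG split of C>T uses
    the 3' base where known and counts the rest as 'unknown'.
    """
    counts = {t: 0 for t in SIX_TYPES}
    cpg = {"CpG": 0, "other": 0, "unknown": 0}
    excluded = 0
    for call in calls:
        if call.var_class != "SNV":
            excluded += 1
            continue
        c5, c3, _ = _call_context(call, genome)
        try:
            six, _, c3p = collapse_substitution(call.ref, call.alt, c5, c3)
        except ValueError:
            excluded += 1
            continue
        counts[six] += 1
        if six == "C>T":
            if not c3p:
                cpg["unknown"] += 1
            elif c3p == "G":
                cpg["CpG"] += 1
            else:
                cpg["other"] += 1
    return SpectrumProfile(counts, cpg, excluded)


@dataclass
class SignatureVector:
    """96-dimension trinucleotide-context profile."""

    counts: np.ndarray  # length 96, canonical order
    n_excluded: int  # calls without sequence-derived context

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=float)
        if self.counts.shape != (96,):
            raise ValueError("signature vector must have 96 entries")

    @property
    def proportions(self) -> np.ndarray:
        t = self.counts.sum()
        return self.counts / t if t else self.counts

    def marginal_six_type(self) -> dict[str, float]:
        return {
            sub: float(self.counts[16 * i : 16 * (i + 1)].sum())
            for i, sub in enumerate(SIX_TYPES)
        }

    def to_series(self) -> pd.Series:
        return pd.Series(self.counts, index=list(CONTEXT96_LABELS))


def context96(calls: CallSet, genome: GenomeModel | None = None) -> SignatureVector:
    """96-context signature over SNV calls with real sequence context.

    Calls whose flanks are not derived from actual sequence (virtual
    chromosomes, chromosome edges) are excluded and counted.
    """
    counts = np.zeros(96)
    excluded = 0
    for call in calls:
        if call.var_class != "SNV":
            excluded += 1
            continue
        c5, c3, real = _call_context(call, genome)
        if not real or not c5 or not c3:
            excluded += 1
            continue
        try:
            six, c5p, c3p = collapse_substitution(call.ref, call.alt, c5, c3)
        except ValueError:
            excluded += 1
            continue
        counts[_CONTEXT96_INDEX[f"{c5p}[{six}]{c3p}"]] += 1
    return SignatureVector(counts, excluded)


def cosine_similarity(v: np.ndarray, w: np.ndarray) -> float:
    """Cosine similarity between two non-negative profile vectors."""
    v = np.asarray(v, dtype=float)
    w = np.asarray(w, dtype=float)
    if v.shape != w.shape:
        raise ValueError("vectors differ in length")
    nv, nw = np.linalg.norm(v), np.linalg.norm(w)
    if nv == 0 or nw == 0:
        raise ValueError("cosine similarity undefined for zero vector")
    return float(np.dot(v, w) / (nv * nw))


def write_signature(sig: SignatureVector, path: str) -> None:
    sig.to_series().rename("count").rename_axis("context").reset_index().to_csv(
        path, sep="\t", index=False
    )


def read_signature(path: str) -> SignatureVector:
    df = pd.read_csv(path, sep="\t")
    values = df.set_index("context").iloc[:, 0]
    missing = set(CONTEXT96_LABELS) - set(values.index)
    if missing:
        raise ValueError(f"signature file missing contexts, e.g. {sorted(missing)[:3]}")
    return SignatureVector(values.loc[list(CONTEXT96_LABELS)].to_numpy(), 0)


@dataclass
class IndelStats:
    length_histogram: dict[int, int]  # signed lengths, insertions > 0
    n_insertions: int
    n_deletions: int

    @property
    def ins_del_ratio(self) -> float | None:
        if self.n_deletions == 0:
            return None
        return self.n_insertions / self.n_deletions


def indel_stats(calls: CallSet) -> IndelStats:
    """Signed length histogram and insertion:deletion count ratio."""
    hist: dict[int, int] = {}
    n_ins = n_del = 0
    for call in calls:
        if call.var_class == "INS":
            n_ins += 1
        elif call.var_class == "DEL":
            n_del += 1
        else:
            continue
        sl = call.indel_length
        hist[sl] = hist.get(sl, 0) + 1
    return IndelStats(dict(sorted(hist.items())), n_ins, n_del)


def per_chromosome_density(
    calls: CallSet, genome: GenomeModel, min_length: int = 10_000_000
) -> pd.Series:
    """SNV count per autosome normalized per 100 Mbp.

    Chromosomes shorter than ``min_length`` are excluded: on a scaffold far
    smaller than the rest, the normalized density is almost always zero with
    occasional huge spikes, which distorts the chromosome-level comparison
    (the enrichment test assumes comparably distributed groups).
    """
    autosomes = [
        c for c in genome.chromosomes if c.autosome and c.length >= min_length
    ]
    if not autosomes:
        raise ValueError("no autosome meets min_length; lower min_length")
    counts = {c.name: 0 for c in autosomes}
    for call in calls:
        if call.var_class == "SNV" and call.chrom in counts:
            counts[call.chrom] += 1
    return pd.Series(
        {c.name: counts[c.name] / c.length * 1e8 for c in autosomes}, name="snv_per_100mbp"
    )


def test_chromosome_enrichment(densities: list[pd.Series]) -> dict:
    """Kruskal-Wallis test of per-chromosome densities across subclones.

    Each chromosome is one group; the per-subclone normalized densities are
    its replicates.  Refuses a single subclone (no replication).
    """
    if len(densities) < 2:
        raise ValueError("chromosome enrichment test needs >= 2 subclones")
    table = pd.DataFrame(densities)
    groups = [table[c].to_numpy() for c in table.columns]
    stat, p = stats.kruskal(*groups)
    return {"statistic": float(stat), "p_value": float(p), "n_chromosomes": len(groups)}
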