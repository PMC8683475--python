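"""Clonal-culture simulator with known truth.

Emulates the statistical structure of the experiment the pipeline analyzes:
a single cell is expanded for D population doublings (the parental clone),
a subclone is then re-derived from a single cell and expanded again, and
parent vs subclone whole-genome calls are compared.

* Mutations acquired along the parental lineage are present in every
  subclone cell: allele frequency 0.5 (heterozygous) or 1.0 (homozygous).
* Mutations acquired at generation g of the subclonal expansion subtend a
  cell fraction of 2^-g, hence allele frequencies 0.25, 0.125, ...
* A small fraction c of sequencing reads comes from contaminating feeder
  cells; feeder-specific variants appear at allele frequencies <= c, and
  cell-derived allele frequencies shrink by (1 - c).
* Read support is binomial at Poisson-distributed depth, and a synthetic
  caller quality score grows with the alt read count, so depth, quality,
  blacklist and AF-trim filtering are all exercisable downstream.

Population doublings stand in for cell-division numbers: one doubling of
the culture is counted as one division along any single-cell lineage, so a
per-base per-doubling rate r yields Poisson(r * 2L * D) heterozygous
parental-phase mutations over a diploid genome of haploid length L.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import CoverageTrack, simulate_coverage
from .filtering import DEL, INS, SNV, CallSet, VariantCall
from .genome import BASES, GenomeModel, PolymorphismBlacklist, revcomp

SIX_TYPES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: six-type probabilities emulating the reported spermatogonial (GS) spectrum:
#: C>T dominant (63%), then C>A (17%)
GS_SPECTRUM = {"C>A": 0.17, "C>G": 0.04, "C>T": 0.63, "T>A": 0.03, "T>C": 0.08, "T>G": 0.05}
#: and the multipotent (mGS) spectrum: C>A dominant (66%), then C>T (20%)
MGS_SPECTRUM = {"C>A": 0.66, "C>G": 0.04, "C>T": 0.20, "T>A": 0.03, "T>C": 0.04, "T>G": 0.03}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class ClonalDesign:
    """Experimental design constants of one clonal comparison."""

    doublings: int = 100  # D, parental expansion
    subclone_doublings: int = 10  # generations modeled for low-AF mutations
    tau: float = 0.3  # downstream AF trim threshold
    min_depth: int = 10
    mean_depth: float = 30.0
    coverage_bin_size: int = 100_000

    def __post_init__(self) -> None:
        if self.doublings < 1:
            raise ValueError("doublings must be >= 1")
        if not 0.0 < self.tau < 0.5:
            raise ValueError("tau must be in (0, 0.5)")
        if self.mean_depth <= self.min_depth:
            raise ValueError("mean_depth must exceed min_depth")


@dataclass
class SimulationParams:
    """Truth parameters of the generator."""

    snv_rate: float = 0.22e-9  # per base per population doubling
    indel_rate: float = 0.024e-9
    six_type_probs: dict[str, float] = field(default_factory=lambda: dict(GS_SPECTRUM))
    ins_del_ratio: float = 0.84  # insertion : deletion count ratio
    indel_length_geom_p: float = 0.6
    contamination: float = 0.005  # fraction of reads from feeder cells
    hom_fraction: float = 0.0  # fraction of parental mutations at AF 1.0
    n_contaminant_sites: int = 2000  # feeder-private + feeder-polymorphic sites
    contaminant_blacklist_fraction: float = 0.5
    contaminant_hom_fraction: float = 0.2
    min_alt_reads: int = 2  # caller emits a candidate only with this support
    gc_fraction: float = 0.42  # flank-base composition on virtual chromosomes
    #: probability that a C>T event inside a gene body sits on the
    #: untranscribed (coding) strand; 0.5 = strand-symmetric.  Only
    #: realizable on virtual chromosomes, where the reference strand of the
    #: emitted substitution is not pinned by actual sequence.
    ct_untranscribed_bias: float = 0.5

    def __post_init__(self) -> None:
        total = sum(self.six_type_probs.get(t, 0.0) for t in SIX_TYPES)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"six-type probabilities sum to {total}, not 1")
        if not 0.0 <= self.contamination < 0.05:
            raise ValueError("contamination must be in [0, 0.05)")

    @property
    def type_vector(self) -> np.ndarray:
        return np.array([self.six_type_probs[t] for t in SIX_TYPES])


@dataclass
class MutationEvent:
    """One truth event, before read sampling."""

    chrom: str
    pos: int
    ref: str
    alt: str
    var_class: str
    phase: str  # 'parental' | 'subclonal-g<g>' | 'contaminant'
    cell_fraction: float
    true_af: float  # allele frequency in the sequenced cell population
    ctx5: str = ""
    ctx3: str = ""
    context_real: bool = False

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class SimulatedExperiment:
    """Truth and observed output for one parent/subclone comparison."""

    subclone: str
    truth: list[MutationEvent]
    calls: CallSet
    parent_coverage: CoverageTrack
    subclone_coverage: CoverageTrack
    design: ClonalDesign
    params: SimulationParams


def caller_quality(alt_reads: int) -> float:
    """Synthetic caller quality, monotone in alt-read support.

    Scaled so that the default thresholds (19 for SNVs, 14 for INDELs)
    retain calls with ~7+ / ~5+ supporting reads and reject marginal ones.
    """
    return float(min(60.0, 3.0 * alt_reads))


def sample_read_support(
    true_af: float,
    mean_depth: float,
    contamination: float,
    rng: np.random.Generator,
) -> tuple[int, int, float]:
    """(alt_reads, total_reads, observed_af) for one cell-derived event.

    total ~ Poisson(mean_depth); alt ~ Binomial(total, true_af * (1 - c)).
    Zero total reads gives observed_af = nan (no coverage).
    """
    if not 0.0 <= true_af <= 1.0:
        raise ValueError("true_af must be in [0, 1]")
    total = int(rng.poisson(mean_depth))
    if total == 0:
        return 0, 0, float("nan")
    alt = int(rng.binomial(total, true_af * (1.0 - contamination)))
    return alt, total, alt / total


def _weighted_chromosome(autosomes, rng: np.random.Generator) -> int:
    lengths = np.array([c.length for c in autosomes], dtype=float)
    return int(rng.choice(len(autosomes), p=lengths / lengths.sum()))


def _draw_flanks(gc: float, rng: np.random.Generator) -> tuple[str, str]:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    i, j = rng.choice(4, size=2, p=p)
    return BASES[i], BASES[j]


def _place_snv(
    genome: GenomeModel,
    params: SimulationParams,
    rng: np.random.Generator,
    gene_index=None,
) -> tuple[str, int, str, str, str, str, bool]:
    """Draw a six-type substitution and place it on a random autosome.

    On context chromosomes the site is rejection-sampled until the reference
    base matches the drawn type (on either strand); on virtual chromosomes
    ref/alt and flanks are assigned consistently with the type.
    """
    type_idx = int(rng.choice(6, p=params.type_vector))
    pyr_ref, pyr_alt = SIX_TYPES[type_idx].split(">")
    autosomes = genome.autosomes
    ci = _weighted_chromosome(autosomes, rng)
    chrom = autosomes[ci]
    on_purine = bool(rng.random() < 0.5)  # emit on the complementary strand
    ref = _COMP[pyr_ref] if on_purine else pyr_ref
    alt = _COMP[pyr_alt] if on_purine else pyr_alt
    if chrom.sequence is not None:
        for _ in range(10_000):
            pos = int(rng.integers(2, chrom.length))
            base = chrom.sequence[pos - 1]
            if base == pyr_ref or base == _COMP[pyr_ref]:
                ref = base
                alt = pyr_alt if base == pyr_ref else _COMP[pyr_alt]
                c5, c3 = genome.context_at(chrom.name, pos)
                return chrom.name, pos, ref, alt, c5, c3, True
        raise RuntimeError(f"no site with base {pyr_ref}/{_COMP[pyr_ref]} on {chrom.name}")
    pos = int(rng.integers(2, chrom.length))
    if (
        SIX_TYPES[type_idx] == "C>T"
        and params.ct_untranscribed_bias != 0.5
        and gene_index is not None
    ):
        bodies = [
            g for g in gene_index.overlapping(chrom.name, pos)
            if g.start <= pos <= g.end
        ]
        if len({g.strand for g in bodies}) == 1:
            # untranscribed <=> pyrimidine written on the coding strand
            # <=> (ref is pyrimidine) == (gene on + strand)
            untranscribed = bool(rng.random() < params.ct_untranscribed_bias)
            plus = bodies[0].strand == "+"
            on_purine = not (untranscribed == plus)
            ref = _COMP[pyr_ref] if on_purine else pyr_ref
            alt = _COMP[pyr_alt] if on_purine else pyr_alt
    f5, f3 = _draw_flanks(params.gc_fraction, rng)
    if on_purine:  # flanks stored as written on the reference strand
        f5, f3 = _COMP[f3], _COMP[f5]
    return chrom.name, pos, ref, alt, f5, f3, False


def _place_indel(
    genome: GenomeModel,
    params: SimulationParams,
    rng: np.random.Generator,
) -> tuple[str, int, str, str, str]:
    is_ins = bool(rng.random() < params.ins_del_ratio / (1.0 + params.ins_del_ratio))
    length = int(rng.geometric(params.indel_length_geom_p))
    autosomes = genome.autosomes
    chrom = autosomes[_weighted_chromosome(autosomes, rng)]
    pos = int(rng.integers(2, max(3, chrom.length - length - 1)))
    if chrom.sequence is not None:
        anchor = chrom.sequence[pos - 1]
        following = chrom.sequence[pos : pos + length]
    else:
        anchor = BASES[rng.integers(4)]
        following = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
    if is_ins:
        insert = "".join(BASES[i] for i in rng.integers(0, 4, size=length))
        return chrom.name, pos, anchor, anchor + insert, INS
    return chrom.name, pos, anchor + following, anchor, DEL


def _truth_events(
    design: ClonalDesign,
    params: SimulationParams,
    genome: GenomeModel,
    blacklist: PolymorphismBlacklist | None,
    rng: np.random.Generator,
    gene_index=None,
) -> list[MutationEvent]:
    L = genome.autosomal_length
    events: list[MutationEvent] = []

    def spawn(var_class: str, phase: str, cell_fraction: float, af: float) -> None:
        if var_class == SNV:
            chrom, pos, ref, alt, c5, c3, real = _place_snv(genome, params, rng, gene_index)
            events.append(
                MutationEvent(chrom, pos, ref, alt, SNV, phase, cell_fraction, af, c5, c3, real)
            )
        else:
            chrom, pos, ref, alt, cls = _place_indel(genome, params, rng)
            events.append(MutationEvent(chrom, pos, ref, alt, cls, phase, cell_fraction, af))

    for rate, var_class in ((params.snv_rate, SNV), (params.indel_rate, "INDEL")):
        mean_parental = rate * 2.0 * L * design.doublings
        if mean_parental > 1e6:
            raise ValueError(
                f"expected parental count {mean_parental:.3g} > 1e6; "
                "rate/genome/doublings combination is not desk-scale"
            )
        for _ in range(rng.poisson(mean_parental)):
            hom = rng.random() < params.hom_fraction
            spawn(var_class, "parental", 1.0, 1.0 if hom else 0.5)
        # subclonal expansion: 2^(g-1) dividing lineages at generation g,
        # each new mutation subtending a cell fraction of 2^-g
        for g in range(1, design.subclone_doublings + 1):
            mean_g = rate * 2.0 * L * (2 ** (g - 1))
            for _ in range(rng.poisson(mean_g)):
                spawn(var_class, f"subclonal-g{g}", 2.0**-g, 0.5 * 2.0**-g)

    # contaminating feeder-cell variants: partly known polymorphisms
    # (removable by the blacklist), partly feeder-private (removable only
    # by the AF trim); pooled AF <= c
    c = params.contamination
    if c > 0 and params.n_contaminant_sites > 0:
        n_bl = int(round(params.n_contaminant_sites * params.contaminant_blacklist_fraction))
        bl_sites = sorted(blacklist.sites) if blacklist is not None else []
        if bl_sites:
            take = min(n_bl, len(bl_sites))
            idx = rng.choice(len(bl_sites), size=take, replace=False)
            for i in idx:
                chrom, pos, ref, alt = bl_sites[int(i)]
                hom = rng.random() < params.contaminant_hom_fraction
                af = c * (1.0 if hom else 0.5)
                cls = SNV if len(ref) == len(alt) == 1 else (INS if len(alt) > len(ref) else DEL)
                events.append(MutationEvent(chrom, pos, ref, alt, cls, "contaminant", c, af))
        n_priv = params.n_contaminant_sites - (n_bl if bl_sites else 0)
        for _ in range(n_priv):
            chrom, pos, ref, alt, c5, c3, real = _place_snv(genome, params, rng)
            hom = rng.random() < params.contaminant_hom_fraction
            af = c * (1.0 if hom else 0.5)
            events.append(
                MutationEvent(chrom, pos, ref, alt, SNV, "contaminant", c, af, c5, c3, real)
            )
    return events


def _observe(
    events: list[MutationEvent],
    design: ClonalDesign,
    params: SimulationParams,
    rng: np.random.Generator,
) -> CallSet:
    """Read-level sampling and caller emission for a truth event list."""
    n = len(events)
    if n == 0:
        return CallSet([], ["simulated"])
    totals = rng.poisson(design.mean_depth, size=n)
    dpp = rng.poisson(design.mean_depth, size=n)
    c = params.contamination
    probs = np.array(
        [
            ev.true_af if ev.phase == "contaminant" else ev.true_af * (1.0 - c)
            for ev in events
        ]
    )
    alts = rng.binomial(totals, np.clip(probs, 0.0, 1.0))
    seen: dict[tuple, VariantCall] = {}
    for ev, alt, total, dp in zip(events, alts, totals, dpp):
        if total == 0 or alt < params.min_alt_reads:
            continue
        if ev.key in seen:
            continue
        seen[ev.key] = VariantCall(
            chrom=ev.chrom,
            pos=ev.pos,
            ref=ev.ref,
            alt=ev.alt,
            af=float(alt) / float(total),
            dp_parent=int(dp),
            dp_sub=int(total),
            quality=caller_quality(int(alt)),
            phase=ev.phase,
            ctx5=ev.ctx5,
            ctx3=ev.ctx3,
            context_real=ev.context_real,
        )
    return CallSet(list(seen.values()), ["simulated"])


def simulate_clonal_experiment(
    design: ClonalDesign,
    params: SimulationParams,
    genome: GenomeModel,
    n_subclones: int = 3,
    blacklist: PolymorphismBlacklist | None = None,
    seed: int | np.random.Generator = 0,
    genes: list | None = None,
) -> list[SimulatedExperiment]:
    """Simulate n parent/subclone comparisons with independent truth.

    ``genes`` is only needed when a transcription-strand bias is simulated
    (``params.ct_untranscribed_bias`` != 0.5).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    gene_index = None
    if genes is not None:
        from .annotate import GeneIndex

        gene_index = GeneIndex(genes)
    experiments = []
    for s in range(n_subclones):
        truth = _truth_events(design, params, genome, blacklist, rng, gene_index)
        calls = _observe(truth, design, params, rng)
        parent_cov = simulate_coverage(
            genome, design.mean_depth, design.coverage_bin_size, rng, sample="parent"
        )
        sub_cov = simulate_coverage(
            genome, design.mean_depth, design.coverage_bin_size, rng, sample=f"sub{s + 1}"
        )
        experiments.append(
            SimulatedExperiment(
                f"sub{s + 1}", truth, calls, parent_cov, sub_cov, design, params
            )
        )
    return experiments


def spike_cnv(
    track: CoverageTrack,
    chrom: str,
    start: int,
    end: int,
    copies: int,
    cell_fraction: float = 1.0,
) -> CoverageTrack:
    """Scale binned depth over a 1-based inclusive interval by the expected
    copy-number factor 1 + cell_fraction * (copies - 2) / 2."""
    if copies < 1:
        raise ValueError("copies must be >= 1")
    if chrom not in track.depths:
        raise ValueError(f"unknown chromosome {chrom}")
    if not 1 <= start <= end <= track.chrom_lengths[chrom]:
        raise ValueError(f"interval {start}-{end} outside {chrom}")
    factor = 1.0 + cell_fraction * (copies - 2) / 2.0
    depths = {c: arr.copy() for c, arr in track.depths.items()}
    b0 = (start - 1) // track.bin_size
    b1 = (end - 1) // track.bin_size
    depths[chrom][b0 : b1 + 1] = depths[chrom][b0 : b1 + 1] * factor
    return CoverageTrack(depths, track.bin_size, dict(track.chrom_lengths), track.sample)


@dataclass
class BulkTimepoint:
    month: int
    calls: CallSet  # comparison against the first (baseline) timepoint
    coverage: CoverageTrack
    truth_keys: set[tuple]


def simulate_bulk_timepoints(
    params: SimulationParams,
    genome: GenomeModel,
    timepoints: list[int],
    snv_per_month: float = 14.0,
    indel_per_month: float = 0.6,
    hom_fraction: float = 0.1,
    mean_depth: float = 30.0,
    bin_size: int = 100_000,
    cnv_event: dict | None = None,
    seed: int | np.random.Generator = 0,
) -> list[BulkTimepoint]:
    """Mutation accumulation in a continuously passaged bulk culture.

    Fixed mutations (AF ~ 0.5 het / 1.0 hom) accrue monotonically between
    timepoints, so the earlier fixed set is a subset of the later one; the
    first timepoint is the baseline against which the others are compared.
    A segmental amplification can be spiked into coverage from a given
    timepoint onward via ``cnv_event`` with keys chrom/start/end/copies/
    cell_fraction/from_month.
    """
    if len(timepoints) < 2:
        raise ValueError("need at least two timepoints")
    if any(b <= a for a, b in zip(timepoints, timepoints[1:])):
        raise ValueError("timepoints must be strictly increasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    design = ClonalDesign(mean_depth=mean_depth, coverage_bin_size=bin_size)

    accumulated: list[MutationEvent] = []
    out: list[BulkTimepoint] = []
    prev = timepoints[0]
    for month in timepoints:
        dt = month - prev
        if dt > 0:
            for mean, var_class in ((snv_per_month * dt, SNV), (indel_per_month * dt, "INDEL")):
                for _ in range(rng.poisson(mean)):
                    hom = rng.random() < hom_fraction
                    af = 1.0 if hom else 0.5
                    if var_class == SNV:
                        chrom, pos, ref, alt, c5, c3, real = _place_snv(genome, params, rng)
                        accumulated.append(
                            MutationEvent(chrom, pos, ref, alt, SNV, "fixed", 1.0, af, c5, c3, real)
                        )
                    else:
                        chrom, pos, ref, alt, cls = _place_indel(genome, params, rng)
                        accumulated.append(
                            MutationEvent(chrom, pos, ref, alt, cls, "fixed", 1.0, af)
                        )
        prev = month
        calls = _observe(list(accumulated), design, params, rng)
        cov = simulate_coverage(genome, mean_depth, bin_size, rng, sample=f"month{month}")
        if cnv_event is not None and month >= cnv_event.get("from_month", timepoints[0]):
            cov = spike_cnv(
                cov,
                cnv_event["chrom"],
                cnv_event["start"],
                cnv_event["end"],
                cnv_event["copies"],
                cnv_event.get("cell_fraction", 1.0),
            )
        out.append(BulkTimepoint(month, calls, cov, {e.key for e in accumulated}))
    return out
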