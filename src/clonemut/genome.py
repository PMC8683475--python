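"""Toy genome world: reference, gene models, expression, polymorphism blacklist.

The analysis only needs three things from a reference genome: chromosome
lengths (for the rate denominator and per-chromosome densities), actual
sequence where trinucleotide context matters, and gene models with strand
for genic annotation.  To keep everything desk-scale the genome is split in
two tiers: a few small "context chromosomes" that carry explicit sequence,
and "virtual chromosomes" that contribute length only, so a ~2 Gb callable
genome is representable without storing 2 Gb of bases.

Coordinates are 1-based inclusive throughout (VCF/GFF convention); the BED
writer converts to 0-based half-open at the boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

# de Bruijn B(4,2) cycle over ACGT: every dinucleotide appears once.
_ALL_DINUC = "AACAGATCCGCTGGTTA"


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Chromosome:
    name: str
    length: int
    autosome: bool = True
    sequence: str | None = None  # explicit only for context chromosomes

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"chromosome {self.name}: non-positive length")
        if self.sequence is not None and len(self.sequence) != self.length:
            raise ValueError(
                f"chromosome {self.name}: sequence length "
                f"{len(self.sequence)} != declared {self.length}"
            )


@dataclass
class GenomeModel:
    """Chromosome set with optional explicit sequence per chromosome."""

    chromosomes: list[Chromosome]

    def __post_init__(self) -> None:
        names = [c.name for c in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        self._by_name = {c.name: c for c in self.chromosomes}

    def __getitem__(self, name: str) -> Chromosome:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def autosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.autosome]

    @property
    def autosome_names(self) -> set[str]:
        return {c.name for c in self.chromosomes if c.autosome}

    @property
    def autosomal_length(self) -> int:
        return sum(c.length for c in self.autosomes)

    @property
    def context_chromosomes(self) -> list[Chromosome]:
        return [c for c in self.chromosomes if c.sequence is not None]

    def base_at(self, chrom: str, pos: int) -> str | None:
        """Reference base at a 1-based position, None on virtual chromosomes."""
        c = self._by_name[chrom]
        if c.sequence is None:
            return None
        if not 1 <= pos <= c.length:
            raise IndexError(f"{chrom}:{pos} out of bounds")
        return c.sequence[pos - 1]

    def context_at(self, chrom: str, pos: int) -> tuple[str, str] | None:
        """(5' base, 3' base) flanking a 1-based position, or None if
        unavailable (virtual chromosome or chromosome edge)."""
        c = self._by_name[chrom]
        if c.sequence is None:
            return None
        if pos <= 1 or pos >= c.length:
            return None
        return c.sequence[pos - 2], c.sequence[pos]

    def slice(self, chrom: str, start: int, end: int) -> str | None:
        """Sequence for a 1-based inclusive interval, None on virtual chromosomes."""
        c = self._by_name[chrom]
        if c.sequence is None:
            return None
        return c.sequence[start - 1 : end]


@dataclass(frozen=True)
class GeneModel:
    """Single-transcript gene model with 1-based inclusive intervals."""

    gene_id: str
    chrom: str
    strand: str  # '+' or '-'
    start: int  # transcription start (left-most coordinate)
    end: int  # transcription end (right-most coordinate)
    exons: tuple[tuple[int, int], ...]
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()
    flank: int = 1000

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        for s, e in self.exons:
            if not (self.start <= s <= e <= self.end):
                raise ValueError(f"{self.gene_id}: exon outside gene span")
        exonic = set()
        for s, e in self.exons:
            exonic.update(range(s, e + 1))
        for s, e in self.utr5 + self.utr3:
            if not set(range(s, e + 1)) <= exonic:
                raise ValueError(f"{self.gene_id}: UTR outside exon union")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


class ExpressionTable(dict):
    """gene id -> FPKM (non-negative)."""

    def validate(self, genes: list[GeneModel]) -> None:
        ids = {g.gene_id for g in genes}
        unknown = set(self) - ids
        if unknown:
            raise ValueError(f"expression for unknown genes: {sorted(unknown)[:5]}")
        for gid, fpkm in self.items():
            if fpkm < 0:
                raise ValueError(f"{gid}: negative FPKM")


class PolymorphismBlacklist:
    """Known polymorphic sites, matched allele-aware as (chrom, pos, ref, alt)."""

    def __init__(self, sites: set[tuple[str, int, str, str]] | None = None):
        self.sites: set[tuple[str, int, str, str]] = set(sites or ())

    def __len__(self) -> int:
        return len(self.sites)

    def __contains__(self, key: tuple[str, int, str, str]) -> bool:
        return key in self.sites

    def add(self, chrom: str, pos: int, ref: str, alt: str) -> None:
        self.sites.add((chrom, pos, ref, alt))

    def validate(self, genome: GenomeModel) -> None:
        for chrom, pos, _, _ in self.sites:
            if chrom not in genome:
                raise ValueError(f"blacklist site on unknown chromosome {chrom}")
            if not 1 <= pos <= genome[chrom].length:
                raise ValueError(f"blacklist site out of bounds: {chrom}:{pos}")


def _random_sequence(length: int, gc_fraction: float, rng: np.random.Generator) -> str:
    p = np.array(
        [
            (1 - gc_fraction) / 2,  # A
            gc_fraction / 2,  # C
            gc_fraction / 2,  # G
            (1 - gc_fraction) / 2,  # T
        ]
    )
    idx = rng.choice(4, size=length, p=p)
    return "".join(np.array(list(BASES))[idx])


def build_toy_genome(
    n_context_chromosomes: int = 2,
    context_length: int = 1_000_000,
    n_virtual_chromosomes: int = 19,
    virtual_length: int = 100_000_000,
    gc_fraction: float = 0.42,
    seed: int | np.random.Generator = 0,
    sex_chromosome_length: int | None = None,
) -> GenomeModel:
    """Deterministic two-tier genome.

    Context chromosomes (``ctx1`` ..) carry explicit random sequence at the
    requested GC fraction; for non-degenerate composition a short cassette
    containing every dinucleotide is embedded so CpG and all 96 trinucleotide
    contexts are reachable even on short chromosomes.  Virtual chromosomes
    (``virt1`` ..) contribute length only.  Two sex-chromosome analogues
    (``chrX``, ``chrY``) are appended and flagged non-autosomal.
    """
    if context_length < 10_000:
        raise ValueError("context chromosomes must be at least 10 kb")
    if virtual_length <= 0 or context_length <= 0:
        raise ValueError("chromosome lengths must be positive")
    if not 0.0 <= gc_fraction <= 1.0:
        raise ValueError("gc_fraction must be in [0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    chroms: list[Chromosome] = []
    for i in range(n_context_chromosomes):
        seq = _random_sequence(context_length, gc_fraction, rng)
        if 0.0 < gc_fraction < 1.0:
            # fixed-offset cassette guaranteeing all 16 dinucleotides
            seq = seq[:100] + _ALL_DINUC + seq[100 + len(_ALL_DINUC) :]
        chroms.append(Chromosome(f"ctx{i + 1}", context_length, True, seq))
    for i in range(n_virtual_chromosomes):
        chroms.append(Chromosome(f"virt{i + 1}", virtual_length, True, None))
    sex_len = sex_chromosome_length or virtual_length
    chroms.append(Chromosome("chrX", sex_len, False, None))
    chroms.append(Chromosome("chrY", max(sex_len // 2, 1), False, None))
    return GenomeModel(chroms)


def _make_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start: int,
    length: int,
    rng: np.random.Generator,
    flank: int = 1000,
) -> GeneModel:
    end = start + length - 1
    n_exons = int(rng.integers(1, 6))
    if length < 2 * n_exons + 10:
        n_exons = 1
    if n_exons == 1:
        exons = ((start, end),)
    else:
        # 2k-2 internal boundaries; segments alternate exon/intron/.../exon
        cuts = np.sort(rng.choice(np.arange(start + 1, end), size=2 * n_exons - 2, replace=False))
        bounds = [start, *cuts.tolist(), end]
        exons = tuple(
            (int(bounds[2 * i] + (1 if i else 0)), int(bounds[2 * i + 1]))
            for i in range(n_exons)
        )
        exons = tuple((min(s, e), max(s, e)) for s, e in exons)
    first, last = exons[0], exons[-1]
    u_left = (first[0], min(first[1], first[0] + max(1, min(200, (first[1] - first[0]) // 2))))
    u_right = (max(last[0], last[1] - max(1, min(200, (last[1] - last[0]) // 2))), last[1])
    utr5, utr3 = ((u_left,), (u_right,)) if strand == "+" else ((u_right,), (u_left,))
    return GeneModel(gene_id, chrom, strand, start, end, exons, utr5, utr3, flank)


def build_gene_models(
    genome: GenomeModel,
    n_genes: int = 50,
    length_median: float = 10_000.0,
    length_sigma: float = 1.0,
    zero_expression_fraction: float = 0.3,
    expression_median: float = 5.0,
    expression_sigma: float = 1.5,
    flank: int = 1000,
    seed: int | np.random.Generator = 0,
) -> tuple[list[GeneModel], ExpressionTable]:
    """Place non-overlapping genes on context chromosomes.

    Gene lengths are log-normal with the given median; FPKM values are
    log-normal with a configurable fraction of zero-expression genes.
    Genes are separated by at least 2*flank+1 bp so flank regions never
    overlap a neighbouring gene body.  Raises if the requested genes cannot
    be placed.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ctx = genome.context_chromosomes
    if not ctx:
        raise ValueError("genome has no context chromosomes")
    lengths = np.maximum(
        200, rng.lognormal(np.log(length_median), length_sigma, size=n_genes)
    ).astype(int)

    genes: list[GeneModel] = []
    cursors = {c.name: flank + 1 for c in ctx}
    order = list(ctx)
    for i, glen in enumerate(lengths):
        strand = "+" if (i % 2 == 0) else "-"
        placed = False
        for c in order:
            gap = int(rng.integers(2 * flank + 1, 4 * flank))
            start = cursors[c.name] + gap
            if start + glen - 1 + flank <= c.length:
                genes.append(
                    _make_gene(f"gene{i + 1:04d}", c.name, strand, start, int(glen), rng, flank)
                )
                cursors[c.name] = start + int(glen)
                placed = True
                break
        if not placed:
            raise ValueError(
                f"cannot place gene {i + 1}/{n_genes} (length {glen}) without overlap"
            )
        order = order[1:] + order[:1]  # round-robin chromosomes

    expr = ExpressionTable()
    zero = rng.random(n_genes) < zero_expression_fraction
    fpkm = rng.lognormal(np.log(expression_median), expression_sigma, size=n_genes)
    for g, z, f in zip(genes, zero, fpkm):
        expr[g.gene_id] = 0.0 if z else float(f)
    expr.validate(genes)
    return genes, expr


def build_blacklist(
    genome: GenomeModel,
    site_density: float = 1e-4,
    seed: int | np.random.Generator = 0,
) -> PolymorphismBlacklist:
    """Poisson-scattered known-polymorphism sites across all chromosomes."""
    if not 0.0 <= site_density <= 0.01:
        raise ValueError("site_density must be in [0, 0.01]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    bl = PolymorphismBlacklist()
    for c in genome.chromosomes:
        n = rng.poisson(site_density * c.length)
        if n == 0:
            continue
        positions = rng.integers(1, c.length + 1, size=n)
        for pos in positions:
            pos = int(pos)
            ref = genome.base_at(c.name, pos) or BASES[rng.integers(4)]
            alt = BASES[rng.integers(4)]
            while alt == ref:
                alt = BASES[rng.integers(4)]
            bl.add(c.name, pos, ref, alt)
    bl.validate(genome)
    return bl


# ---------------------------------------------------------------------------
# Serialization: FASTA + chromosome table + GFF3-like + BED + TSV
# ---------------------------------------------------------------------------

FASTA_NAME = "genome.fa"
CHROM_TABLE_NAME = "chromosomes.tsv"
GFF_NAME = "genes.gff"
BLACKLIST_NAME = "blacklist.bed"
EXPRESSION_NAME = "expression.tsv"


def write_fixture(
    genome: GenomeModel,
    genes: list[GeneModel],
    blacklist: PolymorphismBlacklist,
    expression: ExpressionTable,
    out_dir: str,
) -> dict[str, str]:
    """Serialize the genome world; returns the paths written."""
    os.makedirs(out_dir, exist_ok=True)
    paths = {
        "fasta": os.path.join(out_dir, FASTA_NAME),
        "chromosomes": os.path.join(out_dir, CHROM_TABLE_NAME),
        "genes": os.path.join(out_dir, GFF_NAME),
        "blacklist": os.path.join(out_dir, BLACKLIST_NAME),
        "expression": os.path.join(out_dir, EXPRESSION_NAME),
    }
    try:
        with open(paths["fasta"], "w") as fh:
            for c in genome.context_chromosomes:
                fh.write(f">{c.name}\n")
                for i in range(0, c.length, 60):
                    fh.write(c.sequence[i : i + 60] + "\n")
        with open(paths["chromosomes"], "w") as fh:
            fh.write("chrom\tlength\tautosome\thas_sequence\n")
            for c in genome.chromosomes:
                fh.write(
                    f"{c.name}\t{c.length}\t{int(c.autosome)}\t{int(c.sequence is not None)}\n"
                )
        with open(paths["genes"], "w") as fh:
            for g in genes:
                rows = [("gene", g.start, g.end)]
                rows += [("exon", s, e) for s, e in g.exons]
                rows += [("five_prime_UTR", s, e) for s, e in g.utr5]
                rows += [("three_prime_UTR", s, e) for s, e in g.utr3]
                for ftype, s, e in rows:
                    fh.write(
                        f"{g.chrom}\tclonemut\t{ftype}\t{s}\t{e}\t.\t{g.strand}\t.\t"
                        f"ID={g.gene_id}\n"
                    )
        with open(paths["blacklist"], "w") as fh:
            for chrom, pos, ref, alt in sorted(blacklist.sites):
                fh.write(f"{chrom}\t{pos - 1}\t{pos}\t{ref}\t{alt}\n")
        with open(paths["expression"], "w") as fh:
            fh.write("gene_id\tfpkm\n")
            for gid in sorted(expression):
                fh.write(f"{gid}\t{expression[gid]!r}\n")
    except OSError as exc:
        raise OSError(f"failed writing fixture file: {exc.filename}: {exc}") from exc
    return paths


def read_fixture(
    in_dir: str,
) -> tuple[GenomeModel, list[GeneModel], PolymorphismBlacklist, ExpressionTable]:
    """Inverse of :func:`write_fixture`; round trip is lossless."""
    seqs = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(os.path.join(in_dir, FASTA_NAME), "fasta")
    }
    chroms: list[Chromosome] = []
    with open(os.path.join(in_dir, CHROM_TABLE_NAME)) as fh:
        next(fh)
        for line in fh:
            name, length, autosome, has_seq = line.rstrip("\n").split("\t")
            chroms.append(
                Chromosome(
                    name,
                    int(length),
                    bool(int(autosome)),
                    seqs[name] if int(has_seq) else None,
                )
            )
    genome = GenomeModel(chroms)

    raw: dict[str, dict] = {}
    gene_order: list[str] = []
    with open(os.path.join(in_dir, GFF_NAME)) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            chrom, _, ftype, start, end, _, strand, _, attrs = line.rstrip("\n").split("\t")
            gid = dict(kv.split("=") for kv in attrs.split(";"))["ID"]
            if gid not in raw:
                raw[gid] = {
                    "chrom": chrom,
                    "strand": strand,
                    "exons": [],
                    "utr5": [],
                    "utr3": [],
                }
                gene_order.append(gid)
            rec = raw[gid]
            iv = (int(start), int(end))
            if ftype == "gene":
                rec["span"] = iv
            elif ftype == "exon":
                rec["exons"].append(iv)
            elif ftype == "five_prime_UTR":
                rec["utr5"].append(iv)
            elif ftype == "three_prime_UTR":
                rec["utr3"].append(iv)
    genes = [
        GeneModel(
            gid,
            r["chrom"],
            r["strand"],
            r["span"][0],
            r["span"][1],
            tuple(r["exons"]),
            tuple(r["utr5"]),
            tuple(r["utr3"]),
        )
        for gid, r in ((g, raw[g]) for g in gene_order)
    ]

    bl = PolymorphismBlacklist()
    with open(os.path.join(in_dir, BLACKLIST_NAME)) as fh:
        for line in fh:
            chrom, start0, _, ref, alt = line.rstrip("\n").split("\t")
            bl.add(chrom, int(start0) + 1, ref, alt)

    expr = ExpressionTable()
    with open(os.path.join(in_dir, EXPRESSION_NAME)) as fh:
        next(fh)
        for line in fh:
            gid, fpkm = line.rstrip("\n").split("\t")
            expr[gid] = float(fpkm)
    return genome, genes, bl, expr
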