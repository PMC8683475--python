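"""Candidate-call container, VCF I/O, and the de novo filtering cascade.

The cascade mirrors a parent-vs-subclone somatic calling workflow: calls
must be covered by at least ``min_depth`` reads in *both* samples, pass a
class-specific caller quality threshold (SNV and INDEL thresholds differ),
not coincide allele-for-allele with a known-polymorphism blacklist site,
lie on an autosome, and finally survive an allele-frequency trim at tau.
The number removed by the trim is the input to the truncated-Gaussian
count extrapolation in :mod:`clonemut.rates`.

Boundary semantics are inclusive throughout: depth >= min_depth, quality
>= threshold and AF >= tau are retained.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pysam

from .coverage import CoverageTrack
from .genome import GenomeModel, PolymorphismBlacklist

SNV = "SNV"
INS = "INS"
DEL = "DEL"


def classify_alleles(ref: str, alt: str) -> str:
    if len(ref) == 1 and len(alt) == 1:
        return SNV
    if len(alt) > len(ref):
        return INS
    return DEL


@dataclass(frozen=True)
class VariantCall:
    """One candidate de novo variant from a parent/subclone comparison."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float  # alt reads / total reads in the subclone
    dp_parent: int
    dp_sub: int
    quality: float
    var_class: str = ""
    phase: str = ""  # truth tag when simulated; empty on real data
    ctx5: str = ""  # flanking bases, when known
    ctx3: str = ""
    context_real: bool = False  # True if flanks come from actual sequence

    def __post_init__(self) -> None:
        if not 0.0 <= self.af <= 1.0:
            raise ValueError(f"{self.chrom}:{self.pos}: AF {self.af} outside [0,1]")
        if self.dp_parent < 0 or self.dp_sub < 0:
            raise ValueError(f"{self.chrom}:{self.pos}: negative depth")
        expected = classify_alleles(self.ref, self.alt)
        if self.var_class == "":
            object.__setattr__(self, "var_class", expected)
        elif self.var_class != expected:
            raise ValueError(
                f"{self.chrom}:{self.pos}: class {self.var_class} inconsistent "
                f"with alleles {self.ref}>{self.alt}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def indel_length(self) -> int:
        """Signed INDEL length: insertions positive, deletions negative."""
        return len(self.alt) - len(self.ref)


class CallSet:
    """Sorted, duplicate-free collection of calls with filter provenance."""

    def __init__(self, calls: list[VariantCall] = (), provenance: list[str] = ()):
        ordered = sorted(calls, key=lambda c: (c.chrom, c.pos, c.ref, c.alt))
        keys = [c.key for c in ordered]
        if len(set(keys)) != len(keys):
            dupes = {k for k in keys if keys.count(k) > 1}
            raise ValueError(f"duplicate call keys: {sorted(dupes)[:3]}")
        self.calls = ordered
        self.provenance = list(provenance)

    def __len__(self) -> int:
        return len(self.calls)

    def __iter__(self):
        return iter(self.calls)

    def __eq__(self, other) -> bool:
        return isinstance(other, CallSet) and self.calls == other.calls

    def keys(self) -> set[tuple[str, int, str, str]]:
        return {c.key for c in self.calls}

    def subset(self, predicate, stage: str) -> "CallSet":
        return CallSet(
            [c for c in self.calls if predicate(c)], self.provenance + [stage]
        )

    def of_class(self, var_class: str) -> "CallSet":
        return self.subset(lambda c: c.var_class == var_class, f"class={var_class}")

    def afs(self) -> np.ndarray:
        return np.array([c.af for c in self.calls])


@dataclass
class FilterStage:
    name: str
    params: dict
    n_in: int
    n_out: int


class FilterReport:
    """Audit trail of the cascade: per-stage parameters and in/out counts."""

    def __init__(self) -> None:
        self.stages: list[FilterStage] = []

    def record(self, name: str, params: dict, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name}: count increased {n_in} -> {n_out}")
        self.stages.append(FilterStage(name, params, n_in, n_out))

    def to_dict(self) -> list[dict]:
        return [
            {"stage": s.name, "params": s.params, "n_in": s.n_in, "n_out": s.n_out}
            for s in self.stages
        ]

    def to_json(self, path: str) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


# ---------------------------------------------------------------------------
# VCF-dialect I/O.  Standard VCF 4.2 with AF / DPP / DPS / PHASE / context
# INFO fields; QUAL carries the synthetic caller quality.
# ---------------------------------------------------------------------------

_HEADER_LINES = [
    '##INFO=<ID=AF,Number=A,Type=Float,Description="Alt allele fraction in subclone">',
    '##INFO=<ID=ALTC,Number=A,Type=Integer,Description="Alt read count in subclone">',
    '##INFO=<ID=DPP,Number=1,Type=Integer,Description="Read depth in parent">',
    '##INFO=<ID=DPS,Number=1,Type=Integer,Description="Read depth in subclone">',
    '##INFO=<ID=PHASE,Number=1,Type=String,Description="Simulation truth tag">',
    '##INFO=<ID=CX5,Number=1,Type=String,Description="5-prime flanking base">',
    '##INFO=<ID=CX3,Number=1,Type=String,Description="3-prime flanking base">',
    '##INFO=<ID=CXR,Number=0,Type=Flag,Description="Flanks from actual sequence">',
]


def write_calls(callset: CallSet, path: str, genome: GenomeModel | None = None) -> None:
    chroms: list[tuple[str, int | None]]
    if genome is not None:
        chroms = [(c.name, c.length) for c in genome.chromosomes]
    else:
        seen: dict[str, None] = {}
        for c in callset:
            seen.setdefault(c.chrom, None)
        chroms = [(name, None) for name in seen]
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for name, length in chroms:
            if length is None:
                fh.write(f"##contig=<ID={name}>\n")
            else:
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("\n".join(_HEADER_LINES) + "\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for c in callset:
            info = [f"AF={c.af:.6g}", f"DPP={c.dp_parent}", f"DPS={c.dp_sub}"]
            # AF is stored losslessly as the integer alt count when exact
            alt_count = c.af * c.dp_sub
            if c.dp_sub > 0 and abs(alt_count - round(alt_count)) < 1e-9:
                info.append(f"ALTC={round(alt_count)}")
            if c.phase:
                info.append(f"PHASE={c.phase}")
            if c.ctx5 and c.ctx3:
                info.append(f"CX5={c.ctx5};CX3={c.ctx3}")
                if c.context_real:
                    info.append("CXR")
            fh.write(
                f"{c.chrom}\t{c.pos}\t.\t{c.ref}\t{c.alt}\t{c.quality:.6g}\t.\t"
                + ";".join(info)
                + "\n"
            )


def _scalar(value):
    """pysam returns Number=A INFO values as one-element tuples."""
    if isinstance(value, tuple):
        return value[0]
    return value


def read_calls(path: str) -> CallSet:
    calls: list[VariantCall] = []
    with pysam.VariantFile(path) as vf:
        for i, rec in enumerate(vf.fetch() if vf.index else vf):
            where = f"{path} record {i + 1} ({rec.chrom}:{rec.pos})"
            info = rec.info
            for required in ("AF", "DPP", "DPS"):
                if required not in info:
                    raise ValueError(f"{where}: missing INFO/{required}")
            if len(rec.alts or ()) != 1:
                raise ValueError(f"{where}: expected exactly one ALT allele")
            dps = int(info["DPS"])
            if "ALTC" in info and dps > 0:
                af = _scalar(info["ALTC"]) / dps
            else:
                af = float(_scalar(info["AF"]))
            calls.append(
                VariantCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref=rec.ref,
                    alt=rec.alts[0],
                    af=af,
                    dp_parent=int(info["DPP"]),
                    dp_sub=dps,
                    quality=float(rec.qual) if rec.qual is not None else 0.0,
                    phase=str(info.get("PHASE") or ""),
                    ctx5=str(info.get("CX5") or ""),
                    ctx3=str(info.get("CX3") or ""),
                    context_real=bool(info.get("CXR", False)),
                )
            )
    return CallSet(calls, [f"read:{path}"])


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------


def apply_quality_depth_filters(
    calls: CallSet,
    min_depth: int = 10,
    snv_quality_threshold: float = 19.0,
    indel_quality_threshold: float = 14.0,
    report: FilterReport | None = None,
) -> tuple[CallSet, FilterReport]:
    """Keep calls with depth >= min_depth in both samples and caller quality
    >= the class-specific threshold (19 SNV / 14 INDEL by default)."""
    report = report or FilterReport()

    def depth_ok(c: VariantCall) -> bool:
        return c.dp_parent >= min_depth and c.dp_sub >= min_depth

    def quality_ok(c: VariantCall) -> bool:
        thr = snv_quality_threshold if c.var_class == SNV else indel_quality_threshold
        return c.quality >= thr

    n_in = len(calls)
    after_depth = calls.subset(depth_ok, f"min_depth>={min_depth}")
    report.record("depth", {"min_depth": min_depth}, n_in, len(after_depth))
    out = after_depth.subset(
        quality_ok,
        f"quality>={snv_quality_threshold}(SNV)/{indel_quality_threshold}(INDEL)",
    )
    report.record(
        "quality",
        {"snv": snv_quality_threshold, "indel": indel_quality_threshold},
        len(after_depth),
        len(out),
    )
    return out, report


def apply_blacklist(
    calls: CallSet,
    blacklist: PolymorphismBlacklist,
    report: FilterReport | None = None,
) -> tuple[CallSet, FilterReport]:
    """Remove calls matching a known polymorphic site on (chrom, pos, ref, alt).

    Matching is allele-aware: a de novo event at a polymorphic position with
    a different alternate allele is retained.
    """
    report = report or FilterReport()
    n_in = len(calls)
    out = calls.subset(lambda c: c.key not in blacklist, "blacklist")
    report.record("blacklist", {"n_sites": len(blacklist)}, n_in, len(out))
    return out, report


def exclude_sex_chromosomes(
    calls: CallSet,
    genome: GenomeModel,
    report: FilterReport | None = None,
) -> tuple[CallSet, FilterReport]:
    """Drop calls on chromosomes flagged non-autosomal."""
    report = report or FilterReport()
    for c in calls:
        if c.chrom not in genome:
            raise ValueError(f"call on unknown chromosome {c.chrom}")
    autosomes = genome.autosome_names
    n_in = len(calls)
    out = calls.subset(lambda c: c.chrom in autosomes, "autosomes-only")
    report.record("sex_chromosomes", {}, n_in, len(out))
    return out, report


def trim_low_af(
    calls: CallSet,
    tau: float,
    report: FilterReport | None = None,
) -> tuple[CallSet, FilterReport]:
    """Remove calls with AF < tau; the removed count is reported because the
    Gaussian extrapolation reconstructs the trimmed mass."""
    if not 0.0 < tau < 1.0:
        raise ValueError("tau must be in (0, 1)")
    report = report or FilterReport()
    n_in = len(calls)
    out = calls.subset(lambda c: c.af >= tau, f"af>={tau}")
    report.record("af_trim", {"tau": tau}, n_in, len(out))
    return out, report


def run_cascade(
    calls: CallSet,
    genome: GenomeModel,
    blacklist: PolymorphismBlacklist,
    tau: float,
    min_depth: int = 10,
    snv_quality_threshold: float = 19.0,
    indel_quality_threshold: float = 14.0,
) -> tuple[CallSet, FilterReport]:
    """The full cascade in canonical order (the depth/quality/blacklist/sex
    stages commute; the AF trim is last by convention)."""
    report = FilterReport()
    out, _ = apply_quality_depth_filters(
        calls, min_depth, snv_quality_threshold, indel_quality_threshold, report
    )
    out, _ = apply_blacklist(out, blacklist, report)
    out, _ = exclude_sex_chromosomes(out, genome, report)
    out, _ = trim_low_af(out, tau, report)
    return out, report


def effective_genome_length(
    parent_track: CoverageTrack,
    subclone_track: CoverageTrack,
    min_depth: int = 10,
    chromosomes: set[str] | None = None,
) -> int:
    """Haploid effective genome length: total bases in bins whose mean depth
    is >= min_depth in both samples, optionally restricted to a chromosome
    subset (typically the autosomes)."""
    if not parent_track.same_grid(subclone_track):
        raise ValueError("coverage tracks are on different bin grids")
    total = 0
    for chrom in parent_track.depths:
        if chromosomes is not None and chrom not in chromosomes:
            continue
        ok = (parent_track.depths[chrom] >= min_depth) & (
            subclone_track.depths[chrom] >= min_depth
        )
        total += int(parent_track.bin_lengths(chrom)[ok].sum())
    return total
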