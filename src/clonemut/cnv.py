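"""Coverage-ratio copy-number analysis.

Chromosome-level states are read off the median binned coverage ratio of a
sample against a control: ~1 diploid, ~1.5 trisomic, ~0.5 monosomic, with
intermediate medians interpreted as mixed cell populations (a fraction f of
trisomic cells shifts a whole-chromosome median to 1 + f/2).  Segmental
events are found by run-length thresholding on a median-filtered ratio
track rather than formal changepoint inference — adequate for the
multi-megabase events this analysis targets.

Normalization is two-step: each track is scaled by its autosomal total so
library size cancels, then the ratio track is rescaled so the median
unmasked bin sits at 1.  The second step anchors the diploid mode: without
it a whole-chromosome gain would drag every other chromosome slightly
below 1 and the gained chromosome below its nominal band.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import median_filter

from .coverage import CoverageTrack

DISOMY = "disomy"
TRISOMY = "trisomy"
MONOSOMY = "monosomy"
INTERMEDIATE = "intermediate"
NO_CALL = "no-call"


@dataclass
class RatioTrack:
    """Binned sample/control coverage ratio; masked bins are NaN."""

    ratios: dict[str, np.ndarray]
    bin_size: int
    chrom_lengths: dict[str, int]

    def unmasked(self, chrom: str) -> np.ndarray:
        arr = self.ratios[chrom]
        return arr[~np.isnan(arr)]


@dataclass(frozen=True)
class PloidyCall:
    chrom: str
    state: str
    median_ratio: float
    mixture_fraction: float | None = None  # for intermediate states
    n_bins: int = 0


@dataclass(frozen=True)
class Segment:
    chrom: str
    start: int  # 1-based inclusive
    end: int
    kind: str  # 'gain' or 'loss'
    mean_ratio: float


def coverage_ratio(
    sample: CoverageTrack,
    control: CoverageTrack,
    min_control_depth: float = 10.0,
    autosomes: set[str] | None = None,
) -> RatioTrack:
    """Normalized per-bin coverage ratio with low-control bins masked."""
    if not sample.same_grid(control):
        raise ValueError("sample and control tracks are on different bin grids")
    chroms = list(sample.depths)
    auto = autosomes if autosomes is not None else set(chroms)

    def total(track: CoverageTrack) -> float:
        return float(
            sum(
                (track.depths[c] * track.bin_lengths(c)).sum()
                for c in chroms
                if c in auto
            )
        )
    ts, tc = total(sample), total(control)
    if ts <= 0 or tc <= 0:
        raise ValueError("zero autosomal coverage in sample or control")

    ratios: dict[str, np.ndarray] = {}
    for c in chroms:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = (sample.depths[c] / ts) / (control.depths[c] / tc)
        r[control.depths[c] < min_control_depth] = np.nan
        ratios[c] = r
    # anchor the diploid mode at 1
    pool = np.concatenate([ratios[c] for c in chroms if c in auto])
    mode = np.nanmedian(pool)
    if not np.isfinite(mode) or mode <= 0:
        raise ValueError("cannot normalize: no unmasked autosomal bins")
    for c in chroms:
        ratios[c] = ratios[c] / mode
    return RatioTrack(ratios, sample.bin_size, dict(sample.chrom_lengths))


def call_chromosome_ploidy(
    track: RatioTrack,
    band: float = 0.1,
    min_bins: int = 20,
    chromosomes: set[str] | None = None,
) -> list[PloidyCall]:
    """Median-ratio state per chromosome with fixed bands around 1 / 1.5 / 0.5.

    Medians outside every band are 'intermediate'; for gains between 1 and
    1.5 the trisomic-cell mixture fraction is estimated as f = 2(m - 1),
    for losses between 0.5 and 1 as f = 2(1 - m).
    """
    calls = []
    for chrom, arr in track.ratios.items():
        if chromosomes is not None and chrom not in chromosomes:
            continue
        vals = arr[~np.isnan(arr)]
        if len(vals) < min_bins:
            calls.append(PloidyCall(chrom, NO_CALL, float("nan"), None, len(vals)))
            continue
        m = float(np.median(vals))
        mixture = None
        if abs(m - 1.0) <= band:
            state = DISOMY
        elif abs(m - 1.5) <= band:
            state = TRISOMY
        elif abs(m - 0.5) <= band:
            state = MONOSOMY
        else:
            state = INTERMEDIATE
            if 1.0 < m < 1.5:
                mixture = 2.0 * (m - 1.0)
            elif 0.5 < m < 1.0:
                mixture = 2.0 * (1.0 - m)
        calls.append(PloidyCall(chrom, state, m, mixture, len(vals)))
    return calls


def _runs(mask: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    runs = []
    start = prev = idx[0]
    for i in idx[1:]:
        if i - prev <= max_gap + 1:
            prev = i
        else:
            runs.append((int(start), int(prev)))
            start = prev = i
    runs.append((int(start), int(prev)))
    return runs


def detect_segments(
    track: RatioTrack,
    gain_threshold: float = 1.25,
    loss_threshold: float = 0.75,
    min_run: int = 10,
    max_gap: int = 2,
    filter_window: int = 5,
) -> list[Segment]:
    """Maximal runs of median-filtered bins beyond the gain/loss thresholds.

    Runs shorter than ``min_run`` bins are discarded; runs separated by at
    most ``max_gap`` bins are merged.
    """
    segments = []
    for chrom, arr in track.ratios.items():
        filled = np.where(np.isnan(arr), 1.0, arr)  # masked bins read as neutral
        smooth = median_filter(filled, size=filter_window, mode="nearest")
        for kind, mask in (
            ("gain", smooth >= gain_threshold),
            ("loss", smooth <= loss_threshold),
        ):
            for b0, b1 in _runs(mask, max_gap):
                if b1 - b0 + 1 < min_run:
                    continue
                start = b0 * track.bin_size + 1
                end = min((b1 + 1) * track.bin_size, track.chrom_lengths[chrom])
                segments.append(
                    Segment(chrom, start, end, kind, float(np.nanmean(arr[b0 : b1 + 1])))
                )
    return sorted(segments, key=lambda s: (s.chrom, s.start))


def write_segments_bed(segments: list[Segment], path: str) -> None:
    with open(path, "w") as fh:
        for s in segments:
            fh.write(f"{s.chrom}\t{s.start - 1}\t{s.end}\t{s.kind}\t{s.mean_ratio:.4g}\n")
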