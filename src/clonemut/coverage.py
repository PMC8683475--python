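"""Binned read-depth tracks for effective-genome and copy-number analyses."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import GenomeModel


@dataclass
class CoverageTrack:
    """Per-chromosome binned mean read depth.

    ``depths[chrom][i]`` is the mean per-base depth of the i-th bin,
    covering 0-based [i*bin_size, min((i+1)*bin_size, length)).  Bins tile
    each chromosome; the last bin may be shorter.
    """

    depths: dict[str, np.ndarray]
    bin_size: int
    chrom_lengths: dict[str, int]
    sample: str = ""

    def __post_init__(self) -> None:
        for chrom, arr in self.depths.items():
            n_expected = -(-self.chrom_lengths[chrom] // self.bin_size)
            if len(arr) != n_expected:
                raise ValueError(
                    f"{chrom}: {len(arr)} bins, expected {n_expected} "
                    f"for length {self.chrom_lengths[chrom]} at bin {self.bin_size}"
                )
            if np.any(arr < 0):
                raise ValueError(f"{chrom}: negative depths")

    def bin_lengths(self, chrom: str) -> np.ndarray:
        """Base-pair length of each bin (last one may be partial)."""
        n = len(self.depths[chrom])
        lengths = np.full(n, self.bin_size, dtype=np.int64)
        lengths[-1] = self.chrom_lengths[chrom] - (n - 1) * self.bin_size
        return lengths

    def same_grid(self, other: "CoverageTrack") -> bool:
        return (
            self.bin_size == other.bin_size
            and set(self.depths) == set(other.depths)
            and self.chrom_lengths == other.chrom_lengths
        )


def simulate_coverage(
    genome: GenomeModel,
    mean_depth: float,
    bin_size: int,
    rng: np.random.Generator,
    read_length: int = 150,
    sample: str = "",
) -> CoverageTrack:
    """Coverage with Poisson read-count noise per bin.

    Read starts are uniform, so the number of reads overlapping a bin is
    Poisson with mean ``depth * bin_len / read_length``; bin depth is
    reads * read_length / bin_len.
    """
    depths: dict[str, np.ndarray] = {}
    lengths: dict[str, int] = {}
    for c in genome.chromosomes:
        n = -(-c.length // bin_size)
        bin_len = np.full(n, bin_size, dtype=np.int64)
        bin_len[-1] = c.length - (n - 1) * bin_size
        reads = rng.poisson(mean_depth * bin_len / read_length)
        depths[c.name] = reads * read_length / bin_len
        lengths[c.name] = c.length
    return CoverageTrack(depths, bin_size, lengths, sample)


def write_coverage(track: CoverageTrack, path: str) -> None:
    rows = []
    for chrom in track.depths:
        starts = np.arange(len(track.depths[chrom]), dtype=np.int64) * track.bin_size
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "bin_start": starts,
                    "chrom_length": track.chrom_lengths[chrom],
                    "depth": track.depths[chrom],
                }
            )
        )
    df = pd.concat(rows, ignore_index=True)
    df.insert(0, "sample", track.sample)
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_coverage(path: str) -> CoverageTrack:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise ValueError(f"empty coverage file: {path}")
    starts = df.groupby("chrom", sort=False)["bin_start"].apply(np.asarray)
    bin_size = None
    for chrom, s in starts.items():
        if len(s) > 1:
            bin_size = int(s[1] - s[0])
            break
    if bin_size is None:
        bin_size = int(df["chrom_length"].max())
    depths = {
        chrom: sub["depth"].to_numpy(dtype=float)
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    lengths = {
        chrom: int(sub["chrom_length"].iloc[0])
        for chrom, sub in df.groupby("chrom", sort=False)
    }
    sample = str(df["sample"].iloc[0]) if "sample" in df else ""
    return CoverageTrack(depths, bin_size, lengths, sample)
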