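"""Chromosome/arm coordinate system and the fixed bin grid all signals live on.

Coordinates are 0-based half-open bp internally. Every chromosome is split by
its centromere into a p arm ``[0, cen)`` and a q arm ``[cen, length)``; bins
never cross the centromere, so arm-level statistics are exact sums of bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenomeModel", "BinGrid", "build_genome", "make_bins", "HG38_TABLE"]

# Approximate hg38 autosome + X lengths and centromere midpoints (bp).
HG38_TABLE: dict[str, tuple[int, int]] = {
    "1": (248_956_422, 123_400_000),
    "2": (242_193_529, 93_900_000),
    "3": (198_295_559, 90_900_000),
    "4": (190_214_555, 50_000_000),
    "5": (181_538_259, 48_800_000),
    "6": (170_805_979, 59_800_000),
    "7": (159_345_973, 60_100_000),
    "8": (145_138_636, 45_200_000),
    "9": (138_394_717, 43_000_000),
    "10": (133_797_422, 39_800_000),
    "11": (135_086_622, 53_400_000),
    "12": (133_275_309, 35_500_000),
    "13": (114_364_328, 17_700_000),
    "14": (107_043_718, 17_200_000),
    "15": (101_991_189, 19_000_000),
    "16": (90_338_345, 36_800_000),
    "17": (83_257_441, 25_100_000),
    "18": (80_373_285, 18_500_000),
    "19": (58_617_616, 26_200_000),
    "20": (64_444_167, 28_100_000),
    "21": (46_709_983, 12_000_000),
    "22": (50_818_468, 15_000_000),
    "X": (156_040_895, 60_600_000),
}


@dataclass(frozen=True)
class GenomeModel:
    """Ordered chromosomes with lengths and centromere positions (bp)."""

    names: tuple[str, ...]
    lengths: tuple[int, ...]
    centromeres: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(set(self.names)) != len(self.names):
            raise ValueError("chromosome names must be unique")
        if len(self.names) != len(self.lengths) or len(self.names) != len(self.centromeres):
            raise ValueError("names, lengths and centromeres must align")
        for name, length, cen in zip(self.names, self.lengths, self.centromeres):
            if length <= 0:
                raise ValueError(f"chromosome {name}: non-positive length {length}")
            if not (0 < cen < length):
                raise ValueError(
                    f"chromosome {name}: centromere {cen} outside (0, {length})"
                )

    @property
    def total_length(self) -> int:
        return int(sum(self.lengths))

    def length_of(self, chrom: str) -> int:
        return self.lengths[self.index_of(chrom)]

    def centromere_of(self, chrom: str) -> int:
        return self.centromeres[self.index_of(chrom)]

    def index_of(self, chrom: str) -> int:
        try:
            return self.names.index(chrom)
        except ValueError:
            raise KeyError(f"unknown chromosome {chrom!r}") from None

    def arm_of(self, chrom: str, pos: int) -> str:
        return "p" if pos < self.centromere_of(chrom) else "q"

    def arm_names(self) -> list[str]:
        out = []
        for name in self.names:
            out.extend([f"{name}p", f"{name}q"])
        return out


@dataclass(frozen=True)
class BinGrid:
    """Fixed-width tiling of a genome; last bin of each arm may be short.

    ``bins`` has columns chrom, start, end, arm; rows are in genome order and
    cover every chromosome exactly with no gaps, overlaps, or
    centromere-spanning bins.
    """

    genome: GenomeModel
    bins: pd.DataFrame = field(repr=False)

    @property
    def n_bins(self) -> int:
        return len(self.bins)

    @property
    def lengths_bp(self) -> np.ndarray:
        return (self.bins["end"] - self.bins["start"]).to_numpy()

    @property
    def lengths_mb(self) -> np.ndarray:
        return self.lengths_bp / 1e6

    def chrom_mask(self, chrom: str) -> np.ndarray:
        self.genome.index_of(chrom)  # raises on unknown chromosome
        return (self.bins["chrom"] == chrom).to_numpy()

    def arm_labels(self) -> np.ndarray:
        return (self.bins["chrom"] + self.bins["arm"]).to_numpy()

    def bin_index(self, chrom: str, pos: int) -> int:
        """Index of the bin containing (chrom, pos)."""
        sub = self.bins[self.bins["chrom"] == chrom]
        i = np.searchsorted(sub["start"].to_numpy(), pos, side="right") - 1
        if i < 0 or pos >= sub["end"].iloc[i]:
            raise ValueError(f"position {chrom}:{pos} outside grid")
        return int(sub.index[i])

    def same_grid(self, other: "BinGrid") -> bool:
        return self.bins[["chrom", "start", "end"]].equals(
            other.bins[["chrom", "start", "end"]]
        )


def build_genome(config: dict | None = None, *, preset: str | None = None,
                 scale: float = 1.0) -> GenomeModel:
    """Build a genome from an explicit config or the ``"hg38-like"`` preset.

    Parameters
    ----------
    config
        Mapping with keys ``lengths`` (list of bp), optional ``names``,
        and ``centromere`` (single fraction in (0,1) or list of positions/bp),
        or ``{"preset": "hg38-like", "scale": s}``.
    preset
        ``"hg38-like"`` embeds the autosome+X length/centromere table.
    scale
        Multiply all coordinates by this factor (e.g. 0.1 for a fast
        1/10-scale genome with identical arm structure).
    """
    config = dict(config or {})
    preset = config.pop("preset", preset)
    scale = float(config.pop("scale", scale))
    if scale <= 0:
        raise ValueError(f"scale must be positive, got {scale}")

    if preset is not None:
        if preset != "hg38-like":
            raise ValueError(f"unknown preset {preset!r}")
        names = tuple(HG38_TABLE)
        lengths = tuple(max(1, round(HG38_TABLE[n][0] * scale)) for n in names)
        cens = tuple(max(1, round(HG38_TABLE[n][1] * scale)) for n in names)
        return GenomeModel(names, lengths, cens)

    if "lengths" not in config:
        raise ValueError("config must give 'lengths' or a preset")
    lengths = [round(float(x) * scale) for x in config["lengths"]]
    n = len(lengths)
    names = tuple(config.get("names", [str(i + 1) for i in range(n)]))
    cen = config.get("centromere", 0.5)
    if np.isscalar(cen):
        frac = float(cen)
        if not (0 < frac < 1):
            raise ValueError(f"centromere fraction {frac} outside (0, 1)")
        cens = tuple(round(L * frac) for L in lengths)
    else:
        cens = tuple(round(float(c) * scale) for c in cen)
    return GenomeModel(names, tuple(lengths), cens)


def make_bins(genome: GenomeModel, width: int = 1_000_000) -> BinGrid:
    """Tile every chromosome arm with half-open bins of the given width (bp)."""
    if width <= 0:
        raise ValueError(f"bin width must be positive, got {width}")
    rows: list[tuple[str, int, int, str]] = []
    for name, length, cen in zip(genome.names, genome.lengths, genome.centromeres):
        for arm, lo, hi in (("p", 0, cen), ("q", cen, length)):
            start = lo
            while start < hi:
                end = min(start + width, hi)
                rows.append((name, start, end, arm))
                start = end
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "arm"])
    return BinGrid(genome=genome, bins=bins)
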