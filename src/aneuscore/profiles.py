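"""Per-sample signal containers: probe-level, segmented, and binned log2 ratios."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeModel

__all__ = ["ProbeSignal", "SegmentProfile", "BinnedProfile", "bin_profile"]

log = logging.getLogger(__name__)


@dataclass
class ProbeSignal:
    """Probe-level log2 ratios for one sample.

    ``probes`` has columns chrom, pos, logr, sorted by (chromosome order,
    position); logR is the log2 observed-to-reference intensity ratio.
    """

    sample_id: str
    probes: pd.DataFrame = field(repr=False)
    genome: GenomeModel | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "pos", "logr"}
        missing = required - set(self.probes.columns)
        if missing:
            raise ValueError(f"probe table missing columns: {sorted(missing)}")
        if not np.isfinite(self.probes["logr"].to_numpy(dtype=float)).all():
            raise ValueError("probe logR values must be finite")
        if self.genome is not None:
            order = {n: i for i, n in enumerate(self.genome.names)}
            key = self.probes["chrom"].map(order)
            if key.isna().any():
                bad = self.probes.loc[key.isna(), "chrom"].unique()
                raise ValueError(f"probes on unknown chromosomes: {list(bad)}")
            self.probes = (
                self.probes.assign(_k=key)
                .sort_values(["_k", "pos"], kind="stable")
                .drop(columns="_k")
                .reset_index(drop=True)
            )
            for chrom, sub in self.probes.groupby("chrom", sort=False):
                length = self.genome.length_of(chrom)
                if (sub["pos"] < 0).any() or (sub["pos"] >= length).any():
                    raise ValueError(f"probe positions outside chromosome {chrom}")

    @property
    def n_probes(self) -> int:
        return len(self.probes)


@dataclass
class SegmentProfile:
    """Segmented log2-ratio profile: constant-mean genomic runs for one sample.

    ``segments`` has columns chrom, start, end (0-based half-open bp),
    logr (segment mean), n_probes; non-overlapping and sorted.
    """

    sample_id: str
    segments: pd.DataFrame = field(repr=False)
    genome: GenomeModel | None = None

    def __post_init__(self) -> None:
        required = {"chrom", "start", "end", "logr", "n_probes"}
        missing = required - set(self.segments.columns)
        if missing:
            raise ValueError(f"segment table missing columns: {sorted(missing)}")
        seg = self.segments
        if (seg["end"] <= seg["start"]).any():
            raise ValueError("segments must have end > start")
        for chrom, sub in seg.groupby("chrom", sort=False):
            s = sub.sort_values("start")
            if (s["start"].to_numpy()[1:] < s["end"].to_numpy()[:-1]).any():
                raise ValueError(f"overlapping segments on chromosome {chrom}")
            if self.genome is not None:
                if (s["end"] > self.genome.length_of(chrom)).any():
                    raise ValueError(f"segment beyond chromosome {chrom} bounds")

    @property
    def total_length(self) -> int:
        return int((self.segments["end"] - self.segments["start"]).sum())


@dataclass
class BinnedProfile:
    """One logR value per bin of a BinGrid (length-weighted segment means)."""

    sample_id: str
    grid: BinGrid
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.n_bins,):
            raise ValueError(
                f"expected {self.grid.n_bins} bin values, got {self.values.shape}"
            )
        if not np.isfinite(self.values).all():
            raise ValueError("binned logR values must be finite")


def bin_profile(seg: SegmentProfile, grid: BinGrid,
                min_coverage: float = 0.99) -> BinnedProfile:
    """Project a SegmentProfile onto a BinGrid.

    Each bin receives the length-weighted mean logR of the segments that
    overlap it; bins not touched by any segment get 0 (with a warning).
    Raises if the segments cover less than ``min_coverage`` of the grid span.
    """
    if len(seg.segments) == 0:
        raise ValueError("empty segment profile")
    if seg.genome is not None and set(seg.segments["chrom"]) - set(grid.genome.names):
        raise ValueError("segment chromosomes not in grid genome")

    n = grid.n_bins
    wsum = np.zeros(n)
    cov = np.zeros(n)
    starts = grid.bins["start"].to_numpy()
    ends = grid.bins["end"].to_numpy()
    chrom_arr = grid.bins["chrom"].to_numpy()

    for chrom, sub in seg.segments.groupby("chrom", sort=False):
        mask = chrom_arr == chrom
        if not mask.any():
            raise ValueError(f"chromosome {chrom} not present in grid")
        idx = np.flatnonzero(mask)
        cstarts, cends = starts[idx], ends[idx]
        for s, e, v in zip(sub["start"], sub["end"], sub["logr"]):
            lo = np.searchsorted(cends, s, side="right")
            hi = np.searchsorted(cstarts, e, side="left")
            for j in range(lo, hi):
                ov = min(e, cends[j]) - max(s, cstarts[j])
                if ov > 0:
                    wsum[idx[j]] += v * ov
                    cov[idx[j]] += ov

    total_cov = cov.sum()
    span = grid.lengths_bp.sum()
    if total_cov / span < min_coverage:
        raise ValueError(
            f"segments cover {total_cov / span:.1%} of grid span "
            f"(< {min_coverage:.0%} required)"
        )
    values = np.zeros(n)
    covered = cov > 0
    values[covered] = wsum[covered] / cov[covered]
    if (~covered).any():
        log.warning(
            "%s: %d/%d bins uncovered by segments; set to 0",
            seg.sample_id, int((~covered).sum()), n,
        )
    return BinnedProfile(sample_id=seg.sample_id, grid=grid, values=values)
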