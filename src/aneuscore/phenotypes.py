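"""Closed-form phenotype computations: doubling time, tumor volume, migration."""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .simulate import GrowthCurve

__all__ = ["DoublingTimeResult", "doubling_time", "tumor_volume",
           "relative_migration"]

log = logging.getLogger(__name__)


@dataclass
class DoublingTimeResult:
    hours: float          # nan when the culture did not grow
    non_growing: bool
    mode: str


def doubling_time(curve: GrowthCurve, mode: str = "endpoint") -> DoublingTimeResult:
    """Population doubling time in hours.

    ``endpoint`` (default) applies Td = duration * log(2) / (log(final) -
    log(initial)) between the first and last timepoints; ``fit`` regresses
    log2(count) on time over all points (more robust to noise). A final
    count at or below the initial one is flagged non-growing, not an error.
    """
    t, n = curve.times_h, curve.counts
    if mode == "endpoint":
        duration = t[-1] - t[0]
        if n[-1] <= n[0]:
            log.warning("%s: final count <= initial; non-growing", curve.sample_id)
            return DoublingTimeResult(math.nan, True, mode)
        td = duration * math.log(2) / (math.log(n[-1]) - math.log(n[0]))
        return DoublingTimeResult(float(td), False, mode)
    if mode == "fit":
        slope = stats.linregress(t, np.log2(n)).slope
        if slope <= 0:
            log.warning("%s: non-positive growth slope; non-growing",
                        curve.sample_id)
            return DoublingTimeResult(math.nan, True, mode)
        return DoublingTimeResult(float(1.0 / slope), False, mode)
    raise ValueError(f"unknown mode {mode!r}")


def tumor_volume(width: float, length: float) -> float:
    """Caliper tumor volume, width^2 x length / 2 (mm^3).

    Width is the shorter axis by convention; swapped inputs are corrected
    with a warning.
    """
    if width < 0 or length < 0:
        raise ValueError("caliper measurements must be non-negative")
    if width > length:
        log.warning("width %.3g > length %.3g; swapping to caliper convention",
                    width, length)
        width, length = length, width
    return width ** 2 * length / 2.0


def relative_migration(migrated_count: float, total_count: float) -> float:
    """Migrated cells normalized to the total number of cells seeded."""
    if total_count <= 0:
        raise ValueError("total cell count must be positive")
    if migrated_count < 0:
        raise ValueError("migrated count must be non-negative")
    return migrated_count / total_count
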