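"""Aneuploidy score, fraction genome altered, quantile classes, frequency
tracks, and per-arm group comparisons.

The aneuploidy score (AS) of a sample is the sum of absolute segmented log2
ratios computed *relative to the parental clone's profile*, so alterations
shared with the ancestor cancel. Because the unit of the raw sum depends on
what is summed over, the weighting is configurable: per megabase (default,
invariant to probe density and bin width), per bin, or per constant-value
segment run. FGA is the fraction of total segmented length whose segments
exceed |logR| 0.2 (strictly).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .genome import GenomeModel
from .profiles import BinnedProfile, SegmentProfile

__all__ = [
    "AneuploidyResult", "FrequencyTrack", "relative_profile",
    "aneuploidy_score", "fraction_genome_altered", "classify_by_quantile",
    "alteration_frequency", "compare_arms", "chromosome_mean_copy",
    "score_cohort",
]

CLASS_LOW = "aneuploid_low"
CLASS_MID = "intermediate"
CLASS_HIGH = "aneuploid_high"


@dataclass
class AneuploidyResult:
    sample_id: str
    aneuploidy_score: float
    fga: float
    label: str | None = None

    def __post_init__(self) -> None:
        if self.aneuploidy_score < 0:
            raise ValueError("aneuploidy score must be >= 0")
        if not (0.0 <= self.fga <= 1.0):
            raise ValueError("FGA must lie in [0, 1]")


@dataclass
class FrequencyTrack:
    """Per-bin fraction of group samples called gained / lost."""

    group: str
    n: int
    gain_frac: np.ndarray
    loss_frac: np.ndarray
    track: pd.DataFrame = field(repr=False)


def relative_profile(sample: BinnedProfile, parental: BinnedProfile) -> BinnedProfile:
    """Bin-wise difference sample - parental (ancestral alterations cancel)."""
    if not sample.grid.same_grid(parental.grid):
        raise ValueError("sample and parental profiles use different bin grids")
    return BinnedProfile(sample_id=sample.sample_id, grid=sample.grid,
                         values=sample.values - parental.values)


def aneuploidy_score(rel: BinnedProfile, mode: str = "per_Mb") -> float:
    """Sum of absolute logR over the (parental-relative) binned profile.

    Modes: ``per_Mb`` (|logR| x bin length in Mb, default), ``per_bin``
    (plain sum over bins), ``per_segment`` (one |logR| term per maximal run
    of constant value).
    """
    v = rel.values
    if mode == "per_Mb":
        return float(np.sum(np.abs(v) * rel.grid.lengths_mb))
    if mode == "per_bin":
        return float(np.sum(np.abs(v)))
    if mode == "per_segment":
        chroms = rel.grid.bins["chrom"].to_numpy()
        new_run = np.ones(len(v), dtype=bool)
        new_run[1:] = (v[1:] != v[:-1]) | (chroms[1:] != chroms[:-1])
        return float(np.sum(np.abs(v[new_run])))
    raise ValueError(f"unknown AS mode {mode!r}")


def fraction_genome_altered(seg: SegmentProfile, threshold: float = 0.2) -> float:
    """Length of segments with |mean logR| strictly > threshold over total length."""
    segs = seg.segments
    if len(segs) == 0:
        raise ValueError("empty segment profile")
    lengths = (segs["end"] - segs["start"]).to_numpy(dtype=float)
    altered = np.abs(segs["logr"].to_numpy(dtype=float)) > threshold
    return float(lengths[altered].sum() / lengths.sum())


def classify_by_quantile(values) -> np.ndarray:
    """Quartile classes: <=Q1 boundary -> aneuploid_low, >=Q3 -> aneuploid_high.

    Boundaries use the linear-interpolation empirical quantile; both extreme
    classes are boundary-inclusive. All-identical values yield all
    intermediate with a warning; fewer than 4 samples is an error.
    """
    v = np.asarray(pd.Series(values).to_numpy(), dtype=float)
    if len(v) < 4:
        raise ValueError(f"need >= 4 samples for quartile classes, got {len(v)}")
    if np.ptp(v) == 0:
        warnings.warn("all values identical; every sample classed intermediate")
        return np.full(len(v), CLASS_MID, dtype=object)
    q1, q3 = np.quantile(v, [0.25, 0.75])
    out = np.full(len(v), CLASS_MID, dtype=object)
    out[v <= q1] = CLASS_LOW
    out[v >= q3] = CLASS_HIGH
    return out


def score_cohort(relative_profiles: list[BinnedProfile],
                 seg_profiles: list[SegmentProfile] | None = None,
                 mode: str = "per_Mb",
                 fga_threshold: float = 0.2) -> pd.DataFrame:
    """Per-sample AS (+ FGA when segment profiles are given) with quartile class."""
    ids = [p.sample_id for p in relative_profiles]
    scores = [aneuploidy_score(p, mode=mode) for p in relative_profiles]
    df = pd.DataFrame({"sample_id": ids, "aneuploidy_score": scores})
    if seg_profiles is not None:
        by_id = {s.sample_id: s for s in seg_profiles}
        df["fga"] = [fraction_genome_altered(by_id[i], fga_threshold) for i in ids]
    df["label"] = classify_by_quantile(df["aneuploidy_score"])
    return df


def alteration_frequency(group: list[BinnedProfile],
                         call_threshold: float = 0.2,
                         group_label: str = "group") -> FrequencyTrack:
    """Fraction of (parental-relative) profiles gained/lost per bin."""
    if len(group) == 0:
        raise ValueError("empty group")
    grid = group[0].grid
    mat = np.vstack([p.values for p in group])
    gain = (mat > call_threshold).mean(axis=0)
    loss = (mat < -call_threshold).mean(axis=0)
    track = grid.bins[["chrom", "start", "end", "arm"]].copy()
    track["gain_frac"] = gain
    track["loss_frac"] = loss
    return FrequencyTrack(group=group_label, n=len(group), gain_frac=gain,
                          loss_frac=loss, track=track)


def _arm_means(profiles: list[BinnedProfile]) -> pd.DataFrame:
    """Bin-length-weighted mean logR per arm, one row per sample."""
    grid = profiles[0].grid
    arms = grid.arm_labels()
    w = grid.lengths_bp.astype(float)
    arm_names = [a for a in grid.genome.arm_names() if (arms == a).any()]
    rows = {}
    for p in profiles:
        rows[p.sample_id] = [
            float(np.average(p.values[arms == a], weights=w[arms == a]))
            for a in arm_names
        ]
    return pd.DataFrame.from_dict(rows, orient="index", columns=arm_names)


def compare_arms(group_a: list[BinnedProfile], group_b: list[BinnedProfile],
                 genome: GenomeModel | None = None, fdr_q: float = 0.1,
                 equal_var: bool = False) -> pd.DataFrame:
    """Two-sided two-sample t test per chromosome arm, BH-adjusted.

    Welch by default (``equal_var=True`` for the pooled Student variant).
    Arms where both groups are identical constants get t=0, p=1. Returns a
    table (arm, mean_a, mean_b, t, p, p_adj, significant).
    """
    if len(group_a) < 2 or len(group_b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if not group_a[0].grid.same_grid(group_b[0].grid):
        raise ValueError("groups are on different bin grids")
    ma = _arm_means(group_a)
    mb = _arm_means(group_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_ind(ma.to_numpy(), mb.to_numpy(), axis=0,
                               equal_var=equal_var)
    # zero within-group variance and equal means: no evidence of difference
    degenerate = ~np.isfinite(t) & np.isclose(ma.mean(0), mb.mean(0))
    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    if np.isnan(p).any():
        raise ValueError("t-test produced NaN p-values on non-degenerate arms")
    _, p_adj, _, _ = multipletests(p, method="fdr_bh")
    return pd.DataFrame({
        "arm": ma.columns,
        "mean_a": ma.mean(0).to_numpy(),
        "mean_b": mb.mean(0).to_numpy(),
        "t": t,
        "p": p,
        "p_adj": p_adj,
        "significant": p_adj < fdr_q,
    })


def chromosome_mean_copy(profile: BinnedProfile | SegmentProfile,
                         chrom: str) -> float:
    """Average copy number of a chromosome: 2 * 2**(length-weighted mean logR)."""
    if isinstance(profile, BinnedProfile):
        mask = profile.grid.chrom_mask(chrom)
        if not mask.any():
            raise ValueError(f"chromosome {chrom!r} has no bins")
        m = float(np.average(profile.values[mask],
                             weights=profile.grid.lengths_bp[mask]))
    else:
        sub = profile.segments[profile.segments["chrom"] == chrom]
        if len(sub) == 0:
            raise ValueError(f"chromosome {chrom!r} not in profile")
        w = (sub["end"] - sub["start"]).to_numpy(dtype=float)
        m = float(np.average(sub["logr"].to_numpy(), weights=w))
    return float(2.0 * 2.0 ** m)
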