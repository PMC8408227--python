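"""Kaplan-Meier estimation and log-rank comparisons for aneuploidy strata.

Survival tables carry (sample_id, time, event) with time > 0 and event 1 for
progression/death, 0 for censoring. The stratified analysis splits each TP53
class into fraction-genome-altered quartiles (computed within the class by
default), keeps the aneuploid-low (Q1) and aneuploid-high (Q4) groups, and
compares them with the unweighted log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .metrics import CLASS_HIGH, CLASS_LOW, classify_by_quantile

__all__ = ["KMCurve", "LogrankResult", "km_curve", "logrank_test",
           "stratify_and_compare"]


@dataclass
class KMCurve:
    """Product-limit estimate: survival after each distinct event time."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n: int
    median: float                  # inf when the curve never reaches 0.5
    table: pd.DataFrame = field(repr=False, default=None)

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class LogrankResult:
    statistic: float
    df: int
    p: float

    def __post_init__(self) -> None:
        if self.statistic < 0:
            raise ValueError("log-rank statistic must be >= 0")
        if not (0 <= self.p <= 1):
            raise ValueError("p-value must lie in [0, 1]")


def _check_records(rec: pd.DataFrame) -> pd.DataFrame:
    for col in ("time", "event"):
        if col not in rec.columns:
            raise ValueError(f"survival table missing column {col!r}")
    if len(rec) == 0:
        raise ValueError("empty survival group")
    if (rec["time"] <= 0).any():
        raise ValueError("survival times must be positive")
    if not rec["event"].isin([0, 1]).all():
        raise ValueError("event indicator must be 0 or 1")
    return rec


def km_curve(records: pd.DataFrame, group: str = "") -> KMCurve:
    """Kaplan-Meier product-limit estimator for one group.

    Censored observations at an event time are conventionally at risk for
    that event (events break ties before censorings).
    """
    rec = _check_records(records)
    kmf = KaplanMeierFitter()
    kmf.fit(rec["time"], event_observed=rec["event"])
    ev = kmf.event_table
    ev = ev[ev["observed"] > 0]
    times = ev.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ev.index, "KM_estimate"].to_numpy()
    at_risk = ev["at_risk"].to_numpy(dtype=int)
    median = float(kmf.median_survival_time_)
    return KMCurve(group=group, times=times, survival=surv, at_risk=at_risk,
                   n=len(rec), median=median,
                   table=kmf.event_table)


def logrank_test(groups: dict[str, pd.DataFrame] | list[pd.DataFrame],
                 ) -> LogrankResult:
    """Unweighted log-rank test across >= 2 groups (chi-square, k-1 df)."""
    if isinstance(groups, dict):
        items = list(groups.items())
    else:
        items = [(str(i), g) for i, g in enumerate(groups)]
    if len(items) < 2:
        raise ValueError("need >= 2 groups")
    frames = []
    for label, rec in items:
        rec = _check_records(rec)
        frames.append(pd.DataFrame({
            "time": rec["time"].to_numpy(),
            "event": rec["event"].to_numpy(),
            "group": label,
        }))
    pooled = pd.concat(frames, ignore_index=True)
    res = multivariate_logrank_test(pooled["time"], pooled["group"],
                                    pooled["event"])
    return LogrankResult(statistic=float(res.test_statistic),
                         df=len(items) - 1, p=float(res.p_value))


def stratify_and_compare(records: pd.DataFrame,
                         per_class_quartiles: bool = True) -> dict:
    """Fig-7-style stratification: genotype comparison and, within each TP53
    class, aneuploid-low (FGA Q1) vs aneuploid-high (FGA Q4).

    ``records`` needs sample_id, time, event, fga, call. Quartile boundaries
    come from `classify_by_quantile` within each class (or pooled across
    classes with ``per_class_quartiles=False``); intermediate quartiles are
    dropped from the within-class comparison. Returns a dict with a
    ``"by_genotype"`` entry (curves + 3-way log-rank) and one entry per TP53
    class (Q1/Q4 curves + 2-way log-rank).
    """
    for col in ("fga", "call"):
        if col not in records.columns:
            raise ValueError(f"records missing column {col!r}")
    _check_records(records)

    out: dict = {}
    classes = [c for c in ("WT", "missense", "truncating")
               if (records["call"] == c).any()]
    by_geno = {c: records[records["call"] == c] for c in classes}
    out["by_genotype"] = {
        "curves": {c: km_curve(g, group=c) for c, g in by_geno.items()},
        "test": logrank_test(by_geno) if len(by_geno) >= 2 else None,
    }

    if not per_class_quartiles:
        pooled_labels = pd.Series(classify_by_quantile(records["fga"]),
                                  index=records.index)
    for c in classes:
        sub = records[records["call"] == c]
        if len(sub) < 4:
            raise ValueError(f"stratum {c!r} has {len(sub)} samples; "
                             "quartiles undefined below 4")
        if per_class_quartiles:
            labels = classify_by_quantile(sub["fga"])
        else:
            labels = pooled_labels.loc[sub.index].to_numpy()
        lo = sub[labels == CLASS_LOW]
        hi = sub[labels == CLASS_HIGH]
        out[c] = {
            "curves": {"Q1": km_curve(lo, group=f"{c}/Q1"),
                       "Q4": km_curve(hi, group=f"{c}/Q4")},
            "test": logrank_test({"Q1": lo, "Q4": hi}),
        }
    return out
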