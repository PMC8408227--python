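"""TP53 genotype calls from MAF-like mutation records.

Rules (tumor mode): a sample with sequencing data but no TP53 record, or only
silent/noncoding records, is WT; exactly one missense record is missense; one
truncating-class record (nonsense/stop-gain, frameshift, or splice-site) is
truncating; any in-frame indel, or more than one non-silent alteration of any
mix, removes the sample from analysis. Cell-line mode applies the same logic
(stop-gain is folded into nonsense as a synonym in both modes, so the modes
differ only in bookkeeping of the assayed flag).

Cohort-level filters drop cohorts with fewer than 20 missense individuals or
a missense frequency below 10%, and drop individuals with multiple tumors.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

__all__ = ["TP53Call", "normalize_classification", "classify_tp53",
           "classify_cohort", "apply_cohort_filters", "summarize_genotypes"]

# canonical codes
MISSENSE = "missense"
NONSENSE = "nonsense"
FRAMESHIFT = "frameshift"
SPLICE = "splice_site"
SILENT = "silent"
INFRAME = "in_frame_indel"
NONCODING = "noncoding"
OTHER = "other"

TRUNCATING_CODES = {NONSENSE, FRAMESHIFT, SPLICE}
IGNORED_CODES = {SILENT, NONCODING}

# Input aliases across MAF dialects (matched case-insensitively).
_ALIASES = {
    "missense": MISSENSE, "missense_mutation": MISSENSE,
    "nonsense": NONSENSE, "nonsense_mutation": NONSENSE,
    "stop_gain": NONSENSE, "stopgain": NONSENSE, "stop_gained": NONSENSE,
    "frameshift": FRAMESHIFT, "frame_shift_del": FRAMESHIFT,
    "frame_shift_ins": FRAMESHIFT, "frameshift_variant": FRAMESHIFT,
    "splice_site": SPLICE, "splice_site_variant": SPLICE,
    "silent": SILENT, "synonymous": SILENT, "synonymous_variant": SILENT,
    "in_frame_del": INFRAME, "in_frame_ins": INFRAME, "in_frame_indel": INFRAME,
    "intron": NONCODING, "3'utr": NONCODING, "5'utr": NONCODING,
    "3'flank": NONCODING, "5'flank": NONCODING, "igr": NONCODING,
    "rna": NONCODING, "noncoding": NONCODING,
    "nonstop_mutation": OTHER, "translation_start_site": OTHER, "other": OTHER,
}

CALL_WT = "WT"
CALL_MISSENSE = "missense"
CALL_TRUNCATING = "truncating"
CALL_EXCLUDED = "excluded"
CALL_NOT_ASSAYED = "not_assayed"

REASON_MULTI = "multiple alterations"
REASON_INFRAME = "in-frame"
REASON_UNCLASSIFIABLE = "unclassifiable alteration"


@dataclass
class TP53Call:
    sample_id: str
    call: str
    reason: str = ""

    def __post_init__(self) -> None:
        if self.call == CALL_EXCLUDED and not self.reason:
            raise ValueError("excluded calls must carry a reason")


def normalize_classification(value: str) -> str:
    key = str(value).strip().lower()
    if key in _ALIASES:
        return _ALIASES[key]
    raise ValueError(f"unknown variant classification {value!r}")


def classify_tp53(records, sample_id: str, mode: str = "tumor",
                  assayed: bool = True) -> TP53Call:
    """Call one sample's TP53 genotype from its (TP53-only) mutation records.

    ``records`` is an iterable/Series/DataFrame-column of variant
    classification strings in any accepted dialect. The call is independent
    of record order.
    """
    if mode not in ("tumor", "cell_line"):
        raise ValueError(f"unknown mode {mode!r}")
    if mode == "tumor" and not assayed:
        return TP53Call(sample_id, CALL_NOT_ASSAYED)
    if isinstance(records, pd.DataFrame):
        records = records["Variant_Classification"]
    codes = [normalize_classification(v) for v in records]
    alterations = [c for c in codes if c not in IGNORED_CODES]
    if any(c == INFRAME for c in alterations):
        return TP53Call(sample_id, CALL_EXCLUDED, REASON_INFRAME)
    if len(alterations) == 0:
        return TP53Call(sample_id, CALL_WT)
    if len(alterations) > 1:
        return TP53Call(sample_id, CALL_EXCLUDED, REASON_MULTI)
    code = alterations[0]
    if code == MISSENSE:
        return TP53Call(sample_id, CALL_MISSENSE)
    if code in TRUNCATING_CODES:
        return TP53Call(sample_id, CALL_TRUNCATING)
    return TP53Call(sample_id, CALL_EXCLUDED, REASON_UNCLASSIFIABLE)


def classify_cohort(maf: pd.DataFrame, sample_ids, mode: str = "tumor",
                    assayed=None) -> pd.DataFrame:
    """Call every sample in ``sample_ids`` (absent from the MAF -> WT).

    ``maf`` needs Tumor_Sample_Barcode and Variant_Classification columns
    (rows for genes other than TP53 are dropped if Hugo_Symbol is present);
    ``assayed`` is an optional set of samples with sequencing data (default:
    all of ``sample_ids``).
    """
    if "Hugo_Symbol" in maf.columns:
        maf = maf[maf["Hugo_Symbol"] == "TP53"]
    assayed = set(sample_ids) if assayed is None else set(assayed)
    grouped = dict(list(maf.groupby("Tumor_Sample_Barcode")))
    rows = []
    for sid in sample_ids:
        sub = grouped.get(sid)
        recs = sub["Variant_Classification"] if sub is not None else []
        call = classify_tp53(recs, sid, mode=mode, assayed=sid in assayed)
        rows.append((call.sample_id, call.call, call.reason))
    return pd.DataFrame(rows, columns=["sample_id", "call", "reason"])


def apply_cohort_filters(calls: pd.DataFrame,
                         min_missense: int = 20,
                         min_missense_freq: float = 0.10,
                         ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort- and individual-level exclusions.

    ``calls`` needs sample_id, call, cohort; optional individual_id (for the
    multiple-tumor rule). Drops, in order: individuals with more than one
    tumor sample; cohorts with fewer than ``min_missense`` missense
    individuals; cohorts whose missense frequency among classified samples
    is below ``min_missense_freq``. Returns (kept, exclusion report).
    """
    if "cohort" not in calls.columns:
        raise ValueError("calls table must carry a 'cohort' column")
    kept = calls.copy()
    report = []

    if "individual_id" in kept.columns:
        counts = kept["individual_id"].value_counts()
        multi = set(counts[counts > 1].index)
        for _, row in kept[kept["individual_id"].isin(multi)].iterrows():
            report.append((row["sample_id"], row["cohort"], "multiple tumors"))
        kept = kept[~kept["individual_id"].isin(multi)]

    for cohort, sub in kept.groupby("cohort"):
        classified = sub[sub["call"].isin([CALL_WT, CALL_MISSENSE,
                                           CALL_TRUNCATING])]
        n_mis = int((classified["call"] == CALL_MISSENSE).sum())
        rule = None
        if n_mis < min_missense:
            rule = f"fewer than {min_missense} missense individuals"
        elif len(classified) and n_mis / len(classified) < min_missense_freq:
            rule = f"missense frequency below {min_missense_freq:.0%}"
        if rule is not None:
            for sid in sub["sample_id"]:
                report.append((sid, cohort, rule))
            kept = kept[kept["cohort"] != cohort]

    report_df = pd.DataFrame(report, columns=["sample_id", "cohort", "rule"])
    return kept.reset_index(drop=True), report_df


def summarize_genotypes(calls: pd.DataFrame) -> pd.DataFrame:
    """Contingency counts of calls, per cohort when a cohort column exists."""
    order = [CALL_WT, CALL_MISSENSE, CALL_TRUNCATING, CALL_EXCLUDED,
             CALL_NOT_ASSAYED]
    if len(calls) == 0:
        return pd.DataFrame(0, index=["all"], columns=order)
    if "cohort" in calls.columns:
        tab = calls.groupby("cohort")["call"].value_counts().unstack(fill_value=0)
    else:
        tab = calls["call"].value_counts().to_frame().T
        tab.index = ["all"]
    for c in order:
        if c not in tab.columns:
            tab[c] = 0
    return tab[order]
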