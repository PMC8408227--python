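"""File formats: SEG reader/writer, typed TSV tables, run manifests.

SEG files are tab-separated with 1-based inclusive coordinates (ID, chrom,
loc.start, loc.end, num.mark, seg.mean); internal coordinates are 0-based
half-open, converted at the boundary. Chromosome names are normalized by
stripping a leading ``chr``. All tabular outputs are TSV.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import GenomeModel
from .profiles import ProbeSignal, SegmentProfile

__all__ = ["read_seg", "write_seg", "read_table", "read_survival", "read_maf",
           "read_growth", "read_expression", "read_gene_map",
           "write_probe_signal", "read_probe_signal", "RunManifest",
           "natural_chrom_key", "TABLE_SCHEMAS"]

SEG_COLUMNS = ["ID", "chrom", "loc.start", "loc.end", "num.mark", "seg.mean"]


def normalize_chrom(name: str) -> str:
    name = str(name).strip()
    return name[3:] if name.lower().startswith("chr") else name


def natural_chrom_key(name: str):
    """Sort key giving 1..22 numerically, then X, Y, then others."""
    name = normalize_chrom(name)
    if name.isdigit():
        return (0, int(name), "")
    if name in ("X", "Y"):
        return (1, "XY".index(name), "")
    return (2, 0, name)


def read_seg(path, genome: GenomeModel | None = None) -> list[SegmentProfile]:
    """Read a SEG file into one SegmentProfile per sample.

    Raises on overlapping segments (naming the sample and file lines) and on
    unparseable numeric fields (citing the line number).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    df.columns = [c.strip() for c in df.columns]
    rename = {}
    for col in df.columns:
        key = col.lower().replace("_", ".")
        if key in ("id", "sample", "sample.id"):
            rename[col] = "ID"
        elif key in ("chrom", "chromosome", "chr"):
            rename[col] = "chrom"
        elif key in ("loc.start", "start"):
            rename[col] = "loc.start"
        elif key in ("loc.end", "end"):
            rename[col] = "loc.end"
        elif key in ("num.mark", "num.probes", "nummark"):
            rename[col] = "num.mark"
        elif key in ("seg.mean", "segmean", "mean"):
            rename[col] = "seg.mean"
    df = df.rename(columns=rename)
    required = {"ID", "chrom", "loc.start", "loc.end", "seg.mean"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing SEG columns {sorted(missing)}")

    for col in ("loc.start", "loc.end", "seg.mean"):
        try:
            df[col] = pd.to_numeric(df[col])
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce").isna()
            line = int(df.index[bad][0]) + 2   # header + 1-based
            raise ValueError(
                f"{path}: unparseable {col!r} value on line {line}") from None
    if "num.mark" not in df.columns:
        df["num.mark"] = 0
    df["num.mark"] = pd.to_numeric(df["num.mark"]).astype(int)
    df["chrom"] = df["chrom"].map(normalize_chrom)

    profiles = []
    for sample, sub in df.groupby("ID", sort=False):
        seg = pd.DataFrame({
            "chrom": sub["chrom"].to_numpy(),
            "start": sub["loc.start"].to_numpy(dtype=int) - 1,
            "end": sub["loc.end"].to_numpy(dtype=int),
            "logr": sub["seg.mean"].to_numpy(dtype=float),
            "n_probes": sub["num.mark"].to_numpy(),
        }, index=sub.index)
        for chrom, rows in seg.groupby("chrom", sort=False):
            rows = rows.sort_values("start")
            overlap = rows["start"].to_numpy()[1:] < rows["end"].to_numpy()[:-1]
            if overlap.any():
                k = int(np.flatnonzero(overlap)[0])
                l1 = int(rows.index[k]) + 2
                l2 = int(rows.index[k + 1]) + 2
                raise ValueError(
                    f"{path}: overlapping segments for sample {sample!r} on "
                    f"chromosome {chrom} (lines {l1} and {l2})")
        key = seg["chrom"].map(natural_chrom_key)
        seg = (seg.assign(_k=key).sort_values(["_k", "start"])
               .drop(columns="_k").reset_index(drop=True))
        profiles.append(SegmentProfile(sample_id=str(sample), segments=seg,
                                       genome=genome))
    return profiles


def write_seg(profiles: list[SegmentProfile] | SegmentProfile, path) -> None:
    """Write SegmentProfiles as a standard SEG file (1-based inclusive)."""
    if isinstance(profiles, SegmentProfile):
        profiles = [profiles]
    rows = []
    for p in profiles:
        for _, s in p.segments.iterrows():
            rows.append((p.sample_id, s["chrom"], int(s["start"]) + 1,
                         int(s["end"]), int(s["n_probes"]),
                         float(s["logr"])))
    out = pd.DataFrame(rows, columns=SEG_COLUMNS)
    out.to_csv(path, sep="\t", index=False, float_format="%.17g")


TABLE_SCHEMAS = {
    "survival": {"required": {"sample_id": str, "time": float, "event": int}},
    "growth": {"required": {"sample_id": str, "time_h": float, "count": float}},
    "maf": {"required": {"Tumor_Sample_Barcode": str,
                         "Variant_Classification": str}},
    "gene_map": {"required": {"gene": str, "chrom": str, "pos": int}},
    "metrics": {"required": {"sample_id": str, "aneuploidy_score": float}},
    "probes": {"required": {"sample_id": str, "chrom": str, "pos": int,
                            "logr": float}},
}


def read_table(path, schema: str) -> pd.DataFrame:
    """Read a TSV against a named schema; extra columns are preserved."""
    if schema not in TABLE_SCHEMAS:
        raise ValueError(f"unknown schema {schema!r}")
    spec = TABLE_SCHEMAS[schema]["required"]
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = set(spec) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    for col, typ in spec.items():
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{path}: column {col!r} not coercible to "
                             f"{typ.__name__}: {exc}") from None
    return df


def read_survival(path) -> pd.DataFrame:
    return read_table(path, "survival")


def read_maf(path) -> pd.DataFrame:
    return read_table(path, "maf")


def read_growth(path) -> pd.DataFrame:
    return read_table(path, "growth")


def read_gene_map(path) -> pd.DataFrame:
    return read_table(path, "gene_map")


def read_expression(path) -> pd.DataFrame:
    """Genes x samples TSV with gene identifiers in the first column."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError(f"{path}: expression matrix contains missing values")
    return df


def write_probe_signal(signals: list[ProbeSignal] | ProbeSignal, path) -> None:
    if isinstance(signals, ProbeSignal):
        signals = [signals]
    frames = [s.probes.assign(sample_id=s.sample_id) for s in signals]
    out = pd.concat(frames, ignore_index=True)
    out[["sample_id", "chrom", "pos", "logr"]].to_csv(
        path, sep="\t", index=False, float_format="%.17g")


def read_probe_signal(path, genome: GenomeModel | None = None) -> list[ProbeSignal]:
    df = read_table(path, "probes")
    df["chrom"] = df["chrom"].map(normalize_chrom)
    return [ProbeSignal(sample_id=str(sid),
                        probes=sub[["chrom", "pos", "logr"]].reset_index(drop=True),
                        genome=genome)
            for sid, sub in df.groupby("sample_id", sort=False)]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record: config snapshot, seed, version, file digests."""

    seed: int
    config: dict
    version: str = ""
    inputs: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)
    timestamp: str = ""

    def add_input(self, path) -> None:
        self.inputs[str(path)] = _sha256(Path(path))

    def add_output(self, path) -> None:
        self.outputs[str(path)] = _sha256(Path(path))

    def write(self, path) -> None:
        if not self.version:
            from . import __version__
            self.version = __version__
        self.timestamp = time.strftime("%Y-%m-%dT%H:%M:%S")
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, sort_keys=True)
            fh.write("\n")
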