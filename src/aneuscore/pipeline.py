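"""End-to-end orchestration: simulate -> segment -> score -> downstream.

`run_all` wires every stage on one config and seed and writes TSV outputs
plus a run manifest; it is what the ``aneuscore run-all`` subcommand calls,
and it doubles as the reference in-silico experiment of the package.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .genome import build_genome, make_bins
from .metrics import (alteration_frequency, chromosome_mean_copy,
                      relative_profile, score_cohort)
from .dosage import chromosome_mean_expression, dosage_correlation
from .profiles import bin_profile
from .segment import SegmentationParams, segment_profile
from .seg_io import RunManifest, write_probe_signal, write_seg
from .simulate import (SimulationConfig, make_gene_map, render_probe_signal,
                       simulate_cohort_survival, simulate_expression,
                       simulate_karyotype, simulate_mutation_table)
from .tp53 import classify_cohort

log = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "genome": {"preset": "hg38-like", "scale": 0.1},
    "bin_width": 1_000_000,
    "n_samples": 12,
    "simulation": {},
    "segmentation": {},
}


def _merge_config(config: dict | None) -> dict:
    merged = {k: (dict(v) if isinstance(v, dict) else v)
              for k, v in DEFAULT_CONFIG.items()}
    for k, v in (config or {}).items():
        # the genome block is an alternative spec, not a partial override
        if k != "genome" and isinstance(v, dict) and isinstance(merged.get(k), dict):
            merged[k].update(v)
        else:
            merged[k] = v
    return merged


def simulate_cohort(config: dict | None, seed: int):
    """Simulate a clonal cohort; returns (genome, grid, tracks, signals, parental)."""
    cfg = _merge_config(config)
    genome = build_genome(cfg["genome"])
    grid = make_bins(genome, cfg["bin_width"])
    sim = SimulationConfig(seed=seed, **cfg["simulation"])
    rng = np.random.default_rng(seed)
    tracks, signals = [], []
    # sample 0 is the parental clone: no events by construction
    from .simulate import CopyNumberTrack
    parental_track = CopyNumberTrack(sample_id="P0", grid=grid,
                                     copies=np.full(grid.n_bins, 2))
    parental = render_probe_signal(parental_track, genome, sim.probe_density,
                                   sim.noise_sd, rng)
    for i in range(cfg["n_samples"]):
        track, _ = simulate_karyotype(genome, grid, sim, rng,
                                      sample_id=f"S{i:03d}")
        tracks.append(track)
        signals.append(render_probe_signal(track, genome, sim.probe_density,
                                           sim.noise_sd, rng))
    return genome, grid, tracks, signals, (parental_track, parental), sim


def run_all(config: dict | None, seed: int, out_dir) -> dict:
    """Run the full synthetic pipeline and write outputs under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = _merge_config(config)
    manifest = RunManifest(seed=seed, config=cfg)

    genome, grid, tracks, signals, (ptrack, psignal), sim = \
        simulate_cohort(cfg, seed)
    write_probe_signal([psignal] + signals, out / "probes.tsv")

    params = SegmentationParams(**cfg["segmentation"])
    seg_parental = segment_profile(psignal, params)
    segs = [segment_profile(s, params) for s in signals]
    write_seg([seg_parental] + segs, out / "segments.seg")

    parental_binned = bin_profile(seg_parental, grid)
    binned = [bin_profile(s, grid) for s in segs]
    rel = [relative_profile(b, parental_binned) for b in binned]

    metrics = score_cohort(rel, segs)
    metrics.to_csv(out / "metrics.tsv", sep="\t", index=False)

    freq = alteration_frequency(rel, group_label="all")
    freq.track.to_csv(out / "frequency.tsv", sep="\t", index=False)

    gene_map = make_gene_map(genome, grid, genes_per_chrom=40)
    expr = simulate_expression(tracks, gene_map, sim.dosage_slope,
                               sim.dispersion, np.random.default_rng(seed + 1))
    expr.to_csv(out / "expression.tsv", sep="\t")
    dosage_rows = []
    for chrom in genome.names:
        me = chromosome_mean_expression(expr, gene_map, chrom)
        cn = pd.Series({b.sample_id: chromosome_mean_copy(b, chrom)
                        for b in binned})
        res = dosage_correlation(me, cn, chrom=chrom)
        dosage_rows.append((chrom, res.r, res.p, res.n, res.slope,
                            res.undefined))
    pd.DataFrame(dosage_rows, columns=["chrom", "r", "p", "n", "slope",
                                       "undefined"]).to_csv(
        out / "dosage.tsv", sep="\t", index=False)

    maf, truth = simulate_mutation_table(sim.class_mix, cfg["n_samples"],
                                         np.random.default_rng(seed + 2))
    maf.to_csv(out / "mutations.tsv", sep="\t", index=False)
    calls = classify_cohort(maf, truth.index)
    calls.to_csv(out / "tp53_calls.tsv", sep="\t", index=False)

    surv = simulate_cohort_survival(
        pd.Series(metrics["fga"].to_numpy(),
                  index=truth.index[:len(metrics)]),
        sim.hazard_ratio, sim.baseline_hazard, sim.censor_rate,
        np.random.default_rng(seed + 3))
    surv.to_csv(out / "survival.tsv", sep="\t", index=False)

    for name in ("probes.tsv", "segments.seg", "metrics.tsv", "frequency.tsv",
                 "expression.tsv", "dosage.tsv", "mutations.tsv",
                 "tp53_calls.tsv", "survival.tsv"):
        manifest.add_output(out / name)
    manifest.write(out / "manifest.json")
    log.info("pipeline outputs written to %s", out)
    return {"metrics": metrics, "calls": calls, "survival": surv}
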