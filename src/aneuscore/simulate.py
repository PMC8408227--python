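"""Synthetic-data generators with known ground truth for every pipeline input.

Emulates the study conditions of an isogenic clonal cell-line panel: integer
karyotypes with whole-chromosome/arm/focal events, whole-genome doubling and
chromothripsis; noisy median-centered probe log2-ratio tracks; expression
counts whose per-gene mean follows a gene-dosage power law; TP53 mutation
tables with a stated genotype mix; exponential survival with a hazard ratio
between fraction-genome-altered quartile groups; and exponential growth
curves. All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genome import BinGrid, GenomeModel

__all__ = [
    "KaryotypeEvent",
    "CopyNumberTrack",
    "SimulationConfig",
    "GrowthCurve",
    "simulate_karyotype",
    "render_probe_signal",
    "make_gene_map",
    "simulate_expression",
    "simulate_mutation_table",
    "simulate_cohort_survival",
    "simulate_growth_curve",
    "copy_burden",
]

log = logging.getLogger(__name__)

EVENT_KINDS = (
    "whole_chrom_gain", "whole_chrom_loss", "arm_gain", "arm_loss",
    "focal_gain", "focal_loss", "WGD", "chromothripsis",
)

# Floor used when converting integer copy number to logR; CN=0 has no finite
# log ratio, and arrays saturate on homozygous deletions anyway.
CN_FLOOR = 0.5


@dataclass
class KaryotypeEvent:
    kind: str
    chrom: str | None = None
    arm: str | None = None
    start: int | None = None
    end: int | None = None
    copies: int = 0
    n_switches: int | None = None
    low_state: int | None = None
    high_state: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "chromothripsis":
            if self.n_switches is None or self.n_switches < 2:
                raise ValueError("chromothripsis requires n_switches >= 2")
        elif self.kind != "WGD" and self.copies == 0:
            raise ValueError(f"{self.kind} event must change copies")


@dataclass
class CopyNumberTrack:
    """Ground-truth integer copy number per grid bin for one sample."""

    sample_id: str
    grid: BinGrid
    copies: np.ndarray
    baseline_ploidy: int = 2

    def __post_init__(self) -> None:
        self.copies = np.asarray(self.copies, dtype=int)
        if self.copies.shape != (self.grid.n_bins,):
            raise ValueError("copy array must have one entry per bin")
        if (self.copies < 0).any():
            raise ValueError("copy numbers must be >= 0")
        if self.baseline_ploidy not in (2, 4):
            raise ValueError("baseline ploidy must be 2 (diploid) or 4 (post-WGD)")


@dataclass
class SimulationConfig:
    """Knobs for the whole generator suite; defaults are the study conditions.

    Event counts per clone are Poisson; WGD probability reflects the observed
    ~1-in-5 near-tetraploid clones; probe density and noise are typical of
    SNP-array log-ratio tracks; dosage_slope=1 is strict proportionality of
    expression to copy number.
    """

    seed: int = 0
    events_mean: float = 5.0
    p_wgd: float = 0.2
    p_chromothripsis: float = 0.1
    kind_weights: dict = field(default_factory=lambda: {
        "whole_chrom": 0.4, "arm": 0.3, "focal": 0.3})
    probe_density: float = 2.0      # probes per Mb
    noise_sd: float = 0.1           # Gaussian probe noise, logR units
    dosage_slope: float = 1.0
    dispersion: float = 0.1         # NB dispersion alpha (var = mu + alpha mu^2)
    hazard_ratio: float = 3.0       # FGA Q4 vs rest
    baseline_hazard: float = 1.0 / 1000.0   # events per day
    censor_rate: float = 0.3        # censoring hazard / baseline hazard
    class_mix: dict = field(default_factory=lambda: {
        "WT": 0.35, "missense": 0.35, "truncating": 0.20,
        "multi": 0.05, "inframe": 0.05})

    def __post_init__(self) -> None:
        for name in ("events_mean", "probe_density", "noise_sd", "dosage_slope",
                     "dispersion", "hazard_ratio", "baseline_hazard", "censor_rate"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for p in ("p_wgd", "p_chromothripsis"):
            if not (0 <= getattr(self, p) <= 1):
                raise ValueError(f"{p} must be in [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GrowthCurve:
    sample_id: str
    times_h: np.ndarray
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.times_h = np.asarray(self.times_h, dtype=float)
        self.counts = np.asarray(self.counts, dtype=float)
        if (np.diff(self.times_h) <= 0).any():
            raise ValueError("times must be strictly increasing")
        if (self.counts <= 0).any():
            raise ValueError("cell counts must be positive")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_karyotype(genome: GenomeModel, grid: BinGrid,
                       config: SimulationConfig, seed,
                       sample_id: str = "S",
                       ) -> tuple[CopyNumberTrack, list[KaryotypeEvent]]:
    """Draw one clonal karyotype as integer copies per bin plus its event list.

    Starts diploid; whole-genome doubling (if drawn) is applied first and sets
    the baseline ploidy to 4; each subsequent event adds/removes one copy on a
    whole chromosome, an arm, or a focal interval; chromothripsis rewrites one
    chromosome as alternating runs between two copy states with exactly
    ``n_switches`` state changes. Copies driven below 0 are clamped at 0.
    """
    rng = _rng(seed)
    copies = np.full(grid.n_bins, 2, dtype=int)
    baseline = 2
    events: list[KaryotypeEvent] = []

    if rng.random() < config.p_wgd:
        copies *= 2
        baseline = 4
        events.append(KaryotypeEvent(kind="WGD"))

    arm_labels = grid.arm_labels()
    chrom_arr = grid.bins["chrom"].to_numpy()

    if rng.random() < config.p_chromothripsis:
        chrom = str(rng.choice(genome.names))
        mask = chrom_arr == chrom
        n_bins_c = int(mask.sum())
        max_sw = max(2, n_bins_c - 1)
        n_switches = int(min(rng.integers(4, 13), max_sw))
        low, high = baseline - 1, baseline + 1
        cuts = np.sort(rng.choice(np.arange(1, n_bins_c), size=n_switches,
                                  replace=False))
        state = int(rng.choice([low, high]))
        vals = np.empty(n_bins_c, dtype=int)
        prev = 0
        for cut in list(cuts) + [n_bins_c]:
            vals[prev:cut] = state
            state = high + low - state
            prev = cut
        copies[mask] = vals
        events.append(KaryotypeEvent(
            kind="chromothripsis", chrom=chrom, n_switches=n_switches,
            low_state=low, high_state=high))

    kinds = list(config.kind_weights)
    weights = np.array([config.kind_weights[k] for k in kinds], dtype=float)
    weights /= weights.sum()
    n_events = int(rng.poisson(config.events_mean))
    for _ in range(n_events):
        kind = str(rng.choice(kinds, p=weights))
        sign = int(rng.choice([1, -1]))
        chrom = str(rng.choice(genome.names))
        if kind == "whole_chrom":
            mask = chrom_arr == chrom
            ev = KaryotypeEvent(
                kind="whole_chrom_gain" if sign > 0 else "whole_chrom_loss",
                chrom=chrom, copies=sign)
        elif kind == "arm":
            arm = str(rng.choice(["p", "q"]))
            mask = arm_labels == f"{chrom}{arm}"
            ev = KaryotypeEvent(
                kind="arm_gain" if sign > 0 else "arm_loss",
                chrom=chrom, arm=arm, copies=sign)
        else:  # focal: 2-20% of the chromosome
            length = genome.length_of(chrom)
            width = int(length * rng.uniform(0.02, 0.2))
            start = int(rng.integers(0, max(1, length - width)))
            end = start + max(width, 1)
            mask = (chrom_arr == chrom) \
                & (grid.bins["start"].to_numpy() < end) \
                & (grid.bins["end"].to_numpy() > start)
            ev = KaryotypeEvent(
                kind="focal_gain" if sign > 0 else "focal_loss",
                chrom=chrom, start=start, end=end, copies=sign)
        copies[mask] += sign
        events.append(ev)

    if (copies < 0).any():
        log.warning("%s: %d bins clamped at copy number 0",
                    sample_id, int((copies < 0).sum()))
        copies = np.maximum(copies, 0)

    track = CopyNumberTrack(sample_id=sample_id, grid=grid, copies=copies,
                            baseline_ploidy=baseline)
    return track, events


def copy_burden(track: CopyNumberTrack) -> float:
    """Ground-truth alteration burden: sum of |CN - baseline ploidy| x Mb."""
    dev = np.abs(track.copies - track.baseline_ploidy)
    return float(np.sum(dev * track.grid.lengths_mb))


def render_probe_signal(track: CopyNumberTrack, genome: GenomeModel,
                        density: float, noise_sd: float, seed):
    """Render a copy-number track as a noisy, median-centered probe logR signal.

    Probes are placed at even spacing at the given density (probes/Mb); the
    raw value is log2(CN/2) of the covering bin plus Gaussian noise; the
    genome-wide median is then subtracted, emulating array normalization
    (a pure-WGD genome therefore renders as logR ~ 0 everywhere).
    """
    from .profiles import ProbeSignal

    if density <= 0:
        raise ValueError("probe density must be positive")
    rng = _rng(seed)
    grid = track.grid
    chrom_arr = grid.bins["chrom"].to_numpy()
    starts = grid.bins["start"].to_numpy()
    rows = []
    for name in genome.names:
        length = genome.length_of(name)
        n = max(2, round(length * density / 1e6))
        pos = ((np.arange(n) + 0.5) * length / n).astype(int)
        idx = np.flatnonzero(chrom_arr == name)
        j = np.searchsorted(starts[idx], pos, side="right") - 1
        cn = track.copies[idx[j]]
        logr = np.log2(np.maximum(cn, CN_FLOOR) / 2.0)
        rows.append(pd.DataFrame({"chrom": name, "pos": pos, "logr": logr}))
    probes = pd.concat(rows, ignore_index=True)
    if noise_sd > 0:
        probes["logr"] += rng.normal(0.0, noise_sd, size=len(probes))
    probes["logr"] -= probes["logr"].median()
    return ProbeSignal(sample_id=track.sample_id, probes=probes, genome=genome)


def make_gene_map(genome: GenomeModel, grid: BinGrid,
                  genes_per_chrom: int = 50) -> pd.DataFrame:
    """Deterministic gene placement: evenly spaced genes on each chromosome.

    Returns a table (gene, chrom, pos, bin) usable as the dosage gene map.
    """
    chrom_arr = grid.bins["chrom"].to_numpy()
    starts = grid.bins["start"].to_numpy()
    rows = []
    for name in genome.names:
        length = genome.length_of(name)
        pos = ((np.arange(genes_per_chrom) + 0.5) * length / genes_per_chrom).astype(int)
        idx = np.flatnonzero(chrom_arr == name)
        j = np.searchsorted(starts[idx], pos, side="right") - 1
        for k, (p, b) in enumerate(zip(pos, idx[j])):
            rows.append((f"G_{name}_{k:04d}", name, int(p), int(b)))
    return pd.DataFrame(rows, columns=["gene", "chrom", "pos", "bin"])


def simulate_expression(tracks, gene_map: pd.DataFrame,
                        dosage_slope: float, dispersion: float, seed,
                        base_mean: float = 100.0) -> pd.DataFrame:
    """Negative-binomial counts whose mean follows a gene-dosage power law.

    Gene g in sample s has mean mu_g * (CN_gs / 2) ** dosage_slope, where
    mu_g is a fixed per-gene baseline (lognormal around ``base_mean``) and
    CN_gs the integer copy number of the gene's bin. ``dispersion`` is the NB
    alpha (variance mu + alpha mu^2); alpha=0 degenerates to Poisson.
    Returns a genes x samples count DataFrame.
    """
    if dosage_slope < 0:
        raise ValueError("dosage_slope must be >= 0")
    if len(gene_map) == 0:
        raise ValueError("empty gene map")
    if isinstance(tracks, CopyNumberTrack):
        tracks = [tracks]
    rng = _rng(seed)

    n_bins = tracks[0].grid.n_bins
    bins = gene_map["bin"].to_numpy()
    bad = gene_map.loc[(bins < 0) | (bins >= n_bins), "gene"]
    if len(bad):
        raise ValueError(f"genes mapped outside grid: {list(bad)}")

    n_genes = len(gene_map)
    # per-gene baseline means: fixed given the seed, shared across samples
    mu_g = rng.lognormal(mean=np.log(base_mean), sigma=0.4, size=n_genes)
    out = {}
    for track in tracks:
        cn = track.copies[bins].astype(float)
        mu = mu_g * np.maximum(cn / 2.0, 1e-6) ** dosage_slope
        if dispersion <= 1e-12:
            counts = rng.poisson(mu)
        else:
            n_param = 1.0 / dispersion
            p_param = n_param / (n_param + mu)
            counts = rng.negative_binomial(n_param, p_param)
        out[track.sample_id] = counts
    return pd.DataFrame(out, index=gene_map["gene"].to_numpy())


# --- TP53 mutation tables ------------------------------------------------

_MISSENSE_CHANGES = ["R175H", "R273H", "R248Q", "R273C", "R282W", "G245S", "R248W"]
_TRUNCATING = [
    ("Nonsense_Mutation", "R213*"),
    ("Nonsense_Mutation", "R342*"),
    ("Frame_Shift_Del", "P152fs"),
    ("Frame_Shift_Ins", "T256fs"),
    ("Splice_Site", "X125_splice"),
]
_SILENT_CHANGES = ["L289L", "T125T", "A347A"]


def simulate_mutation_table(class_mix: dict, n_samples: int, seed,
                            cohort: str = "COHORT",
                            ) -> tuple[pd.DataFrame, pd.Series]:
    """MAF-subset TP53 rows realizing a drawn genotype class per sample.

    Classes: WT (no row or silent-only), missense (one hotspot missense),
    truncating (one nonsense/frameshift/splice-site), multi (two non-silent
    alterations), inframe (one in-frame deletion). Returns the mutation table
    and the ground-truth label per sample.
    """
    probs = np.array([class_mix.get(k, 0.0) for k in
                      ("WT", "missense", "truncating", "multi", "inframe")])
    if abs(probs.sum() - 1.0) > 1e-6:
        raise ValueError(f"class mix sums to {probs.sum():.6f}, expected 1")
    rng = _rng(seed)
    labels = rng.choice(["WT", "missense", "truncating", "multi", "inframe"],
                        size=n_samples, p=probs)
    rows = []
    for i, lab in enumerate(labels):
        sample = f"{cohort}-{i:05d}"
        if lab == "WT":
            if rng.random() < 0.3:   # some WT samples carry a silent record
                rows.append((sample, "TP53", "Silent",
                             str(rng.choice(_SILENT_CHANGES))))
        elif lab == "missense":
            rows.append((sample, "TP53", "Missense_Mutation",
                         str(rng.choice(_MISSENSE_CHANGES))))
        elif lab == "truncating":
            vc, pc = _TRUNCATING[rng.integers(len(_TRUNCATING))]
            rows.append((sample, "TP53", vc, pc))
        elif lab == "multi":
            picks = rng.choice(len(_TRUNCATING), size=1)
            rows.append((sample, "TP53", "Missense_Mutation",
                         str(rng.choice(_MISSENSE_CHANGES))))
            vc, pc = _TRUNCATING[int(picks[0])]
            rows.append((sample, "TP53", vc, pc))
        else:  # inframe
            rows.append((sample, "TP53", "In_Frame_Del", "I255del"))
    maf = pd.DataFrame(rows, columns=[
        "Tumor_Sample_Barcode", "Hugo_Symbol", "Variant_Classification",
        "HGVSp_Short"])
    truth = pd.Series(labels, index=[f"{cohort}-{i:05d}" for i in range(n_samples)],
                      name="truth")
    return maf, truth


def simulate_cohort_survival(fga: pd.Series, hazard_ratio: float,
                             baseline_hazard: float, censor_rate: float,
                             seed) -> pd.DataFrame:
    """Exponential event times with an elevated hazard in the upper FGA quartile.

    Samples at or above the 75th FGA percentile get hazard
    baseline * hazard_ratio; all others (including intermediate quartiles)
    stay at baseline. Censoring is independent exponential with hazard
    ``censor_rate * baseline`` (0 disables censoring). Returns a table
    (sample_id, time, event, fga_group) with event=1 for observed events.
    """
    if hazard_ratio <= 0:
        raise ValueError("hazard ratio must be positive")
    if len(fga) == 0:
        raise ValueError("empty cohort")
    rng = _rng(seed)
    fga = pd.Series(fga)
    q3 = float(np.quantile(fga.to_numpy(), 0.75))
    high = fga.to_numpy() >= q3
    hazard = np.where(high, baseline_hazard * hazard_ratio, baseline_hazard)
    t_event = rng.exponential(1.0 / hazard)
    if censor_rate > 0:
        t_cens = rng.exponential(1.0 / (censor_rate * baseline_hazard),
                                 size=len(fga))
    else:
        t_cens = np.full(len(fga), np.inf)
    time = np.minimum(t_event, t_cens)
    event = (t_event <= t_cens).astype(int)
    # strictly positive times (product-limit requires t > 0)
    time = np.maximum(time, 1e-9)
    return pd.DataFrame({
        "sample_id": fga.index.astype(str),
        "time": time,
        "event": event,
        "fga": fga.to_numpy(),
        "fga_group": np.where(high, "Q4", "Q1-3"),
    })


def simulate_growth_curve(true_doubling_time: float, duration: float,
                          n_timepoints: int, noise_cv: float, seed,
                          n0: float = 1000.0, sample_id: str = "S") -> GrowthCurve:
    """Exponential growth N0 * 2^(t/Td) with multiplicative lognormal noise."""
    if true_doubling_time <= 0:
        raise ValueError("doubling time must be positive")
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = _rng(seed)
    t = np.linspace(0.0, duration, n_timepoints)
    counts = n0 * 2.0 ** (t / true_doubling_time)
    if noise_cv > 0:
        sigma = np.sqrt(np.log1p(noise_cv ** 2))
        counts = counts * rng.lognormal(mean=-sigma ** 2 / 2, sigma=sigma,
                                        size=n_timepoints)
    return GrowthCurve(sample_id=sample_id, times_h=t, counts=counts)
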