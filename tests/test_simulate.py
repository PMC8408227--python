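"""Ground-truth generators: karyotypes, probe rendering, expression,
mutation tables, survival, growth curves."""

import numpy as np
import pandas as pd
import pytest

from aneuscore import (SimulationConfig, CopyNumberTrack, copy_burden,
                       render_probe_signal, make_gene_map, simulate_expression,
                       simulate_karyotype, simulate_mutation_table,
                       simulate_cohort_survival, simulate_growth_curve,
                       doubling_time, km_curve, classify_cohort)


@pytest.fixture
def quiet_config():
    return SimulationConfig(events_mean=0.0, p_wgd=0.0, p_chromothripsis=0.0)


class TestKaryotype:
    def test_zero_events_is_diploid(self, small_genome, small_grid, quiet_config):
        track, events = simulate_karyotype(small_genome, small_grid,
                                           quiet_config, seed=1)
        assert events == []
        assert (track.copies == 2).all()
        assert track.baseline_ploidy == 2

    def test_pure_wgd_is_tetraploid(self, small_genome, small_grid):
        cfg = SimulationConfig(events_mean=0.0, p_wgd=1.0, p_chromothripsis=0.0)
        track, events = simulate_karyotype(small_genome, small_grid, cfg, seed=1)
        assert [e.kind for e in events] == ["WGD"]
        assert (track.copies == 4).all()
        assert track.baseline_ploidy == 4

    def test_chromothripsis_switch_count_matches_event(self, small_genome,
                                                       small_grid):
        cfg = SimulationConfig(events_mean=0.0, p_wgd=0.0, p_chromothripsis=1.0)
        for seed in range(5):
            track, events = simulate_karyotype(small_genome, small_grid, cfg,
                                               seed=seed)
            (ev,) = events
            assert ev.kind == "chromothripsis"
            mask = small_grid.chrom_mask(ev.chrom)
            vals = track.copies[mask]
            assert set(vals) <= {ev.low_state, ev.high_state}
            assert int((np.diff(vals) != 0).sum()) == ev.n_switches
            # untargeted chromosomes conserved at CN 2
            assert (track.copies[~mask] == 2).all()

    def test_untargeted_bins_conserved(self, small_genome, small_grid):
        cfg = SimulationConfig(events_mean=3.0, p_wgd=0.0, p_chromothripsis=0.0)
        track, events = simulate_karyotype(small_genome, small_grid, cfg, seed=7)
        touched = np.zeros(small_grid.n_bins, dtype=bool)
        for ev in events:
            if ev.chrom is not None:
                touched |= small_grid.chrom_mask(ev.chrom)
        assert (track.copies[~touched] == 2).all()

    def test_bit_reproducible_for_fixed_seed(self, small_genome, small_grid):
        cfg = SimulationConfig(events_mean=5.0)
        t1, e1 = simulate_karyotype(small_genome, small_grid, cfg, seed=42)
        t2, e2 = simulate_karyotype(small_genome, small_grid, cfg, seed=42)
        assert (t1.copies == t2.copies).all()
        assert e1 == e2


class TestRenderProbeSignal:
    def test_diploid_noiseless_renders_zero(self, small_genome, small_grid):
        track = CopyNumberTrack("S", small_grid,
                                np.full(small_grid.n_bins, 2))
        sig = render_probe_signal(track, small_genome, density=2.0,
                                  noise_sd=0.0, seed=0)
        assert np.allclose(sig.probes["logr"], 0.0)

    def test_pure_wgd_invisible_after_median_centering(self, small_genome,
                                                       small_grid):
        track = CopyNumberTrack("S", small_grid,
                                np.full(small_grid.n_bins, 4),
                                baseline_ploidy=4)
        sig = render_probe_signal(track, small_genome, density=2.0,
                                  noise_sd=0.0, seed=0)
        assert np.allclose(sig.probes["logr"], 0.0)

    def test_single_chromosome_gain_closed_form(self, small_genome, small_grid):
        copies = np.full(small_grid.n_bins, 2)
        copies[small_grid.chrom_mask("5")] = 3
        track = CopyNumberTrack("S", small_grid, copies)
        sig = render_probe_signal(track, small_genome, density=2.0,
                                  noise_sd=0.0, seed=0)
        on = sig.probes["chrom"] == "5"
        assert np.allclose(sig.probes.loc[on, "logr"], np.log2(1.5))
        assert np.allclose(sig.probes.loc[~on, "logr"], 0.0)


class TestExpression:
    def test_zero_slope_decouples_expression_from_cn(self, small_genome,
                                                     small_grid):
        from scipy import stats
        copies = np.full(small_grid.n_bins, 2)
        copies[small_grid.chrom_mask("1")] = 3
        track = CopyNumberTrack("S", small_grid, copies)
        gm = make_gene_map(small_genome, small_grid, genes_per_chrom=200)
        expr = simulate_expression(track, gm, dosage_slope=0.0,
                                   dispersion=0.05, seed=3)
        on = expr.loc[gm.loc[gm["chrom"] == "1", "gene"], "S"]
        off = expr.loc[gm.loc[gm["chrom"] == "2", "gene"], "S"]
        _, p = stats.mannwhitneyu(on, off)
        assert p > 0.01

    def test_unit_slope_low_dispersion_gives_dosage_ratio_two(
            self, small_genome, small_grid):
        copies = np.full(small_grid.n_bins, 2)
        copies[small_grid.chrom_mask("1")] = 4
        track = CopyNumberTrack("S", small_grid, copies)
        gm = make_gene_map(small_genome, small_grid, genes_per_chrom=500)
        expr = simulate_expression(track, gm, dosage_slope=1.0,
                                   dispersion=1e-13, seed=5)
        on = expr.loc[gm.loc[gm["chrom"] == "1", "gene"], "S"].mean()
        off = expr.loc[gm.loc[gm["chrom"] == "2", "gene"], "S"].mean()
        assert on / off == pytest.approx(2.0, rel=0.05)

    def test_empty_gene_map_rejected(self, small_grid):
        track = CopyNumberTrack("S", small_grid, np.full(small_grid.n_bins, 2))
        with pytest.raises(ValueError, match="empty gene map"):
            simulate_expression(track, pd.DataFrame(columns=["gene", "bin"]),
                                1.0, 0.1, seed=0)


class TestMutationTable:
    def test_pure_wt_mix_has_no_nonsilent_rows(self):
        maf, truth = simulate_mutation_table({"WT": 1.0}, 200, seed=0)
        assert (truth == "WT").all()
        assert set(maf["Variant_Classification"]) <= {"Silent"}

    def test_mix_must_sum_to_one(self):
        with pytest.raises(ValueError, match="sums to"):
            simulate_mutation_table({"WT": 0.5, "missense": 0.4}, 10, seed=0)

    def test_classifier_recovers_generated_classes_exactly_per_sample(self):
        mix = {"WT": 0.3, "missense": 0.3, "truncating": 0.2,
               "multi": 0.1, "inframe": 0.1}
        maf, truth = simulate_mutation_table(mix, 500, seed=11)
        calls = classify_cohort(maf, truth.index).set_index("sample_id")
        expected = truth.map({"WT": "WT", "missense": "missense",
                              "truncating": "truncating", "multi": "excluded",
                              "inframe": "excluded"})
        assert (calls["call"] == expected).all()


class TestSurvival:
    def test_hr3_median_ratio_matches_exponential_theory(self):
        fga = pd.Series(np.linspace(0, 1, 500),
                        index=[f"S{i}" for i in range(500)])
        surv = simulate_cohort_survival(fga, hazard_ratio=3.0,
                                        baseline_hazard=1e-3, censor_rate=0.0,
                                        seed=2)
        lo = surv[surv["fga_group"] == "Q1-3"]
        hi = surv[surv["fga_group"] == "Q4"]
        ratio = km_curve(lo).median / km_curve(hi).median
        assert ratio == pytest.approx(3.0, rel=0.2)

    def test_infinite_censoring_gives_flat_curve(self):
        fga = pd.Series(np.linspace(0, 1, 50))
        surv = simulate_cohort_survival(fga, 1.0, 1e-3, censor_rate=1e9, seed=3)
        assert (surv["event"] == 0).all()
        curve = km_curve(surv)
        assert curve.survival_at(surv["time"].max()) == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            simulate_cohort_survival(pd.Series(dtype=float), 2.0, 1e-3, 0.3, 0)


class TestGrowthCurve:
    def test_noiseless_two_doublings(self):
        c = simulate_growth_curve(24.0, 48.0, 5, noise_cv=0.0, seed=0)
        assert c.counts[-1] / c.counts[0] == pytest.approx(4.0)

    def test_doubling_time_is_exact_inverse_at_zero_noise(self):
        c = simulate_growth_curve(17.5, 120.0, 6, noise_cv=0.0, seed=0)
        assert doubling_time(c).hours == pytest.approx(17.5)

    def test_noisy_replicates_recover_true_doubling_time(self):
        tds = [doubling_time(simulate_growth_curve(24.0, 96.0, 5, 0.05, seed=s)
                             ).hours for s in range(100)]
        assert np.mean(tds) == pytest.approx(24.0, rel=0.02)

    def test_invalid_duration_rejected(self):
        with pytest.raises(ValueError):
            simulate_growth_curve(24.0, -1.0, 5, 0.0, seed=0)
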