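"""Aneuploidy score, FGA, quantile classes, frequency tracks, arm tests."""

import numpy as np
import pytest
from statsmodels.stats.multitest import multipletests

from aneuscore import (alteration_frequency, aneuploidy_score,
                       chromosome_mean_copy, classify_by_quantile,
                       compare_arms, fraction_genome_altered, relative_profile)

from conftest import make_binned, make_seg


class TestRelativeProfile:
    def test_identical_profiles_cancel(self, toy_grid):
        p = make_binned(toy_grid, np.linspace(-1, 1, toy_grid.n_bins))
        assert np.allclose(relative_profile(p, p).values, 0.0)

    def test_zero_parental_is_identity(self, toy_grid):
        v = np.linspace(-1, 1, toy_grid.n_bins)
        p = make_binned(toy_grid, v)
        zero = make_binned(toy_grid, np.zeros(toy_grid.n_bins))
        assert np.allclose(relative_profile(p, zero).values, v)

    def test_shared_ancestral_gain_cancels(self, toy_grid):
        v = np.zeros(toy_grid.n_bins)
        v[0] = 0.585
        sample = make_binned(toy_grid, v)
        parental = make_binned(toy_grid, v, sample_id="P")
        assert relative_profile(sample, parental).values[0] == 0.0

    def test_grid_mismatch_rejected(self, toy_genome, toy_grid):
        from aneuscore import make_bins
        other = make_bins(toy_genome, width=5_000_000)
        a = make_binned(toy_grid, np.zeros(toy_grid.n_bins))
        b = make_binned(other, np.zeros(other.n_bins))
        with pytest.raises(ValueError, match="grid"):
            relative_profile(a, b)


class TestAneuploidyScore:
    def test_zero_profile_scores_zero(self, toy_grid):
        assert aneuploidy_score(make_binned(toy_grid, np.zeros(toy_grid.n_bins))) == 0.0

    def test_fifty_mb_run_at_half_logr_scores_25(self, toy_grid):
        v = np.zeros(toy_grid.n_bins)
        v[:5] = 0.5  # five 10 Mb bins on chromosome 1p
        assert aneuploidy_score(make_binned(toy_grid, v)) == pytest.approx(25.0)

    def test_splitting_runs_leaves_per_mb_score_unchanged(self, toy_genome):
        from aneuscore import make_bins
        coarse = make_bins(toy_genome, width=10_000_000)
        fine = make_bins(toy_genome, width=2_000_000)
        vc = np.zeros(coarse.n_bins)
        vc[:4] = -0.7
        vf = np.zeros(fine.n_bins)
        vf[:20] = -0.7  # same 40 Mb at finer binning
        assert aneuploidy_score(make_binned(coarse, vc)) == pytest.approx(
            aneuploidy_score(make_binned(fine, vf)))

    def test_translation_bound_exact_on_nonnegative_profiles(self, toy_grid):
        rng = np.random.default_rng(0)
        v = np.abs(rng.normal(0, 0.3, toy_grid.n_bins))
        c = 0.25
        base = aneuploidy_score(make_binned(toy_grid, v))
        shifted = aneuploidy_score(make_binned(toy_grid, v + c))
        total_mb = toy_grid.lengths_mb.sum()
        assert shifted - base == pytest.approx(c * total_mb)

    def test_weighting_modes(self, toy_grid):
        v = np.zeros(toy_grid.n_bins)
        v[:5] = 0.5
        p = make_binned(toy_grid, v)
        assert aneuploidy_score(p, mode="per_bin") == pytest.approx(2.5)
        assert aneuploidy_score(p, mode="per_segment") == pytest.approx(0.5)
        with pytest.raises(ValueError):
            aneuploidy_score(p, mode="per_probe")


class TestFGA:
    def test_forty_percent_altered(self):
        seg = make_seg([("1", 0, 40_000_000, 0.5),
                        ("1", 40_000_000, 100_000_000, 0.0)])
        assert fraction_genome_altered(seg) == pytest.approx(0.40)

    def test_flat_genome_is_zero(self):
        seg = make_seg([("1", 0, 100_000_000, 0.0)])
        assert fraction_genome_altered(seg) == 0.0

    def test_threshold_is_strict(self):
        seg = make_seg([("1", 0, 50_000_000, 0.2),
                        ("1", 50_000_000, 100_000_000, 0.0)])
        assert fraction_genome_altered(seg) == 0.0

    def test_non_increasing_in_threshold(self):
        rng = np.random.default_rng(5)
        rows, start = [], 0
        for v in rng.normal(0, 0.3, 20):
            rows.append(("1", start, start + 5_000_000, float(v)))
            start += 5_000_000
        seg = make_seg(rows)
        fgas = [fraction_genome_altered(seg, t)
                for t in (0.0, 0.1, 0.2, 0.4, 1.0)]
        assert fgas == sorted(fgas, reverse=True)


class TestQuantileClasses:
    def test_one_to_eight_splits_two_two(self):
        labels = classify_by_quantile(np.arange(1, 9))
        assert list(labels[:2]) == ["aneuploid_low"] * 2
        assert list(labels[-2:]) == ["aneuploid_high"] * 2
        assert list(labels[2:6]) == ["intermediate"] * 4

    def test_identical_values_all_intermediate(self):
        with pytest.warns(UserWarning, match="identical"):
            labels = classify_by_quantile(np.full(10, 3.0))
        assert (labels == "intermediate").all()

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match=">= 4"):
            classify_by_quantile([1.0, 2.0, 3.0])

    def test_invariant_to_strictly_monotone_transform(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            v = rng.choice(1000, size=rng.integers(4, 30), replace=False) / 10
            assert (classify_by_quantile(v) ==
                    classify_by_quantile(np.exp(v / 50))).all()

    def test_group_sizes_bounded_by_quarter_ceiling(self):
        rng = np.random.default_rng(3)
        for n in (4, 5, 8, 11, 17, 40):
            v = rng.choice(10_000, size=n, replace=False).astype(float)
            labels = classify_by_quantile(v)
            bound = int(np.ceil(n / 4))
            assert (labels == "aneuploid_low").sum() <= bound
            assert (labels == "aneuploid_high").sum() <= bound


class TestAlterationFrequency:
    def test_fraction_of_called_profiles(self, toy_grid):
        n = toy_grid.n_bins
        gained = np.zeros(n); gained[0] = 0.585
        flat = np.zeros(n)
        track = alteration_frequency(
            [make_binned(toy_grid, gained, "a"),
             make_binned(toy_grid, gained, "b"),
             make_binned(toy_grid, flat, "c"),
             make_binned(toy_grid, flat, "d")])
        assert track.gain_frac[0] == pytest.approx(0.5)
        assert track.loss_frac[0] == 0.0
        assert (track.gain_frac[1:] == 0).all()

    def test_unaltered_group_is_all_zero(self, toy_grid):
        track = alteration_frequency(
            [make_binned(toy_grid, np.zeros(toy_grid.n_bins))])
        assert (track.gain_frac == 0).all() and (track.loss_frac == 0).all()

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            alteration_frequency([])


class TestCompareArms:
    def test_identical_groups_give_t0_p1(self, toy_grid):
        rng = np.random.default_rng(2)
        group = [make_binned(toy_grid, rng.normal(0, 0.1, toy_grid.n_bins),
                             f"s{i}") for i in range(3)]
        res = compare_arms(group, group)
        assert np.allclose(res["t"], 0.0)
        assert np.allclose(res["p"], 1.0)
        assert not res["significant"].any()

    def test_bh_adjustment_matches_formula(self):
        """p (0.01, 0.02, 0.03, 0.04) at m=4 all adjust to 0.04."""
        _, adj, _, _ = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")
        assert np.allclose(adj, 0.04)
        # independent check: step-up min_k>=rank(p_k * m / k)
        p = np.array([0.01, 0.02, 0.03, 0.04])
        raw = p * 4 / np.arange(1, 5)
        manual = np.minimum.accumulate(raw[::-1])[::-1]
        assert np.allclose(adj, manual)

    def test_shifted_arm_detected_with_fdr_controlled(self, toy_grid):
        """A single-copy shift on 1q (n=5 vs 5, noise 0.05) is flagged at
        q=0.1 in at least 95 of 100 seeds, and the false-discovery
        proportion among flagged arms stays within the BH guarantee."""
        arms = toy_grid.arm_labels()
        shift = (arms == "1q") * 0.585
        detected = 0
        fdp = []
        for seed in range(100):
            rng = np.random.default_rng(seed)

            def group(shifted, n=5):
                return [make_binned(
                    toy_grid,
                    rng.normal(0, 0.05, toy_grid.n_bins)
                    + (shift if shifted else 0), f"g{i}") for i in range(n)]

            res = compare_arms(group(False), group(True))
            flagged = set(res.loc[res["significant"], "arm"])
            detected += "1q" in flagged
            fdp.append(len(flagged - {"1q"}) / max(len(flagged), 1))
        assert detected >= 95
        assert np.mean(fdp) <= 0.1 + 0.03  # q plus Monte Carlo slack

    def test_small_groups_rejected(self, toy_grid):
        p = make_binned(toy_grid, np.zeros(toy_grid.n_bins))
        with pytest.raises(ValueError):
            compare_arms([p], [p, p])

    def test_adjusted_p_not_below_raw(self, toy_grid):
        rng = np.random.default_rng(30)
        a = [make_binned(toy_grid, rng.normal(0, 0.1, toy_grid.n_bins), f"a{i}")
             for i in range(4)]
        b = [make_binned(toy_grid, rng.normal(0, 0.1, toy_grid.n_bins), f"b{i}")
             for i in range(4)]
        res = compare_arms(a, b)
        assert (res["p_adj"] >= res["p"] - 1e-12).all()


class TestChromosomeMeanCopy:
    def test_closed_forms(self, toy_grid):
        n = toy_grid.n_bins
        assert chromosome_mean_copy(make_binned(toy_grid, np.zeros(n)), "1") \
            == pytest.approx(2.0)
        assert chromosome_mean_copy(make_binned(toy_grid, np.ones(n)), "1") \
            == pytest.approx(4.0)

    def test_half_gained_chromosome(self, toy_grid):
        v = np.zeros(toy_grid.n_bins)
        mask = toy_grid.chrom_mask("1")
        idx = np.flatnonzero(mask)
        v[idx[:len(idx) // 2]] = 1.0  # first 50 of 100 Mb at logR 1
        cn = chromosome_mean_copy(make_binned(toy_grid, v), "1")
        assert cn == pytest.approx(2 * 2 ** 0.5)

    def test_segment_profile_input(self):
        seg = make_seg([("1", 0, 100_000_000, 1.0)])
        assert chromosome_mean_copy(seg, "1") == pytest.approx(4.0)
        with pytest.raises(ValueError):
            chromosome_mean_copy(seg, "9")
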