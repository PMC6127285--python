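"""Read-depth CNV caller: normalization, calling, refinement, allele balance."""

import numpy as np
import pandas as pd
import pytest

import secondhit as sh
from secondhit.cnv import CnvCall, RatioMatrix, classify_interval
from secondhit.panel import PanelDesign


def make_matrix(counts: np.ndarray, length=1000) -> sh.CoverageMatrix:
    n_iv, n_s = counts.shape
    starts = np.arange(n_iv) * length
    intervals = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + length,
         "gene": "GENE1", "region_class": "whole-gene-tile", "efficiency": 1.0}
    )
    return sh.CoverageMatrix(
        intervals=intervals,
        counts=pd.DataFrame(counts, columns=[f"S{i}" for i in range(n_s)]),
    )


def make_ratios(values: np.ndarray) -> RatioMatrix:
    """RatioMatrix with given per-(interval, sample) ratios, all callable."""
    n_iv, n_s = values.shape
    starts = np.arange(n_iv) * 1000
    intervals = pd.DataFrame(
        {"chrom": "chr1", "start": starts, "end": starts + 1000,
         "gene": "GENE1", "region_class": "whole-gene-tile", "efficiency": 1.0}
    )
    cols = [f"S{i}" for i in range(n_s)]
    return RatioMatrix(
        intervals=intervals,
        ratios=pd.DataFrame(values, columns=cols),
        reference_stat=pd.DataFrame(np.full_like(values, 1000.0), columns=cols),
        normalization_factors=pd.Series(np.ones(n_s), index=cols),
        callable_mask=pd.DataFrame(np.ones_like(values, dtype=bool), columns=cols),
    )


class TestNormalize:
    def test_identical_samples_give_unit_ratios(self):
        counts = np.tile(np.array([[500], [800], [1200]]), (1, 4))
        rm = sh.normalize_counts(make_matrix(counts))
        assert np.allclose(rm.ratios.to_numpy(), 1.0)

    def test_library_size_confound_removed(self):
        base = np.tile(np.array([[500], [800], [1200]]), (1, 4))
        base[:, 0] *= 2  # double library, same diploid dosage
        rm = sh.normalize_counts(make_matrix(base))
        assert np.allclose(rm.ratios["S0"].to_numpy(), 1.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(7)
        counts = rng.poisson(1000, size=(30, 5))
        a = sh.normalize_counts(make_matrix(counts))
        scaled = counts.astype(float).copy()
        scaled[:, 2] *= 7.3
        b = sh.normalize_counts(make_matrix(scaled.astype(int) * 0 + scaled))
        assert np.allclose(a.ratios.to_numpy(), b.ratios.to_numpy(), atol=1e-9)

    def test_low_reference_flagged_uncallable(self):
        counts = np.full((5, 4), 2000)
        counts[2, :] = 10  # capture dropout across the batch
        rm = sh.normalize_counts(make_matrix(counts))
        assert rm.ratios.iloc[2].isna().all()
        assert not rm.callable_mask.iloc[2].any()

    def test_small_batch_and_degenerate_sample_errors(self):
        with pytest.raises(ValueError, match=">= 3 samples"):
            make_matrix(np.full((4, 2), 100))
        counts = np.full((4, 3), 100)
        counts[:, 1] = 0
        with pytest.raises(ValueError, match="all-zero"):
            sh.normalize_counts(make_matrix(counts))

    def test_het_deletion_ratio_band_monte_carlo(self):
        # 6-sample batches with one CN1 event: event ratios in [0.4, 0.6]
        # in >= 95% of 200 seeded replicates (generative-model oracle).
        # The panel is large relative to the event, as in a real design —
        # total-count normalization is then only negligibly perturbed.
        design = PanelDesign(make_matrix(np.zeros((100, 3), int)).intervals)
        event = sh.CnvEvent("S01", "chr1", 5_000, 8_000, 1)  # 3 intervals
        hits = 0
        for seed in range(200):
            cm = sh.simulate_coverage(
                design,
                sh.SimulationConfig(n_samples=6, mean_depth=100,
                                    cnv_events=(event,), seed=seed),
            )
            rm = sh.normalize_counts(cm)
            vals = rm.ratios.loc[5:7, "S01"]
            hits += bool(((vals >= 0.4) & (vals <= 0.6)).all())
        assert hits >= 190


class TestCalling:
    def test_all_normal_no_calls(self):
        rm = make_ratios(np.ones((20, 4)))
        assert sh.call_cnv_intervals(rm) == []

    def test_long_zero_run_called_homozygous_deletion(self):
        values = np.ones((30, 4))
        values[5:20, 0] = 0.0
        calls = sh.call_cnv_intervals(make_ratios(values))
        assert len(calls) == 1
        c = calls[0]
        assert (c.direction, c.zygosity) == ("deletion", "homozygous")
        assert (c.first_interval, c.last_interval) == (5, 19)

    def test_min_intervals_controls_single_interval_calls(self):
        values = np.ones((10, 4))
        values[4, 0] = 0.5
        assert sh.call_cnv_intervals(make_ratios(values)) == []
        config = sh.CnvConfig(min_intervals=1)
        calls = sh.call_cnv_intervals(make_ratios(values), config)
        assert len(calls) == 1
        assert calls[0].zygosity == "heterozygous"
        assert calls[0].n_intervals == 1

    def test_interior_dropout_tolerated_by_max_gap(self):
        values = np.ones((10, 4))
        values[3:8, 0] = 0.5
        values[5, 0] = 1.0  # one interior normal interval
        calls = sh.call_cnv_intervals(make_ratios(values))
        assert len(calls) == 1
        assert calls[0].n_intervals == 4
        assert (calls[0].first_interval, calls[0].last_interval) == (3, 7)
        # gap larger than max_gap splits the run
        values[5:7, 0] = 1.0
        calls = sh.call_cnv_intervals(make_ratios(values), sh.CnvConfig())
        assert [c.n_intervals for c in calls] == [2]  # 3:5 kept, 7 alone dropped

    def test_threshold_is_strict(self):
        config = sh.CnvConfig()
        assert classify_interval(0.6, config) == "normal"
        assert classify_interval(1.40, config) == "normal"
        assert classify_interval(0.5999, config) == "deletion"
        assert classify_interval(1.4001, config) == "duplication"

    def test_classification_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        values = rng.uniform(0, 2, size=(50, 5))
        config = sh.CnvConfig()
        for ratio in values.ravel():
            if ratio < 0.6:
                expected = "deletion"
            elif ratio > 1.40:
                expected = "duplication"
            else:
                expected = "normal"
            assert classify_interval(ratio, config) == expected

    def test_threshold_monotonicity(self):
        # a stricter threshold never brings new territory into calls: the
        # set of (sample, interval) positions covered by calls shrinks
        rng = np.random.default_rng(3)
        values = rng.uniform(0, 2, size=(40, 4))
        rm = make_ratios(values)

        def covered(config, direction):
            return {
                (c.sample, i)
                for c in sh.call_cnv_intervals(rm, config)
                if c.direction == direction
                for i in range(c.first_interval, c.last_interval + 1)
            }

        base_dup = covered(sh.CnvConfig(), "duplication")
        for theta in (1.5, 1.7, 1.9):
            assert covered(sh.CnvConfig(theta_dup=theta), "duplication") <= base_dup
        base_del = covered(sh.CnvConfig(), "deletion")
        for theta in (0.5, 0.3, 0.1):
            assert covered(sh.CnvConfig(theta_del=theta), "deletion") <= base_del

    def test_calls_sorted_and_non_overlapping(self):
        values = np.ones((40, 4))
        values[2:6, 0] = 0.5
        values[10:14, 0] = 1.6
        values[20:26, 0] = 0.0
        calls = [c for c in sh.call_cnv_intervals(make_ratios(values))
                 if c.sample == "S0"]
        spans = [(c.first_interval, c.last_interval) for c in calls]
        assert spans == sorted(spans)
        for (a1, b1), (a2, b2) in zip(spans, spans[1:]):
            assert b1 < a2


class TestRefinement:
    def test_clean_step_recovered_exactly(self):
        n = 20_000
        depth = np.full(n, 500.0)
        left, right = 7_001, 12_000  # 1-based within track starting at 1
        depth[left - 1: right] = 0.0
        sample = sh.CoverageTrack("chr1", 1, depth)
        reference = sh.CoverageTrack("chr1", 1, np.full(n, 500.0))
        call = CnvCall(
            sample="S", chrom="chr1", start=6_500, end=12_500,
            first_interval=0, last_interval=0, direction="deletion",
            mean_ratio=0.0, zygosity="homozygous", n_intervals=5,
        )
        refined = sh.refine_breakpoints(call, sample, reference)
        assert refined.refined_breakpoints == (left, right)

    def test_no_crossing_returns_warning(self):
        n = 5_000
        sample = sh.CoverageTrack("chr1", 1, np.full(n, 500.0))
        reference = sh.CoverageTrack("chr1", 1, np.full(n, 500.0))
        call = CnvCall(
            sample="S", chrom="chr1", start=1_000, end=2_000,
            first_interval=0, last_interval=0, direction="deletion",
            mean_ratio=0.5, zygosity="heterozygous", n_intervals=2,
        )
        refined = sh.refine_breakpoints(call, sample, reference)
        assert refined.refined_breakpoints is None
        assert refined.refinement_warning == "no-sustained-crossing"

    def test_noisy_duplication_breakpoint_error_bounded(self):
        # simulation oracle with known truth: median |error| <= 25 bp over
        # 100 noisy heterozygous duplications
        errors = []
        for seed in range(100):
            left, right = 10_001, 20_000
            sample, reference = sh.simulate_base_coverage(
                "chr1", 1, 30_000, left, right, copy_number=3,
                mean_depth=100, seed=seed,
            )
            call = CnvCall(
                sample="S", chrom="chr1", start=9_000, end=21_000,
                first_interval=0, last_interval=0, direction="duplication",
                mean_ratio=1.5, zygosity="heterozygous", n_intervals=10,
            )
            refined = sh.refine_breakpoints(call, sample, reference)
            assert refined.refined_breakpoints is not None
            l, r = refined.refined_breakpoints
            errors += [abs(l - left), abs(r - right)]
        assert np.median(errors) <= 25


class TestAlleleBalance:
    def test_balanced_snps_support_two_copies(self):
        snps = pd.DataFrame({"ref_depth": [50] * 10, "alt_depth": [50] * 10})
        assert sh.allele_balance_shift(snps).verdict == "supports two copies"

    def test_two_thirds_fraction_supports_three_copies(self):
        snps = pd.DataFrame({"ref_depth": [67] * 10, "alt_depth": [33] * 10})
        summary = sh.allele_balance_shift(snps)
        assert summary.verdict == "supports three copies"
        assert summary.mean_major_fraction == pytest.approx(0.67)

    def test_no_qualifying_snps_inconclusive(self):
        snps = pd.DataFrame({"ref_depth": [5], "alt_depth": [4]})
        summary = sh.allele_balance_shift(snps)
        assert summary.verdict == "inconclusive"
        assert "depth" in summary.reason

    def test_simulated_three_copy_spans_detected(self):
        # binomial oracle, p = 2/3: 20 SNPs at depth 100
        support = 0
        for seed in range(200):
            snps = sh.simulate_allele_depths(3, 20, 100, seed=seed)
            verdict = sh.allele_balance_shift(snps).verdict
            support += verdict == "supports three copies"
        assert support >= 190
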