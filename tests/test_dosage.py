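import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from seedloh import (
    GenomicInterval,
    MosaicSimParams,
    bin_depths,
    call_deletions,
    call_deletions_refined,
    compute_rrd,
    estimate_mutant_fraction,
    locus_rrd,
    refine_deletion_call,
    simulate_bins,
)
from seedloh.dosage import RRDTable


def _rrd_table(values, chrom="chrA", bin_size=100_000, depth_scale=10.0):
    """Build an RRDTable directly from intended RRD values."""
    n = len(values)
    bins = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": [i * bin_size for i in range(n)],
            "end": [(i + 1) * bin_size for i in range(n)],
            "mean_depth": [v * depth_scale for v in values],
            "rrd": list(map(float, values)),
        }
    )
    return RRDTable(bins=bins, normalization_constant=depth_scale)


class TestBinDepths:
    def test_constant_depth_tiles_with_partial_last_bin(self, small_layout):
        per_base = pd.DataFrame(
            {
                "chrom": "chrA",
                "pos": np.arange(250_000),
                "depth": 10.0,
            }
        )
        bins = bin_depths(per_base, small_layout, 100_000)
        chra = bins[bins["chrom"] == "chrA"]
        assert list(chra["end"] - chra["start"]) == [100_000, 100_000, 50_000]
        assert chra["mean_depth"].tolist() == [10.0, 10.0, 10.0]

    def test_empty_input_gives_zero_depth_everywhere(self, small_layout):
        per_base = pd.DataFrame({"chrom": [], "pos": [], "depth": []})
        bins = bin_depths(per_base, small_layout, 100_000)
        assert (bins["mean_depth"] == 0).all()
        # chrA: 3 bins, chrB: 4 bins
        assert len(bins) == 7

    def test_half_covered_bin_averages_over_all_positions(self, small_layout):
        # depth 10 on the first 50 kb only: absent positions count as zero
        per_base = pd.DataFrame(
            {"chrom": "chrA", "pos": np.arange(50_000), "depth": 10.0}
        )
        bins = bin_depths(per_base, small_layout, 100_000)
        assert bins["mean_depth"].iloc[0] == pytest.approx(5.0)

    def test_unknown_chromosome_rejected(self, small_layout):
        per_base = pd.DataFrame({"chrom": ["chrZ"], "pos": [5], "depth": [1.0]})
        with pytest.raises(ValueError, match="chrZ"):
            bin_depths(per_base, small_layout, 100_000)


class TestComputeRrd:
    def test_simple_median_normalization(self):
        bins = pd.DataFrame(
            {
                "chrom": ["c"] * 3,
                "start": [0, 100, 200],
                "end": [100, 200, 300],
                "mean_depth": [10.0, 10.0, 5.0],
            }
        )
        rrd = compute_rrd(bins)
        assert rrd.normalization_constant == 10.0
        assert rrd.bins["rrd"].tolist() == [1.0, 1.0, 0.5]

    def test_uniform_depths_give_unit_rrd(self, uniform_bins):
        rrd = compute_rrd(uniform_bins)
        assert (rrd.bins["rrd"] == 1.0).all()

    def test_median_rrd_is_one_by_construction(self, arabidopsis_layout):
        bins = simulate_bins(
            MosaicSimParams(layout=arabidopsis_layout, mean_depth=35, seed=21)
        )
        rrd = compute_rrd(bins)
        assert float(rrd.bins["rrd"].median()) == pytest.approx(1.0)

    def test_all_zero_depths_rejected(self, uniform_bins):
        bins = uniform_bins.assign(mean_depth=0.0)
        with pytest.raises(ValueError, match="cannot normalize"):
            compute_rrd(bins)


class TestCallDeletions:
    def test_single_run_called_with_size_and_fraction(self):
        rrd = _rrd_table([1, 1, 0.6, 0.6, 0.6, 1])
        calls = call_deletions(rrd, threshold=0.8, min_bins=3)
        assert len(calls) == 1
        call = calls[0]
        assert call.n_bins == 3
        assert call.size_bp == 300_000
        assert call.interval.start == 200_000
        assert call.mean_rrd == pytest.approx(0.6)
        assert call.mutant_fraction_est == pytest.approx(0.8)

    def test_flat_profile_yields_no_calls(self):
        assert call_deletions(_rrd_table([1.0] * 10)) == []

    def test_short_runs_filtered_by_min_bins(self):
        rrd = _rrd_table([1, 0.5, 0.5, 1, 1, 0.5, 1])
        assert call_deletions(rrd, min_bins=3) == []

    def test_gap_merging_bridges_isolated_high_bin(self):
        rrd = _rrd_table([1, 0.6, 0.6, 1, 0.6, 0.6, 1])
        assert len(call_deletions(rrd, min_bins=3, gap=0)) == 0
        merged = call_deletions(rrd, min_bins=3, gap=1)
        assert len(merged) == 1
        assert merged[0].n_bins == 5

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError, match="threshold"):
            call_deletions(_rrd_table([1.0]), threshold=1.5)

    @settings(derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.floats(min_value=0.05, max_value=1.5), min_size=1, max_size=20
        ),
        st.floats(min_value=0.3, max_value=1.0),
        st.integers(min_value=1, max_value=4),
    )
    def test_matches_brute_force_run_enumeration(self, values, threshold, min_bins):
        """Oracle: naive scan over every start index finds the same maximal
        qualifying runs as the implementation."""
        rrd = _rrd_table(values)
        expected = []
        i = 0
        while i < len(values):
            if values[i] < threshold:
                j = i
                while j < len(values) and values[j] < threshold:
                    j += 1
                if j - i >= min_bins:
                    expected.append((i, j))
                i = j
            else:
                i += 1
        calls = call_deletions(rrd, threshold=threshold, min_bins=min_bins)
        got = [
            (c.interval.start // 100_000, c.interval.end // 100_000) for c in calls
        ]
        assert got == expected

    def test_calls_sorted_and_non_overlapping(self, arabidopsis_layout):
        deletion = GenomicInterval("Chr2", 3_000_000, 4_500_000)
        bins = simulate_bins(
            MosaicSimParams(
                layout=arabidopsis_layout,
                deletion=deletion,
                mutant_fraction=0.9,
                mean_depth=50,
                seed=13,
            )
        )
        calls = call_deletions(compute_rrd(bins))
        by_chrom: dict[str, list] = {}
        for c in calls:
            by_chrom.setdefault(c.interval.chrom, []).append(c)
        for chrom_calls in by_chrom.values():
            for a, b in zip(chrom_calls, chrom_calls[1:]):
                assert a.interval.end <= b.interval.start

    def test_simulated_19_bin_deletion_recovered(self, arabidopsis_layout):
        deletion = GenomicInterval("Chr4", 6_000_000, 7_900_000)
        bins = simulate_bins(
            MosaicSimParams(
                layout=arabidopsis_layout,
                deletion=deletion,
                mutant_fraction=0.7,
                mean_depth=50,
                seed=2,
            )
        )
        rrd = compute_rrd(bins)
        calls = call_deletions_refined(rrd, threshold=0.8, min_bins=3)
        best = max(
            calls,
            key=lambda c: min(c.interval.end, deletion.end)
            - max(c.interval.start, deletion.start),
        )
        assert abs(best.size_bp - 1_900_000) <= 100_000


class TestRefineDeletionCall:
    def test_noiseless_boundaries_unchanged(self):
        rrd = _rrd_table([1, 1, 0.65, 0.65, 0.65, 0.65, 1, 1], depth_scale=50)
        call = call_deletions(rrd)[0]
        refined = refine_deletion_call(rrd, call)
        assert refined.interval == call.interval

    def test_bridges_run_broken_by_single_noisy_bin(self):
        # one interior bin's noise crossed the threshold, splitting the run;
        # the two-level likelihood reunites the full deleted span
        rrd = _rrd_table(
            [1, 1, 0.65, 0.62, 0.85, 0.64, 0.66, 1, 1], depth_scale=50
        )
        fragments = call_deletions(rrd, min_bins=2)
        assert len(fragments) == 2
        for frag in fragments:
            refined = refine_deletion_call(rrd, frag)
            assert refined.interval.start == 200_000
            assert refined.interval.end == 700_000
            assert refined.n_bins == 5


class TestLocusRrd:
    def test_uniform_region_gives_one(self, small_layout):
        rrd = _rrd_table([1.0, 1.0, 1.0], chrom="chrA")
        assert locus_rrd(rrd, small_layout.loci["TT8"]) == pytest.approx(1.0)

    def test_locus_straddling_edge_averages_bins(self):
        rrd = _rrd_table([1.0, 0.65])
        locus = GenomicInterval("chrA", 90_000, 110_000)
        assert locus_rrd(rrd, locus) == pytest.approx(0.825)

    def test_locus_outside_bins_rejected(self):
        rrd = _rrd_table([1.0, 1.0])
        with pytest.raises(ValueError, match="no bin"):
            locus_rrd(rrd, GenomicInterval("chrZ", 0, 1000))

    def test_simulated_deleted_locus_near_065(self, arabidopsis_layout):
        tt8 = arabidopsis_layout.loci["TT8"]
        deletion = GenomicInterval("Chr4", 5_500_000, 7_000_000)
        bins = simulate_bins(
            MosaicSimParams(
                layout=arabidopsis_layout,
                deletion=deletion,
                mutant_fraction=0.7,
                mean_depth=50,
                seed=17,
            )
        )
        value = locus_rrd(compute_rrd(bins), tt8)
        assert value == pytest.approx(0.65, abs=0.35)  # single-bin Poisson noise


class TestEstimateMutantFraction:
    @pytest.mark.parametrize(
        "rrd,m", [(1.0, 0.0), (0.5, 1.0), (0.65, 0.7), (1.2, 0.0), (0.1, 1.0)]
    )
    def test_inverts_mixture_model_with_clamping(self, rrd, m):
        assert estimate_mutant_fraction(rrd) == pytest.approx(m)

    def test_negative_rrd_rejected(self):
        with pytest.raises(ValueError):
            estimate_mutant_fraction(-0.1)

    @pytest.mark.parametrize("m_true", [0.3, 0.5, 0.7, 0.9])
    def test_round_trip_recovery_within_005(self, arabidopsis_layout, m_true):
        # mean over replicate simulations: one 20-bin replicate has
        # sd(m_est) ≈ 0.05 at depth 50, the same size as the tolerance
        deletion = GenomicInterval("Chr3", 2_000_000, 4_000_000)  # 20 bins
        estimates = []
        for seed in range(8):
            bins = simulate_bins(
                MosaicSimParams(
                    layout=arabidopsis_layout,
                    deletion=deletion,
                    mutant_fraction=m_true,
                    mean_depth=50,
                    seed=seed,
                )
            )
            rrd = compute_rrd(bins)
            inside = rrd.bins[
                (rrd.bins["chrom"] == "Chr3")
                & (rrd.bins["start"] >= deletion.start)
                & (rrd.bins["end"] <= deletion.end)
            ]
            estimates.append(
                estimate_mutant_fraction(float(inside["rrd"].mean()))
            )
        assert abs(float(np.mean(estimates)) - m_true) <= 0.05
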