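"""CNA pipeline: binning, normalization, segmentation, events, support."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import pearsonr
from sklearn.metrics import adjusted_rand_score

from clonemap import cna, fixtures
from tests.conftest import copy_number_matrix, make_cna_dataset


class TestVariableBins:
    def test_uniform_reads_give_equal_bins(self):
        # reads exactly evenly spaced on one 1 Mb chromosome
        pos = np.arange(50, 1_000_000, 100, dtype=float)
        bins = cna.build_variable_bins({"chr1": pos}, 10, {"chr1": 1_000_000})
        widths = (bins["end"] - bins["start"]).to_numpy()
        assert len(bins) == 10
        np.testing.assert_allclose(widths, 100_000, atol=1)

    def test_denser_left_half_narrower_bins(self):
        rng = np.random.default_rng(0)
        left = rng.uniform(0, 500_000, 200_000)
        right = rng.uniform(500_000, 1_000_000, 100_000)
        pos = np.sort(np.concatenate([left, right]))
        bins = cna.build_variable_bins({"chr1": pos}, 12, {"chr1": 1_000_000})
        widths = (bins["end"] - bins["start"]).to_numpy()
        left_w = widths[bins["end"] <= 500_000].mean()
        right_w = widths[bins["start"] >= 500_000].mean()
        assert left_w == pytest.approx(right_w / 2, rel=0.1)

    def test_equal_expected_counts_within_one_read(self):
        rng = np.random.default_rng(1)
        reads = {"chr1": np.sort(rng.uniform(0, 5e6, 40_000)),
                 "chr2": np.sort(rng.uniform(0, 5e6, 20_000))}
        bins = cna.build_variable_bins(reads, 60, fixtures.default_genome())
        counts, outside = cna.bin_reads(reads, bins)
        assert outside == 0
        for chrom in ("chr1", "chr2"):
            c = counts[(bins["chrom"] == chrom).to_numpy()]
            assert c.max() - c.min() <= 1

    def test_single_bin(self):
        pos = np.linspace(0, 4e6, 500)
        bins = cna.build_variable_bins({"chr1": pos}, 1, {"chr1": 5_000_000})
        assert len(bins) == 1
        assert (bins.iloc[0]["start"], bins.iloc[0]["end"]) == (0, 5_000_000)

    def test_underpopulated_chrom_collapses_with_warning(self):
        # chr2 has many reads but all at one position: cannot fill its bins
        reads = {"chr1": np.linspace(0, 5e6, 1000),
                 "chr2": np.full(200, 1e6)}
        with pytest.warns(UserWarning, match="chr2"):
            bins = cna.build_variable_bins(reads, 50, fixtures.default_genome())
        assert (bins["chrom"] == "chr2").sum() == 1


class TestNormalization:
    def test_reference_against_itself_median_one(self, cna_dataset):
        bins, counts, _, _ = cna_dataset
        ref = counts["ref"].to_numpy()
        prof = cna.assign_and_normalize("ref", ref, bins, ref)
        assert np.median(prof.copy_ratio) == pytest.approx(1.0, abs=1e-12)

    def test_no_bias_normalization_is_gentle(self):
        bins = fixtures.uniform_bins(fixtures.default_genome(), 200)
        counts = fixtures.simulate_binned_depth(
            bins, {"d": np.full(200, 2)}, [("s", "d")],
            reads_per_sample=500_000, seed=2,
        )["s"].to_numpy()
        norm = cna.gc_normalize(counts, bins["gc"].to_numpy())
        rel = np.abs(norm - counts) / counts
        assert np.median(rel) < 0.05

    def test_quadratic_bias_removed(self):
        bins = fixtures.uniform_bins(fixtures.default_genome(), 500)
        counts = fixtures.simulate_binned_depth(
            bins, {"d": np.full(500, 2)}, [("s", "d")],
            reads_per_sample=500_000, gc_bias=fixtures.quadratic_gc_bias, seed=3,
        )["s"].to_numpy()
        gc = bins["gc"].to_numpy()
        r_pre = pearsonr(counts, gc).statistic
        norm = cna.gc_normalize(counts, gc)
        r_post = pearsonr(norm, gc).statistic
        assert r_pre > 0.5
        assert abs(r_post) < 0.05

    def test_reads_outside_bins_reported(self):
        bins = fixtures.uniform_bins({"chr1": 1_000_000}, 10)
        reads = {"chr1": np.array([100.0, 500.0]), "chrX": np.array([5.0])}
        counts, outside = cna.bin_reads(reads, bins)
        assert counts.sum() == 2 and outside == 0  # chrX silently absent bins
        prof = cna.assign_and_normalize("s", {"chr1": np.array([100.0, 2e6])},
                                        bins, np.ones(10))
        assert prof.reads_outside_bins == 1


class TestSegmentation:
    def test_flat_profiles_no_breakpoints(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame(rng.normal(2.0, 0.05, size=(80, 4)))
        seg = cna.multisample_segment(X, gamma=20)
        assert seg.breakpoints == [0]

    def test_planted_step_found_exactly(self):
        rng = np.random.default_rng(1)
        X = rng.normal(2.0, 0.1, size=(60, 3))
        X[20:40] += 1.0  # height-1 step in all samples
        seg = cna.multisample_segment(pd.DataFrame(X), gamma=20)
        assert len(seg.breakpoints) == 3
        assert abs(seg.breakpoints[1] - 20) <= 1
        assert abs(seg.segments["end_bin"].iloc[1] - 40) <= 1

    def test_huge_gamma_no_breakpoints(self):
        rng = np.random.default_rng(2)
        X = rng.normal(2.0, 0.1, size=(50, 3))
        X[10:30] += 2.0
        seg = cna.multisample_segment(pd.DataFrame(X), gamma=1e9)
        assert seg.breakpoints == [0]

    def test_invalid_gamma_rejected(self):
        with pytest.raises(ValueError):
            cna.multisample_segment(pd.DataFrame(np.ones((10, 2))), gamma=0)

    @pytest.mark.parametrize("seed", range(8))
    def test_dp_equals_exhaustive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 31))
        X = rng.normal(2.0, 0.1, size=(n, 3))
        if rng.random() < 0.8:
            s = int(rng.integers(0, n - 5))
            e = s + int(rng.integers(3, min(10, n - s)))
            X[s:e] += rng.choice([-1.0, 1.0])
        seg = cna.multisample_segment(pd.DataFrame(X), gamma=20)
        starts, ends = seg.breakpoints, seg.breakpoints[1:] + [n]
        dp_cost = 20.0 * (len(starts) - 1)
        for a, b in zip(starts, ends):
            blk = X[a:b]
            dp_cost += float(((blk - blk.mean(axis=0)) ** 2).sum())
        oracle_cost, _ = cna.exhaustive_segment_cost(X, 20.0, max_segments=5)
        assert len(starts) < 5  # oracle's enumeration covers the optimum
        assert dp_cost == pytest.approx(oracle_cost, abs=1e-8)

    def test_breakpoints_never_span_chromosomes(self, cna_dataset):
        bins, counts, _, _ = cna_dataset
        cn = copy_number_matrix(bins, counts).drop(columns=["ref"])
        seg = cna.multisample_segment(cn, bins, gamma=20)
        for _, row in seg.segments.iterrows():
            chroms = bins["chrom"].iloc[row["start_bin"]:row["end_bin"]].unique()
            assert len(chroms) == 1


class TestMergeLevels:
    def test_identical_distributions_merge(self):
        rng = np.random.default_rng(0)
        seg_of_bin = np.repeat([0, 1], 40)
        vals = rng.normal(2.0, 0.1, 80)
        merged = cna.merge_levels(np.array([2.0, 2.01]), seg_of_bin, vals)
        assert merged[0] == merged[1]

    def test_distinct_levels_not_merged(self):
        rng = np.random.default_rng(1)
        seg_of_bin = np.repeat([0, 1], 40)
        vals = np.concatenate([rng.normal(1.0, 0.02, 40), rng.normal(2.0, 0.02, 40)])
        merged = cna.merge_levels(np.array([1.0, 2.0]), seg_of_bin, vals)
        assert merged[0] != merged[1]

    def test_close_levels_merge_by_floor(self):
        rng = np.random.default_rng(2)
        seg_of_bin = np.repeat([0, 1, 2], 30)
        vals = np.concatenate([
            rng.normal(1.0, 0.02, 30), rng.normal(1.02, 0.02, 30),
            rng.normal(2.0, 0.02, 30),
        ])
        merged = cna.merge_levels(np.array([1.0, 1.02, 2.0]), seg_of_bin, vals)
        assert merged[0] == merged[1]
        assert merged[2] != merged[0]

    def test_single_segment_identity(self):
        out = cna.merge_levels(np.array([1.5]), np.zeros(10, int), np.ones(10))
        assert out.tolist() == [1.5]


class TestEvents:
    def test_threshold_rules(self):
        seg = cna.SegmentedProfiles(
            breakpoints=[0, 5, 10],
            segments=pd.DataFrame(
                {"chrom": ["chr1"] * 3, "start_bin": [0, 5, 10],
                 "end_bin": [5, 10, 15]}
            ),
            levels=pd.DataFrame({"s": [2.0, 3.0, 1.0]}),
            gamma=20.0,
        )
        ev = cna.event_vectors(seg, reference_median=2.0, tolerance=0.25)
        assert ev["s"].tolist() == [0, 1, -1]

    def test_planted_gain_loss_through_pipeline(self):
        bins, counts, samples, events = make_cna_dataset(seed=2)
        cn = copy_number_matrix(bins, counts).drop(columns=["ref"])
        seg = cna.multisample_segment(cn, bins, gamma=20)
        ev = cna.event_vectors(seg, reference_median=2.0)
        evb = cna.events_per_bin(seg, ev, len(bins)).to_numpy()
        sub_of = dict(samples)
        cols = {s: i for i, s in enumerate(cn.columns)}
        hits = total = 0
        for e in events:
            carriers = [cols[s] for s in cn.columns if sub_of[s] == e.subclone]
            want = 1 if e.direction == "gain" else -1
            mid = (e.start_bin + e.end_bin) // 2
            for c in carriers:
                total += 1
                hits += evb[mid, c] == want
        assert hits / total >= 0.9


class TestClustering:
    def test_duplicates_merge_first(self):
        rng = np.random.default_rng(0)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": a, "c": rng.normal(size=50)})
        Z, corr = cna.correlation_cluster(X)
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert Z[0, :2].astype(int).tolist() == [0, 1]

    def test_anticorrelated_distance_two(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=50)
        X = pd.DataFrame({"a": a, "b": -a, "c": rng.normal(size=50)})
        _, corr = cna.correlation_cluster(X)
        assert corr.loc["a", "b"] == pytest.approx(-1.0)

    def test_recovers_planted_subclones(self, cna_dataset):
        bins, counts, samples, _ = cna_dataset
        cn = copy_number_matrix(bins, counts).drop(columns=["ref"])
        seg = cna.multisample_segment(cn, bins, gamma=20)
        ev = cna.event_vectors(seg, reference_median=2.0)
        labels = cna.cut_clusters(cna.correlation_cluster(ev)[0], 3)
        truth = [dict(samples)[c] for c in cn.columns]
        assert adjusted_rand_score(truth, labels) == 1.0


class TestAUSupport:
    def test_clear_two_block_high_support(self):
        rng = np.random.default_rng(0)
        base = np.zeros((60, 6))
        base[:30, :3] = 1.0
        base[30:, 3:] = 1.0
        X = pd.DataFrame(base + rng.normal(0, 0.3, base.shape),
                         columns=[f"s{i}" for i in range(6)])
        sup = cna.au_pvalues(X, n_bootstrap=200, seed=0)
        au = {frozenset(c): a for c, a in zip(sup.clades, sup.au)}
        block = au.get(frozenset({0, 1, 2})) or au.get(frozenset({3, 4, 5}))
        assert block is not None and block > 0.95

    def test_noise_not_uniformly_confident(self):
        rng = np.random.default_rng(1)
        X = pd.DataFrame(rng.normal(size=(60, 8)))
        sup = cna.au_pvalues(X, n_bootstrap=150, seed=1)
        inner = [a for c, a in zip(sup.clades, sup.au) if len(c) < 8]
        assert np.median(inner) < 0.95

    def test_zero_bootstrap_rejected(self):
        X = pd.DataFrame(np.ones((10, 4)))
        with pytest.raises(ValueError):
            cna.au_pvalues(X, n_bootstrap=0)

    def test_support_values_in_unit_interval(self):
        rng = np.random.default_rng(2)
        X = pd.DataFrame(rng.normal(size=(40, 5)))
        sup = cna.au_pvalues(X, n_bootstrap=100, seed=2)
        assert np.all((sup.au >= 0) & (sup.au <= 1))
        assert np.all((sup.bp >= 0) & (sup.bp <= 1))
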