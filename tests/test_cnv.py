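"""Copy-number stage: normalization, clustering, CBS, CS labeling, regions."""

import warnings

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from cinsig.cnv import (
    CINRegion,
    CINRegionSet,
    Segment,
    SegmentSet,
    ZeroMedianError,
    best_split,
    call_cin_regions,
    cbs_segment,
    cbs_segment_contig,
    cluster_cells,
    filter_genes_to_stable_regions,
    label_cs_cluster,
    normalize_counts,
    shared_cin_regions,
)
from cinsig.grid import BinGrid
from cinsig.simdata import simulate_cells

from conftest import small_sim_config


def make_grid(n_bins, bin_size=100, contig="chr1", weight=None):
    rows = [(contig, i * bin_size, (i + 1) * bin_size) for i in range(n_bins)]
    df = pd.DataFrame(rows, columns=["contig", "start", "end"])
    if weight is not None:
        df["weight"] = weight
    return BinGrid(df)


class TestNormalize:
    def test_formula(self):
        grid = make_grid(4)
        counts = pd.DataFrame({"a": [10, 10, 20, 10]})
        out = normalize_counts(counts, grid)
        assert out["a"].tolist() == [2, 2, 4, 2]

    def test_constant_profile(self):
        grid = make_grid(5)
        counts = pd.DataFrame({"a": [7] * 5})
        assert normalize_counts(counts, grid)["a"].tolist() == [2] * 5

    def test_zero_median_rejected(self):
        grid = make_grid(4)
        counts = pd.DataFrame({"bad": [0, 0, 0, 1]})
        with pytest.raises(ZeroMedianError, match="bad"):
            normalize_counts(counts, grid)

    def test_weights_adjusted(self):
        grid = make_grid(4, weight=[1.0, 1.0, 0.5, 1.0])
        counts = pd.DataFrame({"a": [10, 10, 5, 10]})
        out = normalize_counts(counts, grid)
        assert out["a"].tolist() == [2, 2, 2, 2]

    def test_median_exactly_two(self, rng):
        grid = make_grid(31)
        counts = pd.DataFrame(rng.integers(1, 100, size=(31, 10)), columns=[f"c{i}" for i in range(10)])
        out = normalize_counts(counts, grid)
        assert np.allclose(np.median(out, axis=0), 2.0, atol=1e-9)


class TestClusterCells:
    def test_two_clean_groups(self):
        grid = make_grid(20)
        data = {}
        for i in range(20):
            base = np.full(20, 2.0)
            if i >= 10:
                base[:10] = 1.0
            data[f"c{i:02d}"] = base + 0.01 * np.random.default_rng(i).normal(size=20)
        profiles = pd.DataFrame(data)
        assignment = cluster_cells(profiles, k=2)
        truth = [0] * 10 + [1] * 10
        found = pd.factorize(np.array([assignment.labels[f"c{i:02d}"] for i in range(20)]))[0]
        assert adjusted_rand_score(truth, found) == 1.0

    def test_k1_single_cluster(self):
        profiles = pd.DataFrame(np.random.default_rng(0).normal(2, 0.1, (5, 8)))
        profiles.columns = [f"c{i}" for i in range(8)]
        assignment = cluster_cells(profiles, k=1)
        assert set(assignment.labels) == {"cluster_1"}

    def test_degenerate_identical_profiles_warn(self):
        profiles = pd.DataFrame(np.full((5, 6), 2.0), columns=[f"c{i}" for i in range(6)])
        with pytest.warns(UserWarning, match="degenerate"):
            assignment = cluster_cells(profiles, k=2)
        assert len(assignment.labels) == 6

    def test_k_too_large(self):
        profiles = pd.DataFrame(np.ones((3, 2)), columns=["a", "b"])
        with pytest.raises(ValueError, match="exceeds"):
            cluster_cells(profiles, k=5)

    def test_column_order_invariant(self):
        rng = np.random.default_rng(5)
        profiles = pd.DataFrame(rng.normal(2, 0.3, (10, 12)),
                                columns=[f"c{i:02d}" for i in range(12)])
        a = cluster_cells(profiles, k=3)
        b = cluster_cells(profiles[list(reversed(profiles.columns))], k=3)
        pd.testing.assert_series_equal(a.labels, b.labels)


def brute_force_best_split(x, min_width=2):
    """Literal triple-loop oracle for the maximal arc statistic."""
    n = len(x)
    best = None
    for i in range(n):
        for j in range(i + 1, n + 1):
            n_in = j - i
            n_out = n - n_in
            if n_in < min_width or n_out < min_width:
                continue
            mean_in = sum(x[i:j]) / n_in
            mean_out = (sum(x) - sum(x[i:j])) / n_out
            t = abs(mean_in - mean_out) / (1.0 / n_in + 1.0 / n_out) ** 0.5
            if best is None or t > best[2]:
                best = (i, j, t)
    return best


class TestCBS:
    def test_clean_step_split_found(self):
        x = np.array([2, 2, 2, 4, 4, 4], float)
        i, j, t = best_split(x)
        assert {i, j} <= {0, 3, 6} and (i == 3 or j == 3)
        oracle = brute_force_best_split(x)
        assert t == pytest.approx(oracle[2])

    def test_clean_step_segment_means(self):
        # 20 bins give the permutation test enough granularity at alpha=0.01
        rng = np.random.default_rng(0)
        x = np.concatenate([np.full(10, 2.0), np.full(10, 4.0)]) + 0.02 * rng.normal(size=20)
        bps = cbs_segment_contig(x, rng=np.random.default_rng(1))
        assert bps == [10]

    def test_flat_profile_single_segment(self):
        x = np.full(6, 2.0)
        assert cbs_segment_contig(x, rng=np.random.default_rng(0)) == []

    def test_matches_bruteforce_on_random_profiles(self, rng):
        # an arc touching a contig edge and its complement score identically,
        # so compare the induced breakpoint sets, not raw (i, j) pairs
        for _ in range(50):
            n = int(rng.integers(4, 13))
            x = rng.normal(2, 1, size=n)
            mine = best_split(x)
            oracle = brute_force_best_split(list(x))
            assert mine[2] == pytest.approx(oracle[2], abs=1e-10)
            mine_bps = {b for b in mine[:2] if 0 < b < n}
            oracle_bps = {b for b in oracle[:2] if 0 < b < n}
            assert mine_bps == oracle_bps

    def test_noisy_step_recovery(self):
        hits = 0
        for rep in range(100):
            rng = np.random.default_rng(rep)
            x = np.where(np.arange(50) >= 25, 3.0, 2.0) + 0.2 * rng.normal(size=50)
            bps = cbs_segment_contig(x, rng=np.random.default_rng(10_000 + rep))
            hits += any(abs(b - 25) <= 1 for b in bps)
        assert hits >= 95

    def test_segments_tile_genome(self):
        grid = make_grid(30)
        rng = np.random.default_rng(3)
        prof = pd.DataFrame({"cl": np.concatenate([np.full(15, 2.0), np.full(15, 3.5)])
                             + 0.05 * rng.normal(size=30)})
        segs = cbs_segment(prof, grid, seed=0)
        df = segs.to_frame()
        assert df["n_bins"].sum() == 30
        # contiguous tiling
        bounds = df.sort_values("start")[["start", "end"]].to_numpy()
        assert bounds[0, 0] == 0 and bounds[-1, 1] == 3000
        assert (bounds[1:, 0] == bounds[:-1, 1]).all()


class TestCSLabeling:
    def _assignment(self, sizes):
        labels = {}
        i = 0
        for cl, n in sizes.items():
            for _ in range(n):
                labels[f"c{i:03d}"] = cl
                i += 1
        from cinsig.cnv import ClusterAssignment

        return ClusterAssignment(labels=pd.Series(labels))

    def test_obvious_cs(self):
        grid = make_grid(10)
        segs = SegmentSet(segments={
            "A": [Segment("chr1", 0, 1000, 2.05, 10)],
            "B": [Segment("chr1", 0, 300, 1.0, 3), Segment("chr1", 300, 1000, 2.0, 7)],
        })
        out = label_cs_cluster(segs, self._assignment({"A": 5, "B": 5}), grid)
        assert out.cs_cluster == "A"

    def test_no_cs_when_all_aberrant(self):
        grid = make_grid(10)
        segs = SegmentSet(segments={
            "A": [Segment("chr1", 0, 1000, 3.0, 10)],
            "B": [Segment("chr1", 0, 1000, 1.0, 10)],
        })
        with pytest.warns(UserWarning, match="no chromosomally stable"):
            out = label_cs_cluster(segs, self._assignment({"A": 5, "B": 5}), grid)
        assert out.cs_cluster is None

    def test_tie_broken_by_size(self):
        grid = make_grid(10)
        segs = SegmentSet(segments={
            "A": [Segment("chr1", 0, 1000, 2.0, 10)],
            "B": [Segment("chr1", 0, 1000, 2.0, 10)],
        })
        out = label_cs_cluster(segs, self._assignment({"A": 3, "B": 7}), grid)
        assert out.cs_cluster == "B"


class TestCINRegions:
    def test_gain_loss_thresholds(self):
        segs = SegmentSet(segments={"X": [
            Segment("chr1", 0, 100, 3.1, 1),
            Segment("chr1", 100, 200, 2.3, 1),
            Segment("chr1", 200, 300, 1.2, 1),
        ]})
        regions = call_cin_regions(segs, cn_delta=0.5)
        out = [(r.start, r.end, r.direction) for r in regions.regions["X"]]
        assert out == [(0, 100, "gain"), (200, 300, "loss")]

    def test_adjacent_merge(self):
        segs = SegmentSet(segments={"X": [
            Segment("chr1", 0, 100, 1.0, 1),
            Segment("chr1", 100, 200, 1.3, 1),
        ]})
        regions = call_cin_regions(segs, cn_delta=0.5)
        assert [(r.start, r.end) for r in regions.regions["X"]] == [(0, 200)]

    def test_shared_intersection(self):
        a = [CINRegion("chr1", 0, 100, "gain")]
        b = [CINRegion("chr1", 50, 150, "gain")]
        out = shared_cin_regions([a, b])
        assert [(r.start, r.end, r.direction) for r in out] == [(50, 100, "gain")]

    def test_shared_direction_mismatch(self):
        a = [CINRegion("chr1", 0, 100, "gain")]
        b = [CINRegion("chr1", 0, 100, "loss")]
        assert shared_cin_regions([a, b]) == []

    def test_shared_commutative_associative(self):
        a = [CINRegion("chr1", 0, 100, "gain"), CINRegion("chr2", 0, 50, "loss")]
        b = [CINRegion("chr1", 50, 150, "gain"), CINRegion("chr2", 10, 60, "loss")]
        c = [CINRegion("chr1", 70, 200, "gain")]
        abc1 = shared_cin_regions([shared_cin_regions([a, b]), c])
        abc2 = shared_cin_regions([a, shared_cin_regions([b, c])])
        abc3 = shared_cin_regions([c, b, a])
        assert abc1 == abc2 == abc3

    def test_gene_filter(self):
        regions = [CINRegionSet(regions={"X": [CINRegion("chr1", 100, 200, "loss")]})]
        genes = pd.DataFrame([
            ("in_region", "chr1", 120, 180),
            ("outside", "chr1", 300, 400),
            ("straddle", "chr1", 199, 250),
            ("other_contig", "chr2", 0, 50),
        ], columns=["gene", "contig", "start", "end"])
        out = filter_genes_to_stable_regions(genes, regions)
        assert out["gene"].tolist() == ["outside", "other_contig"]

    def test_gene_on_unknown_contig_excluded(self):
        grid = make_grid(4)
        regions = [CINRegionSet(regions={"X": []})]
        genes = pd.DataFrame([("g", "chrZ", 0, 10)], columns=["gene", "contig", "start", "end"])
        with pytest.warns(UserWarning, match="absent from grid"):
            out = filter_genes_to_stable_regions(genes, regions, grid=grid)
        assert len(out) == 0


class TestSimulationRecovery:
    def test_cluster_and_cs_recovery(self):
        cfg = small_sim_config(seed=17)
        grid = cfg.grid()
        counts, truth = simulate_cells(cfg, grid)
        profiles = normalize_counts(counts, grid)
        assignment = cluster_cells(profiles, k=2)
        truth_labels = truth.cells.set_index("barcode")["clone"]
        pred = assignment.labels.loc[truth_labels.index]
        ari = adjusted_rand_score(pd.factorize(truth_labels)[0], pd.factorize(pred)[0])
        assert ari >= 0.9
        mean_profiles = pd.DataFrame({
            cl: profiles[assignment.cells_of(cl)].mean(axis=1) for cl in assignment.clusters
        })
        segs = cbs_segment(mean_profiles, grid, seed=17)
        out = label_cs_cluster(segs, assignment, grid)
        cs_cells = set(out.cells_of(out.cs_cluster))
        cs_truth = set(truth_labels.index[truth_labels == "CS"])
        assert len(cs_cells & cs_truth) / len(cs_truth) > 0.9
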