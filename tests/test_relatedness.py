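import numpy as np
import pandas as pd
import pytest

from ibdcoal.panel_io import DemographicModel, GeneticMap
from ibdcoal.relatedness import (
    cluster_average_linkage,
    estimate_ne,
    expected_cousin_sharing,
    genome_coverage,
    knn_predict_location,
    pair_summaries,
)
from ibdcoal.simulate import simulate_pair_path


def seg_frame(rows):
    return pd.DataFrame(rows, columns=["ind_a", "ind_b", "start_cm", "end_cm"])


@pytest.fixture
def map100():
    return GeneticMap(np.array([1.0, 100_000_001.0]), np.array([0.0, 100.0]))


def grid_union_oracle(intervals, total_cm, res=0.001):
    """Count 0.001 cM grid cells covered by >= 1 interval."""
    grid = np.zeros(int(round(total_cm / res)), dtype=bool)
    for lo, hi in intervals:
        grid[int(round(lo / res)) : int(round(hi / res))] = True
    return grid.sum() * res


class TestPairSummaries:
    def test_single_segment_fraction(self, map100):
        ps = pair_summaries(seg_frame([("a", "b", 10.0, 20.0)]), map100)
        assert ps.fraction_genome[("a", "b")] == pytest.approx(0.1)
        assert ps.n_segments[("a", "b")] == 1

    def test_overlap_union(self, map100):
        ps = pair_summaries(
            seg_frame([("a", "b", 0.0, 10.0), ("b", "a", 5.0, 15.0)]), map100
        )
        assert ps.total_cm[("a", "b")] == pytest.approx(15.0)
        assert ps.n_segments[("a", "b")] == 2

    def test_random_toy_vs_grid_oracle(self, map100, rng):
        rows = []
        for _ in range(60):
            a, b = sorted(rng.choice(list("abcde"), 2, replace=False))
            lo = rng.uniform(0, 95)
            rows.append((a, b, lo, lo + rng.uniform(0.01, 5)))
        ps = pair_summaries(seg_frame(rows), map100)
        for key, tot in ps.total_cm.items():
            ivs = [(lo, hi) for a, b, lo, hi in rows if tuple(sorted((a, b))) == key]
            assert tot == pytest.approx(grid_union_oracle(ivs, 100.0), abs=0.002 * len(ivs))

    def test_bp_segments_converted_via_map(self, map100):
        df = pd.DataFrame(
            [("a", "b", 1, 10_000_001)], columns=["ind_a", "ind_b", "start_bp", "end_bp"]
        )
        ps = pair_summaries(df, map100)
        assert ps.total_cm[("a", "b")] == pytest.approx(10.0)

    def test_outside_map_rejected(self, map100):
        with pytest.raises(ValueError, match="outside map"):
            pair_summaries(seg_frame([("a", "b", 90.0, 130.0)]), map100)


class TestGenomeCoverage:
    def test_empty_and_full(self, map100):
        assert genome_coverage(seg_frame([]), "a", map100) == 0.0
        full = seg_frame([("a", "b", 0.0, 100.0)])
        assert genome_coverage(full, "a", map100) == pytest.approx(1.0)

    def test_union_across_partners_vs_grid(self, map100, rng):
        rows = []
        for _ in range(40):
            other = rng.choice(list("bcdef"))
            lo = rng.uniform(0, 90)
            rows.append(("a", other, lo, lo + rng.uniform(0.1, 8)))
        cov = genome_coverage(seg_frame(rows), "a", map100)
        oracle = grid_union_oracle([(lo, hi) for _, _, lo, hi in rows], 100.0) / 100.0
        assert cov == pytest.approx(oracle, abs=1e-3)


class TestEstimateNe:
    def test_formula(self):
        assert estimate_ne(0.01, 50.0) == pytest.approx(5000.0)
        assert estimate_ne(1.0, 50.0) == pytest.approx(50.0)

    def test_zero_fraction_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_ne(0.0, 50.0)

    def test_recovery_from_simulated_truth(self):
        # simulation recovery: oracle f_T from ground-truth trees at T=50
        # (pooled over seeds; the full 3-Ne check lives in the acceptance suite)
        from ibdcoal.simulate import simulate_panel

        ne = 2500.0
        model = DemographicModel([(0.0, ne)])
        fs = [
            simulate_panel(60, 10.0, model, mutation_rate=0.0, seed=s).mean_fraction_below(50.0)
            for s in (1, 2, 3)
        ]
        est = estimate_ne(float(np.mean(fs)), 50.0)
        assert est == pytest.approx(ne, rel=0.15)

    def test_fraction_oracle_matches_truth_paths(self):
        # the fast tree-count summary equals averaging per-pair truth paths
        from ibdcoal.simulate import simulate_panel

        model = DemographicModel([(0.0, 800.0)])
        sim = simulate_panel(12, 2.0, model, mutation_rate=0.0, seed=9)
        pairs = [(i, j) for i in range(12) for j in range(i + 1, 12)]
        per_pair = np.mean([
            p.fraction_below(50.0) for p in sim.truth_paths(pairs).values()
        ])
        assert sim.mean_fraction_below(50.0) == pytest.approx(per_pair, abs=1e-12)


class TestExpectedCousinSharing:
    @pytest.mark.parametrize("k,expect", [(2, 226.5), (3, 56.6), (5, 3.5)])
    def test_printed_values(self, k, expect):
        assert round(expected_cousin_sharing(k, 7247.14), 1) == expect

    def test_quarter_ratio(self):
        for k in range(1, 8):
            ratio = expected_cousin_sharing(k + 1) / expected_cousin_sharing(k)
            assert ratio == pytest.approx(0.25)

    def test_validation(self):
        with pytest.raises(ValueError):
            expected_cousin_sharing(0)


class TestKnnPrediction:
    def test_k1_picks_top_neighbor(self):
        sim = {("q", "a"): 50.0, ("q", "b"): 10.0}
        coords = {"a": (1.0, 2.0), "b": (9.0, 9.0), "q": (1.5, 2.0)}
        res = knn_predict_location(sim, coords, ["q"], K=1)
        assert res["predictions"]["q"] == (1.0, 2.0)

    def test_all_equal_similarity_centroid(self):
        sim = {("q", c): 5.0 for c in "abcd"}
        coords = {"a": (0, 0), "b": (0, 2), "c": (2, 0), "d": (2, 2), "q": (1, 1)}
        res = knn_predict_location(sim, coords, ["q"], K=4)
        assert res["predictions"]["q"] == (1.0, 1.0)
        assert res["summary"]["median_error"] == 0.0

    def test_excluded_pair_skipped(self):
        sim = {("q", "a"): 50.0, ("q", "b"): 10.0}
        coords = {"a": (1.0, 2.0), "b": (9.0, 9.0), "q": (0, 0)}
        res = knn_predict_location(sim, coords, ["q"], K=1, exclude_pairs=[("a", "q")])
        assert res["predictions"]["q"] == (9.0, 9.0)

    def test_insufficient_neighbors_nan(self):
        with pytest.warns(UserWarning, match="usable neighbors"):
            res = knn_predict_location({}, {"q": (0, 0)}, ["q"], K=1)
        assert np.isnan(res["predictions"]["q"][0])

    def test_beats_random_assignment_in_synthetic_geography(self, rng):
        # sharing strictly decreasing in distance -> kNN must beat permutation
        n = 40
        pts = {f"i{k}": (float(rng.uniform(0, 100)), float(rng.uniform(0, 100)))
               for k in range(n)}
        ids = list(pts)
        sim = {}
        for i in range(n):
            for j in range(i + 1, n):
                d = np.hypot(pts[ids[i]][0] - pts[ids[j]][0], pts[ids[i]][1] - pts[ids[j]][1])
                sim[(ids[i], ids[j])] = 1000.0 / (1.0 + d)
        queries = ids[:10]
        res = knn_predict_location(sim, pts, queries, K=3)
        knn_err = res["summary"]["mean_error"]
        others = ids[10:]
        rand_errs = []
        for _ in range(100):
            picks = rng.choice(others, size=len(queries))
            rand_errs.append(np.mean([
                np.hypot(pts[q][0] - pts[p][0], pts[q][1] - pts[p][1])
                for q, p in zip(queries, picks)
            ]))
        assert knn_err < np.mean(rand_errs)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


def oracle_linkage(ids, similarity):
    """O(n^3) reference: recompute cross-cluster means from the raw matrix."""
    sim = {tuple(sorted(k)): v for k, v in similarity.items()}
    clusters = {i: [v] for i, v in enumerate(ids)}
    labels = {i: i for i in clusters}
    merges = []
    next_id = len(ids)
    while len(clusters) > 1:
        best = None
        keys = sorted(clusters)
        for x, i in enumerate(keys):
            for j in keys[x + 1 :]:
                vals = [
                    sim.get(tuple(sorted((a, b))), 0.0)
                    for a in clusters[i] for b in clusters[j]
                ]
                avg = float(np.mean(vals))
                if best is None or avg > best[0] + 1e-15:
                    best = (avg, i, j)
        avg, i, j = best
        clusters[i] = clusters[i] + clusters.pop(j)
        merges.append((labels[i], labels[j], avg, len(clusters[i])))
        labels[i] = next_id
        next_id += 1
    return merges


class TestClusterAverageLinkage:
    def test_two_blocks(self):
        sim = {}
        for block in (("a", "b", "c"), ("d", "e", "f")):
            for i in range(3):
                for j in range(i + 1, 3):
                    sim[(block[i], block[j])] = 1.0
        dend = cluster_average_linkage(sim, ids=list("abcdef"), restrict_to_component=False)
        # first four merges happen within blocks (similarity > 0)
        assert [m[2] for m in dend.merges[:4]] == pytest.approx([1.0, 1.0, 1.0, 1.0])
        labels = dend.flat_clusters(cut=0.5)
        assert len(set(labels.values())) == 2
        assert labels["a"] == labels["b"] == labels["c"]
        assert labels["d"] == labels["e"] == labels["f"]
        assert labels["a"] != labels["d"]

    def test_single_node(self):
        dend = cluster_average_linkage({}, ids=["only"], restrict_to_component=False)
        assert dend.merges == []
        assert dend.flat_clusters(0.5) == {"only": 0}

    def test_min_cluster_size_unassigned(self):
        sim = {("a", "b"): 1.0}
        dend = cluster_average_linkage(sim, ids=["a", "b", "c"], restrict_to_component=False)
        labels = dend.flat_clusters(cut=0.5, min_cluster_size=2)
        assert labels["a"] == labels["b"] == 0
        assert labels["c"] == -1

    def test_component_restriction(self, caplog):
        sim = {("a", "b"): 1.0, ("b", "c"): 0.5, ("d", "e"): 0.9}
        dend = cluster_average_linkage(sim)
        assert sorted(dend.ids) == ["a", "b", "c"]

    @pytest.mark.parametrize("seed", range(8))
    def test_merge_order_matches_bruteforce(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(5, 31))
        ids = [f"n{k}" for k in range(n)]
        sim = {}
        # distinct similarities on a sparse random graph, kept connected via a chain
        for k in range(n - 1):
            sim[(ids[k], ids[k + 1])] = float(r.uniform(0.1, 1.0))
        for _ in range(n):
            i, j = r.integers(n, size=2)
            if i != j:
                sim[tuple(sorted((ids[i], ids[j])))] = float(r.uniform(0.1, 1.0))
        dend = cluster_average_linkage(sim, ids=ids, restrict_to_component=False)
        oracle = oracle_linkage(ids, sim)
        assert len(dend.merges) == len(oracle)
        for got, want in zip(dend.merges, oracle):
            assert got[0] == want[0] and got[1] == want[1]
            assert got[2] == pytest.approx(want[2], abs=1e-12)
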