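"""Cluster grouping: features, score semantics, optimizer recovery."""

import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from clonemap import fixtures, grouping

# ---------------------------------------------------------------------------
# independent hand evaluation of the separation score (plain loops)
# ---------------------------------------------------------------------------

def naive_score(features: pd.DataFrame, assignment, weights, n_neighbors=10):
    """Literal evaluation of the printed score with explicit loops."""
    cols = ["x", "y", "area", "axis_ratio", "angle"]
    mat = features[cols].to_numpy(dtype=float)
    # z-score each column (population SD), then weight
    out = np.empty_like(mat)
    wvec = [weights.get("position", 1.0), weights.get("position", 1.0),
            weights["area"], weights["axis_ratio"], weights["angle"]]
    for j in range(mat.shape[1]):
        col = mat[:, j]
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        out[:, j] = z * wvec[j]
    assignment = list(assignment)
    groups = sorted(set(assignment))
    mu = {g: out[[a == g for a in assignment]].mean(axis=0) for g in groups}
    sig = {g: out[[a == g for a in assignment]].std(axis=0) for g in groups}
    diff = 0.0
    for m in groups:
        for n in groups:
            if m == n:
                continue
            for i in range(out.shape[1]):
                diff += abs(mu[m][i] - mu[n][i])
    var_within = sum(sig[g][i] for g in groups for i in range(out.shape[1]))
    # neighbors: brute-force distance sort on raw positions
    pos = features[["x", "y"]].to_numpy(dtype=float)
    n_pts = len(pos)
    k = min(n_neighbors, n_pts - 1)
    nr = 0.0
    for g in groups:
        members = [p for p in range(n_pts) if assignment[p] == g]
        for p in members:
            d = np.hypot(pos[:, 0] - pos[p, 0], pos[:, 1] - pos[p, 1])
            order = [q for q in np.argsort(d, kind="stable") if q != p][:k]
            nsc = sum(1 for q in order if assignment[q] == g)
            ndc = k - nsc
            expo = min(ndc / nsc, n_neighbors) if nsc else n_neighbors
            nr += 2.0**expo / len(members)
    if len(groups) == 1 or diff == 0:
        return 0.0
    if var_within == 0:
        return float("inf")
    return diff / (var_within * nr)


def random_features(rng, n):
    return pd.DataFrame(
        {
            "x": rng.uniform(0, 400, n),
            "y": rng.uniform(0, 400, n),
            "area": rng.uniform(50, 800, n),
            "axis_ratio": rng.uniform(1, 4, n),
            "angle": rng.uniform(0, 180, n),
        },
        index=pd.RangeIndex(n, name="cluster_id"),
    )


class TestComponentsAndFeatures:
    def test_two_disjoint_blobs(self):
        mask = np.zeros((40, 40), dtype=int)
        mask[2:8, 2:8] = 1
        mask[20:30, 20:26] = 1
        labels = grouping.label_components(mask.astype(bool))
        assert labels.max() == 2

    def test_single_pixel_component(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[5, 5] = True
        feats = grouping.extract_features(mask)
        assert len(feats) == 1
        row = feats.iloc[0]
        assert row["area"] == 1 and row["axis_ratio"] == 1.0

    def test_planted_mask_component_count(self, demo_mask):
        mask, truth = demo_mask
        feats = grouping.extract_features(mask)
        assert len(feats) == len(truth.group_of_cluster)
        assert set(feats.index) == set(truth.group_of_cluster)

    def test_square_blob_symmetric(self):
        mask = np.zeros((30, 30), dtype=bool)
        mask[10:20, 10:20] = True
        row = grouping.extract_features(mask).iloc[0]
        assert row["area"] == 100
        assert row["axis_ratio"] == pytest.approx(1.0, abs=1e-6)
        assert row["angle"] % 90 == pytest.approx(0.0, abs=1e-6)

    @pytest.mark.parametrize(
        "ratio,angle,angle_tol",
        [(3.0, 30.0, 2.0), (2.0, 120.0, 4.0), (4.0, 75.0, 2.0)],
    )
    def test_analytic_ellipse_recovered(self, ratio, angle, angle_tol):
        # rasterize an analytic ellipse independently of the fixtures code
        h = w = 221
        cy = cx = 110
        b = 16.0
        a = ratio * b
        rows, cols = np.mgrid[0:h, 0:w]
        x = cols - cx
        y = -(rows - cy)
        th = np.deg2rad(angle)
        u = x * np.cos(th) + y * np.sin(th)
        v = -x * np.sin(th) + y * np.cos(th)
        mask = (u / a) ** 2 + (v / b) ** 2 <= 1.0
        row = grouping.extract_features(mask).iloc[0]
        assert row["axis_ratio"] == pytest.approx(ratio, rel=0.05)
        # the bounding-rectangle orientation is less identifiable for
        # rounder blobs, hence the elongation-dependent tolerance
        assert row["angle"] == pytest.approx(angle, abs=angle_tol)


class TestNeighborCounts:
    def test_two_far_groups_pure(self):
        rng = np.random.default_rng(0)
        feats = random_features(rng, 24)
        feats.loc[:11, ["x", "y"]] = rng.uniform(0, 50, (12, 2))
        feats.loc[12:, ["x", "y"]] = rng.uniform(500, 550, (12, 2))
        assign = np.array([0] * 12 + [1] * 12)
        nc = grouping.neighbor_counts(feats, assign, 10)
        assert (nc["NDC"] == 0).all()
        assert (nc["NSC"] + nc["NDC"] == 10).all()

    def test_singleton_amid_other_group(self):
        rng = np.random.default_rng(1)
        feats = random_features(rng, 12)
        feats[["x", "y"]] = rng.uniform(0, 30, (12, 2))
        assign = np.array([0] + [1] * 11)
        nc = grouping.neighbor_counts(feats, assign, 10)
        assert nc["NSC"].iloc[0] == 0

    def test_small_n_uses_all_others(self):
        rng = np.random.default_rng(2)
        feats = random_features(rng, 6)
        nc = grouping.neighbor_counts(feats, np.zeros(6, int), 10)
        assert (nc["effective_n"] == 5).all()

    def test_random_assignment_mean_nsc_matches_fraction(self):
        # uniform points, random labels: E[NSC/k] ~ share of same-label others
        rng = np.random.default_rng(3)
        n, frac = 400, 0.3
        feats = random_features(rng, n)
        means = []
        for rep in range(5):
            assign = (rng.random(n) < frac).astype(int)
            nc = grouping.neighbor_counts(feats, assign, 10)
            sel = assign == 1
            means.append((nc["NSC"][sel] / 10).mean())
        assert np.mean(means) == pytest.approx(frac, abs=0.03)


class TestGroupingScore:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_hand_evaluation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 40))
        feats = random_features(rng, n)
        assign = rng.integers(0, 3, n)
        weights = {
            "position": 1.0,
            "area": float(rng.uniform(0.1, 10)),
            "axis_ratio": float(rng.uniform(0.1, 10)),
            "angle": float(rng.uniform(0.1, 10)),
        }
        bd = grouping.grouping_score(feats, assign, weights)
        expected = naive_score(feats, assign, weights)
        assert bd.score == pytest.approx(expected, rel=1e-12)

    def test_relabel_invariance(self):
        rng = np.random.default_rng(10)
        feats = random_features(rng, 30)
        assign = rng.integers(0, 3, 30)
        weights = dict(position=1.0, area=2.0, axis_ratio=0.5, angle=1.5)
        s1 = grouping.grouping_score(feats, assign, weights).score
        remap = {0: 7, 1: 5, 2: 9}
        s2 = grouping.grouping_score(feats, [remap[a] for a in assign], weights).score
        assert s1 == pytest.approx(s2, rel=1e-12)

    def test_translation_invariance(self):
        rng = np.random.default_rng(11)
        feats = random_features(rng, 25)
        assign = rng.integers(0, 2, 25)
        weights = dict(position=1.0, area=1.0, axis_ratio=1.0, angle=1.0)
        s1 = grouping.grouping_score(feats, assign, weights).score
        shifted = feats.copy()
        shifted["x"] += 123.0
        shifted["y"] -= 55.0
        s2 = grouping.grouping_score(shifted, assign, weights).score
        assert s1 == pytest.approx(s2, rel=1e-9)

    def test_all_one_group_scores_zero(self):
        rng = np.random.default_rng(12)
        feats = random_features(rng, 20)
        bd = grouping.grouping_score(
            feats, np.zeros(20, int),
            dict(position=1.0, area=1.0, axis_ratio=1.0, angle=1.0),
        )
        assert bd.score == 0.0 and bd.difference_between_groups == 0.0

    def test_pure_neighborhoods_floor_neighbor_ratio(self):
        rng = np.random.default_rng(13)
        feats = random_features(rng, 24)
        feats.loc[:11, ["x", "y"]] = rng.uniform(0, 50, (12, 2))
        feats.loc[12:, ["x", "y"]] = rng.uniform(900, 950, (12, 2))
        assign = np.array([0] * 12 + [1] * 12)
        bd = grouping.grouping_score(
            feats, assign, dict(position=1.0, area=1.0, axis_ratio=1.0, angle=1.0)
        )
        assert bd.neighbor_ratio == pytest.approx(2.0)  # every term 2^0


class TestOptimizer:
    CFG = grouping.GroupingConfig(sweep_stride=13, candidate_group_counts=(2, 3, 4))

    @pytest.mark.parametrize("seed", range(3))
    def test_recovers_planted_groups(self, seed):
        mask, truth = fixtures.make_mask_with_groups(3, 10, (512, 512), seed=seed)
        feats = grouping.extract_features(mask)
        res = grouping.optimize_grouping(feats, self.CFG)
        planted = [truth.group_of_cluster[i] for i in feats.index]
        assert adjusted_rand_score(planted, res.assignment.to_numpy()) == 1.0

    def test_two_clusters_forced_partition(self):
        rng = np.random.default_rng(0)
        feats = random_features(rng, 2)
        res = grouping.optimize_grouping(
            feats, grouping.GroupingConfig(sweep_stride=20,
                                           candidate_group_counts=(2,))
        )
        assert res.breakdown.n_groups == 2
        assert np.isfinite(res.breakdown.score) or res.breakdown.score == np.inf

    def test_never_beats_brute_force_oracle(self):
        rng = np.random.default_rng(5)
        feats = random_features(rng, 6)
        weights = dict(position=1.0, area=1.0, axis_ratio=1.0, angle=1.0)
        _, oracle_score = grouping.brute_force_best_partition(feats, weights,
                                                             max_groups=3)
        cfg = grouping.GroupingConfig(
            sweep_min=1.0, sweep_max=1.0, sweep_step=1.0,
            candidate_group_counts=(2, 3),
        )
        res = grouping.optimize_grouping(feats, cfg)
        assert res.breakdown.score <= oracle_score + 1e-9

    def test_grid_budget_warning(self):
        rng = np.random.default_rng(6)
        feats = random_features(rng, 12)
        cfg = grouping.GroupingConfig(grid_budget=8, sweep_stride=10,
                                      candidate_group_counts=(2,))
        with pytest.warns(UserWarning, match="grid"):
            grouping.optimize_grouping(feats, cfg)

    def test_sweep_grid_default_width(self):
        vals = grouping.GroupingConfig().weight_values()
        assert vals[0] == pytest.approx(0.1)
        assert vals[-1] == pytest.approx(9.85)
        assert len(vals) == 40
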