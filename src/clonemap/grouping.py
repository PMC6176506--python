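"""Morphological grouping of cell clusters on a labeled tissue mask.

Cell clusters segmented from a stained section are summarized by four
features — centroid position, pixel area, major/minor axis ratio of the
fitted ellipse, and the orientation angle of the minimum-area bounding
rectangle — and partitioned by weighted hierarchical clustering.  The
partition and the feature weights are chosen to maximize a separation
score

    score = difference_between_groups
            / (variance_within_groups * neighbor_ratio)

with
    difference_between_groups = sum_{n != m} sum_i |mu_{i,m} - mu_{i,n}|,
    variance_within_groups    = sum_m sum_i sigma_{i,m},
    neighbor_ratio            = sum_m sum_{p in m} 2^(NDC_{m,p}/NSC_{m,p}) / N_m,

where mu_{i,m}, sigma_{i,m} are the mean and standard deviation of
(standardized, weighted) feature i in group m, and NSC/NDC count the
same-/different-group members among each cluster's ten nearest spatial
neighbors.  The position weight is fixed at 1 and the other three
feature weights are swept over a grid (0.1-10, step 0.25 by default).

Notes on conventions adopted where the score leaves room: features are
z-score standardized before weighting (position contributes both
coordinates under the single position weight); the n != m sum runs over
ordered pairs exactly as written (each unordered pair twice); a cluster
whose ten neighbors all lie in other groups (NSC = 0) contributes
2^n_neighbors, keeping the penalty finite; zero within-group spread
with positive between-group difference scores +inf.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from skimage.measure import label as sk_label
from skimage.measure import regionprops

FEATURE_COLUMNS = ("x", "y", "area", "axis_ratio", "angle")


@dataclass
class GroupingConfig:
    """Sweep and clustering settings for :func:`optimize_grouping`."""

    position_weight: float = 1.0
    sweep_min: float = 0.1
    sweep_max: float = 10.0
    sweep_step: float = 0.25
    sweep_stride: int = 1
    n_neighbors: int = 10
    candidate_group_counts: tuple[int, ...] = (2, 3, 4, 5, 6, 7, 8)
    linkage_method: str = "ward"
    standardize: bool = True
    grid_budget: int = 2000

    def weight_values(self) -> np.ndarray:
        vals = np.arange(self.sweep_min, self.sweep_max + 1e-9, self.sweep_step)
        if len(vals) == 0:
            raise ValueError("empty sweep grid")
        return vals[:: max(1, self.sweep_stride)]


@dataclass
class GroupingScoreBreakdown:
    difference_between_groups: float
    variance_within_groups: float
    neighbor_ratio: float
    score: float
    n_groups: int
    n_features: int
    group_sizes: dict[int, int] = field(default_factory=dict)


@dataclass
class GroupingResult:
    weights: dict[str, float]
    assignment: pd.Series  # index: cluster_id -> group label
    breakdown: GroupingScoreBreakdown
    trace: pd.DataFrame  # one row per (weights, n_groups) evaluated


# ---------------------------------------------------------------------------
# components and features
# ---------------------------------------------------------------------------

def label_components(mask: np.ndarray) -> np.ndarray:
    """Connected components (8-connectivity) of a mask; background is 0.

    A boolean/binary mask is labeled from scratch; an integer mask with
    more than one distinct positive value is trusted as an existing
    labeling, so planted label identities survive.
    """
    mask = np.asarray(mask)
    if mask.size == 0:
        raise ValueError("empty mask")
    if mask.dtype == bool or len(np.unique(mask[mask > 0])) <= 1:
        return sk_label(mask > 0, connectivity=2)
    return mask.astype(np.int32)


def extract_features(mask: np.ndarray) -> pd.DataFrame:
    """Per-cluster morphology features from a labeled mask.

    position = pixel centroid (x = column, y = row); area = pixel
    count; axis_ratio = major/minor axis of the second-central-moment
    ellipse fit, with the minor axis floored at 1 px for degenerate
    (collinear) components; angle = orientation of the longer side of
    the minimum-area bounding rectangle versus the horizontal, in
    [0, 180) measured counter-clockwise with y up.
    """
    labels = label_components(mask)
    rows = []
    for prop in regionprops(labels):
        major, minor = prop.axis_major_length, prop.axis_minor_length
        if major < 1e-9:
            ratio = 1.0
        else:
            ratio = major / max(minor, 1.0)
        ratio = max(ratio, 1.0)
        angle = _min_rect_angle(prop.coords)
        cy, cx = prop.centroid
        rows.append((prop.label, cx, cy, int(prop.area), ratio, angle))
    return pd.DataFrame(
        rows, columns=["cluster_id", "x", "y", "area", "axis_ratio", "angle"]
    ).set_index("cluster_id")


def _min_rect_angle(coords: np.ndarray) -> float:
    """Angle of the minimum-area bounding rectangle's longer side.

    Degrees in [0, 180), measured from the +x axis counter-clockwise in
    standard (y-up) orientation.  Pixel footprints use the four corners
    of each pixel so single pixels and straight lines behave.
    """
    from shapely import MultiPoint

    if len(coords) == 1:
        return 0.0
    r = coords[:, 0].astype(float)
    c = coords[:, 1].astype(float)
    # pixel corner cloud in (x, y-up) coordinates
    xs = np.concatenate([c - 0.5, c + 0.5, c - 0.5, c + 0.5])
    ys = np.concatenate([-(r - 0.5), -(r - 0.5), -(r + 0.5), -(r + 0.5)])
    rect = MultiPoint(list(zip(xs, ys))).minimum_rotated_rectangle
    xy = np.asarray(rect.exterior.coords) if rect.geom_type == "Polygon" else None
    if xy is None:
        return 0.0
    edges = np.diff(xy[:3], axis=0)  # two adjacent sides
    lengths = np.hypot(edges[:, 0], edges[:, 1])
    longer = edges[int(np.argmax(lengths))]
    ang = np.degrees(np.arctan2(longer[1], longer[0])) % 180.0
    return float(ang)


# ---------------------------------------------------------------------------
# score
# ---------------------------------------------------------------------------

def neighbor_counts(
    features: pd.DataFrame, assignment: np.ndarray | pd.Series, n_neighbors: int = 10
) -> pd.DataFrame:
    """Same-/different-group counts among each cluster's nearest neighbors.

    Neighbors are found by Euclidean distance on the raw (unweighted)
    centroid positions.  If fewer than ``n_neighbors + 1`` clusters
    exist, all other clusters are used and the effective count
    recorded; NSC + NDC always equals that effective count.
    """
    from sklearn.neighbors import NearestNeighbors

    assignment = np.asarray(assignment)
    pos = features[["x", "y"]].to_numpy()
    n = len(pos)
    if n < 2:
        raise ValueError("need at least 2 clusters")
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(pos)
    _, idx = nn.kneighbors(pos)
    neigh = idx[:, 1:]  # drop self
    same = assignment[neigh] == assignment[:, None]
    nsc = same.sum(axis=1)
    return pd.DataFrame(
        {"NSC": nsc, "NDC": k - nsc, "effective_n": k}, index=features.index
    )


def standardize_and_weight(
    features: pd.DataFrame,
    weights: dict[str, float],
    standardize: bool = True,
) -> np.ndarray:
    """Feature matrix -> z-scored, weight-multiplied array (n x 5).

    The position weight multiplies both x and y; constant columns keep
    z-score 0.
    """
    mat = features.loc[:, list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    if standardize:
        sd = mat.std(axis=0)
        sd[sd == 0] = 1.0
        mat = (mat - mat.mean(axis=0)) / sd
    w = np.array(
        [
            weights.get("position", 1.0),
            weights.get("position", 1.0),
            weights["area"],
            weights["axis_ratio"],
            weights["angle"],
        ]
    )
    if (w <= 0).any():
        raise ValueError("weights must be positive")
    return mat * w


def grouping_score(
    features: pd.DataFrame,
    assignment: np.ndarray | pd.Series,
    weights: dict[str, float],
    n_neighbors: int = 10,
    standardize: bool = True,
) -> GroupingScoreBreakdown:
    """Evaluate the grouping separation score for one assignment."""
    assignment = np.asarray(assignment)
    mat = standardize_and_weight(features, weights, standardize)
    groups = np.unique(assignment)
    n_c, n_f = len(groups), mat.shape[1]
    mus = np.vstack([mat[assignment == g].mean(axis=0) for g in groups])
    sigmas = np.vstack([mat[assignment == g].std(axis=0) for g in groups])

    diff = 0.0
    for m, n_ in itertools.permutations(range(n_c), 2):
        diff += np.abs(mus[m] - mus[n_]).sum()
    var_within = float(sigmas.sum())

    nc_tab = neighbor_counts(features, assignment, n_neighbors)
    nsc = nc_tab["NSC"].to_numpy(dtype=float)
    ndc = nc_tab["NDC"].to_numpy(dtype=float)
    exponent = np.where(nsc > 0, ndc / np.maximum(nsc, 1e-300), float(n_neighbors))
    exponent = np.minimum(exponent, float(n_neighbors))
    terms = 2.0 ** exponent
    group_sizes = {int(g): int((assignment == g).sum()) for g in groups}
    neighbor_ratio = 0.0
    for g in groups:
        sel = assignment == g
        neighbor_ratio += terms[sel].sum() / sel.sum()

    if n_c == 1 or diff == 0.0:
        score = 0.0
    elif var_within == 0.0:
        score = float("inf")
    else:
        score = diff / (var_within * neighbor_ratio)
    return GroupingScoreBreakdown(
        difference_between_groups=float(diff),
        variance_within_groups=var_within,
        neighbor_ratio=float(neighbor_ratio),
        score=float(score),
        n_groups=n_c,
        n_features=n_f,
        group_sizes=group_sizes,
    )


# ---------------------------------------------------------------------------
# optimizer
# ---------------------------------------------------------------------------

def optimize_grouping(
    features: pd.DataFrame, config: GroupingConfig | None = None
) -> GroupingResult:
    """Sweep feature weights and group counts; return the score arg-max.

    For every weight combination on the sweep grid (position fixed at
    its unit weight) and every candidate group count, hierarchical
    clustering is run on the weighted standardized features and the
    resulting partition scored.  Ties are broken toward fewer groups,
    then the lexicographically smaller weight vector.  A full grid at
    step 0.25 is ~40^3 combinations; a warning is emitted when the grid
    exceeds ``config.grid_budget`` and ``sweep_stride`` subsamples it.
    """
    if config is None:
        config = GroupingConfig()
    n = len(features)
    if n < 2:
        raise ValueError("need at least 2 clusters to group")
    values = config.weight_values()
    combos = list(itertools.product(values, repeat=3))
    if len(combos) > config.grid_budget:
        warnings.warn(
            f"weight grid has {len(combos)} combinations "
            f"(budget {config.grid_budget}); consider sweep_stride",
            stacklevel=2,
        )
    ks = [k for k in config.candidate_group_counts if 2 <= k <= n]
    if not ks:
        ks = [min(2, n)]

    best = None  # (score, n_groups, weight_tuple, assignment, breakdown)
    trace_rows = []
    for wa, wr, wg in combos:
        weights = {
            "position": config.position_weight,
            "area": float(wa),
            "axis_ratio": float(wr),
            "angle": float(wg),
        }
        mat = standardize_and_weight(features, weights, config.standardize)
        Z = linkage(mat, method=config.linkage_method)
        for k in ks:
            assign = fcluster(Z, t=k, criterion="maxclust")
            bd = grouping_score(
                features, assign, weights, config.n_neighbors, config.standardize
            )
            trace_rows.append((wa, wr, wg, k, bd.score))
            key = (bd.score, -bd.n_groups, (-wa, -wr, -wg))
            if best is None or key > best[0]:
                best = (key, weights, assign, bd)
    _, weights, assign, bd = best
    assignment = pd.Series(assign, index=features.index, name="group")
    trace = pd.DataFrame(
        trace_rows,
        columns=["w_area", "w_axis_ratio", "w_angle", "n_groups", "score"],
    )
    return GroupingResult(weights=weights, assignment=assignment, breakdown=bd,
                          trace=trace)


def brute_force_best_partition(
    features: pd.DataFrame,
    weights: dict[str, float],
    max_groups: int = 3,
    n_neighbors: int = 10,
    standardize: bool = True,
) -> tuple[np.ndarray, float]:
    """Exhaustive search over all set partitions into <= max_groups groups.

    Exponential in the number of clusters; intended as an oracle for
    small instances (<= 8 clusters).
    """
    n = len(features)
    if n > 12:
        raise ValueError("exhaustive partition search is limited to small n")
    best_assign, best_score = None, -np.inf
    for assign in _set_partitions(n, max_groups):
        bd = grouping_score(features, assign, weights, n_neighbors, standardize)
        if bd.score > best_score:
            best_assign, best_score = assign, bd.score
    return np.asarray(best_assign), float(best_score)


def _set_partitions(n: int, max_groups: int):
    """Yield all assignments of n items into at most max_groups groups,
    in restricted-growth-string form (canonical labeling)."""

    def rec(i, assign, used):
        if i == n:
            yield list(assign)
            return
        for g in range(min(used + 1, max_groups)):
            assign.append(g)
            yield from rec(i + 1, assign, max(used, g + 1))
            assign.pop()

    yield from rec(0, [], 0)
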