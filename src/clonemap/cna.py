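"""Copy-number alteration profiling and subclone clustering.

Low-depth whole-genome sequencing of amplified cell clusters is turned
into copy-number profiles by the variable-size binning method: the
genome is split into bins holding an equal expected number of uniquely
mapped reference reads (equalizing mappability), per-bin counts are
Lowess-normalized against GC content, and copy ratios are obtained by
dividing by the median normalized depth of the reference DNA.

Profiles from many samples are then segmented jointly — an exact
dynamic program over breakpoints shared across samples with a
per-breakpoint penalty gamma (default 20) — and each segment is encoded
per sample as an event: 0 at the reference level, +1 for a gain, -1 for
a loss.  Samples are clustered on the Pearson correlation of their
event vectors (distance 1 - r, average linkage), and cluster support is
quantified by multiscale bootstrap resampling of the feature axis,
yielding approximately unbiased (AU) p-values via the probit model
z(r) = v*sqrt(r) + c/sqrt(r), AU = Phi(c - v).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, fcluster, to_tree
from scipy.spatial.distance import squareform
from scipy.stats import mannwhitneyu, norm
from statsmodels.nonparametric.smoothers_lowess import lowess

DEFAULT_GAMMA = 20.0
DEFAULT_SCALES = tuple(np.round(np.arange(0.5, 1.45, 0.1), 1))


# ---------------------------------------------------------------------------
# binning
# ---------------------------------------------------------------------------

def build_variable_bins(
    read_positions: dict[str, np.ndarray],
    n_bins: int,
    chrom_lengths: dict[str, int],
    gc_track=None,
) -> pd.DataFrame:
    """Variable-size bins with equal expected reference read counts.

    Bin counts are apportioned to chromosomes in proportion to their
    reference read totals; within a chromosome, boundaries are the
    read-position quantiles (edges at midpoints between the flanking
    reads), so per-bin expected counts differ by at most one read.  A
    chromosome with fewer reads than its allocation collapses to a
    single bin with a warning.  ``gc_track(chrom, start, end)``
    supplies per-bin GC; by default a deterministic synthetic track is
    used (see :func:`clonemap.fixtures.synthetic_gc`).
    """
    from clonemap.fixtures import _allocate, synthetic_gc

    chroms = list(chrom_lengths)
    counts = np.array([len(read_positions.get(c, ())) for c in chroms], dtype=float)
    if counts.sum() < n_bins:
        raise ValueError("total reference reads must be >= n_bins")
    alloc = _allocate(counts, n_bins)
    rows = []
    for chrom, k in zip(chroms, alloc):
        pos = np.sort(np.asarray(read_positions.get(chrom, ()), dtype=float))
        length = chrom_lengths[chrom]
        k = max(1, int(k))
        if min(len(pos), len(np.unique(pos))) < k:
            warnings.warn(
                f"{chrom}: only {len(np.unique(pos))} distinct read positions "
                f"for {k} bins; using one bin",
                stacklevel=2,
            )
            k = 1
        splits = np.round(np.linspace(0, len(pos), k + 1)).astype(int)[1:-1]
        edges = [0]
        for s in splits:
            edges.append(int((pos[s - 1] + pos[s]) / 2))
        edges.append(length)
        for s, e in zip(edges[:-1], edges[1:]):
            if e <= s:
                e = s + 1
            rows.append((chrom, s, e, len(pos) / counts.sum() / k))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end", "expected_fraction"])
    bins["expected_fraction"] /= bins["expected_fraction"].sum()
    if gc_track is None:
        bins["gc"] = synthetic_gc(bins)
    else:
        bins["gc"] = [
            gc_track(c, s, e) for c, s, e in bins[["chrom", "start", "end"]].itertuples(index=False)
        ]
    return bins


def bin_reads(read_positions: dict[str, np.ndarray], bins: pd.DataFrame
              ) -> tuple[np.ndarray, int]:
    """Count reads per bin (half-open intervals); also reads outside bins."""
    counts = np.zeros(len(bins), dtype=int)
    outside = 0
    for chrom, sub in bins.groupby("chrom", sort=False):
        pos = np.asarray(read_positions.get(str(chrom), ()), dtype=float)
        if len(pos) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        idx = np.searchsorted(starts, pos, side="right") - 1
        ok = (idx >= 0) & (pos < ends[np.clip(idx, 0, len(ends) - 1)])
        outside += int((~ok).sum())
        np.add.at(counts, sub.index.to_numpy()[idx[ok]], 1)
    return counts, outside


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

@dataclass
class BinnedProfile:
    sample_id: str
    raw_count: np.ndarray
    gc_normalized_depth: np.ndarray
    copy_ratio: np.ndarray  # 1 = reference median
    reads_outside_bins: int = 0
    reference_ploidy: float = 2.0

    @property
    def copy_number(self) -> np.ndarray:
        """Absolute copy-number estimate (reference median -> ploidy).

        Joint segmentation runs on this scale: a one-copy gain or loss
        is a unit-height step, which is what the breakpoint penalty
        gamma = 20 is calibrated against.
        """
        return self.copy_ratio * self.reference_ploidy


def gc_normalize(counts: np.ndarray, gc: np.ndarray, span: float = 0.3) -> np.ndarray:
    """Divide counts by a Lowess fit of count on GC, rescaled to keep the mean.

    With (near-)constant GC no bias is identifiable and counts pass
    through unchanged.
    """
    counts = np.asarray(counts, dtype=float)
    gc = np.asarray(gc, dtype=float)
    if np.ptp(gc) < 1e-6:
        return counts.copy()
    fit = lowess(counts, gc, frac=span, return_sorted=False)
    floor = max(counts.mean() * 1e-3, 1e-9)
    fit = np.maximum(fit, floor)
    return counts / fit * fit.mean()


def assign_and_normalize(
    sample_id: str,
    reads_or_counts,
    bins: pd.DataFrame,
    reference_counts: np.ndarray,
    lowess_span: float = 0.3,
) -> BinnedProfile:
    """Bin a sample's reads, GC-normalize, and form copy ratios.

    ``reads_or_counts`` is either a dict of per-chromosome read
    positions or a precomputed per-bin count vector.  The sample's
    GC-normalized depths are scaled to the reference's total and
    divided by the median normalized reference depth, so the reference
    profile against itself is exactly 1 at the median.
    """
    outside = 0
    if isinstance(reads_or_counts, dict):
        counts, outside = bin_reads(reads_or_counts, bins)
    else:
        counts = np.asarray(reads_or_counts)
        if len(counts) != len(bins):
            raise ValueError("count vector length must match bin count")
    gc = bins["gc"].to_numpy()
    norm_depth = gc_normalize(counts, gc, lowess_span)
    ref_norm = gc_normalize(np.asarray(reference_counts, dtype=float), gc, lowess_span)
    ref_median = np.median(ref_norm)
    if ref_median <= 0:
        raise ValueError("reference profile has non-positive median depth")
    # library-size correction: map the sample's median bin onto the
    # reference's median bin, so the (majority, copy-neutral) median
    # bin sits at ratio 1 even when large gains dilute the rest of a
    # fixed-size library
    scale = ref_median / max(np.median(norm_depth), 1e-12)
    copy_ratio = norm_depth * scale / ref_median
    return BinnedProfile(
        sample_id=sample_id,
        raw_count=counts.astype(int),
        gc_normalized_depth=norm_depth,
        copy_ratio=copy_ratio,
        reads_outside_bins=outside,
    )


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

@dataclass
class SegmentedProfiles:
    breakpoints: list[int]  # global bin indices of segment starts (incl. 0)
    segments: pd.DataFrame  # chrom, start_bin, end_bin per segment
    levels: pd.DataFrame  # segment x sample mean copy ratio
    gamma: float


def multisample_segment(
    ratios: pd.DataFrame,
    bins: pd.DataFrame | None = None,
    gamma: float = DEFAULT_GAMMA,
) -> SegmentedProfiles:
    """Joint piecewise-constant segmentation with shared breakpoints.

    Minimizes sum over samples and bins of the squared deviation from
    the per-sample segment mean, plus ``gamma`` per breakpoint, by an
    exact O(n^2) dynamic program; breakpoints are shared across all
    samples and never span a chromosome boundary.  ``ratios`` is a
    bins x samples frame of copy ratios.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    X = ratios.to_numpy(dtype=float)
    n = X.shape[0]
    if bins is None:
        chrom = np.zeros(n, dtype=int)
    else:
        chrom = pd.factorize(bins["chrom"])[0]

    breakpoints: list[int] = []
    offset = 0
    for c in np.unique(chrom):
        block = X[chrom == c]
        bps = _segment_block(block, gamma)
        breakpoints.extend(offset + b for b in bps)
        offset += block.shape[0]

    starts = sorted(breakpoints)
    ends = starts[1:] + [n]
    seg_rows, level_rows = [], []
    for s, e in zip(starts, ends):
        if bins is not None:
            seg_rows.append((bins["chrom"].iloc[s], s, e))
        else:
            seg_rows.append(("genome", s, e))
        level_rows.append(X[s:e].mean(axis=0))
    segments = pd.DataFrame(seg_rows, columns=["chrom", "start_bin", "end_bin"])
    levels = pd.DataFrame(level_rows, columns=ratios.columns)
    return SegmentedProfiles(breakpoints=starts, segments=segments, levels=levels,
                             gamma=gamma)


def _segment_block(X: np.ndarray, gamma: float) -> list[int]:
    """Exact DP over one chromosome; returns segment start indices (incl. 0)."""
    n = X.shape[0]
    if n == 0:
        return []
    csum = np.vstack([np.zeros(X.shape[1]), np.cumsum(X, axis=0)])
    csum2 = np.vstack([np.zeros(X.shape[1]), np.cumsum(X**2, axis=0)])

    best = np.full(n + 1, np.inf)
    prev = np.zeros(n + 1, dtype=int)
    best[0] = -gamma  # first segment carries no breakpoint penalty
    for j in range(1, n + 1):
        lengths = j - np.arange(j)
        s = csum[j] - csum[:j]
        s2 = (csum2[j] - csum2[:j]).sum(axis=1)
        seg_cost = s2 - (s**2).sum(axis=1) / lengths
        cand = best[:j] + seg_cost + gamma
        i = int(np.argmin(cand))
        best[j] = cand[i]
        prev[j] = i
    starts = []
    j = n
    while j > 0:
        i = prev[j]
        starts.append(i)
        j = i
    return sorted(starts)


def exhaustive_segment_cost(X: np.ndarray, gamma: float, max_segments: int = 5
                            ) -> tuple[float, list[int]]:
    """Brute-force minimum of the segmentation objective on a small block.

    Enumerates every breakpoint subset with up to ``max_segments``
    segments; independent oracle for :func:`multisample_segment` on
    instances of <= ~30 bins.
    """
    from itertools import combinations

    n = X.shape[0]
    best_cost, best_starts = np.inf, [0]
    for k in range(1, max_segments + 1):
        for inner in combinations(range(1, n), k - 1):
            starts = [0, *inner]
            ends = [*inner, n]
            cost = gamma * (k - 1)
            for s, e in zip(starts, ends):
                seg = X[s:e]
                cost += float(((seg - seg.mean(axis=0)) ** 2).sum())
            if cost < best_cost:
                best_cost, best_starts = cost, starts
    return best_cost, best_starts


# ---------------------------------------------------------------------------
# level merging
# ---------------------------------------------------------------------------

def merge_levels(
    segment_levels: np.ndarray,
    segment_of_bin: np.ndarray,
    bin_values: np.ndarray,
    p_threshold: float = 1e-4,
    abs_floor: float = 0.1,
) -> np.ndarray:
    """Collapse segment levels that are not meaningfully distinct.

    Iteratively merges the closest pair of levels while a two-sample
    rank test (Mann-Whitney) between their pooled bin values has
    p > ``p_threshold`` or the level difference is below ``abs_floor``;
    merged levels take the bin-weighted mean.  Returns the merged level
    per segment (a reduced alphabet shared across segments).
    """
    levels = np.asarray(segment_levels, dtype=float).copy()
    segment_of_bin = np.asarray(segment_of_bin)
    bin_values = np.asarray(bin_values, dtype=float)
    # level groups: start with one group per distinct level value
    groups: dict[float, list[int]] = {}
    for s, lv in enumerate(levels):
        groups.setdefault(round(float(lv), 12), []).append(s)
    group_list = [(lv, segs) for lv, segs in groups.items()]

    def pooled(segs):
        sel = np.isin(segment_of_bin, segs)
        return bin_values[sel]

    while len(group_list) > 1:
        group_list.sort(key=lambda t: t[0])
        diffs = [
            (group_list[i + 1][0] - group_list[i][0], i)
            for i in range(len(group_list) - 1)
        ]
        d, i = min(diffs)
        a_lv, a_segs = group_list[i]
        b_lv, b_segs = group_list[i + 1]
        va, vb = pooled(a_segs), pooled(b_segs)
        if d < abs_floor:
            mergeable = True
        elif len(va) and len(vb):
            if np.ptp(np.concatenate([va, vb])) == 0:
                mergeable = True
            else:
                p = mannwhitneyu(va, vb, alternative="two-sided").pvalue
                mergeable = p > p_threshold
        else:
            mergeable = True
        if not mergeable:
            break
        w = len(va) + len(vb)
        new_lv = (a_lv * len(va) + b_lv * len(vb)) / w if w else (a_lv + b_lv) / 2
        group_list[i] = (new_lv, a_segs + b_segs)
        del group_list[i + 1]

    out = np.empty_like(levels)
    for lv, segs in group_list:
        out[segs] = lv
    return out


# ---------------------------------------------------------------------------
# events and clustering
# ---------------------------------------------------------------------------

def event_vectors(
    segmented: SegmentedProfiles,
    reference_median: float = 1.0,
    tolerance: float = 0.25,
) -> pd.DataFrame:
    """Encode each segment per sample as {-1 loss, 0 neutral, +1 gain}.

    A segment is a gain if its level exceeds the reference median by
    more than ``tolerance`` (relative), a loss if below by more than
    ``tolerance``; 0.25 splits diploid from single-copy gain/loss at
    the ratio midpoints 1.25 / 0.75.
    """
    levels = segmented.levels.to_numpy(dtype=float)
    hi = reference_median * (1 + tolerance)
    lo = reference_median * (1 - tolerance)
    events = np.zeros_like(levels, dtype=int)
    events[levels > hi] = 1
    events[levels < lo] = -1
    return pd.DataFrame(events, columns=segmented.levels.columns)


def events_per_bin(segmented: SegmentedProfiles, events: pd.DataFrame,
                   n_bins: int) -> pd.DataFrame:
    """Expand per-segment events back to the bin axis (for clustering)."""
    out = np.zeros((n_bins, events.shape[1]), dtype=int)
    for row, (s, e) in enumerate(
        segmented.segments[["start_bin", "end_bin"]].itertuples(index=False)
    ):
        out[s:e] = events.to_numpy()[row]
    return pd.DataFrame(out, columns=events.columns)


def correlation_cluster(matrix: pd.DataFrame) -> tuple[np.ndarray, pd.DataFrame]:
    """Hierarchical clustering of samples on Pearson correlation.

    ``matrix`` is features x samples (event vectors or copy ratios);
    distance = 1 - r, average linkage.  Returns (linkage matrix,
    correlation matrix).  Constant (featureless) samples get r = 0
    against everything.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x features
    n = X.shape[0]
    if n < 2:
        raise ValueError("need >= 2 samples")
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(X)
    corr = np.nan_to_num(corr, nan=0.0)  # constant samples: r := 0
    np.fill_diagonal(corr, 1.0)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2, 0.0, None)
    Z = average(squareform(dist, checks=False))
    corr_df = pd.DataFrame(corr, index=matrix.columns, columns=matrix.columns)
    return Z, corr_df


def cut_clusters(Z: np.ndarray, k: int) -> np.ndarray:
    """Flat cluster labels from a linkage matrix at ``k`` clusters."""
    return fcluster(Z, t=k, criterion="maxclust")


# ---------------------------------------------------------------------------
# multiscale bootstrap (AU p-values)
# ---------------------------------------------------------------------------

@dataclass
class ClusterSupport:
    linkage: np.ndarray
    clades: list[frozenset[int]]  # per internal node, leaf index set
    au: np.ndarray  # per internal node
    bp: np.ndarray  # ordinary bootstrap probability (scale 1)
    bp_by_scale: pd.DataFrame  # scales x nodes
    n_bootstrap: int
    scales: tuple[float, ...] = DEFAULT_SCALES
    degenerate: np.ndarray = field(default=None)  # nodes never re-formed


def _clades_of(Z: np.ndarray, n: int) -> list[frozenset[int]]:
    tree = to_tree(Z)
    clades = []

    def leaves(node):
        if node.is_leaf():
            return frozenset([node.id])
        s = leaves(node.left) | leaves(node.right)
        clades.append(s)
        return s

    leaves(tree)
    return clades


def au_pvalues(
    matrix: pd.DataFrame,
    n_bootstrap: int = 10_000,
    scales: tuple[float, ...] = DEFAULT_SCALES,
    seed: int = 0,
) -> ClusterSupport:
    """Approximately unbiased cluster support via multiscale bootstrap.

    The feature axis (rows of ``matrix``, e.g. bins or segments) is
    resampled with replacement at each scale r in ``scales`` to size
    round(r * n_features), ``n_bootstrap`` times per scale; samples are
    re-clustered each time and the per-clade bootstrap probability
    BP(r) recorded.  The probit model z(r) = v*sqrt(r) + c/sqrt(r) with
    z = Phi^-1(1 - BP) is fit by weighted least squares and
    AU = Phi(c - v).  Clades that never re-form at any scale are
    degenerate and get AU = 0 with a flag.
    """
    if n_bootstrap <= 0:
        raise ValueError("n_bootstrap must be positive")
    n_samples = matrix.shape[1]
    if n_samples < 3:
        raise ValueError("need >= 3 samples for cluster support")
    rng = np.random.default_rng(seed)
    Z, _ = correlation_cluster(matrix)
    clades = _clades_of(Z, n_samples)
    n_feat = matrix.shape[0]
    X = matrix

    counts = np.zeros((len(scales), len(clades)), dtype=int)
    for si, r in enumerate(scales):
        m = max(3, int(round(r * n_feat)))
        for _ in range(n_bootstrap):
            idx = rng.integers(0, n_feat, size=m)
            Zb, _ = correlation_cluster(X.iloc[idx])
            boot_clades = set(_clades_of(Zb, n_samples))
            for ci, clade in enumerate(clades):
                if clade in boot_clades:
                    counts[si, ci] += 1

    bp_by_scale = counts / n_bootstrap
    au = np.zeros(len(clades))
    bp1 = np.zeros(len(clades))
    degenerate = np.zeros(len(clades), dtype=bool)
    sq = np.sqrt(np.asarray(scales))
    design = np.column_stack([sq, 1.0 / sq])
    one_idx = int(np.argmin(np.abs(np.asarray(scales) - 1.0)))
    for ci in range(len(clades)):
        bp1[ci] = bp_by_scale[one_idx, ci]
        if counts[:, ci].sum() == 0:
            degenerate[ci] = True
            continue
        if (counts[:, ci] == n_bootstrap).all():
            # recovered in every replicate at every scale: maximal support
            au[ci] = 1.0
            continue
        # clamp away from 0/1 for the probit transform
        bp = np.clip(bp_by_scale[:, ci], 0.5 / n_bootstrap, 1 - 0.5 / n_bootstrap)
        z = norm.ppf(1.0 - bp)
        var = bp * (1 - bp) / (n_bootstrap * norm.pdf(z) ** 2)
        w = 1.0 / np.maximum(var, 1e-12)
        W = design * w[:, None]
        try:
            beta = np.linalg.solve(design.T @ W, W.T @ z)
        except np.linalg.LinAlgError:
            degenerate[ci] = True
            continue
        v, c = beta
        au[ci] = norm.cdf(c - v)
    au[degenerate] = 0.0
    return ClusterSupport(
        linkage=Z,
        clades=clades,
        au=au,
        bp=bp1,
        bp_by_scale=pd.DataFrame(bp_by_scale, index=list(scales)),
        n_bootstrap=n_bootstrap,
        scales=tuple(scales),
        degenerate=degenerate,
    )
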