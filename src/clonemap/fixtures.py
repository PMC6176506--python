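"""Synthetic inputs with planted ground truth for every pipeline stage.

Each generator is a pure function of its parameters and a seed, and
emulates one of the toolkit's real-world inputs: labeled segmentation
masks of stained tissue, per-bin read counts from low-depth WGS of
amplified cell clusters, per-caller variant call sets with allele
depths, UMI-tagged deep-sequencing read observations, and real-time
amplification fluorescence curves.  The planted truth (group labels,
subclone structure, variant origin) rides along so downstream modules
can be scored against it.

The default synthetic genome is deliberately small — two chromosomes of
5 Mb with a few hundred bins — which is enough to exercise the binning,
normalization, segmentation and consensus mathematics at seconds scale.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

BASES = ("A", "C", "G", "T")

DEFAULT_CALLERS = ("A", "B", "C")


class PackingError(RuntimeError):
    """Raised when non-overlapping cluster placement is unsatisfiable."""


@dataclass
class CNAEvent:
    chrom: str
    start_bin: int
    end_bin: int  # half-open in bin index space
    subclone: str
    direction: str  # "gain" | "loss"


@dataclass
class Variant:
    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    subclone: str | None  # None for germline
    af: float


@dataclass
class PlantedTruth:
    """Ground truth planted by the generators.

    ``group_of_cluster`` maps mask label values to morphological group
    ids; ``subclone_of_sample`` maps sample ids to subclone ids.
    Regenerating any fixture with the same seed reproduces it exactly.
    """

    seed: int = 0
    chrom_lengths: dict[str, int] = field(default_factory=dict)
    group_of_cluster: dict[int, int] = field(default_factory=dict)
    subclone_of_sample: dict[str, str] = field(default_factory=dict)
    cna_events: list[CNAEvent] = field(default_factory=list)
    somatic_variants: list[Variant] = field(default_factory=list)
    germline_variants: list[Variant] = field(default_factory=list)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "PlantedTruth":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            seed=d["seed"],
            chrom_lengths=dict(d["chrom_lengths"]),
            group_of_cluster={int(k): int(v) for k, v in d["group_of_cluster"].items()},
            subclone_of_sample=dict(d["subclone_of_sample"]),
            cna_events=[CNAEvent(**e) for e in d["cna_events"]],
            somatic_variants=[Variant(**v) for v in d["somatic_variants"]],
            germline_variants=[Variant(**v) for v in d["germline_variants"]],
        )


# ---------------------------------------------------------------------------
# genome and bins
# ---------------------------------------------------------------------------

def default_genome(n_chroms: int = 2, chrom_length: int = 5_000_000) -> dict[str, int]:
    return {f"chr{i + 1}": chrom_length for i in range(n_chroms)}


def uniform_bins(chrom_lengths: Mapping[str, int], n_bins: int) -> pd.DataFrame:
    """Equal-width bins with equal expected read fractions and a smooth GC track."""
    lengths = pd.Series(chrom_lengths, dtype=float)
    alloc = _allocate(lengths.to_numpy(), n_bins)
    rows = []
    for (chrom, length), k in zip(chrom_lengths.items(), alloc):
        edges = np.linspace(0, length, k + 1).astype(int)
        for s, e in zip(edges[:-1], edges[1:]):
            rows.append((chrom, int(s), int(e)))
    bins = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    bins["expected_fraction"] = 1.0 / len(bins)
    bins["gc"] = synthetic_gc(bins)
    return bins


def synthetic_gc(bins: pd.DataFrame) -> np.ndarray:
    """Deterministic GC track over bin midpoints, range ~0.30-0.60.

    Two incommensurate sinusoids with sub-Mb periods: GC then varies
    isochore-like from bin to bin but stays uncorrelated with the
    multi-Mb copy-number events the fixtures plant, as in real genomes.
    """
    mid = (bins["start"].to_numpy() + bins["end"].to_numpy()) / 2.0
    chrom_idx = pd.factorize(bins["chrom"])[0]
    phase1 = 2 * np.pi * mid / 3.9e5 + 0.7 * chrom_idx
    phase2 = 2 * np.pi * mid / 1.37e5 + 1.3 * chrom_idx
    return 0.45 + 0.10 * np.sin(phase1) + 0.05 * np.sin(phase2)


def _allocate(weights: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of `total` among positive weights."""
    w = np.asarray(weights, dtype=float)
    if w.sum() <= 0:
        raise ValueError("weights must have positive sum")
    raw = total * w / w.sum()
    base = np.floor(raw).astype(int)
    rem = total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:rem]] += 1
    return base


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

_DEFAULT_GROUP_GEOMETRY = dict(
    centroid_sd=45.0,
    area_mean=300.0,
    area_sd=30.0,
    axis_ratio_mean=1.5,
    axis_ratio_sd=0.08,
    angle_mean=20.0,
    angle_sd=4.0,
)


def default_group_geometry(n_groups: int, image_size: tuple[int, int]) -> list[dict]:
    """Well-separated per-group geometry distributions.

    Groups sit at distinct spatial anchors and differ strongly in area,
    elongation and orientation, emulating subclones with distinct
    collective growth morphology.
    """
    h, w = image_size
    anchors = _group_anchors(n_groups, h, w)
    out = []
    for g in range(n_groups):
        geom = dict(_DEFAULT_GROUP_GEOMETRY)
        geom["center"] = anchors[g]
        geom["area_mean"] = 200.0 + 250.0 * g
        geom["axis_ratio_mean"] = 1.3 + 1.2 * g
        geom["angle_mean"] = (15.0 + 55.0 * g) % 180.0
        out.append(geom)
    return out


def _group_anchors(n: int, h: int, w: int) -> list[tuple[float, float]]:
    k = int(np.ceil(np.sqrt(n)))
    xs = np.linspace(0.18, 0.82, k) * w
    ys = np.linspace(0.18, 0.82, k) * h
    pts = [(x, y) for y in ys for x in xs]
    return pts[:n]


def make_mask_with_groups(
    n_groups: int,
    clusters_per_group: int,
    image_size: tuple[int, int] = (512, 512),
    geometry: Sequence[Mapping] | None = None,
    margin: int = 3,
    max_tries: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, PlantedTruth]:
    """Labeled mask of elliptical cell-cluster blobs in ``n_groups`` groups.

    Each blob is an analytically filled ellipse realizing its group's
    geometry distribution (centroid dispersion around a group anchor,
    area, major/minor axis ratio, orientation angle).  Blobs never
    touch: candidate placements overlapping the occupied footprint
    (inflated by ``margin`` pixels) are rejected and resampled, and an
    unsatisfiable packing raises :class:`PackingError` after
    ``max_tries`` attempts per blob.  Labels are 1..N with background 0.
    """
    if n_groups < 1 or clusters_per_group < 1:
        raise ValueError("n_groups and clusters_per_group must be >= 1")
    rng = np.random.default_rng(seed)
    h, w = image_size
    if geometry is None:
        geometry = default_group_geometry(n_groups, image_size)
    if len(geometry) != n_groups:
        raise ValueError("need one geometry spec per group")

    mask = np.zeros((h, w), dtype=np.int32)
    occupied = np.zeros((h, w), dtype=bool)
    group_of_cluster: dict[int, int] = {}
    label = 0
    for g, geom in enumerate(geometry):
        cx0, cy0 = geom.get("center", (w / 2, h / 2))
        for _ in range(clusters_per_group):
            label += 1
            placed = False
            for _try in range(max_tries):
                cx = rng.normal(cx0, geom["centroid_sd"])
                cy = rng.normal(cy0, geom["centroid_sd"])
                area = max(20.0, rng.normal(geom["area_mean"], geom["area_sd"]))
                ratio = max(1.0, rng.normal(geom["axis_ratio_mean"], geom["axis_ratio_sd"]))
                angle = rng.normal(geom["angle_mean"], geom["angle_sd"]) % 180.0
                b = max(1.5, np.sqrt(area / (np.pi * ratio)))
                a = ratio * b
                sl, inside = _ellipse_pixels(cx, cy, a, b, angle, h, w)
                if inside is None:
                    continue
                slp, pad = _ellipse_pixels(cx, cy, a + margin, b + margin, angle, h, w)
                if pad is None:
                    continue
                if occupied[slp][pad].any():
                    continue
                mask[sl][inside] = label
                occupied[slp][pad] = True
                group_of_cluster[label] = g
                placed = True
                break
            if not placed:
                raise PackingError(
                    f"could not place cluster {label} after {max_tries} tries; "
                    "reduce cluster count or size, or enlarge the image"
                )
    truth = PlantedTruth(seed=seed, group_of_cluster=group_of_cluster)
    return mask, truth


def _ellipse_pixels(cx, cy, a, b, angle_deg, h, w):
    """Boolean footprint of a rotated ellipse, restricted to its bbox.

    Angle convention: degrees counter-clockwise from the +x (column)
    axis in standard orientation (y up); image rows grow downward.
    Returns (bbox slices, boolean array) or (None, None) if the ellipse
    leaves the image.
    """
    r = max(a, b)
    r0, r1 = int(np.floor(cy - r)) - 1, int(np.ceil(cy + r)) + 2
    c0, c1 = int(np.floor(cx - r)) - 1, int(np.ceil(cx + r)) + 2
    if r0 < 0 or c0 < 0 or r1 > h or c1 > w:
        return None, None
    rows, cols = np.mgrid[r0:r1, c0:c1]
    x = cols - cx
    y = -(rows - cy)  # flip: image rows grow downward
    th = np.deg2rad(angle_deg)
    u = x * np.cos(th) + y * np.sin(th)
    v = -x * np.sin(th) + y * np.cos(th)
    inside = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    if not inside.any():
        return None, None
    return (slice(r0, r1), slice(c0, c1)), inside


# ---------------------------------------------------------------------------
# binned depth
# ---------------------------------------------------------------------------

def make_subclone_profiles(
    bins: pd.DataFrame,
    subclones: Sequence[str],
    events_per_subclone: int = 2,
    event_span_bins: tuple[int, int] = (25, 50),
    base_copy: int = 2,
    seed: int = 0,
) -> tuple[dict[str, np.ndarray], list[CNAEvent]]:
    """Per-subclone integer copy states with planted, non-overlapping events.

    Each subclone starts from the diploid base state and receives
    ``events_per_subclone`` private gains/losses over contiguous bin
    ranges; ranges never overlap within a subclone so that recovered
    event vectors are unambiguous.
    """
    rng = np.random.default_rng(seed)
    n = len(bins)
    profiles: dict[str, np.ndarray] = {}
    events: list[CNAEvent] = []
    chrom_of_bin = bins["chrom"].to_numpy()
    for sc in subclones:
        copy = np.full(n, base_copy, dtype=int)
        taken = np.zeros(n, dtype=bool)
        for _ in range(events_per_subclone):
            for _try in range(200):
                span = int(rng.integers(event_span_bins[0], event_span_bins[1] + 1))
                if span >= n:
                    span = max(1, n // 3)
                s = int(rng.integers(0, n - span))
                e = s + span
                if taken[s:e].any() or chrom_of_bin[s] != chrom_of_bin[e - 1]:
                    continue
                direction = "gain" if rng.random() < 0.5 else "loss"
                copy[s:e] = base_copy + 1 if direction == "gain" else base_copy - 1
                taken[s:e] = True
                events.append(CNAEvent(str(chrom_of_bin[s]), s, e, sc, direction))
                break
        profiles[sc] = copy
    return profiles, events


def simulate_binned_depth(
    bins: pd.DataFrame,
    subclone_profiles: Mapping[str, np.ndarray],
    samples: Sequence[tuple[str, str]],
    reads_per_sample: int = 100_000,
    gc_bias: Callable[[np.ndarray], np.ndarray] | Sequence[float] | None = None,
    noise_model: str = "poisson",
    nb_dispersion: float = 0.1,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-bin read counts for each sample given its subclone's copy state.

    Expected count per bin is proportional to copy state x expected
    read fraction x GC bias evaluated at the bin GC; counts are drawn
    Poisson or negative-binomial (variance mu + dispersion*mu^2).
    ``gc_bias`` may be a callable of GC fraction or polynomial
    coefficients for :func:`numpy.polyval`; it must be positive over
    the observed GC range.
    """
    rng = np.random.default_rng(seed)
    gc = bins["gc"].to_numpy()
    frac = bins["expected_fraction"].to_numpy()
    bias = _eval_gc_bias(gc_bias, gc)
    counts = {}
    for sample_id, subclone in samples:
        copy = np.asarray(subclone_profiles[subclone], dtype=float)
        if (copy < 0).any():
            raise ValueError("copy states must be >= 0")
        if len(copy) != len(bins):
            raise ValueError("profile length must match bin count")
        mu = copy * frac * bias
        if (mu < 0).any():
            raise ValueError("negative expected count")
        mu = mu / mu.sum() * reads_per_sample
        if noise_model == "poisson":
            counts[sample_id] = rng.poisson(mu)
        elif noise_model in ("nb", "negative-binomial"):
            if nb_dispersion <= 0:
                counts[sample_id] = rng.poisson(mu)
            else:
                nshape = 1.0 / nb_dispersion
                p = nshape / (nshape + mu)
                counts[sample_id] = rng.negative_binomial(nshape, p)
        else:
            raise ValueError(f"unknown noise model {noise_model!r}")
    return pd.DataFrame(counts, index=bins.index)


def quadratic_gc_bias(gc: np.ndarray) -> np.ndarray:
    """Default planted GC bias: quadratic, monotone over the GC range.

    Rises from ~0.6x at GC 0.30 to ~0.9x at GC 0.60, emulating the
    amplification/coverage preference for GC-rich fragments; induces a
    clearly positive count-GC correlation for normalization to remove.
    """
    gc = np.asarray(gc, dtype=float)
    return 0.6 + 3.5 * (gc - 0.30) ** 2


def _eval_gc_bias(gc_bias, gc: np.ndarray) -> np.ndarray:
    if gc_bias is None:
        return np.ones_like(gc)
    bias = gc_bias(gc) if callable(gc_bias) else np.polyval(np.asarray(gc_bias), gc)
    bias = np.asarray(bias, dtype=float)
    if (bias <= 0).any():
        raise ValueError("GC bias must be positive over the observed GC range")
    return bias


def simulate_read_positions(
    bins: pd.DataFrame,
    copy_state: np.ndarray | None,
    n_reads: int,
    gc_bias=None,
    seed: int = 0,
) -> dict[str, np.ndarray]:
    """Sorted per-chromosome read positions; copy_state None means flat."""
    rng = np.random.default_rng(seed)
    gc = bins["gc"].to_numpy()
    frac = bins["expected_fraction"].to_numpy()
    copy = np.ones(len(bins)) if copy_state is None else np.asarray(copy_state, float)
    weights = copy * frac * _eval_gc_bias(gc_bias, gc)
    weights = weights / weights.sum()
    bin_idx = rng.choice(len(bins), size=n_reads, p=weights)
    start = bins["start"].to_numpy()[bin_idx]
    end = bins["end"].to_numpy()[bin_idx]
    pos = start + (rng.random(n_reads) * (end - start)).astype(int)
    chroms = bins["chrom"].to_numpy()[bin_idx]
    out = {}
    for chrom in bins["chrom"].unique():
        out[str(chrom)] = np.sort(pos[chroms == chrom])
    return out


# ---------------------------------------------------------------------------
# variant calls
# ---------------------------------------------------------------------------

def make_variant_truth(
    chrom_lengths: Mapping[str, int],
    subclones: Sequence[str],
    shared_somatic: int = 10,
    private_somatic: int = 5,
    germline: int = 20,
    somatic_af: float = 0.5,
    seed: int = 0,
) -> PlantedTruth:
    """Plant germline plus clonal (shared) and subclone-private somatic SNVs."""
    rng = np.random.default_rng(seed)
    used: set[tuple[str, int]] = set()

    def draw_locus():
        for _ in range(1000):
            chrom = str(rng.choice(list(chrom_lengths)))
            pos = int(rng.integers(1, chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos
        raise RuntimeError("locus space exhausted")

    def draw_alleles():
        ref = str(rng.choice(BASES))
        alt = str(rng.choice([b for b in BASES if b != ref]))
        return ref, alt

    somatic, germ = [], []
    for _ in range(shared_somatic):
        chrom, pos = draw_locus()
        ref, alt = draw_alleles()
        somatic.append(Variant(chrom, pos, ref, alt, "*", somatic_af))
    for sc in subclones:
        for _ in range(private_somatic):
            chrom, pos = draw_locus()
            ref, alt = draw_alleles()
            somatic.append(Variant(chrom, pos, ref, alt, sc, somatic_af))
    for _ in range(germline):
        chrom, pos = draw_locus()
        ref, alt = draw_alleles()
        af = 0.5 if rng.random() < 0.7 else 1.0
        germ.append(Variant(chrom, pos, ref, alt, None, af))
    return PlantedTruth(
        seed=seed,
        chrom_lengths=dict(chrom_lengths),
        somatic_variants=somatic,
        germline_variants=germ,
    )


@dataclass
class CallerSim:
    """Output bundle of :func:`simulate_caller_vcfs`."""

    calls: pd.DataFrame  # sample, caller, chrom, pos, ref, alt, alt_depth, total_depth
    normal_calls: pd.DataFrame
    depths: dict[str, pd.DataFrame]  # sample -> chrom,pos,ref,A,C,G,T (+attrs contract)
    artifacts: pd.DataFrame  # sample-private WGA artifacts actually planted


def simulate_caller_vcfs(
    truth: PlantedTruth,
    samples: Sequence[tuple[str, str]],
    callers: Sequence[str] = DEFAULT_CALLERS,
    sensitivity: Mapping[str, float] | float = 0.9,
    false_calls_per_mb: Mapping[str, float] | float = 0.2,
    wga_errors_per_sample: float = 10.0,
    mean_depth: float = 80.0,
    depth_dispersion: float = 0.15,
    artifact_af: float = 0.35,
    base_error_rate: float = 1e-3,
    seed: int = 0,
) -> CallerSim:
    """Per-caller per-sample SNV call sets plus a paired normal.

    A sample's amplified DNA carries the germline variants, the somatic
    variants of its subclone (subclone ``"*"`` means clonal/shared by
    all), and a Poisson number of sample-private WGA artifacts.  Each
    caller then detects each DNA variant independently with its
    sensitivity and adds its own false calls at ``false_calls_per_mb``.
    Per-base pile-up depth tables (one per sample, covering the union
    of all emitted loci) reflect the DNA truth, not the caller errors,
    and carry the MQ>=30 / no-supplementary read-filter declaration.
    """
    rng = np.random.default_rng(seed)
    if isinstance(sensitivity, (int, float)):
        sensitivity = {c: float(sensitivity) for c in callers}
    if isinstance(false_calls_per_mb, (int, float)):
        false_calls_per_mb = {c: float(false_calls_per_mb) for c in callers}
    for c in callers:
        if not 0 <= sensitivity[c] <= 1:
            raise ValueError("sensitivity must be in [0,1]")
    genome_mb = sum(truth.chrom_lengths.values()) / 1e6

    used = {(v.chrom, v.pos) for v in truth.somatic_variants + truth.germline_variants}

    def draw_locus():
        while True:
            chrom = str(rng.choice(list(truth.chrom_lengths)))
            pos = int(rng.integers(1, truth.chrom_lengths[chrom] + 1))
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    # per-sample DNA truth: locus -> (ref, alt, af)
    dna: dict[str, dict[tuple[str, int], tuple[str, str, float]]] = {}
    artifact_rows = []
    for sample_id, subclone in samples:
        carried: dict[tuple[str, int], tuple[str, str, float]] = {}
        for v in truth.germline_variants:
            carried[(v.chrom, v.pos)] = (v.ref, v.alt, v.af)
        for v in truth.somatic_variants:
            if v.subclone == "*" or v.subclone == subclone:
                carried[(v.chrom, v.pos)] = (v.ref, v.alt, v.af)
        n_art = rng.poisson(wga_errors_per_sample)
        for _ in range(n_art):
            chrom, pos = draw_locus()
            ref = str(rng.choice(BASES))
            alt = str(rng.choice([b for b in BASES if b != ref]))
            carried[(chrom, pos)] = (ref, alt, artifact_af)
            artifact_rows.append((sample_id, chrom, pos, ref, alt))
        dna[sample_id] = carried
    artifacts = pd.DataFrame(
        artifact_rows, columns=["sample", "chrom", "pos", "ref", "alt"]
    )

    # caller false calls (NGS errors, not in the DNA)
    false_rows = []
    for sample_id, _ in samples:
        for c in callers:
            n_fc = rng.poisson(false_calls_per_mb[c] * genome_mb)
            for _ in range(n_fc):
                chrom, pos = draw_locus()
                ref = str(rng.choice(BASES))
                alt = str(rng.choice([b for b in BASES if b != ref]))
                false_rows.append((sample_id, c, chrom, pos, ref, alt))

    # union of loci needing a pile-up row, per sample
    all_loci: dict[tuple[str, int], tuple[str, str]] = {}
    for carried in dna.values():
        for locus, (ref, alt, _af) in carried.items():
            all_loci[locus] = (ref, alt)
    for _s, _c, chrom, pos, ref, alt in false_rows:
        all_loci.setdefault((chrom, pos), (ref, alt))
    loci_sorted = sorted(all_loci)

    depths: dict[str, pd.DataFrame] = {}
    base_idx = {b: i for i, b in enumerate(BASES)}
    for sample_id, _sub in samples:
        carried = dna[sample_id]
        rows = []
        for chrom, pos in loci_sorted:
            ref, alt = all_loci[(chrom, pos)]
            af = 0.0
            if (chrom, pos) in carried:
                ref, alt, af = carried[(chrom, pos)]
            total = _draw_depth(rng, mean_depth, depth_dispersion)
            counts = np.zeros(4, dtype=int)
            alt_n = rng.binomial(total, af) if af > 0 else 0
            counts[base_idx[alt]] = alt_n
            for b in BASES:
                if b not in (ref, alt):
                    counts[base_idx[b]] = rng.binomial(total - counts.sum(), base_error_rate)
            counts[base_idx[ref]] = total - counts.sum()
            rows.append((chrom, pos, ref, *counts))
        df = pd.DataFrame(rows, columns=["chrom", "pos", "ref", *BASES])
        df.attrs["min_mapq"] = 30
        df.attrs["supplementary"] = "excluded"
        depths[sample_id] = df

    # caller call sets: detected DNA variants + that caller's false calls
    call_rows = []
    for sample_id, _sub in samples:
        dtab = depths[sample_id].set_index(["chrom", "pos"])
        for (chrom, pos), (ref, alt, af) in sorted(dna[sample_id].items()):
            row = dtab.loc[(chrom, pos)]
            total = int(sum(row[b] for b in BASES))
            for c in callers:
                if rng.random() < sensitivity[c]:
                    call_rows.append(
                        (sample_id, c, chrom, pos, ref, alt, int(row[alt]), total)
                    )
    depth_idx = {s: depths[s].set_index(["chrom", "pos"]) for s, _ in samples}
    for sample_id, c, chrom, pos, ref, alt in false_rows:
        row = depth_idx[sample_id].loc[(chrom, pos)]
        # caller error: reported alt support is spurious low-count noise
        call_rows.append(
            (sample_id, c, chrom, pos, ref, alt,
             max(int(row[alt]), 1), int(sum(row[b] for b in BASES)))
        )
    calls = pd.DataFrame(
        call_rows,
        columns=["sample", "caller", "chrom", "pos", "ref", "alt",
                 "alt_depth", "total_depth"],
    ).sort_values(["sample", "caller", "chrom", "pos"], ignore_index=True)

    normal_rows = []
    for v in truth.germline_variants:
        total = _draw_depth(rng, mean_depth, depth_dispersion)
        alt_n = rng.binomial(total, v.af)
        normal_rows.append((v.chrom, v.pos, v.ref, v.alt, alt_n, total))
    normal_calls = pd.DataFrame(
        normal_rows, columns=["chrom", "pos", "ref", "alt", "alt_depth", "total_depth"]
    ).sort_values(["chrom", "pos"], ignore_index=True)

    return CallerSim(calls=calls, normal_calls=normal_calls, depths=depths,
                     artifacts=artifacts)


def _draw_depth(rng, mean_depth: float, dispersion: float) -> int:
    if dispersion <= 0:
        return max(1, int(rng.poisson(mean_depth)))
    nshape = 1.0 / dispersion
    p = nshape / (nshape + mean_depth)
    return max(1, int(rng.negative_binomial(nshape, p)))


# ---------------------------------------------------------------------------
# UMI reads
# ---------------------------------------------------------------------------

def simulate_umi_reads(
    loci: pd.DataFrame,
    true_af: float | Sequence[float] = 0.0,
    families_per_locus: int = 200,
    reads_per_family: int | tuple[str, float] = ("poisson", 5.0),
    per_read_error: float = 1e-3,
    seed: int = 0,
) -> pd.DataFrame:
    """UMI-family read observations: (family_tag, chrom, pos, base).

    Each family descends from one template molecule whose base is the
    locus alt allele with probability ``true_af`` else the reference;
    every read then reports the template base, miscalled uniformly to
    another base with probability ``per_read_error``.  ``loci`` needs
    columns chrom, pos, ref, alt.
    """
    if not 0 <= per_read_error <= 1:
        raise ValueError("per_read_error must be in [0,1]")
    rng = np.random.default_rng(seed)
    afs = np.broadcast_to(np.asarray(true_af, dtype=float), (len(loci),))
    rows = []
    for (idx, locus), af in zip(loci.reset_index(drop=True).iterrows(), afs):
        chrom, pos, ref, alt = locus["chrom"], int(locus["pos"]), locus["ref"], locus["alt"]
        for fam in range(families_per_locus):
            tag = f"{chrom}:{pos}:F{fam:05d}"
            template = alt if rng.random() < af else ref
            if isinstance(reads_per_family, int):
                n_reads = reads_per_family
            else:
                n_reads = max(1, int(rng.poisson(reads_per_family[1])))
            for _ in range(n_reads):
                base = template
                if per_read_error > 0 and rng.random() < per_read_error:
                    base = str(rng.choice([b for b in BASES if b != template]))
                rows.append((tag, chrom, pos, base))
    return pd.DataFrame(rows, columns=["family_tag", "chrom", "pos", "base"])


# ---------------------------------------------------------------------------
# amplification curves
# ---------------------------------------------------------------------------

def simulate_amp_curves(
    start_times: Sequence[float | None],
    plateau: float = 1000.0,
    noise_sd: float = 3.0,
    sample_interval: float = 1.0,
    duration: float = 80.0,
    rise_rate: float = 0.25,
    seed: int = 0,
) -> pd.DataFrame:
    """Real-time amplification fluorescence curves sampled on a fixed grid.

    Each curve is flat baseline before its start time, then a
    saturating-exponential rise to ``plateau`` (sigmoidal overall, with
    the take-off at the planted start); Gaussian noise of ``noise_sd``
    is added throughout.  ``start_times`` entries of None produce
    negative-control curves (flat noise).  Returns a frame with a
    ``time_min`` column plus one column per curve.
    """
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, duration + 1e-9, sample_interval)
    data = {"time_min": t}
    for i, t0 in enumerate(start_times):
        if t0 is None:
            signal = np.zeros_like(t)
        else:
            signal = np.where(t < t0, 0.0, plateau * (1 - np.exp(-rise_rate * (t - t0))))
        if noise_sd > 0:
            signal = signal + rng.normal(0.0, noise_sd, size=t.shape)
        data[f"curve_{i}"] = signal
    return pd.DataFrame(data)
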