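"""Spatial mapping of genomic subclones onto tissue sections.

Cell-cluster coordinates (per-section x, y plus a section index) are
joined with their subclone assignments; the third dimension is
reconstructed from the section index times the physical slice spacing
(700 um by default, matching serial sectioning of a tumor block).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_SECTION_SPACING_UM = 700.0

MAP_COLUMNS = ["cluster_id", "section_index", "x", "y", "z_um", "subclone"]


@dataclass
class SpatialMap:
    table: pd.DataFrame  # MAP_COLUMNS (+ optional annotation columns)
    section_spacing_um: float = DEFAULT_SECTION_SPACING_UM
    unmatched_coords: list = field(default_factory=list)
    unmatched_assignments: list = field(default_factory=list)


def build_map(
    coords: pd.DataFrame,
    assignments: pd.DataFrame,
    section_spacing_um: float = DEFAULT_SECTION_SPACING_UM,
    annotations: pd.DataFrame | None = None,
) -> SpatialMap:
    """Join cluster coordinates with subclone labels into a 3D map.

    ``coords`` needs (cluster_id, section_index, x, y); ``assignments``
    needs (cluster_id, subclone).  Clusters without an assignment are
    kept as "unassigned" with a warning; assignment rows without
    coordinates are reported as unmatched.  z = section_index x
    spacing.
    """
    for col in ("cluster_id", "section_index", "x", "y"):
        if col not in coords.columns:
            raise ValueError(f"coords missing column {col!r}")
    if "cluster_id" not in assignments.columns or "subclone" not in assignments.columns:
        raise ValueError("assignments need columns cluster_id, subclone")
    merged = coords.merge(
        assignments[["cluster_id", "subclone"]], on="cluster_id", how="left"
    )
    unassigned = merged["subclone"].isna()
    if unassigned.any():
        warnings.warn(
            f"{int(unassigned.sum())} clusters without subclone assignment",
            stacklevel=2,
        )
    merged["subclone"] = merged["subclone"].fillna("unassigned")
    merged["z_um"] = merged["section_index"].astype(float) * section_spacing_um
    missing_coords = sorted(
        set(assignments["cluster_id"]) - set(coords["cluster_id"])
    )
    table = merged[["cluster_id", "section_index", "x", "y", "z_um", "subclone"]]
    if annotations is not None:
        table = table.merge(annotations, on="cluster_id", how="left")
    return SpatialMap(
        table=table.reset_index(drop=True),
        section_spacing_um=section_spacing_um,
        unmatched_coords=sorted(merged.loc[unassigned, "cluster_id"].tolist()),
        unmatched_assignments=missing_coords,
    )


def export_map(smap: SpatialMap, path: str | Path) -> Path:
    """Write the map as TSV (always); returns the path written."""
    path = Path(path)
    smap.table.to_csv(path, sep="\t", index=False)
    return path


def read_map(path: str | Path, section_spacing_um: float = DEFAULT_SECTION_SPACING_UM
             ) -> SpatialMap:
    table = pd.read_csv(path, sep="\t")
    return SpatialMap(table=table, section_spacing_um=section_spacing_um)


def subclone_colors(smap: SpatialMap) -> dict[str, str]:
    """Stable subclone -> color mapping (sorted label order)."""
    import matplotlib

    labels = sorted(smap.table["subclone"].astype(str).unique())
    cmap = matplotlib.colormaps["tab10"]
    return {lab: matplotlib.colors.to_hex(cmap(i % 10)) for i, lab in enumerate(labels)}


def plot_sections(smap: SpatialMap, out_prefix: str | Path) -> list[Path]:
    """Static 2D scatter per section, colored by subclone."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    colors = subclone_colors(smap)
    paths = []
    for section, sub in smap.table.groupby("section_index"):
        fig, ax = plt.subplots(figsize=(5, 5))
        for lab, grp in sub.groupby("subclone"):
            ax.scatter(grp["x"], grp["y"], s=18, color=colors[str(lab)], label=str(lab))
        ax.set_title(f"section {section} (z = {section * smap.section_spacing_um:g} um)")
        ax.invert_yaxis()
        ax.legend(fontsize=8)
        p = Path(f"{out_prefix}_section{section}.png")
        fig.savefig(p, dpi=120)
        plt.close(fig)
        paths.append(p)
    return paths


def contiguity(smap: SpatialMap, k: int = 5) -> float:
    """Mean same-subclone fraction among each cluster's k nearest 3D neighbors.

    A value near 1 means subclones are spatially segregated; near the
    subclone size fractions means spatial mixing.
    """
    from sklearn.neighbors import NearestNeighbors

    tab = smap.table[smap.table["subclone"] != "unassigned"]
    if len(tab) < k + 1:
        raise ValueError("too few assigned clusters for the contiguity statistic")
    X = tab[["x", "y", "z_um"]].to_numpy(dtype=float)
    labels = tab["subclone"].to_numpy()
    nn = NearestNeighbors(n_neighbors=k + 1).fit(X)
    _, idx = nn.kneighbors(X)
    same = labels[idx[:, 1:]] == labels[:, None]
    return float(same.mean())
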