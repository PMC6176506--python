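"""Single-strand consensus validation of detected SNVs.

Targeted deep sequencing with unique molecular tags lets each read
family be collapsed to the consensus base of its template molecule — a
single-strand consensus sequence (SSCS) — which suppresses per-read
sequencing errors by orders of magnitude.  Loci where an SNV had been
detected (targets) are then compared against loci with no detected SNV
(background): the background non-reference SSCS allele fractions form
an empirical null, each target gets an add-one empirical p-value, and
targets surviving Benjamini-Hochberg FDR control at 0.05 are considered
validated.

Duplex (double-strand) consensus is deliberately out of scope: the
library construction this validates amplifies before tagging, which
retains single-strand but not duplex information.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

BASES = ("A", "C", "G", "T")


def call_sscs(
    reads: pd.DataFrame,
    min_family_size: int = 3,
    consensus_fraction: float = 0.9,
) -> pd.DataFrame:
    """Collapse UMI families to one consensus observation per molecule.

    ``reads`` has columns (family_tag, chrom, pos, base).  Families
    smaller than ``min_family_size`` are dropped; a family's consensus
    is the base carrying at least ``consensus_fraction`` of its reads,
    otherwise the family is discarded as ambiguous.  Returns per-locus
    consensus base counts (chrom, pos, A, C, G, T, n_families).
    """
    if not 0.5 < consensus_fraction <= 1.0:
        raise ValueError("consensus_fraction must be in (0.5, 1]")
    if reads.empty:
        return pd.DataFrame(columns=["chrom", "pos", *BASES, "n_families"])
    fam = (
        reads.groupby(["chrom", "pos", "family_tag", "base"], observed=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = fam.groupby(["chrom", "pos", "family_tag"], observed=True)["n"].transform("sum")
    fam["frac"] = fam["n"] / totals
    fam["family_size"] = totals
    winners = fam[
        (fam["family_size"] >= min_family_size)
        & (fam["frac"] >= consensus_fraction)
    ]
    # at most one base per family can reach a fraction > 0.5
    counts = (
        winners.groupby(["chrom", "pos", "base"], observed=True)
        .size()
        .unstack(fill_value=0)
        .reindex(columns=list(BASES), fill_value=0)
        .reset_index()
    )
    counts.columns.name = None
    counts["n_families"] = counts[list(BASES)].sum(axis=1)
    return counts


def nonref_fractions(sscs_counts: pd.DataFrame, loci: pd.DataFrame) -> pd.DataFrame:
    """Per-locus non-reference SSCS fraction for the given loci.

    ``loci`` needs columns (chrom, pos, ref).  Loci with zero SSCS
    depth get fraction 0 and depth 0.
    """
    idx = sscs_counts.set_index(["chrom", "pos"]) if not sscs_counts.empty else None
    rows = []
    for locus in loci.itertuples(index=False):
        chrom, pos, ref = locus.chrom, int(locus.pos), str(locus.ref).upper()
        depth, nonref = 0, 0
        if idx is not None and (chrom, pos) in idx.index:
            row = idx.loc[(chrom, pos)]
            depth = int(row["n_families"])
            nonref = depth - int(row[ref]) if ref in BASES else depth
        frac = nonref / depth if depth else 0.0
        rows.append((chrom, pos, ref, depth, nonref, frac))
    return pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "sscs_depth", "nonref_count", "nonref_fraction"]
    )


def background_null(background_fractions: np.ndarray, min_loci: int = 20) -> np.ndarray:
    """Empirical null of non-reference fractions from background loci."""
    bg = np.asarray(background_fractions, dtype=float)
    if len(bg) < min_loci:
        raise ValueError(f"need >= {min_loci} background loci for the null")
    return np.sort(bg)


def empirical_p(observed: float, null: np.ndarray) -> float:
    """Add-one empirical p: (1 + #background >= observed)/(1 + n_background)."""
    null = np.asarray(null, dtype=float)
    return (1.0 + (null >= observed).sum()) / (1.0 + len(null))


@dataclass
class LocusValidation:
    table: pd.DataFrame  # chrom,pos,ref,sscs_depth,nonref_fraction,p,q,validated
    fdr: float


def validate_loci(
    target_fractions: pd.DataFrame,
    null: np.ndarray,
    fdr: float = 0.05,
) -> LocusValidation:
    """BH-validate target loci against the background null.

    ``target_fractions`` is the output of :func:`nonref_fractions` on
    the target loci.  Each target's add-one empirical p-value is
    BH-adjusted across targets; a locus is validated iff q < ``fdr``.
    """
    tab = target_fractions.copy()
    if tab.empty:
        tab["p"] = tab["q"] = tab["validated"] = []
        return LocusValidation(table=tab, fdr=fdr)
    tab["p"] = [empirical_p(x, null) for x in tab["nonref_fraction"]]
    _, q, _, _ = multipletests(tab["p"].to_numpy(), method="fdr_bh")
    tab["q"] = q
    tab["validated"] = tab["q"] < fdr
    return LocusValidation(table=tab, fdr=fdr)
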