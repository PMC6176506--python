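"""Multi-caller somatic SNV consensus and confirmation.

Low-input amplified genomes are noisy: sequencing errors produce
caller-specific false positives and whole-genome amplification (WGA)
introduces polymerase errors private to one sample.  The consensus
procedure attacks both, in order:

1. germline subtraction — variants seen in the paired normal are
   removed;
2. intra-sample double calling — within each sample, only variants
   called by >= 2 of the 3 callers survive (suppresses sequencing
   errors);
3. confident sites — only loci double-called in >= 2 samples survive
   (suppresses sample-private WGA artifacts);
4. Fisher confirmation — at a confident site, a sample's variant is
   accepted when at least one caller detected it there and its allele
   count is significantly larger than the largest other non-reference
   base count (one-sided Fisher's exact test, p < 1e-4).

Confirmed variants are finally partitioned into subclone-shared and
subclone-exclusive sets given sample-to-subclone labels.

Depth tables consumed here must come from alignments filtered to
mapping quality >= 30 with supplementary alignments removed; the
contract is checked, not re-applied (see :func:`read_filter_contract`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact

BASES = ("A", "C", "G", "T")
KEY = ["chrom", "pos", "ref", "alt"]

REQUIRED_MIN_MAPQ = 30


def read_filter_contract(metadata: dict) -> None:
    """Validate that a depth table declares the upstream read filter.

    The pipeline consumes per-base depth tables computed from BAM files
    in which reads with mapping quality < 30 or a supplementary
    alignment were removed.  The table metadata must declare
    ``min_mapq`` (exactly 30 or stricter) and
    ``supplementary: "excluded"``; anything else is rejected.
    """
    if "min_mapq" not in metadata or "supplementary" not in metadata:
        raise ValueError(
            "depth table must declare its read filter: "
            "min_mapq=30 and supplementary=excluded"
        )
    if int(metadata["min_mapq"]) < REQUIRED_MIN_MAPQ:
        raise ValueError(
            f"depth table declares min_mapq={metadata['min_mapq']}; "
            f"the pipeline requires min_mapq>={REQUIRED_MIN_MAPQ}"
        )
    if str(metadata["supplementary"]).lower() != "excluded":
        raise ValueError("depth table must exclude supplementary alignments")


def normalize_calls(calls: pd.DataFrame) -> pd.DataFrame:
    """Uppercase alleles, split nothing (SNVs only), drop non-SNVs."""
    out = calls.copy()
    out["ref"] = out["ref"].str.upper()
    out["alt"] = out["alt"].str.upper()
    snv = (out["ref"].str.len() == 1) & (out["alt"].str.len() == 1)
    snv &= out["ref"].isin(BASES) & out["alt"].isin(BASES)
    return out[snv].reset_index(drop=True)


def subtract_germline(calls: pd.DataFrame, normal_calls: pd.DataFrame) -> pd.DataFrame:
    """Remove exact (chrom,pos,ref,alt) matches to the paired-normal set."""
    if normal_calls.empty:
        return calls.copy()
    normal_keys = set(map(tuple, normalize_calls(normal_calls)[KEY].to_numpy()))
    keys = list(map(tuple, calls[KEY].to_numpy()))
    keep = [k not in normal_keys for k in keys]
    return calls[keep].reset_index(drop=True)


def double_called_sites(calls: pd.DataFrame, min_callers: int = 2) -> pd.DataFrame:
    """Per sample, keep variants called by >= min_callers distinct callers."""
    if calls.empty:
        return calls.iloc[0:0][["sample", *KEY]].copy()
    grouped = (
        calls.groupby(["sample", *KEY], as_index=False)["caller"]
        .nunique()
        .rename(columns={"caller": "n_callers"})
    )
    return grouped[grouped["n_callers"] >= min_callers].reset_index(drop=True)


def confident_sites(double_called: pd.DataFrame, min_samples: int = 2) -> pd.DataFrame:
    """Loci double-called in >= min_samples samples (removes WGA artifacts)."""
    if double_called.empty:
        return double_called.iloc[0:0][KEY].copy()
    if double_called["sample"].nunique() < min_samples:
        warnings.warn(
            f"fewer than {min_samples} samples: no site can be confident",
            stacklevel=2,
        )
    counts = (
        double_called.groupby(KEY, as_index=False)["sample"]
        .nunique()
        .rename(columns={"sample": "n_samples"})
    )
    return counts[counts["n_samples"] >= min_samples].reset_index(drop=True)


def fisher_confirm(
    alt_depth: int,
    max_other_nonref_depth: int,
    total_depth: int,
    p_threshold: float = 1e-4,
) -> tuple[bool, float]:
    """One-sided exact test: alt allele enriched over other non-ref bases.

    The 2x2 table is [[alt, other], [total - alt, total - other]] where
    `other` is the depth of the largest other non-reference base (the
    most conservative comparator); the test asks whether the alt count
    is significantly larger.  Zero total depth rejects with p = 1.
    """
    if total_depth <= 0:
        return False, 1.0
    table = [
        [alt_depth, max_other_nonref_depth],
        [total_depth - alt_depth, total_depth - max_other_nonref_depth],
    ]
    p = float(fisher_exact(table, alternative="greater").pvalue)
    return p < p_threshold, p


@dataclass
class FinalCalls:
    """Confirmed somatic SNVs and their subclone partition."""

    calls: pd.DataFrame  # sample, chrom, pos, ref, alt, fisher_p, callers
    partition: pd.DataFrame  # chrom,pos,ref,alt, subclones, klass
    confident: pd.DataFrame  # the confident loci that were tested


def final_calls(
    calls: pd.DataFrame,
    normal_calls: pd.DataFrame,
    depths: dict[str, pd.DataFrame],
    sample_subclones: dict[str, str] | None = None,
    min_callers: int = 2,
    min_samples: int = 2,
    fisher_p: float = 1e-4,
) -> FinalCalls:
    """Full consensus pipeline on per-caller per-sample call sets.

    ``depths`` maps sample ids to per-base depth tables (chrom, pos,
    ref, A, C, G, T) whose metadata must satisfy the read-filter
    contract.  At every confident site, each sample in which at least
    one caller detected the variant is tested by Fisher confirmation
    against that sample's pile-up.  With subclone labels supplied, the
    surviving variants are partitioned into shared (seen in more than
    one subclone) and exclusive sets.
    """
    for sample_id, dtab in depths.items():
        read_filter_contract(dtab.attrs)
    calls = normalize_calls(calls)
    somatic = subtract_germline(calls, normal_calls)
    dc = double_called_sites(somatic, min_callers)
    conf = confident_sites(dc, min_samples)
    conf_keys = set(map(tuple, conf[KEY].to_numpy()))

    depth_idx = {
        s: dtab.set_index(["chrom", "pos"]) for s, dtab in depths.items()
    }
    rows = []
    detected = somatic.groupby(["sample", *KEY])["caller"].agg(
        lambda s: ",".join(sorted(set(s)))
    )
    for (sample_id, chrom, pos, ref, alt), callers in detected.items():
        if (chrom, pos, ref, alt) not in conf_keys:
            continue
        dtab = depth_idx.get(sample_id)
        if dtab is None or (chrom, pos) not in dtab.index:
            continue
        row = dtab.loc[(chrom, pos)]
        base_depths = {b: int(row[b]) for b in BASES}
        total = sum(base_depths.values())
        alt_d = base_depths.get(alt, 0)
        other = max(
            (d for b, d in base_depths.items() if b not in (ref, alt)), default=0
        )
        ok, p = fisher_confirm(alt_d, other, total, fisher_p)
        if ok:
            rows.append((sample_id, chrom, pos, ref, alt, p, callers))
    final = pd.DataFrame(
        rows, columns=["sample", *KEY, "fisher_p", "callers"]
    ).sort_values(["sample", "chrom", "pos"], ignore_index=True)

    partition = _partition(final, sample_subclones)
    return FinalCalls(calls=final, partition=partition, confident=conf)


def _partition(final: pd.DataFrame, sample_subclones: dict[str, str] | None
               ) -> pd.DataFrame:
    if final.empty:
        return pd.DataFrame(columns=[*KEY, "subclones", "klass"])
    if sample_subclones is None:
        sample_subclones = {}
    rows = []
    for key, grp in final.groupby(KEY):
        subclones = sorted(
            {sample_subclones.get(s, "unassigned") for s in grp["sample"]}
        )
        klass = "shared" if len(subclones) > 1 else f"exclusive:{subclones[0]}"
        rows.append((*key, ",".join(subclones), klass))
    return pd.DataFrame(rows, columns=[*KEY, "subclones", "klass"])
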