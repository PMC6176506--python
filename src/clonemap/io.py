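"""Readers and writers for the toolkit's file formats.

Conventions are strict: BED intervals are 0-based half-open with
start < end; VCF positions are 1-based (read and written through
pysam); masks travel as integer-matrix TSV or 16-bit PNG/TIFF; per-base
depth tables are TSV with `#key=value` header lines declaring the
upstream read filter; dendrograms with bootstrap support are written as
newick via scikit-bio.  Malformed lines fail hard with the offending
line number.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


# ---------------------------------------------------------------------------
# chromosome naming
# ---------------------------------------------------------------------------

def normalize_chrom(name: str, style: str = "chr") -> str:
    """Normalize a chromosome name to 'chr'-prefixed or plain style."""
    base = name[3:] if name.lower().startswith("chr") else name
    return f"chr{base}" if style == "chr" else base


def check_chrom_style(names) -> None:
    """Reject inputs mixing 'chr'-prefixed and plain chromosome names."""
    has_chr = {str(n).lower().startswith("chr") for n in names}
    if len(has_chr) > 1:
        raise ValueError(
            "mixed chromosome naming (chr-prefixed and plain); normalize first"
        )


# ---------------------------------------------------------------------------
# TSV / BED
# ---------------------------------------------------------------------------

def read_tsv_matrix(path: str | Path, index_col=0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_tsv_matrix(df: pd.DataFrame, path: str | Path, index: bool = True) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=index)
    return path


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3+ reader: 0-based half-open, start < end enforced per line."""
    rows = []
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: BED needs >= 3 columns")
            chrom, start, end = parts[0], parts[1], parts[2]
            try:
                start, end = int(start), int(end)
            except ValueError as exc:
                raise ValueError(f"{path}:{ln}: non-integer coordinates") from exc
            if start < 0 or end <= start:
                raise ValueError(
                    f"{path}:{ln}: invalid interval [{start}, {end}) "
                    "(need 0 <= start < end)"
                )
            rows.append((chrom, start, end, *parts[3:]))
    ncols = max((len(r) for r in rows), default=3)
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(4, ncols + 1)]
    df = pd.DataFrame(rows, columns=names[:ncols])
    check_chrom_style(df["chrom"])
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, header=False)
    return path


# ---------------------------------------------------------------------------
# masks
# ---------------------------------------------------------------------------

def read_mask(path: str | Path) -> np.ndarray:
    """Integer label mask from TSV or single-channel PNG/TIFF."""
    path = Path(path)
    if path.suffix.lower() in (".tsv", ".txt"):
        arr = np.loadtxt(path, dtype=np.int64, ndmin=2)
    else:
        import imageio.v3 as iio

        arr = np.asarray(iio.imread(path))
        if arr.ndim != 2:
            raise ValueError(f"{path}: mask must be single-channel")
    if (arr < 0).any():
        raise ValueError(f"{path}: mask labels must be >= 0")
    return arr.astype(np.int32)


def write_mask(mask: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    mask = np.asarray(mask)
    if path.suffix.lower() in (".tsv", ".txt"):
        np.savetxt(path, mask, fmt="%d", delimiter="\t")
    else:
        import imageio.v3 as iio

        if mask.max() > np.iinfo(np.uint16).max:
            raise ValueError("mask labels exceed 16-bit range")
        iio.imwrite(path, mask.astype(np.uint16))
    return path


# ---------------------------------------------------------------------------
# per-base depth tables
# ---------------------------------------------------------------------------

def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Depth TSV (chrom, pos, ref, A, C, G, T) with `#key=value` metadata.

    The metadata lands in ``df.attrs`` and is validated downstream
    against the read-filter contract.
    """
    meta = {}
    with open(path) as fh:
        ln = 0
        for line in fh:
            ln += 1
            if not line.startswith("#"):
                break
            if "=" in line:
                k, v = line[1:].strip().split("=", 1)
                meta[k.strip()] = v.strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"chrom", "pos", "ref", "A", "C", "G", "T"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: depth table missing columns {sorted(missing)}")
    df.attrs.update(meta)
    return df


def write_depth_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for k, v in df.attrs.items():
            fh.write(f"#{k}={v}\n")
        df.to_csv(fh, sep="\t", index=False)
    return path


# ---------------------------------------------------------------------------
# VCF (pysam)
# ---------------------------------------------------------------------------

def write_vcf(
    calls: pd.DataFrame,
    path: str | Path,
    chrom_lengths: dict[str, int],
    sample_name: str = "SAMPLE",
    info_columns: tuple[str, ...] = (),
) -> Path:
    """Write SNV records (chrom, pos, ref, alt, alt_depth, total_depth) as VCF 4.2.

    Allele depths go into the sample's AD/DP fields; extra
    ``info_columns`` become INFO entries (floats/ints/strings by
    dtype).
    """
    import pysam

    path = Path(path)
    header = pysam.VariantHeader()
    for chrom, length in chrom_lengths.items():
        header.contigs.add(chrom, length=length)
    header.formats.add("AD", "R", "Integer", "Allelic depths (ref, alt)")
    header.formats.add("DP", "1", "Integer", "Total read depth")
    for col in info_columns:
        kind = "Float" if pd.api.types.is_float_dtype(calls[col]) else (
            "Integer" if pd.api.types.is_integer_dtype(calls[col]) else "String"
        )
        header.info.add(col.upper(), "1", kind, col)
    header.add_sample(sample_name)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        ordered = calls.sort_values(["chrom", "pos"], kind="stable")
        for row in ordered.itertuples(index=False):
            rec = vcf.new_record(
                contig=str(row.chrom),
                start=int(row.pos) - 1,
                stop=int(row.pos),
                alleles=(str(row.ref), str(row.alt)),
            )
            total = int(getattr(row, "total_depth", 0))
            alt_d = int(getattr(row, "alt_depth", 0))
            rec.samples[sample_name]["AD"] = (total - alt_d, alt_d)
            rec.samples[sample_name]["DP"] = total
            for col in info_columns:
                val = getattr(row, col)
                rec.info[col.upper()] = (
                    float(val) if isinstance(val, (float, np.floating)) else val
                )
            vcf.write(rec)
    return path


def read_vcf(path: str | Path) -> pd.DataFrame:
    """Read SNV records back into (chrom, pos, ref, alt, alt_depth, total_depth).

    Multi-allelic records are split into one row per alt allele;
    non-SNV alleles are dropped after normalization.
    """
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        sample = next(iter(vcf.header.samples), None)
        for rec in vcf:
            for ai, alt in enumerate(rec.alts or ()):
                ref, alt = rec.ref.upper(), str(alt).upper()
                if len(ref) != 1 or len(alt) != 1:
                    continue
                alt_d, total = 0, 0
                if sample is not None:
                    fmt = rec.samples[sample]
                    ad = fmt.get("AD")
                    if ad is not None and len(ad) > ai + 1 and ad[ai + 1] is not None:
                        alt_d = int(ad[ai + 1])
                    dp = fmt.get("DP")
                    total = int(dp) if dp is not None else int(sum(x or 0 for x in ad or ()))
                rows.append((rec.contig, rec.pos, ref, alt, alt_d, total))
    df = pd.DataFrame(
        rows, columns=["chrom", "pos", "ref", "alt", "alt_depth", "total_depth"]
    )
    if not df.empty:
        check_chrom_style(df["chrom"])
    return df


# ---------------------------------------------------------------------------
# newick
# ---------------------------------------------------------------------------

def write_newick(
    linkage_matrix: np.ndarray,
    labels: list[str],
    path: str | Path,
    support: dict[frozenset[int], float] | None = None,
) -> Path:
    """Dendrogram (scipy linkage) -> newick, internal nodes named by support.

    ``support`` maps leaf-index sets to a support value (e.g. AU
    p-values); matching internal nodes are annotated
    ``AU=<value>``.
    """
    from io import StringIO

    from scipy.cluster.hierarchy import to_tree
    from skbio import TreeNode

    root = to_tree(linkage_matrix)

    def build(node):
        if node.is_leaf():
            return TreeNode(name=labels[node.id], length=node.dist), frozenset([node.id])
        left, lset = build(node.left)
        right, rset = build(node.right)
        leaf_set = lset | rset
        name = None
        if support is not None and leaf_set in support:
            name = f"AU={support[leaf_set]:.3f}"
        parent = TreeNode(name=name, children=[left, right], length=node.dist)
        return parent, leaf_set

    tree, _ = build(root)
    buf = StringIO()
    tree.write(buf, format="newick")
    Path(path).write_text(buf.getvalue())
    return Path(path)


def read_newick(path: str | Path):
    from skbio import TreeNode

    return TreeNode.read(str(path), format="newick")
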