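"""Amplification and sequencing quality control.

Whole-genome amplification by MDA is monitored in real time; the
amplification start time (AST, minutes until the fluorescence signal
rises observably above baseline) gates sample quality — good isolations
start amplifying within 40 min, failed isolations and negative controls
later or never.  Sequencing-level quality is summarized by the area
under the Lorenz curve of per-bin read counts (0.5 = perfectly uniform
coverage; higher AUC means broader genome coverage), the Pearson
correlation of a sample's copy-number profile with the bulk tumor
profile, and the fraction of reads aligned to the genome (< 0.2 flags a
failed isolation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import median_filter
from scipy.stats import pearsonr

NOT_REACHED = "not reached"


@dataclass
class QCReport:
    sample_id: str
    ast: float | None = None  # minutes; None = not reached / not measured
    lorenz_auc: float | None = None
    cna_correlation: float | None = None
    alignment_ratio: float | None = None
    pcr_panel_ok: bool | None = None  # external wet-lab 16-primer validation
    passed: bool | None = None
    fail_reasons: list[str] = field(default_factory=list)


def amplification_start_time(
    times: np.ndarray,
    fluorescence: np.ndarray,
    baseline_points: int = 5,
    sd_factor: float = 10.0,
    persistence: int = 2,
    smooth_window: int = 3,
) -> float | str:
    """Earliest time the smoothed signal rises observably above baseline.

    The signal is median-smoothed, a threshold of baseline mean +
    ``sd_factor`` x baseline SD is computed from the first
    ``baseline_points`` smoothed values, and the AST is the first
    threshold crossing that persists for at least ``persistence``
    consecutive samples, refined by linear interpolation between the
    bracketing samples.  Returns ``"not reached"`` for curves that
    never cross (negative controls, failed isolations).
    """
    times = np.asarray(times, dtype=float)
    fluorescence = np.asarray(fluorescence, dtype=float)
    if times.ndim != 1 or times.shape != fluorescence.shape:
        raise ValueError("times and fluorescence must be equal-length 1-D arrays")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if len(times) < baseline_points:
        raise ValueError(f"need at least {baseline_points} baseline points")

    k = min(smooth_window, len(fluorescence))
    if k % 2 == 0:
        k -= 1
    signal = (
        median_filter(fluorescence, size=k, mode="nearest")
        if k >= 3 else fluorescence.copy()
    )
    # baseline statistics on the raw signal: smoothing shrinks the noise
    # and would make the 10-SD threshold overly eager on flat curves
    baseline = fluorescence[:baseline_points]
    threshold = baseline.mean() + sd_factor * baseline.std()

    above = signal > threshold
    n = len(signal)
    for i in range(n):
        if not above[i]:
            continue
        run = above[i : i + persistence]
        persists = run.all() and (len(run) == persistence or i == n - 1)
        if not persists:
            continue
        if i == 0:
            return float(times[0])
        # linear interpolation between the last sub-threshold sample and i
        t0, t1 = times[i - 1], times[i]
        y0, y1 = signal[i - 1], signal[i]
        if y1 == y0:
            return float(t1)
        return float(t0 + (threshold - y0) / (y1 - y0) * (t1 - t0))
    return NOT_REACHED


def lorenz_auc(bin_counts: np.ndarray) -> float:
    """Area under the Lorenz curve of per-bin read counts.

    Bins are sorted by ascending count; x is the cumulative bin
    fraction and y the cumulative read fraction; the area is the
    trapezoid rule.  Perfectly uniform coverage gives exactly 0.5 and
    all reads in one of B bins gives 1/(2B); higher values mean more
    uniform coverage.
    """
    counts = np.asarray(bin_counts, dtype=float)
    if counts.ndim != 1 or len(counts) < 2:
        raise ValueError("need >= 2 bins")
    if (counts < 0).any():
        raise ValueError("counts must be >= 0")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero counts: Lorenz curve undefined")
    y = np.concatenate([[0.0], np.cumsum(np.sort(counts)) / total])
    x = np.linspace(0.0, 1.0, len(counts) + 1)
    return float(np.trapezoid(y, x))


def cna_correlation(
    sample_profile: np.ndarray,
    bulk_profile: np.ndarray,
    mask: np.ndarray | None = None,
) -> float:
    """Pearson correlation between a sample's and the bulk's bin profiles.

    ``mask`` marks unreliable bins (True = drop) in either profile;
    both profiles must live on the same bin set.
    """
    a = np.asarray(sample_profile, dtype=float)
    b = np.asarray(bulk_profile, dtype=float)
    if a.shape != b.shape:
        raise ValueError("profiles must share the same bin set")
    keep = np.isfinite(a) & np.isfinite(b)
    if mask is not None:
        keep &= ~np.asarray(mask, dtype=bool)
    if keep.sum() < 3:
        raise ValueError("too few reliable bins for a correlation")
    return float(pearsonr(a[keep], b[keep]).statistic)


def alignment_ratio(aligned_reads: int, total_reads: int, low_threshold: float = 0.2
                    ) -> tuple[float, bool]:
    """Fraction of reads aligned to the genome, with the < 0.2 low flag."""
    if total_reads <= 0:
        raise ValueError("total_reads must be > 0")
    if aligned_reads < 0 or aligned_reads > total_reads:
        raise ValueError("aligned_reads must lie in [0, total_reads]")
    ratio = aligned_reads / total_reads
    return ratio, ratio < low_threshold


def qc_gate(
    report: QCReport,
    ast_threshold: float = 40.0,
    alignment_threshold: float = 0.2,
    auc_threshold: float | None = None,
    correlation_threshold: float | None = None,
) -> QCReport:
    """Pass/fail gate with the reason for every violated threshold.

    Defaults: AST <= 40 min and alignment ratio >= 0.2 are enforced;
    Lorenz-AUC and bulk-correlation floors are off unless configured
    (the workflow sets a project-specific cutoff there).
    """
    reasons = []
    if report.ast is None:
        reasons.append(f"AST {NOT_REACHED}")
    elif report.ast > ast_threshold:
        reasons.append(f"AST {report.ast:.1f} min > {ast_threshold:g} min")
    if report.alignment_ratio is not None and report.alignment_ratio < alignment_threshold:
        reasons.append(
            f"alignment ratio {report.alignment_ratio:.3f} < {alignment_threshold:g}"
        )
    if auc_threshold is not None and (
        report.lorenz_auc is None or report.lorenz_auc < auc_threshold
    ):
        reasons.append(f"Lorenz AUC below {auc_threshold:g}")
    if correlation_threshold is not None and (
        report.cna_correlation is None or report.cna_correlation < correlation_threshold
    ):
        reasons.append(f"bulk CNA correlation below {correlation_threshold:g}")
    if report.pcr_panel_ok is False:
        reasons.append("PCR validation panel failed")
    report.fail_reasons = reasons
    report.passed = not reasons
    return report
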