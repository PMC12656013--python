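"""Site-level variant QC.

Retention rules for a pre-called VCF: GATK-style site annotations
(QualByDepth > 1, mapping quality > 40, Fisher strand < 80), minor allele
frequency, per-site missing rate, heterozygous-call rate, and exclusive
mean-depth bounds.  The MAF rule retains sites with MAF >= min_maf (the
standard reading of a high-quality-site filter); the missing-rate rule is
the literal "retain missing < 0.8".  Both are configurable.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import VariantTable

log = logging.getLogger(__name__)

# order in which the first failing criterion is attributed in the report
CRITERIA = ("qd", "mq", "fs", "maf", "missing", "het", "depth")


@dataclass
class QCThresholds:
    min_qd: float = 1.0
    min_mq: float = 40.0
    max_fs: float = 80.0
    min_maf: float = 0.05
    max_missing: float = 0.8
    max_het: float = 0.05
    depth_range: tuple[float, float] = (2.0, 15.0)  # exclusive bounds

    def __post_init__(self):
        lo, hi = self.depth_range
        if not lo < hi:
            raise ValueError("depth_range lower bound must be below upper bound")


@dataclass
class SiteQCStats:
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    missing_rate: float
    het_rate: float
    mean_depth: float  # NaN when DP absent
    qd: float
    mq: float
    fs: float


def compute_site_stats(variants: VariantTable) -> pd.DataFrame:
    """Per-site QC statistics from a loaded variant table.

    MAF uses called alleles only; het_rate is over called samples;
    mean_depth is NaN when no genotype carries DP (treated as passing by
    :func:`filter_sites`).
    """
    gt = variants.gt
    called = (gt >= 0).all(axis=2)
    n_called = called.sum(axis=1)
    alt_count = np.where(gt > 0, 1, 0).sum(axis=2)
    alt_count = np.where(called, alt_count, 0).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = alt_count / (2.0 * n_called)
        maf = np.minimum(freq, 1.0 - freq)
        het_rate = np.where(
            n_called > 0,
            (variants.het_mask() & called).sum(axis=1) / np.maximum(n_called, 1),
            np.nan,
        )
    missing_rate = 1.0 - n_called / max(variants.n_samples, 1)
    if variants.dp is not None:
        dp = np.where(called, variants.dp, np.nan)
        with np.errstate(invalid="ignore"):
            any_dp = np.isfinite(dp).any(axis=1)
            mean_depth = np.where(any_dp, np.nanmean(np.where(np.isfinite(dp), dp, np.nan), axis=1), np.nan)
    else:
        mean_depth = np.full(variants.n_sites, np.nan)
    out = variants.sites[["chrom", "pos", "ref", "alt", "qd", "mq", "fs"]].copy()
    out["maf"] = np.where(n_called > 0, maf, np.nan)
    out["missing_rate"] = missing_rate
    out["het_rate"] = het_rate
    out["mean_depth"] = mean_depth
    return out


def site_stats_records(stats: pd.DataFrame) -> list[SiteQCStats]:
    """The same statistics as typed records (convenience for callers that
    prefer objects over the frame)."""
    return [
        SiteQCStats(
            chrom=r.chrom, pos=int(r.pos), ref=r.ref, alt=r.alt,
            maf=r.maf, missing_rate=r.missing_rate, het_rate=r.het_rate,
            mean_depth=r.mean_depth, qd=r.qd, mq=r.mq, fs=r.fs,
        )
        for r in stats.itertuples(index=False)
    ]


def filter_sites(
    stats: pd.DataFrame, thresholds: QCThresholds | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the retention predicate; returns (retained stats, full report).

    A site is retained iff every criterion passes; absent INFO fields (NaN)
    pass their criterion.  The report carries one row per input site with a
    pass flag and the first failing criterion in the fixed order
    qd, mq, fs, maf, missing, het, depth.  The operation is a pure per-site
    predicate, hence idempotent and order-independent.
    """
    thresholds = thresholds or QCThresholds()
    t = thresholds
    s = stats
    lo, hi = t.depth_range

    def passes(values, ok):
        v = values.to_numpy(dtype=float)
        return np.where(np.isfinite(v), ok(v), True)

    checks = {
        "qd": passes(s["qd"], lambda v: v > t.min_qd),
        "mq": passes(s["mq"], lambda v: v > t.min_mq),
        "fs": passes(s["fs"], lambda v: v < t.max_fs),
        "maf": passes(s["maf"], lambda v: v >= t.min_maf),
        "missing": passes(s["missing_rate"], lambda v: v < t.max_missing),
        "het": passes(s["het_rate"], lambda v: v < t.max_het),
        "depth": passes(s["mean_depth"], lambda v: (v > lo) & (v < hi)),
    }
    n_absent = int((~np.isfinite(s[["qd", "mq", "fs"]].to_numpy(float))).sum())
    if n_absent:
        log.info("%d absent INFO values passed their criterion", n_absent)

    report = s.copy()
    retained = np.ones(len(s), dtype=bool)
    first_fail = np.asarray([""] * len(s), dtype=object)
    for crit in CRITERIA:
        ok = checks[crit]
        newly = retained & ~ok & (first_fail == "")
        first_fail[newly] = crit
        retained &= ok
    report["retained"] = retained
    report["failing_criterion"] = first_fail
    return s[retained].reset_index(drop=True), report


def qc_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Counts removed per (first-failing) criterion plus the retained total."""
    rows = [
        {"criterion": c, "removed": int((report["failing_criterion"] == c).sum())}
        for c in CRITERIA
    ]
    rows.append({"criterion": "retained", "removed": int(report["retained"].sum())})
    return pd.DataFrame(rows)


def apply_qc(
    variants: VariantTable, thresholds: QCThresholds | None = None
) -> tuple[VariantTable, pd.DataFrame]:
    """Filter a variant table in memory; returns (filtered table, report)."""
    stats = compute_site_stats(variants)
    _, report = filter_sites(stats, thresholds)
    keep = report["retained"].to_numpy()
    filtered = VariantTable(
        samples=variants.samples,
        sites=variants.sites[keep].reset_index(drop=True),
        gt=variants.gt[keep],
        dp=variants.dp[keep] if variants.dp is not None else None,
    )
    return filtered, report
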