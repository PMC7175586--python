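"""Expression filtering, CPM transforms and sample outlier detection.

The standard order mirrors a bulk RNA-seq QC narrative: drop excluded gene
ids (mitochondrial / non-canonical contigs supplied by the caller), remove
genes hoarding an outsized read share, remove lowly expressed genes, then
flag outlier samples by their median inter-sample correlation of log2-CPM
values using Tukey's fences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix

logger = logging.getLogger(__name__)


@dataclass
class FilterReport:
    """Which genes a filtering step removed and the matrix sizes around it."""

    removed: list[str]
    n_before: int
    n_after: int
    step: str = ""

    def __post_init__(self) -> None:
        assert self.n_after == self.n_before - len(self.removed)


@dataclass
class OutlierReport:
    """Tukey's-fences decision record over median inter-sample correlations."""

    median_correlation: dict[str, float]
    q1: float
    q3: float
    iqr: float
    lower_fence: float
    upper_fence: float
    flagged: list[str] = field(default_factory=list)


def cpm_transform(
    m: ExpressionMatrix, log2: bool = False, pseudocount: float = 1.0
) -> ExpressionMatrix:
    """Counts-per-million normalization, optionally log2 with a pseudocount.

    ``cpm[g, s] = 1e6 * count[g, s] / sum_g count[g, s]``; with ``log2`` the
    values become ``log2(cpm + pseudocount)`` and the unit tag ``log2cpm``.
    The pseudocount is applied on the CPM scale.
    """
    if m.unit != "counts":
        raise ValueError(f"cpm_transform expects counts, got unit={m.unit!r}")
    colsums = m.values.sum(axis=0)
    zero = np.flatnonzero(colsums == 0)
    if zero.size:
        raise ValueError(f"zero total counts for sample(s): {[m.sample_ids[i] for i in zero]}")
    cpm = 1e6 * m.values / colsums
    if log2:
        return ExpressionMatrix(
            np.log2(cpm + pseudocount), m.gene_ids, m.sample_ids, unit="log2cpm"
        )
    return ExpressionMatrix(cpm, m.gene_ids, m.sample_ids, unit="cpm")


def exclude_genes(
    m: ExpressionMatrix, exclusion_list: list[str]
) -> tuple[ExpressionMatrix, FilterReport]:
    """Remove a caller-supplied id list (e.g. mitochondrial genes).

    Ids absent from the matrix are ignored with a warning.
    """
    present = set(m.gene_ids)
    unknown = [g for g in exclusion_list if g not in present]
    if unknown:
        logger.warning("exclusion list contains %d unknown ids (ignored)", len(unknown))
    to_drop = set(exclusion_list) & present
    keep = [g for g in m.gene_ids if g not in to_drop]
    out = m.subset_genes(keep)
    report = FilterReport(
        removed=sorted(to_drop), n_before=m.n_genes, n_after=out.n_genes, step="exclude_genes"
    )
    return out, report


def filter_high_share(
    m: ExpressionMatrix, share_threshold: float = 0.01, sample_fraction: float = 0.5
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes that gather more than ``share_threshold`` of a sample's
    reads in more than ``sample_fraction`` of the samples.

    Such genes are almost always technical artifacts (e.g. a single rRNA
    fragment soaking up reads) and distort library-size normalization.  The
    decision uses per-sample read shares, so it is invariant to scaling any
    library.
    """
    if m.unit != "counts":
        raise ValueError("filter_high_share operates on counts")
    colsums = m.values.sum(axis=0)
    if (colsums == 0).any():
        raise ValueError("zero total counts in at least one sample")
    share = m.values / colsums
    n_over = (share > share_threshold).sum(axis=1)
    removed_mask = n_over > sample_fraction * m.n_samples
    keep = [g for g, r in zip(m.gene_ids, removed_mask) if not r]
    removed = [g for g, r in zip(m.gene_ids, removed_mask) if r]
    out = m.subset_genes(keep)
    return out, FilterReport(removed, m.n_genes, out.n_genes, step="filter_high_share")


def filter_low_expressed(
    m: ExpressionMatrix, sample_fraction: float = 0.2
) -> tuple[ExpressionMatrix, FilterReport]:
    """Drop genes expressed below the per-sample median in at least
    ``sample_fraction`` of the samples.

    The reference median is computed per sample across the genes of the
    matrix as given (i.e. after the high-share filter).  "At least 20%" is a
    real-valued threshold: a gene is removed when its sub-median sample
    count is >= ``sample_fraction * n_samples``.
    """
    med = np.median(m.values, axis=0)
    n_below = (m.values < med).sum(axis=1)
    removed_mask = n_below >= sample_fraction * m.n_samples
    keep = [g for g, r in zip(m.gene_ids, removed_mask) if not r]
    removed = [g for g, r in zip(m.gene_ids, removed_mask) if r]
    out = m.subset_genes(keep)
    return out, FilterReport(removed, m.n_genes, out.n_genes, step="filter_low_expressed")


def detect_outliers(m: ExpressionMatrix, method: str = "pearson") -> OutlierReport:
    """Flag outlier samples by Tukey's fences on median inter-sample
    correlation of log2-CPM expression.

    For each sample the median of its correlations with all other samples is
    taken; samples whose median falls outside
    ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]`` are flagged.  Quartiles use linear
    interpolation (NumPy's default), which matters when fence membership
    sits on a boundary.
    """
    if m.unit != "log2cpm":
        raise ValueError(f"detect_outliers expects log2cpm, got unit={m.unit!r}")
    if m.n_samples < 4:
        raise ValueError("outlier fences need at least 4 samples")
    if method == "pearson":
        corr = np.corrcoef(m.values.T)
    elif method == "spearman":
        from scipy.stats import rankdata

        ranks = rankdata(m.values, axis=0)
        corr = np.corrcoef(ranks.T)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    np.fill_diagonal(corr, np.nan)
    med = np.nanmedian(corr, axis=1)
    q1, q3 = np.percentile(med, [25, 75])
    iqr = q3 - q1
    lower, upper = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    flagged = [s for s, v in zip(m.sample_ids, med) if v < lower or v > upper]
    return OutlierReport(
        median_correlation=dict(zip(m.sample_ids, med.tolist())),
        q1=float(q1),
        q3=float(q3),
        iqr=float(iqr),
        lower_fence=float(lower),
        upper_fence=float(upper),
        flagged=flagged,
    )


def run_preprocess(
    counts: ExpressionMatrix,
    exclusion_list: list[str] | None = None,
    share_threshold: float = 0.01,
    share_sample_fraction: float = 0.5,
    low_sample_fraction: float = 0.2,
    outlier_method: str = "pearson",
    pseudocount: float = 1.0,
) -> tuple[ExpressionMatrix, dict]:
    """Full preprocessing pass: exclusions, both gene filters, outlier
    removal; returns the filtered count matrix (outlier samples dropped) and
    a dict of reports."""
    reports: dict = {}
    m = counts
    if exclusion_list:
        m, reports["exclude"] = exclude_genes(m, exclusion_list)
    m, reports["high_share"] = filter_high_share(m, share_threshold, share_sample_fraction)
    m, reports["low_expressed"] = filter_low_expressed(m, low_sample_fraction)
    log2cpm = cpm_transform(m, log2=True, pseudocount=pseudocount)
    outliers = detect_outliers(log2cpm, method=outlier_method)
    reports["outliers"] = outliers
    if outliers.flagged:
        keep = [s for s in m.sample_ids if s not in set(outliers.flagged)]
        m = m.subset_samples(keep)
    return m, reports
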