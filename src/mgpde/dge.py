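"""Negative-binomial Wald differential expression with covariates, with or
without cell-composition (MGP) adjustment.

The model per gene is ``log mu = log(size factor) + X beta`` with NB2 noise;
the Wald test targets the case/control coefficient.  Library size is
normalized by median-of-ratios size factors; multiple testing uses
Benjamini-Hochberg with an optional mean-expression independent filter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from ._design import design_matrix
from ._nbglm import fit_nb_glm
from .io import ExpressionMatrix

logger = logging.getLogger(__name__)

LOG2 = np.log(2.0)


@dataclass
class DEResult:
    """Per-gene DE table plus the model it came from.

    ``table`` columns: base_mean, lfc (log2, positive = higher in cases),
    wald_stat, p, fdr (NaN when removed by independent filtering).
    """

    table: pd.DataFrame
    model_tag: str
    size_factors: pd.Series
    design_columns: list[str]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.table.index)

    def significant(self, alpha: float = 0.05) -> list[str]:
        t = self.table
        return t.index[(t["fdr"] < alpha).fillna(False)].tolist()


def size_factors(m: ExpressionMatrix) -> pd.Series:
    """Median-of-ratios library-size factors.

    For genes with nonzero counts in every sample, each sample's factor is
    the median ratio of its counts to the gene-wise geometric mean; factors
    are then normalized to geometric mean 1.
    """
    if m.unit != "counts":
        raise ValueError("size factors are defined on counts")
    allpos = (m.values > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has nonzero counts in all samples; pre-filter low-expressed genes first"
        )
    logv = np.log(m.values[allpos])
    geo = np.exp(logv.mean(axis=1, keepdims=True))
    fac = np.median(m.values[allpos] / geo, axis=0)
    fac = fac / stats.gmean(fac)  # geometric mean 1
    return pd.Series(fac, index=m.sample_ids, name="size_factor")


def _independent_filter(
    base_mean: np.ndarray, p: np.ndarray, alpha: float
) -> tuple[np.ndarray, float]:
    """Pick the mean-expression quantile threshold that maximizes BH
    rejections at ``alpha``; ties go to the lowest threshold.  Returns the
    boolean mask of genes kept for FDR and the chosen threshold."""
    quantiles = np.arange(0.0, 0.96, 0.05)
    best_mask, best_rej, best_theta = None, -1, 0.0
    finite = np.isfinite(p)
    for theta in quantiles:
        cut = np.quantile(base_mean[finite], theta) if theta > 0 else -np.inf
        mask = finite & (base_mean >= cut)
        if mask.sum() == 0:
            continue
        rej = int(multipletests(p[mask], alpha=alpha, method="fdr_bh")[0].sum())
        if rej > best_rej:
            best_mask, best_rej, best_theta = mask, rej, theta
    return best_mask, best_theta


def fit_nb_de(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    mgp_scores: pd.DataFrame | None = None,
    mgp_covariates: list[str] | None = None,
    alpha: float = 0.05,
    independent_filtering: bool = True,
) -> DEResult:
    """NB Wald differential expression, case vs control.

    ``covariates`` name sample-table columns; ``mgp_covariates`` name cell
    types whose MGP scores join the design (the composition adjustment).
    Continuous covariates are centered and scaled.  The Wald statistic is
    referred to a t distribution with ``n - p`` degrees of freedom, a
    small-sample correction that matters at cohort sizes around 26.

    Genes with zero counts everywhere are reported with NaN statistics.
    """
    if m.unit != "counts":
        raise ValueError("differential expression operates on counts")
    for g in ("case", "control"):
        if (samples.loc[m.sample_ids, "group"].astype(str) == g).sum() < 2:
            raise ValueError(f"need at least 2 {g} samples")
    sam = samples.loc[m.sample_ids]
    X = design_matrix(
        sam, covariates, mgp_scores=mgp_scores, mgp_cells=mgp_covariates, include_group=True
    )
    gi = list(X.columns).index("group")
    sf = size_factors(m)
    offset = np.log(sf.to_numpy())
    norm_counts = m.values / sf.to_numpy()
    base_mean = norm_counts.mean(axis=1)

    testable = m.values.sum(axis=1) > 0
    n, p_dim = X.shape
    lfc = np.full(m.n_genes, np.nan)
    wald = np.full(m.n_genes, np.nan)
    pvals = np.full(m.n_genes, np.nan)
    if testable.any():
        fit = fit_nb_glm(m.values[testable], X.to_numpy(float), offset)
        beta_g = fit.beta[:, gi]
        se_g = fit.se[:, gi]
        stat = np.where(se_g > 0, beta_g / np.maximum(se_g, 1e-300), np.nan)
        lfc[testable] = beta_g / LOG2
        wald[testable] = stat
        pvals[testable] = 2.0 * stats.t.sf(np.abs(stat), df=max(n - p_dim, 1))
        n_bad = int((~fit.converged).sum())
        if n_bad:
            logger.warning("%d genes did not converge; p set to missing", n_bad)
            bad_idx = np.flatnonzero(testable)[~fit.converged]
            pvals[bad_idx] = np.nan
            wald[bad_idx] = np.nan

    fdr = np.full(m.n_genes, np.nan)
    if independent_filtering:
        mask, theta = _independent_filter(base_mean, pvals, alpha)
        logger.info("independent filtering kept %d genes (quantile %.2f)", mask.sum(), theta)
    else:
        mask = np.isfinite(pvals)
    if mask is not None and mask.any():
        fdr[mask] = multipletests(pvals[mask], method="fdr_bh")[1]

    table = pd.DataFrame(
        {"base_mean": base_mean, "lfc": lfc, "wald_stat": wald, "p": pvals, "fdr": fdr},
        index=m.gene_ids,
    )
    tag = "covariates_plus_mgp" if mgp_covariates else "covariates_only"
    return DEResult(table=table, model_tag=tag, size_factors=sf, design_columns=list(X.columns))


def compare_models(de0: DEResult, de_ct: DEResult, alpha: float = 0.05) -> dict:
    """Count FDR-significant genes with and without composition adjustment
    and their overlap."""
    if de0.gene_ids != de_ct.gene_ids:
        raise ValueError("DE results cover different gene universes")
    sig0 = set(de0.significant(alpha))
    sig_ct = set(de_ct.significant(alpha))
    both = sig0 & sig_ct
    return {
        "n_sig_0": len(sig0),
        "n_sig_ct": len(sig_ct),
        "n_both": len(both),
        "genes_0": sorted(sig0),
        "genes_ct": sorted(sig_ct),
        "genes_both": sorted(both),
    }
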