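"""Marker gene profiles: PCA-based surrogates for relative cell-type
abundance in bulk tissue.

A cell type's marker genes co-vary across bulk samples mainly because the
cell type's share of the tissue varies.  The first principal component of
the z-scored marker expression therefore tracks relative abundance.  To
keep single outlier samples or misbehaving markers from steering that
component, the PCA is repeated on balanced group subsamples, markers whose
loading opposes the majority trend are dropped per repetition, every sample
is projected onto each repetition's component, and the per-sample median
over repetitions is the final marker gene profile (MGP).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._design import design_matrix
from .io import ExpressionMatrix, GeneSetCollection

logger = logging.getLogger(__name__)


@dataclass
class MGPResult:
    """Per-sample MGP scores with the markers that survived screening.

    ``scores`` is samples x cell types, each column standardized (zero mean,
    unit variance) and sign-oriented so that higher scores mean higher
    inferred abundance (positive correlation with mean marker z-expression).
    """

    scores: pd.DataFrame
    retained_markers: dict[str, list[str]]
    var_explained: dict[str, float]
    n_subsamples: int
    seed: int | None = None

    @property
    def cell_types(self) -> list[str]:
        return list(self.scores.columns)


def _zscore_rows(values: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Z-score each gene (row) across samples; returns (z, mean, sd)."""
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=1, keepdims=True)
    return (values - mean) / sd, mean, sd


def _pc1(z_samples_by_markers: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """First principal component of a samples x markers z-matrix.

    Returns (scores, loadings, variance fraction).  Columns are re-centered
    before the SVD so projection of out-of-fit samples stays consistent.
    """
    X = z_samples_by_markers - z_samples_by_markers.mean(axis=0, keepdims=True)
    _, s, vt = np.linalg.svd(X, full_matrices=False)
    loadings = vt[0]
    scores = X @ loadings
    var_frac = float(s[0] ** 2 / np.sum(s**2)) if np.sum(s**2) > 0 else 0.0
    return scores, loadings, var_frac


def _orient(loadings: np.ndarray, tie_sign: float = 1.0) -> float:
    """Sign flip putting the majority of loadings positive; ties broken
    toward ``tie_sign``."""
    pos = int((loadings > 0).sum())
    neg = int((loadings < 0).sum())
    if pos > neg:
        return 1.0
    if neg > pos:
        return -1.0
    return tie_sign if tie_sign != 0 else 1.0


def estimate_mgp_once(
    m: ExpressionMatrix, markers: set[str] | list[str]
) -> tuple[pd.Series, pd.Series]:
    """Single-shot MGP: PC1 of the z-scored marker expression.

    Returns per-sample scores and per-marker loadings, oriented so the
    majority of loadings are positive.  Zero-variance markers are dropped
    with a warning; fewer than two usable markers is an error.
    """
    if m.unit != "log2cpm":
        raise ValueError(f"MGP estimation expects log2cpm, got unit={m.unit!r}")
    if m.n_samples < 3:
        raise ValueError("MGP estimation needs at least 3 samples")
    present = [g for g in m.gene_ids if g in set(markers)]
    sub = m.subset_genes(present)
    sd = sub.values.std(axis=1, ddof=1)
    usable = [g for g, s in zip(sub.gene_ids, sd) if s > 0]
    if len(usable) < len(sub.gene_ids):
        warnings.warn(
            f"dropped {len(sub.gene_ids) - len(usable)} zero-variance markers", stacklevel=2
        )
    if len(usable) < 2:
        raise ValueError(f"need >= 2 usable markers in the matrix, have {len(usable)}")
    sub = sub.subset_genes(usable)
    z, _, _ = _zscore_rows(sub.values)
    scores, loadings, _ = _pc1(z.T)
    sign = _orient(loadings)
    return (
        pd.Series(sign * scores, index=m.sample_ids, name="mgp"),
        pd.Series(sign * loadings, index=usable, name="loading"),
    )


def estimate_mgp(
    m: ExpressionMatrix,
    marker_collection: GeneSetCollection,
    samples: pd.DataFrame,
    n_subsamples: int = 100,
    seed: int | None = 0,
) -> MGPResult:
    """Robust MGP estimation via repeated balanced subsampling.

    Per cell type and repetition: draw ``min(n_case, n_control)`` samples
    without replacement from each group, fit PC1 on the subsample's z-scored
    markers, drop markers whose loading sign opposes the majority trend,
    refit on the survivors, project **all** samples onto that component and
    standardize the projected scores.  Each sample's MGP is its median score
    across repetitions.  Markers retained in more than half the repetitions
    make the final ``retained_markers`` list.

    One RNG stream per cell type is derived from ``seed`` and the cell
    type's position in the sorted name list, so results do not depend on
    iteration order.
    """
    if m.unit != "log2cpm":
        raise ValueError(f"MGP estimation expects log2cpm, got unit={m.unit!r}")
    groups = samples.loc[m.sample_ids, "group"].astype(str)
    case_ids = [s for s in m.sample_ids if groups[s] == "case"]
    ctrl_ids = [s for s in m.sample_ids if groups[s] == "control"]
    if len(case_ids) < 2 or len(ctrl_ids) < 2:
        raise ValueError("each group needs at least 2 samples for balanced subsampling")
    k = min(len(case_ids), len(ctrl_ids))
    sample_pos = {s: i for i, s in enumerate(m.sample_ids)}

    cell_types = sorted(marker_collection.set_ids)
    score_cols: dict[str, np.ndarray] = {}
    retained: dict[str, list[str]] = {}
    var_explained: dict[str, float] = {}

    for ct_index, ct in enumerate(cell_types):
        rng = np.random.default_rng([0 if seed is None else seed, ct_index])
        markers = [g for g in marker_collection[ct].gene_ids if g in set(m.gene_ids)]
        sub = m.subset_genes(markers)
        sd = sub.values.std(axis=1, ddof=1)
        markers = [g for g, s in zip(sub.gene_ids, sd) if s > 0]
        if len(markers) < 2:
            raise ValueError(f"cell type {ct!r}: fewer than 2 usable markers")
        expr = m.subset_genes(markers).values  # markers x samples

        all_scores = np.empty((n_subsamples, m.n_samples))
        keep_counts = np.zeros(len(markers), dtype=int)
        prev_sign = 1.0
        for rep in range(n_subsamples):
            chosen = list(rng.choice(case_ids, size=k, replace=False)) + list(
                rng.choice(ctrl_ids, size=k, replace=False)
            )
            cols = [sample_pos[s] for s in chosen]
            fit = expr[:, cols]
            mu = fit.mean(axis=1, keepdims=True)
            sig = fit.std(axis=1, ddof=1, keepdims=True)
            ok = sig[:, 0] > 0
            if ok.sum() < 2:
                all_scores[rep] = np.nan
                continue
            zfit = ((fit - mu) / np.where(sig > 0, sig, 1.0))[ok]
            _, loadings, _ = _pc1(zfit.T)
            sign = _orient(loadings, tie_sign=prev_sign)
            survivors = np.flatnonzero(ok)[sign * loadings > 0]
            if survivors.size < 2:
                survivors = np.flatnonzero(ok)
            # refit the component on sign-consistent markers only
            zfit2 = ((fit[survivors] - mu[survivors]) / sig[survivors])
            _, loadings2, _ = _pc1(zfit2.T)
            sign2 = _orient(loadings2, tie_sign=prev_sign)
            prev_sign = sign2
            keep_counts[survivors] += 1
            # project all samples with the subsample's centering and scale
            z_all = (expr[survivors] - mu[survivors]) / sig[survivors]
            center = z_all[:, cols].mean(axis=1, keepdims=True)
            proj = sign2 * ((z_all - center).T @ loadings2)
            proj_sd = proj.std(ddof=1)
            all_scores[rep] = (proj - proj.mean()) / (proj_sd if proj_sd > 0 else 1.0)

        mgp = np.nanmedian(all_scores, axis=0)
        final_markers = [g for g, c in zip(markers, keep_counts) if c > 0.5 * n_subsamples]
        if len(final_markers) < 2:
            final_markers = markers

        # orient the final profile toward mean marker z-expression, then
        # standardize the column
        zfull, _, _ = _zscore_rows(m.subset_genes(final_markers).values)
        mean_z = zfull.mean(axis=0)
        r = np.corrcoef(mgp, mean_z)[0, 1]
        if np.isfinite(r) and r < 0:
            mgp = -mgp
        mgp = (mgp - mgp.mean()) / mgp.std(ddof=1)
        score_cols[ct] = mgp
        retained[ct] = final_markers
        _, _, var_explained[ct] = _pc1(zfull.T)

    scores = pd.DataFrame(score_cols, index=m.sample_ids)
    return MGPResult(
        scores=scores,
        retained_markers=retained,
        var_explained=var_explained,
        n_subsamples=n_subsamples,
        seed=seed,
    )


def compare_marker_sets(mgp_a: MGPResult, mgp_b: MGPResult) -> pd.DataFrame:
    """Pearson correlation of MGPs computed from two marker catalogs.

    Useful to check that profiles are a property of the tissue rather than
    of one particular marker list.
    """
    common = [ct for ct in mgp_a.cell_types if ct in mgp_b.cell_types]
    if not common:
        raise ValueError("no common cell types between the two MGP results")
    if list(mgp_a.scores.index) != list(mgp_b.scores.index):
        raise ValueError("MGP results cover different samples")
    rows = []
    for ct in common:
        r, p = stats.pearsonr(mgp_a.scores[ct], mgp_b.scores[ct])
        rows.append({"cell_type": ct, "pearson_r": r, "p_value": p})
    return pd.DataFrame(rows).set_index("cell_type")


def mgp_group_test(
    mgp: MGPResult,
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    adjust_mgps: list[str] | None = None,
) -> pd.DataFrame:
    """Case-control differences in MGPs, covariate-adjusted, two readouts.

    (a) OLS ``MGP ~ group + covariates (+ other MGPs)``: the group
    coefficient and its t-test p-value.  (b) The MGP residualized on the
    covariates (group excluded), then a two-sided Wilcoxon rank-sum test
    between groups on the residuals.  ``adjust_mgps`` lists other cell types
    whose scores enter both adjustments, used to check whether an apparent
    shift in one cell type is explained by another's.
    """
    import statsmodels.api as sm

    adjust_mgps = list(adjust_mgps or [])
    unknown = [c for c in adjust_mgps if c not in mgp.cell_types]
    if unknown:
        raise ValueError(f"adjust_mgps not in MGP result: {unknown}")
    sam = samples.loc[mgp.scores.index]
    is_case = (sam["group"].astype(str) == "case").to_numpy()

    rows = []
    for ct in mgp.cell_types:
        others = [c for c in adjust_mgps if c != ct]
        y = mgp.scores[ct].to_numpy(float)
        X = design_matrix(
            sam, covariates, mgp_scores=mgp.scores, mgp_cells=others, include_group=True
        )
        fit = sm.OLS(y, X.to_numpy(float)).fit()
        gi = list(X.columns).index("group")
        X0 = X.drop(columns="group")
        resid = sm.OLS(y, X0.to_numpy(float)).fit().resid
        w_stat, w_p = stats.ranksums(resid[is_case], resid[~is_case])
        rows.append(
            {
                "cell_type": ct,
                "lm_coefficient": fit.params[gi],
                "lm_p": fit.pvalues[gi],
                "wilcoxon_stat": w_stat,
                "wilcoxon_p": w_p,
            }
        )
    return pd.DataFrame(rows).set_index("cell_type")
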