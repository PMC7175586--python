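"""Sample covariate structure: pairwise correlogram and association of
variables with the leading expression principal components.

Bulk brain expression is dominated by RNA quality and cellular composition;
these diagnostics make that structure visible before any model is chosen.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.decomposition import PCA

from .io import ExpressionMatrix
from .mgp import MGPResult

logger = logging.getLogger(__name__)


@dataclass
class AssociationReport:
    """Pairwise Pearson structure and PC-variable associations."""

    pairwise_r: pd.DataFrame
    pairwise_p: pd.DataFrame
    pc_assoc: pd.DataFrame  # columns: pc, variable, f_p, pc_variance_fraction


def _variable_frame(
    samples: pd.DataFrame, mgp: MGPResult | None, for_correlogram: bool
) -> tuple[pd.DataFrame, dict[str, pd.Series]]:
    """Numeric encodings of sample variables.

    Binary categoricals (group, sex, two-level batch) are coded 0/1.
    Multi-level categoricals cannot carry a single Pearson coefficient, so
    they are excluded from the correlogram but returned separately to enter
    the PC F-tests as categorical regressors.
    """
    numeric: dict[str, pd.Series] = {}
    categorical: dict[str, pd.Series] = {}
    for col in ("group", "sex", "batch", "cohort", "age", "pmi", "rin"):
        if col not in samples.columns:
            continue
        s = samples[col]
        if pd.api.types.is_numeric_dtype(s):
            numeric[col] = pd.to_numeric(s)
        else:
            levels = sorted(s.astype(str).unique())
            if len(levels) == 1:
                logger.warning("variable %r is constant; omitted", col)
            elif len(levels) == 2:
                numeric[col] = (s.astype(str) == levels[1]).astype(float)
            else:
                if for_correlogram:
                    logger.warning(
                        "variable %r has %d levels; excluded from the Pearson correlogram",
                        col,
                        len(levels),
                    )
                categorical[col] = s.astype(str)
    if mgp is not None:
        for ct in mgp.cell_types:
            numeric[f"mgp_{ct}"] = mgp.scores[ct]
    return pd.DataFrame(numeric, index=samples.index), categorical


def correlogram(samples: pd.DataFrame, mgp: MGPResult | None = None) -> AssociationReport:
    """All pairwise Pearson correlations among sample variables and MGPs,
    with two-sided t-test p-values.

    Constant variables yield undefined correlations and are reported as
    missing.  Multi-level categoricals are excluded (a single Pearson
    coefficient is undefined for them).
    """
    if len(samples) < 4:
        raise ValueError("correlogram needs at least 4 samples")
    df, _ = _variable_frame(samples, mgp, for_correlogram=True)
    cols = list(df.columns)
    n = len(cols)
    r = np.full((n, n), np.nan)
    p = np.full((n, n), np.nan)
    for i in range(n):
        r[i, i], p[i, i] = 1.0, 0.0
        for j in range(i + 1, n):
            x, y = df[cols[i]].to_numpy(float), df[cols[j]].to_numpy(float)
            if x.std() == 0 or y.std() == 0:
                logger.warning("constant variable in pair (%s, %s); r undefined", cols[i], cols[j])
                continue
            r[i, j], p[i, j] = stats.pearsonr(x, y)
            r[j, i], p[j, i] = r[i, j], p[i, j]
    return AssociationReport(
        pairwise_r=pd.DataFrame(r, index=cols, columns=cols),
        pairwise_p=pd.DataFrame(p, index=cols, columns=cols),
        pc_assoc=pd.DataFrame(columns=["pc", "variable", "f_p", "pc_variance_fraction"]),
    )


def pc_association(
    m: ExpressionMatrix,
    samples: pd.DataFrame,
    mgp: MGPResult | None = None,
    n_pcs: int = 5,
) -> pd.DataFrame:
    """Associate sample variables with the top expression PCs.

    PCA is run on gene-standardized log2-CPM (samples as observations; each
    gene centered and unit-scaled).  Each PC score is regressed on each
    variable separately and the regression F-test p-value reported, together
    with the PC's variance fraction.
    """
    if m.unit != "log2cpm":
        raise ValueError(f"pc_association expects log2cpm, got unit={m.unit!r}")
    max_pcs = min(m.n_samples - 1, m.n_genes)
    if n_pcs > max_pcs:
        raise ValueError(f"n_pcs={n_pcs} exceeds the maximum {max_pcs}")
    sam = samples.loc[m.sample_ids]
    sd = m.values.std(axis=1, ddof=1)
    X = m.values[sd > 0]
    X = (X - X.mean(axis=1, keepdims=True)) / X[:, :].std(axis=1, ddof=1, keepdims=True)
    pca = PCA(n_components=n_pcs, svd_solver="full")
    scores = pca.fit_transform(X.T)
    var_frac = pca.explained_variance_ratio_

    numeric, categorical = _variable_frame(sam, mgp, for_correlogram=False)
    rows = []
    for k in range(n_pcs):
        y = scores[:, k]
        for var in list(numeric.columns) + list(categorical):
            if var in numeric.columns:
                x = numeric[var].to_numpy(float)
                if x.std() == 0:
                    continue
                design = np.column_stack([np.ones_like(x), x])
            else:
                dummies = pd.get_dummies(categorical[var], drop_first=True).to_numpy(float)
                design = np.column_stack([np.ones(len(y)), dummies])
            fit = sm.OLS(y, design).fit()
            rows.append(
                {
                    "pc": k + 1,
                    "variable": var,
                    "f_p": float(fit.f_pvalue),
                    "pc_variance_fraction": float(var_frac[k]),
                }
            )
    return pd.DataFrame(rows)
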