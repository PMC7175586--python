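"""Design-matrix construction shared by the MGP group tests and the NB DE
model.  Continuous covariates are centered and unit-scaled; categorical
covariates are dummy-coded dropping the first level; group is coded
control=0 / case=1 so positive coefficients mean higher in cases."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CONTINUOUS = {"age", "pmi", "rin"}


def design_matrix(
    samples: pd.DataFrame,
    covariates: list[str] | None = None,
    mgp_scores: pd.DataFrame | None = None,
    mgp_cells: list[str] | None = None,
    include_group: bool = True,
    scale_continuous: bool = True,
) -> pd.DataFrame:
    """Build a full design matrix (intercept first, group column named
    ``group`` when included) indexed like ``samples``.

    Covariates missing from the sample table are dropped with a warning so a
    sparse annotation file degrades gracefully rather than erroring.
    Raises ``ValueError`` naming aliased columns if the result is rank
    deficient.
    """
    covariates = list(covariates or [])
    parts: dict[str, np.ndarray] = {"intercept": np.ones(len(samples))}
    if include_group:
        parts["group"] = (samples["group"].astype(str) == "case").to_numpy(float)
    for cov in covariates:
        if cov not in samples.columns:
            logger.warning("covariate %r absent from sample table; dropped from model", cov)
            continue
        col = samples[cov]
        if cov in CONTINUOUS or pd.api.types.is_numeric_dtype(col):
            x = pd.to_numeric(col).to_numpy(float)
            if scale_continuous:
                sd = x.std(ddof=1)
                x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            parts[cov] = x
        else:
            dummies = pd.get_dummies(col.astype(str), prefix=cov, drop_first=True)
            for name in dummies.columns:
                parts[name] = dummies[name].to_numpy(float)
    if mgp_cells:
        if mgp_scores is None:
            raise ValueError("mgp_cells given without MGP scores")
        for cell in mgp_cells:
            if cell not in mgp_scores.columns:
                raise ValueError(f"cell type {cell!r} not in MGP scores")
            x = mgp_scores.loc[samples.index, cell].to_numpy(float)
            if scale_continuous:
                sd = x.std(ddof=1)
                x = (x - x.mean()) / sd if sd > 0 else x - x.mean()
            parts[f"mgp_{cell}"] = x
    X = pd.DataFrame(parts, index=samples.index)
    _check_full_rank(X)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    arr = X.to_numpy(float)
    if np.linalg.matrix_rank(arr) == X.shape[1]:
        return
    # name an aliased pair for the error message
    nonconst = [c for c in X.columns if c != "intercept" and X[c].std() > 0]
    corr = X[nonconst].corr().abs()
    np.fill_diagonal(corr.to_numpy(), 0.0)
    pair = np.unravel_index(np.argmax(corr.to_numpy()), corr.shape)
    a, b = corr.index[pair[0]], corr.columns[pair[1]]
    raise ValueError(f"design matrix is rank deficient; aliased columns include {a!r} and {b!r}")
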