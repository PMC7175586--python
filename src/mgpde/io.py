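"""Readers, writers and the pipeline's core data containers.

Expression data moves through the pipeline as an :class:`ExpressionMatrix`
(genes x samples with a unit tag), sample annotations as a validated
:class:`pandas.DataFrame` produced by :func:`read_sample_table`, and marker /
pathway gene sets as a :class:`GeneSetCollection`.  Supported on-disk formats
are plain TSV, MatrixMarket coordinate files with id sidecars, and GMT.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

logger = logging.getLogger(__name__)

Unit = Literal["counts", "cpm", "log2cpm"]

_VALID_UNITS = ("counts", "cpm", "log2cpm")
_OPTIONAL_SAMPLE_COLS = ("sex", "age", "pmi", "rin", "batch", "cohort")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with an explicit unit.

    Parameters
    ----------
    values
        Nonnegative numeric array of shape ``(n_genes, n_samples)``
        (log2cpm values may be negative only when a pseudocount < 1 is used,
        so nonnegativity is enforced for counts and cpm only).
    gene_ids, sample_ids
        Unique identifiers matching the matrix dimensions.
    unit
        One of ``counts``, ``cpm``, ``log2cpm``.  Transitions between units
        happen only through the declared transforms in
        :mod:`mgpde.preprocess`.
    """

    values: np.ndarray
    gene_ids: list[str]
    sample_ids: list[str]
    unit: Unit = "counts"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        if self.unit not in _VALID_UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {_VALID_UNITS}")
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.sample_ids)} samples"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.sample_ids, "sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("expression values contain non-finite entries")
        if self.unit in ("counts", "cpm") and (self.values < 0).any():
            g, s = np.argwhere(self.values < 0)[0]
            raise ValueError(
                f"negative value at gene {self.gene_ids[g]!r}, sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def subset_genes(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [idx[g] for g in keep]
        return ExpressionMatrix(self.values[rows], list(keep), list(self.sample_ids), self.unit)

    def subset_samples(self, keep: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in keep]
        return ExpressionMatrix(self.values[:, cols], list(self.gene_ids), list(keep), self.unit)


@dataclass
class GeneSet:
    set_id: str
    name: str
    gene_ids: list[str]

    def __len__(self) -> int:
        return len(self.gene_ids)


@dataclass
class GeneSetCollection:
    """Named gene sets, either cell-type markers or pathway annotations."""

    sets: list[GeneSet]
    kind: Literal["marker", "pathway"] = "pathway"

    def __post_init__(self) -> None:
        _check_unique([s.set_id for s in self.sets], "gene set")
        for s in self.sets:
            seen: dict[str, None] = {}
            for g in s.gene_ids:
                seen.setdefault(g, None)
            s.gene_ids = list(seen)

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, set_id: str) -> GeneSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    @property
    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def as_dict(self) -> dict[str, list[str]]:
        return {s.set_id: list(s.gene_ids) for s in self.sets}


def _check_unique(ids: Iterable[str], what: str) -> None:
    counts = pd.Series(list(ids)).value_counts()
    dups = counts[counts > 1].index.tolist()
    if dups:
        raise ValueError(f"duplicate {what} ids: {sorted(dups)}")


# ---------------------------------------------------------------------------
# expression matrices


def read_counts(path: str | Path, format: str = "tsv") -> ExpressionMatrix:
    """Read a gene x sample count matrix.

    ``tsv``: header row of sample ids, first column of gene ids.
    ``mtx``: MatrixMarket coordinate file ``X.mtx`` with id sidecars
    ``X.mtx.genes`` and ``X.mtx.samples`` (one id per line).

    Counts need not be integers; upstream transcript-abundance estimators
    collapsed to gene level produce fractional counts.  Non-integer values
    trigger a warning only.
    """
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        _check_unique(df.index.astype(str), "gene")
        _check_unique(df.columns.astype(str), "sample")
        try:
            values = df.to_numpy(dtype=float)
        except ValueError:
            bad = df.map(lambda v: not _is_number(v))
            r, c = np.argwhere(bad.to_numpy())[0]
            raise ValueError(
                f"non-numeric cell at gene {df.index[r]!r}, sample {df.columns[c]!r}: "
                f"{df.iat[r, c]!r}"
            ) from None
        gene_ids, sample_ids = df.index.astype(str).tolist(), df.columns.astype(str).tolist()
    elif format == "mtx":
        mat = scipy.io.mmread(path)
        if scipy.sparse.issparse(mat):
            mat = mat.toarray()
        values = np.asarray(mat, dtype=float)
        gene_ids = Path(f"{path}.genes").read_text().split()
        sample_ids = Path(f"{path}.samples").read_text().split()
    else:
        raise ValueError(f"unknown format {format!r}; expected 'tsv' or 'mtx'")
    if not np.allclose(values, np.round(values)):
        warnings.warn("counts are not integer-valued (estimated abundances?)", stacklevel=2)
    return ExpressionMatrix(values, gene_ids, sample_ids, unit="counts")


def write_counts(m: ExpressionMatrix, path: str | Path, format: str = "tsv") -> None:
    """Write an expression matrix in a format :func:`read_counts` round-trips."""
    path = Path(path)
    if format == "tsv":
        m.to_frame().to_csv(path, sep="\t", index_label="gene_id")
    elif format == "mtx":
        scipy.io.mmwrite(str(path), scipy.sparse.coo_matrix(m.values))
        Path(f"{path}.genes").write_text("\n".join(m.gene_ids) + "\n")
        Path(f"{path}.samples").write_text("\n".join(m.sample_ids) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}")


def _is_number(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


# ---------------------------------------------------------------------------
# sample tables


def read_sample_table(
    path: str | Path,
    group_map: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Read and validate a sample annotation TSV.

    Required columns: ``sample_id`` and ``group``.  Optional: sex, age, pmi
    (hours), rin (1-10), batch, cohort.  ``group_map`` translates cohort
    labels (e.g. ``{"PD": "case", "Ctrl": "control"}``) onto the canonical
    case/control coding; labels already equal to case/control pass through.
    """
    df = pd.read_csv(Path(path), sep="\t", dtype={"sample_id": str})
    return validate_sample_table(df, group_map=group_map)


def validate_sample_table(
    df: pd.DataFrame, group_map: dict[str, str] | None = None
) -> pd.DataFrame:
    df = df.copy()
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise ValueError(f"sample table is missing required column {col!r}")
    df["sample_id"] = df["sample_id"].astype(str)
    _check_unique(df["sample_id"], "sample")
    if df["group"].isna().any():
        raise ValueError("sample table has missing group labels")
    if group_map:
        df["group"] = df["group"].map(lambda g: group_map.get(g, g))
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise ValueError(
            f"unknown group labels {sorted(bad)}; map them to case/control via group_map"
        )
    if "rin" in df.columns:
        rin = pd.to_numeric(df["rin"])
        out = df.loc[(rin < 1) | (rin > 10), "sample_id"].tolist()
        if out:
            raise ValueError(f"RIN outside [1, 10] for samples {out}")
        df["rin"] = rin
    for col in ("age", "pmi"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col])
    for col in ("sex", "batch", "cohort", "group"):
        if col in df.columns:
            df[col] = df[col].astype("category")
    missing = [c for c in _OPTIONAL_SAMPLE_COLS if c not in df.columns]
    if missing:
        logger.warning("sample table lacks optional covariates: %s", ", ".join(missing))
    df.attrs["missing_covariates"] = missing
    return df.set_index("sample_id", drop=False)


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(
    path: str | Path,
    format: str = "gmt",
    kind: Literal["marker", "pathway"] = "pathway",
) -> GeneSetCollection:
    """Read gene sets from GMT (``id TAB description TAB gene...``) or a
    two-column (set_id, gene_id) TSV.  Duplicate genes within a set are kept
    once; empty sets are dropped with a warning."""
    path = Path(path)
    sets: list[GeneSet] = []
    if format == "gmt":
        for lineno, line in enumerate(path.read_text().splitlines(), start=1):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path.name}:{lineno}: malformed GMT line (need >= 3 tab-separated fields)"
                )
            set_id, name, genes = fields[0], fields[1], [g for g in fields[2:] if g]
            sets.append(GeneSet(set_id, name, genes))
    elif format == "two_column_tsv":
        df = pd.read_csv(path, sep="\t", header=None, names=["set_id", "gene_id"], dtype=str)
        for set_id, sub in df.groupby("set_id", sort=True):
            sets.append(GeneSet(str(set_id), str(set_id), sub["gene_id"].tolist()))
    else:
        raise ValueError(f"unknown gene-set format {format!r}")
    nonempty = [s for s in sets if len(s.gene_ids) > 0]
    if len(nonempty) < len(sets):
        warnings.warn(f"dropped {len(sets) - len(nonempty)} empty gene sets", stacklevel=2)
    return GeneSetCollection(nonempty, kind=kind)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([s.set_id, s.name, *s.gene_ids])
        for s in collection.sets
    ]
    Path(path).write_text("\n".join(lines) + "\n")
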