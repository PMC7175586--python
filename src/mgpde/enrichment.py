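"""Pathway-level analysis: signed gene scores, gene score resampling (GSR)
enrichment, and the delta-significance statistic quantifying how
composition adjustment attenuates or strengthens each pathway.

Gene scores fold the DE p-value and fold-change direction into a single
number per direction: ``S_up = p/2`` when the gene goes up (LFC >= 0) and
``1 - p/2`` when it goes down, with ``S_down = 1 - S_up``.  Small scores
mean strong evidence in the given direction.  GSR compares a gene set's
mean log-score against means of randomly resampled same-size sets from the
scored universe.  The delta statistic per pathway is
``log10(p_0) - log10(p_CT)``: negative when adding cell-type covariates
erodes the pathway's significance (composition-driven signal), positive
when adjustment sharpens it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .dge import DEResult
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

P_MIN = 1e-300


def gene_scores(de: DEResult) -> pd.DataFrame:
    """Signed per-gene scores from a DE result.

    Columns ``s_up``, ``s_down``, ``log_s_up``, ``log_s_down`` (natural
    log).  Genes with missing p are excluded; p is clamped to
    ``[1e-300, 1]`` before the log.
    """
    t = de.table
    ok = t["p"].notna() & t["lfc"].notna()
    p = t.loc[ok, "p"].to_numpy(float)
    lfc = t.loc[ok, "lfc"].to_numpy(float)
    s_up = np.where(lfc < 0, 1.0 - p / 2.0, p / 2.0)
    s_down = 1.0 - s_up
    out = pd.DataFrame(
        {
            "s_up": s_up,
            "s_down": s_down,
            "log_s_up": np.log(np.clip(s_up, P_MIN, 1.0)),
            "log_s_down": np.log(np.clip(s_down, P_MIN, 1.0)),
        },
        index=t.index[ok],
    )
    return out


@dataclass
class EnrichmentResult:
    """GSR enrichment over one direction: per-set observed mean log-score,
    raw resampling p and BH-corrected p."""

    table: pd.DataFrame  # index set_id; columns n_genes_used, observed, p_raw, p_bh
    direction: str
    n_resample: int

    def significant(self, alpha: float = 0.05) -> list[str]:
        return self.table.index[self.table["p_bh"] < alpha].tolist()


def gsr_enrichment(
    scores: pd.DataFrame,
    sets: GeneSetCollection,
    direction: str = "up",
    n_resample: int = 10000,
    min_size: int = 5,
    max_size: int = 200,
    seed: int | None = 0,
) -> EnrichmentResult:
    """Gene score resampling enrichment for one direction.

    Each set is intersected with the scored universe; sets outside
    ``[min_size, max_size]`` effective genes are dropped.  The observed
    statistic is the mean log-score of member genes (lower = stronger); the
    null is the mean over ``n_resample`` random same-size subsets of the
    universe, shared across sets of equal size.  Raw p uses the +1/+1
    correction, so the smallest attainable value is ``1/(n_resample+1)``.
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    col = f"log_s_{direction}"
    if len(scores) == 0:
        raise ValueError("empty gene score universe")
    universe = scores.index.to_numpy()
    values = scores[col].to_numpy(float)
    pos = {g: i for i, g in enumerate(universe)}

    eligible: list[tuple[str, np.ndarray]] = []
    for s in sets:
        idx = np.array([pos[g] for g in s.gene_ids if g in pos], dtype=int)
        if min_size <= idx.size <= max_size:
            eligible.append((s.set_id, idx))
    rng = np.random.default_rng(seed)
    null_by_size: dict[int, np.ndarray] = {}
    rows = []
    for set_id, idx in sorted(eligible):
        k = idx.size
        if k not in null_by_size:
            draw = rng.integers(0, len(universe), size=(n_resample, k))
            null_by_size[k] = values[draw].mean(axis=1)
        observed = float(values[idx].mean())
        p_raw = (1.0 + np.sum(null_by_size[k] <= observed)) / (n_resample + 1.0)
        rows.append(
            {"set_id": set_id, "n_genes_used": k, "observed": observed, "p_raw": p_raw}
        )
    table = pd.DataFrame(rows).set_index("set_id") if rows else pd.DataFrame(
        columns=["n_genes_used", "observed", "p_raw"]
    )
    if len(table):
        table["p_bh"] = multipletests(table["p_raw"].to_numpy(), method="fdr_bh")[1]
    else:
        table["p_bh"] = []
    return EnrichmentResult(table=table, direction=direction, n_resample=n_resample)


def delta_significance(
    enr0: EnrichmentResult, enr_ct: EnrichmentResult, alpha: float = 0.05
) -> pd.DataFrame:
    """Delta = log10(p_0) - log10(p_CT) on BH-corrected enrichment p-values.

    Only pathways significant in at least one model (p_0 < alpha or
    p_CT < alpha) are scored.  Rows are sorted ascending, so the largest
    losses of significance under composition adjustment come first; read
    the tail for the largest gains.  Zero p-values are clamped to each
    result's resampling floor before the log.
    """
    if enr0.direction != enr_ct.direction:
        raise ValueError("enrichment results are for different directions")
    common = enr0.table.index.intersection(enr_ct.table.index)
    p0 = enr0.table.loc[common, "p_bh"].to_numpy(float)
    pct = enr_ct.table.loc[common, "p_bh"].to_numpy(float)
    floor0 = 1.0 / (enr0.n_resample + 1.0)
    floor_ct = 1.0 / (enr_ct.n_resample + 1.0)
    if (p0 <= 0).any() or (pct <= 0).any():
        logger.warning("zero enrichment p-values clamped to the resampling floor")
    delta = np.log10(np.where(p0 > 0, p0, floor0)) - np.log10(
        np.where(pct > 0, pct, floor_ct)
    )
    out = pd.DataFrame(
        {"direction": enr0.direction, "p0": p0, "p_ct": pct, "delta": delta}, index=common
    )
    out = out[(out["p0"] < alpha) | (out["p_ct"] < alpha)]
    return out.sort_values("delta")


def replicated_pathways(
    enr_a: dict[str, EnrichmentResult],
    enr_b: dict[str, EnrichmentResult],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pathways significant (BH p < alpha) in both cohorts in the same
    direction.  Inputs map direction -> EnrichmentResult per cohort."""
    rows = []
    for direction in ("up", "down"):
        if direction not in enr_a or direction not in enr_b:
            continue
        sig_a = set(enr_a[direction].significant(alpha))
        sig_b = set(enr_b[direction].significant(alpha))
        for set_id in sorted(sig_a & sig_b):
            rows.append(
                {
                    "set_id": set_id,
                    "direction": direction,
                    "p_bh_a": enr_a[direction].table.loc[set_id, "p_bh"],
                    "p_bh_b": enr_b[direction].table.loc[set_id, "p_bh"],
                }
            )
    return pd.DataFrame(rows, columns=["set_id", "direction", "p_bh_a", "p_bh_b"])


def overlap_coefficient(a: set[str], b: set[str]) -> float:
    """Szymkiewicz-Simpson overlap: |A ∩ B| / min(|A|, |B|)."""
    if not a or not b:
        return 0.0
    return len(a & b) / min(len(a), len(b))


def overlap_group(sets: GeneSetCollection, threshold: float = 0.5) -> list[list[str]]:
    """Single-linkage clusters of gene sets whose pairwise overlap
    coefficient exceeds ``threshold``.

    Used to group redundant pathways (e.g. GO parents/children) when
    reporting; empty sets are excluded with a warning.
    """
    members = {}
    for s in sets:
        if len(s.gene_ids) == 0:
            warnings.warn(f"empty gene set {s.set_id!r} excluded from grouping", stacklevel=2)
            continue
        members[s.set_id] = set(s.gene_ids)
    g = nx.Graph()
    g.add_nodes_from(members)
    ids = sorted(members)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if overlap_coefficient(members[a], members[b]) > threshold:
                g.add_edge(a, b)
    return [sorted(c) for c in sorted(nx.connected_components(g), key=lambda c: sorted(c)[0])]
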