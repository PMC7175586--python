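"""Synthetic bulk RNA-seq generator with known cell-composition structure.

Counts are negative-binomial draws around linear mixtures of cell-type
signature profiles: per sample, cell-type proportions come from a Dirichlet
prior with an optional case-only shift applied on the log (softmax) scale —
the composition confounder.  Within-cell-type regulatory effects are
planted as log2 fold changes on genes disjoint from the markers, so
"compositional" and "regulatory" signal are identifiable by construction.
Per-gene RIN-dependent degradation multiplies the expected counts.  Every
latent quantity is returned as ground truth.

Defaults mirror a two-group post-mortem cortex cohort: 13 cases vs 13
controls, five cortical cell types with neuron-dominant baseline
proportions, 30 markers per type, an oligodendrocyte excess in cases, and
RIN spanning 3.0-7.2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .coverage_qc import CoverageSet
from .io import ExpressionMatrix, GeneSet, GeneSetCollection
from .io import validate_sample_table

DEFAULT_CELL_TYPES = ("neuron", "oligodendrocyte", "astrocyte", "microglia", "endothelial")
# neuron-dominant cortical baseline (proportions x concentration 30; the
# concentration encodes the substantial subject-to-subject composition
# variability of bulk cortex dissections, driven by gray/white matter ratio)
DEFAULT_ALPHA = (12.0, 7.5, 6.0, 3.0, 1.5)


@dataclass
class SimConfig:
    """Generator parameters; see module docstring for the model."""

    n_genes: int = 2000
    cell_types: tuple[str, ...] = DEFAULT_CELL_TYPES
    markers_per_type: int = 30
    marker_fold: float = 4.0  # log2 specificity of a marker for its own type
    signature_sd: float = 1.5  # log2 spread of a gene's expression across cell types
    n_case: int = 13
    n_control: int = 13
    dirichlet_alpha: tuple[float, ...] = DEFAULT_ALPHA
    composition_shift: dict = field(
        default_factory=lambda: {"oligodendrocyte": 0.5}
    )  # additive log-proportion shift in cases
    n_regulatory_de: int = 100
    regulatory_lfc: float = 1.0
    dispersion: float = 0.1
    lib_size_mean: float = 1e6
    lib_size_cv: float = 0.3
    rin_range: tuple[float, float] = (3.0, 7.2)
    degradation_strength: float = 0.1  # max per-gene decay rate per RIN unit lost
    n_pathways: int = 30
    pathway_size_range: tuple[int, int] = (10, 30)
    confounded_fraction: float = 0.3
    seed: int = 0

    @property
    def n_cell_types(self) -> int:
        return len(self.cell_types)

    def validate(self) -> None:
        if self.markers_per_type * self.n_cell_types > self.n_genes:
            raise ValueError("more markers requested than genes available")
        if len(self.dirichlet_alpha) != self.n_cell_types:
            raise ValueError("dirichlet_alpha length must match cell_types")
        if self.n_case < 2 or self.n_control < 2:
            raise ValueError("need at least 2 samples per group")
        unknown = set(self.composition_shift) - set(self.cell_types)
        if unknown:
            raise ValueError(f"composition_shift names unknown cell types: {sorted(unknown)}")


@dataclass
class SimTruth:
    """Everything the generator knows; the oracle for downstream tests."""

    proportions: pd.DataFrame  # samples x cell types, rows sum to 1
    marker_assignments: dict[str, list[str]]
    regulatory_lfc: pd.Series  # planted log2 fold changes (nonzero genes only)
    pathway_labels: dict[str, str]  # set_id -> composition-confounded|regulatory|null
    rin: pd.Series
    degradation_rate: pd.Series  # per-gene susceptibility gamma
    nb_means: pd.DataFrame  # genes x samples expected counts
    signatures: pd.DataFrame | None = None  # genes x cell types raw profiles
    # (normalize each column to sum 1 to recover the mixture weights)


def _streams(seed: int, n: int) -> list[np.random.Generator]:
    return [np.random.default_rng([seed, k]) for k in range(n)]


def simulate_bulk(
    config: SimConfig,
) -> tuple[ExpressionMatrix, pd.DataFrame, GeneSetCollection, GeneSetCollection, SimTruth]:
    """Generate (counts, sample table, marker sets, pathway sets, truth).

    Fully reproducible from ``config.seed``; independent sub-streams per
    model component keep components decoupled when parameters change.
    """
    config.validate()
    rng_sig, rng_prop, rng_meta, rng_counts, rng_pw = _streams(config.seed, 5)
    G, C = config.n_genes, config.n_cell_types
    n = config.n_case + config.n_control
    gene_ids = [f"g{i:05d}" for i in range(G)]
    sample_ids = [f"s{i:02d}" for i in range(n)]
    is_case = np.array([True] * config.n_case + [False] * config.n_control)

    # --- cell-type signatures (log2-normal), markers strictly specific
    base = rng_sig.normal(5.0, 2.0, size=G)
    noise = rng_sig.normal(0.0, config.signature_sd, size=(G, C))
    log_sig = base[:, None] + noise
    marker_ids: dict[str, list[str]] = {}
    perm = rng_sig.permutation(G)
    marker_flat: list[int] = []
    for c, ct in enumerate(config.cell_types):
        chosen = perm[c * config.markers_per_type : (c + 1) * config.markers_per_type]
        marker_flat.extend(chosen.tolist())
        marker_ids[ct] = sorted(gene_ids[i] for i in chosen)
        # own type: base + fold; other types: clipped at or below base
        log_sig[chosen, :] = base[chosen, None] + np.minimum(noise[chosen], 0.0)
        log_sig[chosen, c] = base[chosen] + config.marker_fold
    sig = 2.0**log_sig
    sig_norm = sig / sig.sum(axis=0, keepdims=True)  # per-type relative profile

    # --- proportions: Dirichlet baseline, case-only softmax shift
    props = rng_prop.dirichlet(np.asarray(config.dirichlet_alpha, float), size=n)
    shift = np.array([config.composition_shift.get(ct, 0.0) for ct in config.cell_types])
    shifted = props * np.exp(shift)[None, :]
    shifted /= shifted.sum(axis=1, keepdims=True)
    props = np.where(is_case[:, None], shifted, props)

    # --- regulatory DE genes, disjoint from markers
    non_marker = np.setdiff1d(np.arange(G), np.array(marker_flat, dtype=int))
    reg_idx = rng_sig.choice(non_marker, size=config.n_regulatory_de, replace=False)
    reg_lfc = np.zeros(G)
    signs = np.where(np.arange(config.n_regulatory_de) % 2 == 0, 1.0, -1.0)
    reg_lfc[reg_idx] = signs * config.regulatory_lfc

    # --- sample metadata
    rin = rng_meta.uniform(*config.rin_range, size=n)
    lib = config.lib_size_mean * np.exp(
        rng_meta.normal(0.0, config.lib_size_cv, size=n)
        - 0.5 * config.lib_size_cv**2
    )
    sex = rng_meta.choice(["M", "F"], size=n)
    age = np.round(np.clip(rng_meta.normal(72.0, 8.0, size=n), 50, 95), 1)
    pmi = np.round(rng_meta.uniform(2.0, 30.0, size=n), 1)
    batch = np.where(rng_meta.random(n) < 0.5, "b1", "b2")

    # --- expected counts: libsize * degradation * mixture * regulatory fold
    gamma = rng_meta.uniform(0.0, config.degradation_strength, size=G)
    deg = np.exp(-gamma[:, None] * (config.rin_range[1] - rin)[None, :])
    mixture = sig_norm @ props.T  # genes x samples
    fold = 2.0 ** (reg_lfc[:, None] * is_case[None, :])
    mu = lib[None, :] * deg * mixture * fold

    # --- NB sampling
    if config.dispersion > 0:
        r = 1.0 / config.dispersion
        counts = rng_counts.negative_binomial(r, r / (r + mu))
    else:
        counts = rng_counts.poisson(mu)
    expr = ExpressionMatrix(counts.astype(float), gene_ids, sample_ids, unit="counts")

    samples = validate_sample_table(
        pd.DataFrame(
            {
                "sample_id": sample_ids,
                "group": np.where(is_case, "case", "control"),
                "sex": sex,
                "age": age,
                "pmi": pmi,
                "rin": np.round(rin, 2),
                "batch": batch,
                "cohort": "sim",
            }
        )
    )

    markers = GeneSetCollection(
        [GeneSet(ct, f"{ct} markers", list(marker_ids[ct])) for ct in config.cell_types],
        kind="marker",
    )
    pathways, labels = _simulate_pathways(config, gene_ids, marker_ids, reg_idx, reg_lfc, rng_pw)

    truth = SimTruth(
        proportions=pd.DataFrame(props, index=sample_ids, columns=list(config.cell_types)),
        marker_assignments=marker_ids,
        regulatory_lfc=pd.Series(
            reg_lfc[reg_idx], index=[gene_ids[i] for i in reg_idx], name="lfc"
        ),
        pathway_labels=labels,
        rin=pd.Series(rin, index=sample_ids, name="rin"),
        degradation_rate=pd.Series(gamma, index=gene_ids, name="gamma"),
        nb_means=pd.DataFrame(mu, index=gene_ids, columns=sample_ids),
        signatures=pd.DataFrame(sig, index=gene_ids, columns=list(config.cell_types)),
    )
    return expr, samples, markers, pathways, truth


def _simulate_pathways(config, gene_ids, marker_ids, reg_idx, reg_lfc, rng):
    """Three pathway flavors: composition-confounded (one cell type's
    markers), regulatory (planted-DE genes of one direction), null."""
    n_conf = int(round(config.confounded_fraction * config.n_pathways))
    n_reg = min(n_conf, config.n_pathways - n_conf)
    n_null = config.n_pathways - n_conf - n_reg
    lo, hi = config.pathway_size_range
    sets, labels = [], {}
    up = [gene_ids[i] for i in reg_idx if reg_lfc[i] > 0]
    down = [gene_ids[i] for i in reg_idx if reg_lfc[i] < 0]
    cell_types = list(config.cell_types)
    for j in range(n_conf):
        ct = cell_types[j % len(cell_types)]
        pool = marker_ids[ct]
        k = min(int(rng.integers(lo, hi + 1)), len(pool))
        sets.append(
            GeneSet(f"confounded_{ct}_{j:02d}", f"{ct} marker pathway",
                    sorted(rng.choice(pool, size=k, replace=False)))
        )
        labels[sets[-1].set_id] = "composition-confounded"
    for j in range(n_reg):
        pool = up if j % 2 == 0 else down
        direction = "up" if j % 2 == 0 else "down"
        k = min(int(rng.integers(lo, hi + 1)), len(pool))
        if k < 2:
            continue
        sets.append(
            GeneSet(f"regulatory_{direction}_{j:02d}", "planted regulatory pathway",
                    sorted(rng.choice(pool, size=k, replace=False)))
        )
        labels[sets[-1].set_id] = "regulatory"
    for j in range(n_null):
        k = int(rng.integers(lo, hi + 1))
        sets.append(
            GeneSet(f"null_{j:02d}", "random pathway",
                    sorted(rng.choice(gene_ids, size=k, replace=False)))
        )
        labels[sets[-1].set_id] = "null"
    return GeneSetCollection(sets, kind="pathway"), labels


def simulate_coverage(
    n_transcripts: int,
    length_range: tuple[int, int],
    protocol: str,
    rin_per_sample: dict[str, float],
    seed: int = 0,
    depth: float = 30.0,
    cohort: str | None = None,
) -> list[CoverageSet]:
    """Per-sample transcript coverage under two library protocols.

    ``random_primed``: uniform expected coverage with mild edge loss,
    insensitive to RIN.  ``polyA``: exponential retention from the 3' end
    with per-base decay rate growing as RIN drops, emulating degraded
    poly(A)-selected libraries.  Base-level noise is Poisson; transcript
    weights are log-normal.
    """
    if protocol not in ("random_primed", "polyA"):
        raise ValueError(f"unknown protocol {protocol!r}")
    lo, hi = length_range
    if lo < 200:
        raise ValueError("transcript lengths must be >= 200")
    rng = np.random.default_rng([seed, 7])
    lengths = rng.integers(lo, hi + 1, size=n_transcripts)
    weights = np.exp(rng.normal(0.0, 1.0, size=n_transcripts))
    out = []
    for sample_id in sorted(rin_per_sample):
        rin = rin_per_sample[sample_id]
        cov: dict[str, np.ndarray] = {}
        w: dict[str, float] = {}
        for t in range(n_transcripts):
            L = int(lengths[t])
            x = np.arange(L)
            if protocol == "random_primed":
                shape = 1.0 - 0.2 * (np.exp(-x / 20.0) + np.exp(-(L - 1 - x) / 20.0))
            else:
                lam = max(10.0 - rin, 0.0) * 3e-4
                shape = np.exp(-lam * (L - 1 - x))
            mean_cov = depth * weights[t] * shape
            tid = f"t{t:04d}"
            cov[tid] = rng.poisson(mean_cov).astype(float)
            w[tid] = float(weights[t] * shape.mean())
        out.append(
            CoverageSet(
                sample_id=sample_id, coverage=cov, weights=w, rin=rin,
                cohort=cohort or protocol,
            )
        )
    return out
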