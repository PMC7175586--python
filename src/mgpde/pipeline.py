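"""End-to-end orchestration: simulate or ingest, preprocess, MGPs, covariate
diagnostics, differential expression with and without composition
adjustment, enrichment in both directions, and delta-significance scoring.

Every stage writes TSV outputs under the run directory and registers them
in a :class:`RunManifest`.  The MGP covariates entering the adjusted DE
model are, by default, those cell types whose covariate-adjusted group
difference is significant (Wilcoxon p < 0.05); a config override replaces
the rule with a fixed list.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd

from . import __version__
from .covariates import correlogram, pc_association
from .dge import DEResult, compare_models, fit_nb_de
from .enrichment import delta_significance, gene_scores, gsr_enrichment
from .io import (
    ExpressionMatrix,
    read_counts,
    read_gene_sets,
    read_sample_table,
    write_counts,
    write_gene_sets,
)
from .mgp import estimate_mgp, mgp_group_test
from .preprocess import cpm_transform, run_preprocess
from .synthetic import SimConfig, simulate_bulk

logger = logging.getLogger(__name__)


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    version: str
    started: str
    files: list[dict] = field(default_factory=list)

    def add(self, stage: str, path: Path, n_rows: int) -> None:
        self.files.append({"stage": stage, "path": str(path), "n_rows": int(n_rows)})

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.files, columns=["stage", "path", "n_rows"])
        df.attrs.update(
            config_hash=self.config_hash, seed=self.seed, version=self.version
        )
        return df

    def write(self, path: Path) -> None:
        header = (
            f"# config_hash={self.config_hash}\tseed={self.seed}"
            f"\tversion={self.version}\tstarted={self.started}\n"
        )
        with open(path, "w") as fh:
            fh.write(header)
            self.to_frame().to_csv(fh, sep="\t", index=False)


def config_hash(config: dict) -> str:
    """Stable hash of a config dict (key order irrelevant)."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_all(config: dict, out_dir: str | Path) -> RunManifest:
    """Run the full pipeline from a config dict; returns the manifest.

    Config keys (all optional unless noted): ``seed``; either ``simulate``
    (SimConfig field overrides) or ``inputs`` (paths: counts, samples,
    markers, pathways, optional group_map); ``preprocess`` (filter
    parameters); ``mgp`` (n_subsamples); ``covariates`` (sample-table
    columns for the models); ``mgp_selection`` ("auto" or an explicit cell
    type list); ``alpha``; ``enrichment`` (n_resample, min_size, max_size).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = RunManifest(
        config_hash=config_hash(config),
        seed=seed,
        version=__version__,
        started=datetime.now(timezone.utc).isoformat(timespec="seconds"),
    )
    alpha = float(config.get("alpha", 0.05))
    covs = config.get("covariates", ["sex", "age", "pmi", "rin", "batch"])

    # --- stage: inputs
    if "inputs" in config:
        paths = config["inputs"]
        counts = read_counts(paths["counts"])
        samples = read_sample_table(paths["samples"], group_map=paths.get("group_map"))
        markers = read_gene_sets(paths["markers"], kind="marker")
        pathways = read_gene_sets(paths["pathways"], kind="pathway")
        logger.info("loaded inputs: %d genes x %d samples", counts.n_genes, counts.n_samples)
    else:
        sim_overrides = dict(config.get("simulate", {}))
        sim_overrides.setdefault("seed", seed)
        if "composition_shift" in sim_overrides:
            sim_overrides["composition_shift"] = dict(sim_overrides["composition_shift"])
        sim = SimConfig(**sim_overrides)
        counts, samples, markers, pathways, truth = simulate_bulk(sim)
        truth.proportions.to_csv(out / "truth_proportions.tsv", sep="\t")
        manifest.add("simulate", out / "truth_proportions.tsv", len(truth.proportions))
        logger.info("simulated %d genes x %d samples", counts.n_genes, counts.n_samples)
    write_counts(counts, out / "counts_raw.tsv")
    manifest.add("inputs", out / "counts_raw.tsv", counts.n_genes)
    write_gene_sets(markers, out / "markers.gmt")
    write_gene_sets(pathways, out / "pathways.gmt")
    manifest.add("inputs", out / "markers.gmt", len(markers))
    manifest.add("inputs", out / "pathways.gmt", len(pathways))

    # --- stage: preprocess
    pp = config.get("preprocess", {})
    filtered, reports = run_preprocess(counts, **pp)
    samples = samples.loc[filtered.sample_ids]
    write_counts(filtered, out / "counts_filtered.tsv")
    manifest.add("preprocess", out / "counts_filtered.tsv", filtered.n_genes)
    pd.DataFrame(
        {
            "sample_id": list(reports["outliers"].median_correlation),
            "median_correlation": list(reports["outliers"].median_correlation.values()),
            "flagged": [
                s in set(reports["outliers"].flagged)
                for s in reports["outliers"].median_correlation
            ],
        }
    ).to_csv(out / "outliers.tsv", sep="\t", index=False)
    manifest.add("preprocess", out / "outliers.tsv", counts.n_samples)
    logger.info(
        "preprocess: %d -> %d genes, %d outlier samples removed",
        counts.n_genes,
        filtered.n_genes,
        len(reports["outliers"].flagged),
    )

    # --- stage: MGP
    log2cpm = cpm_transform(filtered, log2=True)
    mgp = estimate_mgp(
        log2cpm,
        markers,
        samples,
        n_subsamples=int(config.get("mgp", {}).get("n_subsamples", 100)),
        seed=seed,
    )
    mgp.scores.to_csv(out / "mgp_scores.tsv", sep="\t")
    manifest.add("mgp", out / "mgp_scores.tsv", len(mgp.scores))
    group_tests = mgp_group_test(mgp, samples, covariates=covs)
    group_tests.to_csv(out / "mgp_group_tests.tsv", sep="\t")
    manifest.add("mgp", out / "mgp_group_tests.tsv", len(group_tests))

    # --- stage: covariate diagnostics
    assoc = correlogram(samples, mgp)
    assoc.pairwise_r.to_csv(out / "correlogram_r.tsv", sep="\t")
    assoc.pairwise_p.to_csv(out / "correlogram_p.tsv", sep="\t")
    manifest.add("covariates", out / "correlogram_r.tsv", len(assoc.pairwise_r))
    n_pcs = min(5, len(samples) - 1)
    pc = pc_association(log2cpm, samples, mgp, n_pcs=n_pcs)
    pc.to_csv(out / "pc_association.tsv", sep="\t", index=False)
    manifest.add("covariates", out / "pc_association.tsv", len(pc))

    # --- stage: MGP covariate selection
    selection = config.get("mgp_selection", "auto")
    if selection == "auto":
        selected = group_tests.index[group_tests["wilcoxon_p"] < 0.05].tolist()
        logger.info(
            "MGP selection rule (Wilcoxon p < 0.05 after covariate adjustment): %s",
            selected or "none",
        )
    else:
        selected = list(selection)
        logger.info("MGP selection overridden by config: %s", selected)

    # --- stage: differential expression, both models
    de0 = fit_nb_de(filtered, samples, covariates=covs, alpha=alpha)
    de_ct = fit_nb_de(
        filtered,
        samples,
        covariates=covs,
        mgp_scores=mgp.scores,
        mgp_covariates=selected,
        alpha=alpha,
    )
    for de, tag in ((de0, "covariates_only"), (de_ct, "covariates_plus_mgp")):
        path = out / f"de_{tag}.tsv"
        de.table.sort_values("p").to_csv(path, sep="\t")
        manifest.add("dge", path, len(de.table))
    comparison = compare_models(de0, de_ct, alpha=alpha)
    (out / "de_comparison.json").write_text(json.dumps(comparison, indent=2))
    manifest.add("dge", out / "de_comparison.json", 1)
    logger.info(
        "DE: %d significant without MGPs, %d with, %d in both (FDR < %g)",
        comparison["n_sig_0"],
        comparison["n_sig_ct"],
        comparison["n_both"],
        alpha,
    )

    # --- stage: enrichment and delta
    enr_cfg = config.get("enrichment", {})
    n_resample = int(enr_cfg.get("n_resample", 10000))
    min_size = int(enr_cfg.get("min_size", 5))
    max_size = int(enr_cfg.get("max_size", 200))
    deltas = {}
    for direction in ("up", "down"):
        enr = {}
        for de, tag in ((de0, "0"), (de_ct, "ct")):
            enr[tag] = gsr_enrichment(
                gene_scores(de),
                pathways,
                direction=direction,
                n_resample=n_resample,
                min_size=min_size,
                max_size=max_size,
                seed=seed,
            )
            path = out / f"enrichment_{direction}_{tag}.tsv"
            enr[tag].table.to_csv(path, sep="\t")
            manifest.add("enrichment", path, len(enr[tag].table))
        deltas[direction] = delta_significance(enr["0"], enr["ct"], alpha=alpha)
        path = out / f"delta_{direction}.tsv"
        deltas[direction].to_csv(path, sep="\t")
        manifest.add("delta", path, len(deltas[direction]))

    manifest.write(out / "manifest.tsv")
    (out / "config_resolved.json").write_text(json.dumps(config, indent=2, default=str))
    return manifest
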