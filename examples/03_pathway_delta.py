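"""Pathway-level delta-significance: which pathways lose or keep their
enrichment when the model adjusts for cell composition.

delta = log10(p_without_MGPs) - log10(p_with_MGPs) on BH-corrected
gene-score-resampling p-values; negative delta = the pathway's signal was
composition-driven.
"""

from mgpde import (
    SimConfig,
    cpm_transform,
    delta_significance,
    estimate_mgp,
    fit_nb_de,
    gene_scores,
    gsr_enrichment,
    run_preprocess,
    simulate_bulk,
)

COVS = ["sex", "age", "pmi", "rin", "batch"]

cfg = SimConfig(
    seed=1, composition_shift={"oligodendrocyte": 1.3},
    n_regulatory_de=100, regulatory_lfc=1.5,
)
expr, samples, markers, pathways, truth = simulate_bulk(cfg)
filtered, _ = run_preprocess(expr)
log2cpm = cpm_transform(filtered, log2=True)
mgp = estimate_mgp(log2cpm, markers, samples, seed=1)

de0 = fit_nb_de(filtered, samples, covariates=COVS)
de_ct = fit_nb_de(filtered, samples, covariates=COVS,
                  mgp_scores=mgp.scores, mgp_covariates=["oligodendrocyte"])

enr0 = gsr_enrichment(gene_scores(de0), pathways, "up", n_resample=5000, seed=1)
enr_ct = gsr_enrichment(gene_scores(de_ct), pathways, "up", n_resample=5000, seed=1)
delta = delta_significance(enr0, enr_ct)

print("pathway                        flavor                    p0       pCT     delta")
for set_id, row in delta.iterrows():
    flavor = truth.pathway_labels[set_id]
    print(
        f"{set_id:<30} {flavor:<22} {row['p0']:8.4f} "
        f"{row['p_ct']:8.4f} {row['delta']:+7.2f}"
    )
print(
    "\nComposition-confounded pathways (built from marker genes) sit at the "
    "top with strongly negative delta; planted regulatory pathways stay "
    "significant after adjustment (delta near or above zero)."
)
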