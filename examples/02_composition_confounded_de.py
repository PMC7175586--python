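"""The central experiment: a case-only oligodendrocyte excess with NO
regulatory effects still produces hundreds of 'differentially expressed'
genes — until the oligodendrocyte MGP joins the model as a covariate.
"""

from scipy.stats import hypergeom

from mgpde import (
    SimConfig,
    compare_models,
    cpm_transform,
    estimate_mgp,
    fit_nb_de,
    run_preprocess,
    simulate_bulk,
)

COVS = ["sex", "age", "pmi", "rin", "batch"]

cfg = SimConfig(seed=1, composition_shift={"oligodendrocyte": 1.3}, n_regulatory_de=0)
expr, samples, markers, _, truth = simulate_bulk(cfg)
filtered, _ = run_preprocess(expr)
log2cpm = cpm_transform(filtered, log2=True)
mgp = estimate_mgp(log2cpm, markers, samples, seed=1)

de0 = fit_nb_de(filtered, samples, covariates=COVS)
de_ct = fit_nb_de(
    filtered, samples, covariates=COVS,
    mgp_scores=mgp.scores, mgp_covariates=["oligodendrocyte"],
)
c = compare_models(de0, de_ct)

sig0 = set(c["genes_0"])
oligo = set(truth.marker_assignments["oligodendrocyte"]) & set(filtered.gene_ids)
p_hyper = hypergeom.sf(len(sig0 & oligo) - 1, filtered.n_genes, len(oligo), len(sig0))

print(f"FDR<0.05 genes, covariates only:      {c['n_sig_0']}")
print(f"FDR<0.05 genes, + oligodendrocyte MGP: {c['n_sig_ct']}")
print(f"oligodendrocyte markers among them:    {len(sig0 & oligo)}/{len(oligo)} "
      f"(hypergeometric p = {p_hyper:.2e})")
print(
    "\nNo gene is regulated in this simulation: every unadjusted discovery is "
    "composition masquerading as regulation, and the MGP covariate removes "
    "essentially all of them."
)
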