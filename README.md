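# mgpde — cell-composition-aware differential expression for bulk brain RNA-seq

Bulk brain tissue is a mixture: neurons, oligodendrocytes, astrocytes,
microglia and endothelial cells contribute reads in proportions that vary
from sample to sample (gray/white matter ratio at dissection, disease-related
gliosis or neuronal loss).  When those proportions differ between cases and
controls, standard differential expression confuses *composition change* with
*regulatory change* inside cells.  `mgpde` implements a pipeline that

1. estimates relative cell-type abundance per sample directly from the bulk
   counts via **marker gene profiles (MGPs)** — for each cell type, the first
   principal component of the z-scored log2-CPM expression of its marker
   genes, robustified by 100 balanced subsampling repetitions with
   opposite-sign marker removal and a per-sample median;
2. runs per-gene **negative-binomial Wald differential expression**
   (log μ = offset(log *s*) + Xβ, median-of-ratios size factors *s*, per-gene
   ML dispersion, BH FDR) with experimental covariates, **with and without
   the MGPs** as additional covariates;
3. scores genes with the signed transform
   S_up = {1 − p/2 if LFC < 0; p/2 if LFC ≥ 0}, S_down = 1 − S_up, and tests
   pathways by **gene score resampling** (mean log score of a set vs. means
   of random same-size sets);
4. ranks every pathway by **delta significance**
   Δ = log₁₀(p₀) − log₁₀(p_CT), the change in BH-corrected enrichment
   p-value when cell-type covariates enter the model — Δ < 0 flags signal
   that was carried by composition;
5. provides transcript-coverage QC (5′/3′ bias, coverage CV, RIN
   regressions) contrasting poly(A) and random-primed library protocols, and
6. ships a **synthetic-data generator** that produces NB-noised mixtures of
   cell-type signatures with Dirichlet proportions, a case-only composition
   shift, planted regulatory fold changes, RIN-dependent degradation and
   labeled pathway flavors — so every stage is verifiable against ground
   truth without downloading anything.

The intended users are researchers analyzing case/control bulk RNA-seq from
heterogeneous tissue who want to know how much of their differential signal
survives composition adjustment.

## Worked example

`examples/02_composition_confounded_de.py` simulates a 13-case / 13-control
cohort in which the **only** group difference is an oligodendrocyte excess in
cases (no gene is regulated), then fits both DE models:

```
FDR<0.05 genes, covariates only:      270
FDR<0.05 genes, + oligodendrocyte MGP: 2
oligodendrocyte markers among them:    25/25 (hypergeometric p = 2.04e-13)
```

All 270 unadjusted "discoveries" are composition masquerading as regulation —
they are saturated with oligodendrocyte markers — and the single MGP
covariate removes >99% of them.  `examples/03_pathway_delta.py` shows the
pathway-level view:

```
pathway                        flavor                    p0       pCT     delta
confounded_oligodendrocyte_01  composition-confounded   0.0008   1.0000   -3.08
regulatory_up_00               regulatory               0.0008   0.0012   -0.18
```

Marker-built pathways lose all significance under adjustment (Δ ≪ 0); planted
regulatory pathways keep theirs.  The other examples cover MGP↔truth recovery
(`01`, Spearman ρ 0.85–0.99 per cell type), coverage QC (`04`) and the
one-call pipeline (`05`).

A thin CLI mirrors the library:

```bash
mgpde simulate --out sim/ --seed 7
mgpde run-all --config config.yaml --out run/
```

## Layout

- `src/mgpde/` — library: `io`, `preprocess`, `mgp`, `covariates`, `dge`,
  `enrichment`, `coverage_qc`, `synthetic`, `pipeline`, `cli`
- `examples/` — one narrative script per capability
- `docs/methods.md` — models, assumptions, parameter choices, limitations
- `tests/` — unit, property and end-to-end acceptance tests
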