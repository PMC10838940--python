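# sclc-caf

Analysis pipeline linking cancer-associated-fibroblast (CAF) abundance in
bulk small-cell lung cancer (SCLC) transcriptomes to tumor phenotype, the
immune microenvironment, and predicted drug sensitivity.

SCLC is mostly a neuroendocrine (NE) tumor, but a minority of cases adopt a
non-neuroendocrine (Non-NE) phenotype with a more inflamed microenvironment
and different drug vulnerabilities. This package estimates fibroblast
content per sample from expression alone, splits a cohort into high/low CAF
infiltration groups, and quantifies how the groups differ in phenotype and
predicted chemosensitivity. It is written for computational biologists who
have a genes × samples expression table (FPKM/TPM or log2(x+1), declared
explicitly) and gene-set files, and want every step scripted, seeded and
testable — including a synthetic-cohort generator with full ground truth so
the whole pipeline can be validated without any downloads.

## What it computes

**CAF abundance** by three estimators over the classic marker panel
(PDGFRA, PDGFRB, PDPN, FAP, THY1, COL1A1, COL1A2, COL3A1, ACTA2, S100A4):

* marker-mean score: mean log2 expression of the markers;
* single-sample rank enrichment (ssGSEA-style): with genes ranked by
  expression per sample, score = Σᵢ (ECDF_hit(i) − ECDF_miss(i)) with hit
  weights rankᵅ (α = 0.25);
* constrained least squares: per sample solve min‖R·f − x‖² s.t. f ≥ 0
  against a reference profile matrix R, fractions f/Σf.

**Infiltration grouping**: Ward clustering (Euclidean, k = 2) of the
composite of z-scored marker rows plus z-scored fibroblast-abundance rows;
the cluster with the greater mean composite is "high".

**Phenotype and immune scores** per sample:

* NE score = (corr(x, v_NE) − corr(x, v_NonNE))/2, Pearson against
  reference NE/Non-NE expression vectors; > 0 ⇒ NE, < 0 ⇒ Non-NE;
* CYT = √(GZMA·PRF1) (geometric mean, small offset);
* APM = median z-scored expression of antigen-presentation genes;
* T-cell-inflamed GEP = Σ wᵢ·log2(xᵢ+1) with user-supplied weights;
* SCLC-A/N/P/Y subtype = argmax of ASCL1/NEUROD1/POU2F3/YAP1;
* IHC score = proportion bin (0–4) × intensity bin (0–3).

**Group inference**: GSEA with a weighted Kolmogorov–Smirnov enrichment
score, phenotype-permutation null, NES = ES / mean|same-sign null ES| and
nominal p with the +1 correction; per-set pathway scores compared with an
empirical-Bayes moderated t (variance shrinkage with prior df d₀ and prior
variance s₀² fitted by moment matching on log s²); Benjamini–Hochberg FDR;
Pearson/Spearman correlations and the usual two-group tests.

**Drug-sensitivity transfer**: per drug, ridge regression
(XᵀX + λI)⁻¹Xᵀy of cell-line log-IC50-like response on standardized
expression, λ by 5-fold CV; applied to the cohort (lower score = more
sensitive) and compared high vs low with the moderated t — logFC > 0 means
the high-infiltration group is predicted more resistant.

## Worked example

Run the whole pipeline on a default synthetic cohort (80 samples, 5,000
genes, ~30% of samples drawn from the high-infiltration mixture
component):

```bash
sclc-caf run-all --seed 1 --out run_out
cat run_out/report.json
```

The report's summary (seed 1):

```json
{
  "group_sizes": {"high": 25, "low": 55},
  "caf_vs_ne_score": {"r": -0.583, "p": 1.39e-08, "sign": -1},
  "mean_ne_score": {"high": -0.138, "low": 0.238, "p": 5.1e-11},
  "nes": {"NE_program": -1.48, "NonNE_program": 1.52},
  "drug_directions": {"more_resistant_in_high": 5, "more_sensitive_in_high": 3}
}
```

Reading: 25/80 samples cluster as high CAF infiltration; the fibroblast
marker score correlates negatively with the NE score (r = −0.58), the high
group's mean NE score is significantly lower than the low group's, the NE
gene program is depleted (NES = −1.48) and the Non-NE program enriched
(NES = +1.52) in the high group, and five of the eight synthetic drugs —
including all whose causal genes load on the fibroblast program — are
predicted more resistant in the high group. Per-stage tables
(`abundance.csv`, `labels.csv`, `scores.csv`, `gsea.csv`,
`drug_comparison.csv`, …) are written next to the report, along with the
cohort's ground truth and a config echo.

The same stages are available as library functions
(`sclc_caf.simulate_cohort`, `marker_mean_score`, `cluster_infiltration`,
`ne_score`, `gsea_nes`, `moderated_t`, `fit_ridge_transfer`, …) and as
individual subcommands (`simulate`, `abundance`, `cluster`, `score`,
`gsea`, `compare`, `drugs`).

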