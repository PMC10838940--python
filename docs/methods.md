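# Methods

This note documents the models and procedures implemented in `sclc_caf`,
the assumptions behind them, the parameters that matter, and the choices
made where the design was genuinely open. Nothing here states an empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Scope and assumptions

The pipeline analyzes bulk gene-level expression of tumor cohorts. It
assumes (i) expression is available on a declared scale — linear
(FPKM/TPM-like, non-negative) or log2(x+1) — and the scale is *never*
inferred from the values, because FPKM-vs-log ambiguity in public data is
not resolvable automatically; (ii) gene identifiers are symbols matched
case-sensitively, with no alias resolution; (iii) duplicate gene rows in
input files represent probe-level redundancy and are collapsed by the
per-sample maximum (configurable to mean). Standard deviations use the
n−1 denominator throughout.

## Fibroblast abundance

Three estimators are provided; none claims numeric parity with any
published deconvolution tool — what the downstream analysis needs is a
per-sample quantity monotone in fibroblast content.

* **Marker mean** — mean log2 expression of the CAF marker panel present
  in the matrix. Linear input is log2(x+1)-transformed first so a single
  highly expressed marker cannot dominate.
* **Single-sample rank enrichment** — genes are ranked per sample by
  expression, descending, ties broken by gene id (real GSEA
  implementations differ here; the lexicographic rule makes every result
  deterministic). With N genes and set size |S|, position i contributes
  weight rankᵢᵅ (rank N for the top gene) normalized by the in-set total
  if in-set, and 1/(N−|S|) otherwise; the score is either the summed
  difference of the two running ECDFs (`sum`, the ssGSEA convention —
  used with α = 0.25 for the fibroblast, stromal and immune scores,
  matching the classic stromal/immune score formulation) or the signed
  extremum of the running difference (`max_dev`). Because weights depend
  only on ranks, the score at α = 0 is invariant under any strictly
  monotone per-sample transform.
* **NNLS deconvolution** — per sample, min‖R·f − x‖² subject to f ≥ 0
  over the genes shared with a user-supplied non-negative reference R
  (solved by `scipy.optimize.nnls`), reporting raw coefficients and
  normalized fractions. Rank-deficient references, fewer shared genes
  than cell types, and all-zero samples are rejected rather than
  silently fitted.

## Infiltration grouping

The composite matrix stacks z-scored marker expression rows and z-scored
fibroblast-abundance rows (the three estimators by default); constant
rows are dropped with a warning. Samples are clustered by Ward linkage on
Euclidean distance and the dendrogram is cut at k = 2 — the published
analyses this emulates do not state their clustering parameters, so this
convention is pinned and recorded in every run report. The cluster with
the greater column-mean composite is labeled "high"; exact equality of
means (degenerate input) is broken deterministically with a warning. A
direct consequence, asserted in tests: the high group always has the
greater mean fibroblast marker score.

## Phenotype and immune scores

* **NE score** = (Pearson(x, v_NE) − Pearson(x, v_NonNE))/2 over the
  genes shared between the sample and the reference panel; > 0 is called
  NE, < 0 Non-NE, and exactly 0 — which the source definition leaves
  unspecified — is labeled `undetermined`. A sample constant over the
  panel has no defined correlation; it is flagged, not scored 0. The
  score is invariant under positive affine transforms of the sample
  vector and antisymmetric under swapping the reference vectors. Whether
  to correlate on linear or log expression is left to the caller's scale
  choice; the pipeline uses log2(x+1).
* **CYT** = √((GZMA+ε)(PRF1+ε)) on linear expression, ε = 0.01 by
  default so the geometric mean is defined at zero counts.
* **APM** = per-sample median of z-scored expression of the
  antigen-presentation gene set; zero-variance genes are excluded and
  logged. The score is bounded by the min/max of the z-scores used.
* **T-cell-inflamed GEP** = Σ wᵢ·log2(xᵢ+1). The canonical 18-gene
  weights come from a patent and are not shipped; a weight file is a
  required input, and a present panel gene without a weight is an error
  (silent zero-weighting would corrupt the score). The score is linear
  in the weight vector.
* **Subtype** = argmax of ASCL1/NEUROD1/POU2F3/YAP1 expression, ties
  resolved by the fixed priority A > N > P > Y with a logged flag.
* **IHC a×b** — proportion bins pinned as [0,5]→0, (5,25]→1, (25,50]→2,
  (50,75]→3, (75,100]→4 (the published bin edges leave 5–6% unassigned;
  the half-open convention closes the gap), intensity
  negative/weak/medium/strong → 0–3.

## Group inference

* **Ranking metric** — signal-to-noise (μ_h−μ_l)/(σ_h+σ_l) with each
  group σ floored at max(0.2·|μ|, 0.2) (the canonical GSEA default,
  configurable); descending order, ties lexicographic.
* **GSEA** — weighted KS running sum: hit increment |m|ᵖ normalized by
  the in-set total (p = 1), miss decrement 1/(N−|S|); ES is the extremum
  of largest magnitude. The null is label permutation (phenotype mode)
  with re-ranking per permutation; with fewer than 7 samples in either
  group the phenotype null is too coarse and the call falls back to
  random same-size gene sets with a warning. NES = ES divided by the
  mean |null ES| of matching sign; nominal p = (1 + #{same-sign nulls at
  least as extreme})/(1 + #same-sign nulls), so p ≥ 1/(n_perm+1) and is
  never exactly 0. All permutation procedures require an explicit seed;
  an unseeded call is an error, not a silent nondeterminism.
* **Per-set pathway scores** — the rank-ECDF single-sample engine
  (α = 1, max-deviation statistic) applied to a set library, one score
  per set per sample. This is a rank-based analog of per-set pathway
  scoring suitable for moderated-t group comparison; the kernel-density
  variant used by some tools is deliberately not implemented.
* **Moderated t** — per feature, pooled two-sample variance s² on
  d = n₁+n₂−2 df. Hyper-parameters by moment matching on
  e = log s² − ψ(d/2) + log(d/2): the excess of Var(e) over ψ′(d/2)
  determines the prior df d₀ via the trigamma inverse (Newton iteration
  from the asymptotic start, as in the standard empirical-Bayes
  fit), and s₀² = exp(ē + ψ(d₀/2) − log(d₀/2)). When the moment
  equation has no positive solution (no excess spread) the prior df is
  infinite and s₀² = exp(ē), the bias-corrected estimate of the common
  variance — this keeps the null type-I error at its nominal level,
  which the acceptance script measures. Posterior variance
  (d₀s₀² + ds²)/(d₀+d); t with d₀+d df; BH q-values. `prior_df=0`
  recovers the ordinary pooled t exactly (tested to 1e−10).
* **Elementary tests** — Pearson/Spearman correlation with the t-based
  two-sided p (also exposed as `correlation_pvalue(r, n)` for checking
  printed values); Welch/Student t, ANOVA, and Mann–Whitney U with exact
  enumeration for tie-free samples of total n ≤ 40 and the
  tie-corrected normal approximation otherwise (the source description
  is ambiguous between per-group and total n; total was pinned).

## Drug-sensitivity transfer

Per drug: genes standardized to mean 0, sd 1 on the training lines
(sd < 1e−8 dropped), λ chosen from a log grid (10⁻²…10⁴, 13 points) by
5-fold seeded CV on mean squared error, closed-form solve
(XᵀX+λI)⁻¹Xᵀy, intercept = mean response. Predictions standardize cohort
genes with the *training* transform; model genes missing from the cohort
are imputed at the training mean (standardized 0), keeping cohorts
comparable across drugs, with the count logged. Cross-dataset batch
homogenization (a ComBat-like step in published transfer tools) is out
of scope; per-gene standardization is the pinned substitute and absorbs
per-gene affine differences only. Predictions are invariant to affine
rescaling of any input gene. Group comparison: logFC = mean(high) −
mean(low) of predicted scores, inference via the moderated t across
drugs (ordinary t with a warning when only one drug is present);
because lower score = more sensitive, logFC > 0 reads "more resistant
in the high group".

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes,
with full ground truth:

* **Profiles** — one lognormal baseline per gene (meanlog 3, sdlog 1,
  an FPKM-like spread) shared across the four components (NE tumor,
  Non-NE tumor, fibroblast, immune); each program gene is multiplied by
  the fold-change (default 8×) in its home component only, so with
  fold-change 1 the profiles are identical. An IL6 gene belongs to the
  fibroblast program. Program seeds use real symbols (ASCL1, REST,
  GZMA, …) so the generic scoring code runs unchanged on synthetic data.
* **Samples** — fibroblast fraction f from the mixture
  0.7·Beta(2,18) + 0.3·Beta(10,10); the mixture component is the
  ground-truth `intended_group`, mirroring a <30% prevalence of high
  infiltration. Phenotype is Non-NE with probability
  expit(−2 + 6f) (≈0.12 at f = 0, ≈0.88 at f = 0.5), encoding the
  fibroblast/Non-NE association as a generative assumption to be
  recovered. Immune fraction = clip(0.4·f + N(0, 0.05), 0, 1−f): the
  positive coupling encodes the fibroblast/immune association, and the
  coefficient 0.4 keeps high-CAF samples with substantial tumor
  content, as resected tumor samples have — a larger coefficient would
  let stromal dilution of the tumor programs dominate their
  phenotype-driven regulation. Observed expression is the convex
  profile mixture under multiplicative lognormal noise (σ = 0.3;
  additive Gaussian available). With σ = 0 each expression column
  equals the profile mixture exactly (tested). One seeded stream drives
  all draws; (config, seed) reproduces a cohort bit for bit.
* **IHC triples** — a shared latent drives an αSMA-like marker; a
  REST-like latent correlates with it at ρ, a CD56-like latent at −ρ.
  Each marker's latent is binned into proportion quintiles (a ∈ 0–4)
  and intensity quartiles (b ∈ 0–3) — one latent drives both bins,
  i.e. staining intensity is co-monotone with extent — and the score is
  a·b, so binning attenuates the latent correlation.
* **Drug training fixture** — Gaussian expression on a log-like scale,
  response = intercept + Σ wᵢxᵢ + noise with a chosen number of causal
  genes.

What the generator does *not* model: count-level noise
(negative-binomial dispersion), batch effects, correlated gene-gene
structure beyond the four programs, cell-type spillover, and partial
marker specificity. Tests passing on synthetic cohorts therefore show
that the estimators and inference recover the assumed mixture structure
under lognormal noise — not that they are robust to the full noise
structure of real cohorts.

## Numerical choices and degenerate inputs

Ranking ties are broken lexicographically everywhere. Zero-variance
rows are excluded from z-score-based scores and from the moderated-t
prior fit, with warnings, and a fully constant input is an error. NNLS
fractions require a positive coefficient sum. The trigamma inverse
iterates Newton to 1e−10 relative tolerance with closed-form asymptotes
outside [1e−6, 1e7]. Table output uses 10 significant digits, enough
for lossless round-trips at analysis precision. Pipeline stage seeds
are derived from the master seed by a fixed affine map (mod 2³¹−1), so
any stage rerun alone reproduces its output.

## Problem sizes

Default validation sizes, chosen to exercise the cohort scale the
pipeline targets while keeping a full run fast: synthetic cohorts of 80
samples × 5,000 genes (20 cohorts for recovery medians), 400 null
repetitions with 199 label permutations each for calibration, 500–1,000
permutations for cohort-level GSEA, and a 200-line × 50-gene ridge
fixture with 5 causal genes at noise sd 0.5.

## Known limitations

The three abundance estimators are analogs, not reimplementations, of
published tools; absolute values are not comparable across estimators.
Exact reproduction of published cohort splits is sensitive to
clustering choices those publications do not state. The GSVA-style
stage is rank-ECDF only. The drug stage fits linear models with no
batch correction and assumes log-scale responses. No survival analysis
and no figure rendering are included.
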