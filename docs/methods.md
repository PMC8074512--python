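# Methods

This note documents the statistical models, the synthetic study
conditions, and the numerical choices behind `sexewas`, in the spirit of a
package vignette: what is computed, under which assumptions, and what the
passing tests do and do not establish about real data.

## Models

**Value scales.** Methylation fractions (β ∈ (0,1)) are converted to
M-values, M = log2(β/(1−β)), before any regression; β is clipped to
[1e−6, 1−1e−6] first so M stays finite. The inverse map
β = 2^M/(1+2^M) is exact to 1e−12 round-trip.

**Per-cohort association.** After slide-batch residualization, each
feature is fitted by OLS. The sex-stratified model is
`residual ~ age + Braak + neuron proportion` within one sex; the reported
effect is the Braak coefficient (M-units per stage) with its t-based
two-sided P at the residual degrees of freedom. The interaction model is
`residual ~ age + sex + Braak + sex:Braak + sex:age + neuron proportion`
with female as the reference level, so the sex:Braak coefficient equals
the male-minus-female slope; on balanced noiseless data it reconciles
exactly with the difference of the stratified estimates (tested to 1e−9).
Per-feature OLS is vectorized across features (shared design, many
responses); P-values per cohort use the t reference, while everything
downstream consumes estimate/SE pairs.

**Regions.** Contiguous probe clusters are maximal position-sorted runs
with inter-probe gaps ≤ 200 bp (inclusive) and ≥ 3 members. Within each
cluster, co-methylated cores are selected by a single pass of
leave-one-out correlations (each probe against the mean of the rest);
probes below r = 0.4 are dropped and the largest surviving contiguous run
of ≥ 3 probes is kept. Region statistics apply the same linear models to
the per-sample median of member residuals. The r = 0.4 default follows
the convention of co-methylation-based DMR callers and is exposed as a
flag; selection runs on residualized M-values, consistent with what is
subsequently tested.

**Inflation and empirical null.** The conventional inflation factor is
λ = median(χ²₁(p)) / 0.4549364. The empirical-null estimate fits a
3-component Gaussian mixture to the z = estimate/SE vector by seeded
multi-restart EM with conjugate (MAP) priors that mirror the Bayesian
formulation of empirical-null estimation: Dirichlet pseudo-counts
(90, 5, 5) keep the central component dominant a priori, the signal
components' means are anchored at median ± 4·MAD (prior strength κ = 50)
so they cannot absorb the null's tails on signal-free inputs, and
variances carry a weak inverse-gamma anchor at MAD². The anchor distance
matters: at ±3·MAD the side components clip the null's tails, biasing σ₀
down ~1.3% and making corrected P-values slightly anti-conservative; at
±4·MAD the estimator is unbiased to <0.5% on scaled nulls while still
recovering a 5% signal component at z ≈ 4 (validated on planted
mixtures). Correction is z' = (z−μ₀)/σ₀ with corrected estimate
est − μ₀·se and corrected SE σ₀·se, so corrected estimate/SE ≡ z'.

**Meta-analysis.** Correction precedes combination. Fixed effects use
inverse-variance weights w = se⁻²; heterogeneity is Cochran's
Q = Σw(est − est̄)² on k−1 df. Features with P_het < 0.05 are refitted
with DerSimonian–Laird weights (se² + τ²)⁻¹,
τ² = max(0, (Q−(k−1))/(Σw − Σw²/Σw)), and the random-effects estimate,
SE and P become the final ones (the flag-free default reports the
selected model's estimate alongside its P). Meta z uses the normal
reference. Features present in fewer than two cohorts are dropped; k is
recorded per feature.

**Discovery.** Stratified discoveries are BH at q < 0.05 within each
sex's meta P-values; CpGs and regions form separate families. Stagewise
testing screens BH on min(p_f, p_m) at α = 0.05, then applies Holm over
each screened feature's (p_f, p_m, p_int) at the adjusted level
α_adj = R·α/n. Holm was fixed as the confirmation correction (the
stagewise framework admits variants; a flag selects response residual
behavior elsewhere, not here) — under the simulated global null the
measured FWER is ≈ 0.03–0.05 over 500 replicates.

**Enrichment and gene ranking.** Fisher tests are two-sided with the
sample odds ratio; hyper- and hypomethylated foregrounds are tested
separately. Region-database overlap uses half-open 0-based intervals;
touching boundaries do not overlap. Regulatory domains are basal 5 kb
upstream / 1 kb downstream of the TSS (strand-aware), extended outward to
the neighboring basal boundary and capped at 1 Mb from the TSS; multi-CpG
regions are located by their midpoint for linking, and distances are
signed relative to the TSS and strand (upstream negative). Gene scores
are Y = −log10(min linked P) pooled over CpGs and regions; the
link-count bias is removed with a gamma GAM (log link, ~10 cubic
B-spline basis functions, second-order penalty, GCV-selected smoothing;
linear gamma GLM fallback) and genes are ranked by deviance residuals.
Pre-ranked GSEA uses the weighted KS statistic at weight 1, gene-label
permutations with a fixed seed, sign-matched NES normalization, nominal P
at resolution 1/(n_perm+1), and the standard pooled-NES FDR; ties in the
running-sum extremum resolve to the earliest index.

**QTL integration.** Methylation residuals remove neuron proportion,
batch, plate and age (nested batch/plate factors are tolerated as
rank-deficient designs — residuals remain well-defined); expression
residuals remove age and the log2(FPKM+1) of the five CNS cell-type
marker genes (ENO2, GFAP, CD68, OLIG2, CD34), used directly as covariates.
eQTM models are expression residual ~ methylation residual + Braak per
linked pair; mQTL models are methylation residual ~ dosage + batch +
3 genotype PCs per candidate pair, per sex, with BH within each
(scan × sex) family. Candidate SNPs satisfy: within 500 kb of the CpG
position or region ends (inclusive), MAF ≥ 0.01 (inclusive),
info ≥ 0.4 (inclusive), AD-association P < 0.05 (strict).

## Synthetic study conditions

The generator emulates a four-cohort prefrontal-cortex 450K meta-analysis
with 642 female and 388 male samples (largest cohort ~60%). Defaults, and
why:

- **Residual scale 1.5 M-units.** Back-calculated from the reference
  tables bundled with the package: meta-analysis SEs of ≈0.03 at
  n_female = 642 and sd(Braak) ≈ 2 imply a per-CpG residual SD of
  ≈ 0.03·2·√642 ≈ 1.5. This single number sets the power of every
  replicate study.
- **Effect classes** {null 92.5%, female-only 2%, male-only 2%, shared
  1.5%, opposite 2%} with slope magnitude 0.15 M-units/stage. The
  opposite class plants ±0.6×0.15 per sex (interaction 0.18), mirroring
  the published interaction hits whose per-sex estimates are attenuated
  relative to the top stratified effects while the interaction magnitude
  is ≈1.2–1.5× the stratified scale.
- **Structure.** Baselines from a 3-component normal mixture on the M
  scale (unmethylated/hemi/methylated); per-CpG age and neuron-proportion
  effects; slide batches of 8 samples with per-(probe, slide) shifts of
  SD 0.2; within-cluster correlation via a shared latent factor with
  loading 0.7 (pairwise r ≈ 0.5 — the real correlation level is not
  identified by the reference study, so this is a stated convention);
  Braak uniform on 0–6; ages uniform on 55–95; neuron proportions
  Beta(5, 7). Detection P is U(0, 1e−4) for good probes and U(0.1, 1)
  for a configurable 1% failing set.
- **Genotypes and expression.** Imputed-style dosages in [0, 2]; 50
  linked SNPs shift their CpG by 0.3 M-units per dosage unit; 50 genes'
  log2(FPKM+1) is linear in their linked CpG's M-value with slope −0.4
  plus N(0, 0.5) noise; cell-type marker genes present by name.

What the generator does **not** emulate: probe-level technical chemistry
(IDAT intensities, dye bias), realistic LD, chromosome X/Y, non-Gaussian
residual heavy tails, and cohort-specific missingness. Passing recovery
tests therefore demonstrate the statistical machinery under the stated
conditions, not robustness to every artifact of real arrays.

## Replicate studies and problem sizes

Error-rate and recovery studies run the modeling chain (QC → M-values →
slide residualization → models → empirical-null correction →
meta-analysis → discovery) at 5,000 CpGs per replicate — 50 all-null
replicates for error rates, ~10 planted-effect replicates for recovery;
these sizes give Monte-Carlo SEs of ≤0.03 on the reported rates while
keeping each study to a few minutes. Quantile/BMIQ normalization is
skipped inside replicate loops: simulated arrays carry no between-sample
distributional shifts, so the stage is a no-op there by construction; its
contracts are tested separately (KS between design types < 0.05 after
alignment, monotonicity, identity on type I).

Measured behavior at the default conditions: female-stratified
sensitivity ≈ 0.87 for planted 0.15-slope effects with false-discovery
proportion ≈ 0.03–0.05; the stagewise interaction arm confirms ≈ 0.38 of
planted opposite CpGs, ≈ 0.55–0.60 of which appear in neither stratified
set. The interaction arm's sensitivity is intrinsically limited at this
problem size: with 2% planted effects among 5,000 CpGs the BH selection
thresholds sit at z ≈ 3.0–3.3, and an opposite pair (±0.09 M-units/stage)
yields an interaction z of only ≈ 3.7, so roughly a third of such CpGs
clear screening and Holm confirmation. At genome scale (450K probes,
discovery families of a few hundred) the thresholds move to z ≈ 4.4 and
the same configuration separates cleanly — the stratified/interaction
complementarity is a large-n phenomenon that a desk-scale simulation
compresses.

## Numerical choices and edge cases

- Detection-P rule: probes are retained when detected (P < 0.01) in all
  samples; a flag inverts the rule (drop only probes failing everywhere)
  for compatibility with the looser reading of that QC step.
- Quantile normalization: reference is the row-mean of sorted columns;
  ties map to the mean of the spanned reference quantiles (deterministic).
- BMIQ: per-sample 3-state beta-mixture EM with posterior-weighted
  method-of-moments M-steps (fast and monotone-stable; class boundaries
  initialized at β = 0.2/0.75, max 500 iterations, tolerance 1e−6);
  U/M classes are quantile-mapped through fitted beta CDFs, the hemi
  class is linearly rescaled between the transformed class boundaries,
  and within-sample monotonicity is enforced by a final isotonic pass.
  Non-convergent samples fall back to identity with a warning.
- PCA outlier removal uses centered (not scaled) betas of the top-variance
  probes and runs once, not iteratively.
- Neuron-proportion estimation is a two-reference constrained projection
  (closed form, clipped to [0, 1]); it is validated only on synthetic
  mixtures of the bundled neuron/glia profiles.
- Zero-variance probes count as correlation 0 in co-methylation selection;
  duplicate probe positions on one chromosome are rejected.
- All randomness flows through explicit integer seeds; fixed seeds give
  byte-identical generator output and identical discovery tables across
  reruns.

## Known limitations

- The empirical-null EM is a point-estimate analog of the Bayesian
  reference; it reports no posterior uncertainty for μ₀/σ₀.
- The stagewise confirmation is fixed to Holm; Shaffer-style logical
  constraints between the three hypotheses are not exploited.
- GSEA FDR follows the classic pooled-permutation recipe, which is known
  to be conservative for small set collections.
- Region inventories depend on the supplied annotation; the bundled
  cluster scheme reproduces the construction rule, not any specific
  array's region count.
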