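# sexewas

Sex-specific epigenome-wide meta-analysis of Alzheimer's disease
neuropathology.

DNA methylation changes in post-mortem brain track the spread of tau
pathology (Braak stage 0–6), and they do so differently in women and men.
`sexewas` implements, as a tested and reusable Python pipeline, the full
analysis used to map such sex-specific differences across multiple
Illumina 450K cohorts:

1. **Per-cohort preprocessing** — probe QC (detection P, smoking-associated
   probes, SNPs within 5 bp of the probe 3' end at MAF ≥ 1%), sample QC
   (bisulfite conversion < 88%, PCA outliers beyond ±3 SD on PC1/PC2),
   quantile normalization plus BMIQ alignment of type I/II probe designs,
   M-value conversion (M = log2(β/(1−β))), slide-batch residualization,
   and reference-based estimation of the neuronal proportion of each bulk
   sample.
2. **Association models** — per CpG (and per co-methylated region,
   summarized by the median member M-value), a sex-stratified model
   `residual ~ age + Braak + neuron proportion` fitted within each sex,
   and a sex-by-Braak interaction model
   `residual ~ age + sex + Braak + sex:Braak + sex:age + neuron proportion`
   whose interaction coefficient is the male-minus-female Braak slope.
3. **Inflation correction and meta-analysis** — conventional genomic
   inflation λ and an empirical-null fit (3-component Gaussian mixture on
   z-scores) whose central component supplies the bias μ₀ and inflation
   σ₀; statistics are rescaled (z' = (z−μ₀)/σ₀) per cohort and combined by
   inverse-variance fixed-effects meta-analysis, switching to
   DerSimonian–Laird random effects when Cochran's Q has P < 0.05.
4. **Discovery** — BH-FDR selection within each sex, plus stagewise
   testing for sex-specificity: screen the per-feature global null with BH
   on min(p_female, p_male), then confirm the female, male and interaction
   hypotheses per screened feature with Holm at the adjusted level
   R·α/n (per-feature FWER control).
5. **Interpretation** — Fisher enrichment against island relation / gene
   features / chromatin states, LOLA-style region-overlap enrichment,
   basal-plus-extension regulatory-domain gene linking (5 kb up / 1 kb
   down, extended up to 1 Mb), gamma-GAM de-biasing of per-gene minimum
   P-values by link count, pre-ranked GSEA, and eQTM / cis-mQTL scans with
   the study's SNP filters (500 kb window, MAF ≥ 1%, info ≥ 0.4, AD
   association P < 0.05), run separately per sex.

Because the cohorts behind such studies are controlled-access, the package
ships a first-class synthetic-data generator (`sexewas.simulate`) that
reproduces the study conditions — four cohorts, 642 female / 388 male
samples, correlated CpG blocks, planted sex-specific Braak slopes, mQTL
and eQTM links — with a ground-truth table, so every downstream stage is
testable end-to-end without downloads.

## Worked example

```python
import pandas as pd
from sexewas.simulate import SimConfig, generate_dataset
from sexewas import preprocess as pp, cohort as cm, meta as mt, discovery as disc

cfg = SimConfig(n_cpgs=5000, seed=11)
study = generate_dataset(cfg)

tables = {"female": [], "male": [], "interaction": []}
for c in study.cohorts:
    m = pd.DataFrame(pp.beta_to_m(c.beta.values), index=c.beta.index,
                     columns=c.beta.columns)
    resid = pp.residualize(m, c.samples[["slide"]])
    tables["female"].append(cm.fit_stratified(resid, c.samples, "F", cohort=c.name))
    tables["male"].append(cm.fit_stratified(resid, c.samples, "M", cohort=c.name))
    tables["interaction"].append(cm.fit_interaction(resid, c.samples, cohort=c.name))

meta = {a: mt.combine_cohort_tables(tables[a], seed=1)[0] for a in tables}
female_hits = disc.discovery_set(meta["female"])
truth = study.truth
planted = truth.index[truth.effect_class == "female_only"]
print(len(female_hits), "female discoveries;",
      planted.isin(female_hits.index).mean().round(3), "of planted recovered")
```

This prints `206 female discoveries; 0.867 of planted recovered`: at the
default study conditions (residual SD 1.5 M-units, slopes of 0.15 M-units
per Braak stage at 2% of CpGs) the female-stratified arm recovers ~87% of
the planted female-only effects, and ~5% of its discoveries are true
nulls — the behavior BH at FDR 0.05 guarantees in expectation.

The bundled reference tables illustrate the complementarity of the two
analyses on published results:

```python
from sexewas.reference import stratified_top_cpgs, interaction_cpgs
from sexewas.discovery import direction_concordance

t = stratified_top_cpgs()
f = t[t.significant_in == "female"]
print(direction_concordance(f.estimate_female, f.estimate_male))
# {'same': 9, 'opposite': 1, 'zero': 0}
print(direction_concordance(interaction_cpgs().estimate_female,
                            interaction_cpgs().estimate_male))
# {'same': 1, 'opposite': 13, 'zero': 0}
```

Top stratified hits are mostly attenuated-but-same-direction in the other
sex, while interaction hits almost always have opposite directions — the
two analyses surface different biology.

A full configuration-driven run (all stages, TSV outputs plus a manifest):

```bash
sexewas run-all --seed 7 --outdir results/demo
```

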