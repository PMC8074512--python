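"""Multi-cohort 450K-like synthetic data with known sex-specific effect structure.

The generator emulates the structure of a four-cohort post-mortem brain
methylation study: per-cohort beta/detection-P matrices and sample sheets,
a manifest-like probe annotation with co-methylated probe clusters,
genotype dosages with planted cis-mQTL effects, FPKM-scale expression with
planted eQTM effects, and a ground-truth table recording every planted
effect so downstream recovery is scoreable.

M-values are generated as

    M = baseline + age effect + neuron-proportion effect + slide effect
        + sex-specific Braak slope * Braak + correlated within-region noise
        + independent noise

and mapped to betas via beta = 2**M / (1 + 2**M). Defaults reproduce the
study conditions of a ~1,030-sample meta-analysis (642 female / 388 male
across four cohorts, largest cohort ~60% of samples) with a per-CpG
residual scale of 1.5 M-units, which back-calculates from meta-analysis
standard errors of ~0.03 at that sample size.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sexewas.preprocess import m_to_beta

EFFECT_CLASSES = ("null", "female_only", "male_only", "shared", "opposite")

DEFAULT_PROPORTIONS = {
    "null": 0.925,
    "female_only": 0.02,
    "male_only": 0.02,
    "shared": 0.015,
    "opposite": 0.02,
}

#: canonical CNS cell-type marker genes (neurons, astrocytes, microglia,
#: oligodendrocytes, endothelial cells)
MARKER_GENES = ("ENO2", "GFAP", "CD68", "OLIG2", "CD34")


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic multi-cohort generator."""

    n_cohorts: int = 4
    # per-cohort sample sizes; totals mirror 642 female / 388 male with the
    # largest cohort holding ~60% of samples
    n_female: tuple = (385, 109, 84, 64)
    n_male: tuple = (233, 66, 50, 39)
    n_cpgs: int = 20_000
    n_regions: int | None = None          # default: n_cpgs // 20
    region_size_mean: float = 6.0         # mean probes per cluster (>=3 enforced)
    effect_class_proportions: dict = field(default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    slope_magnitude: float = 0.15         # M-units per Braak stage
    opposite_scale: float = 0.6           # per-sex |slope| of the opposite class, x magnitude
    age_range: tuple = (55.0, 95.0)
    age_slope_sd: float = 0.01            # per-CpG age effect SD, M-units/year
    braak_levels: tuple = (0, 1, 2, 3, 4, 5, 6)
    neuron_prop_params: tuple = (5.0, 7.0)  # Beta(a,b) on (0,1)
    neuron_slope_sd: float = 0.3          # per-CpG neuron-proportion effect SD
    noise_sd: float = 1.5                 # independent residual SD, M-units
    batch_effect_sd: float = 0.2          # per (slide, probe) random shift
    region_loading: float = 0.7           # shared latent-factor loading within regions
    samples_per_slide: int = 8
    type2_attenuation: float = 1.0        # <1 compresses type II M-values (design bias)
    frac_failing_probes: float = 0.01
    n_low_conversion: int = 0             # per-cohort samples with conversion < 88
    frac_smoking: float = 0.005
    frac_snp_probes: float = 0.01
    n_snps: int = 500
    n_genes: int = 300
    n_mqtl: int = 50                      # SNPs with a planted dosage effect
    mqtl_effect: float = 0.3              # M-units per dosage unit
    n_eqtm: int = 50                      # genes with a planted methylation effect
    eqtm_effect: float = -0.4             # log2-expression units per M-unit
    expression_noise_sd: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.n_cohorts <= 0 or self.n_cpgs <= 0:
            raise ValueError("counts must be positive")
        if len(self.n_female) != self.n_cohorts or len(self.n_male) != self.n_cohorts:
            raise ValueError("per-cohort sample sizes must match n_cohorts")
        if any(n <= 0 for n in self.n_female) or any(n <= 0 for n in self.n_male):
            raise ValueError("counts must be positive")
        tot = sum(self.effect_class_proportions.get(c, 0.0) for c in EFFECT_CLASSES)
        if abs(tot - 1.0) > 1e-8:
            raise ValueError("effect_class_proportions must sum to 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_regions is None:
            self.n_regions = max(1, self.n_cpgs // 20)


@dataclass
class CohortData:
    """One cohort's matrices: betas, detection P-values and the sample sheet."""

    name: str
    beta: pd.DataFrame
    detp: pd.DataFrame
    samples: pd.DataFrame


@dataclass
class SimulatedStudy:
    """Everything :func:`generate_dataset` produces for one configuration."""

    config: SimConfig
    cohorts: list
    probes: pd.DataFrame           # manifest-like annotation
    truth: pd.DataFrame            # per-CpG effect class, true slopes, region id
    smoking_probes: list
    cets_reference: pd.DataFrame   # neuron/glia mean betas at marker probes
    _dosage_seed: int = 0


@dataclass
class GenotypeData:
    dosage: pd.DataFrame           # SNPs x samples, in [0, 2]
    snps: pd.DataFrame             # snp_id, chr, pos, maf, info, p_AD
    pcs: pd.DataFrame              # samples x PC1..PC3
    truth: pd.DataFrame            # planted snp -> cpg links with effects


@dataclass
class ExpressionData:
    expr: pd.DataFrame             # genes x samples, FPKM scale (>= 0)
    genes: pd.DataFrame            # gene, chr, tss, strand
    truth: pd.DataFrame            # planted gene -> cpg links with effects


# ---------------------------------------------------------------------------
# probe map: positions, clusters, annotation
# ---------------------------------------------------------------------------

def _build_probe_map(cfg: SimConfig, rng: np.random.Generator):
    """Lay out probes on chromosomes: clustered regions plus isolated singletons.

    Cluster members are spaced 20-120 bp apart (gaps <= 200 so the cluster
    scheme recovers them); everything else is separated by > 200 bp.
    """
    sizes = np.maximum(3, rng.poisson(cfg.region_size_mean - 1, cfg.n_regions) + 1)
    total_in_regions = int(sizes.sum())
    if total_in_regions > cfg.n_cpgs:
        # shrink the region count so singletons remain
        keep = np.searchsorted(np.cumsum(sizes), int(cfg.n_cpgs * 0.6)) + 1
        sizes = sizes[:keep]
        total_in_regions = int(sizes.sum())
    n_single = cfg.n_cpgs - total_in_regions

    n_chrom = min(22, max(1, cfg.n_cpgs // 500))
    chroms = [f"chr{i + 1}" for i in range(n_chrom)]
    pos, chrom_col, region_id = [], [], []
    units = [("region", i) for i in range(len(sizes))] + [("single", i) for i in range(n_single)]
    rng.shuffle(units)
    per_chrom = int(np.ceil(len(units) / n_chrom))
    u = 0
    for ch in chroms:
        cursor = int(rng.integers(10_000, 50_000))
        for _ in range(per_chrom):
            if u >= len(units):
                break
            kind, idx = units[u]
            if kind == "region":
                for k in range(sizes[idx]):
                    chrom_col.append(ch)
                    pos.append(cursor)
                    region_id.append(f"r{idx:05d}")
                    cursor += int(rng.integers(20, 121))
            else:
                chrom_col.append(ch)
                pos.append(cursor)
                region_id.append("")
            cursor += int(rng.integers(1_000, 20_000))
            u += 1
    probe_ids = [f"cg{i:08d}" for i in range(len(pos))]
    ann = pd.DataFrame({
        "chr": chrom_col,
        "pos": pos,
        "region_id": region_id,
    }, index=pd.Index(probe_ids, name="probe_id"))
    return ann


def _assign_classes(ann: pd.DataFrame, cfg: SimConfig, rng: np.random.Generator):
    """Assign effect classes at feature level (whole regions share a class)."""
    props = np.array([cfg.effect_class_proportions.get(c, 0.0) for c in EFFECT_CLASSES])
    region_ids = [r for r in ann["region_id"].unique() if r]
    features = region_ids + list(ann.index[ann["region_id"] == ""])
    labels = rng.choice(len(EFFECT_CLASSES), size=len(features), p=props)
    feat_class = dict(zip(features, (EFFECT_CLASSES[i] for i in labels)))
    cls = np.empty(len(ann), dtype=object)
    for i, (pid, rid) in enumerate(zip(ann.index, ann["region_id"])):
        cls[i] = feat_class[rid] if rid else feat_class[pid]
    return cls


def _class_slopes(cls, cfg: SimConfig, rng: np.random.Generator):
    m = cfg.slope_magnitude
    n = len(cls)
    sf = np.zeros(n)
    sm = np.zeros(n)
    sign = rng.choice([-1.0, 1.0], size=n)
    sf[cls == "female_only"] = (sign * m)[cls == "female_only"]
    sm[cls == "male_only"] = (sign * m)[cls == "male_only"]
    shared = cls == "shared"
    sf[shared] = (sign * m)[shared]
    sm[shared] = (sign * m)[shared]
    opp = cls == "opposite"
    sf[opp] = (sign * m * cfg.opposite_scale)[opp]
    sm[opp] = (-sign * m * cfg.opposite_scale)[opp]
    return sf, sm


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def generate_dataset(config: SimConfig) -> SimulatedStudy:
    """Generate the full multi-cohort methylation study for one configuration.

    Returns a :class:`SimulatedStudy` with per-cohort betas, detection
    P-values and sample sheets, the probe annotation, the planted-truth
    table, the smoking-probe list and the neuron/glia reference profiles.
    Byte-identical for a fixed ``config.seed``.
    """
    cfg = config
    ss = np.random.SeedSequence(cfg.seed)
    children = ss.spawn(cfg.n_cohorts + 2)
    rng = np.random.default_rng(children[0])

    ann = _build_probe_map(cfg, rng)
    n_probes = len(ann)
    cls = _assign_classes(ann, cfg, rng)
    slope_f, slope_m = _class_slopes(cls, cfg, rng)

    # per-CpG nuisance structure
    base_comp = rng.choice(3, size=n_probes, p=(0.3, 0.2, 0.5))
    baseline = np.choose(base_comp, [rng.normal(-3.0, 0.8, n_probes),
                                     rng.normal(0.0, 0.8, n_probes),
                                     rng.normal(3.0, 0.8, n_probes)])
    age_coef = rng.normal(0.0, cfg.age_slope_sd, n_probes)
    neuron_coef = rng.normal(0.0, cfg.neuron_slope_sd, n_probes)

    # manifest-like columns
    design_type = np.where(rng.random(n_probes) < 0.28, "I", "II")
    island_relation = rng.choice(["island", "shore", "shelf", "opensea"],
                                 size=n_probes, p=(0.3, 0.23, 0.1, 0.37))
    gene_label = np.array([f"GENE{i // 40:04d}" for i in range(n_probes)])
    snp_dist = np.full(n_probes, np.nan)
    snp_maf = np.full(n_probes, np.nan)
    has_snp = rng.random(n_probes) < cfg.frac_snp_probes
    snp_dist[has_snp] = rng.integers(0, 6, has_snp.sum())
    snp_maf[has_snp] = rng.uniform(0.01, 0.5, has_snp.sum())
    # a few annotated SNPs that are too distant / too rare to trigger removal
    far_snp = (~has_snp) & (rng.random(n_probes) < cfg.frac_snp_probes)
    snp_dist[far_snp] = rng.integers(6, 50, far_snp.sum())
    snp_maf[far_snp] = rng.uniform(0.001, 0.5, far_snp.sum())

    ann = ann.assign(design_type=design_type, island_relation=island_relation,
                     gene=gene_label, snp_dist_3p=snp_dist, snp_maf=snp_maf)

    smoking = list(rng.choice(ann.index.values,
                              size=int(cfg.frac_smoking * n_probes), replace=False))

    # CETS-like marker probes: strong neuron/glia separation
    n_markers = min(200, n_probes // 20)
    marker_idx = rng.choice(n_probes, size=n_markers, replace=False)
    marker_delta = rng.choice([-1.0, 1.0], n_markers) * rng.uniform(1.5, 3.0, n_markers)
    neuron_coef[marker_idx] = marker_delta
    cets = pd.DataFrame({
        "neuron": m_to_beta(baseline[marker_idx] + marker_delta),
        "glia": m_to_beta(baseline[marker_idx]),
    }, index=ann.index[marker_idx])

    failing = rng.choice(n_probes, size=int(cfg.frac_failing_probes * n_probes),
                         replace=False)

    region_codes, region_index = pd.factorize(ann["region_id"])
    truth = pd.DataFrame({
        "effect_class": cls,
        "true_slope_female": slope_f,
        "true_slope_male": slope_m,
        "region_id": ann["region_id"].values,
    }, index=ann.index)

    cohorts = []
    braak = np.asarray(cfg.braak_levels)
    for c in range(cfg.n_cohorts):
        crng = np.random.default_rng(children[1 + c])
        nf, nm = cfg.n_female[c], cfg.n_male[c]
        n = nf + nm
        sids = [f"c{c}_s{i:04d}" for i in range(n)]
        sex = np.array(["F"] * nf + ["M"] * nm)
        age = crng.uniform(*cfg.age_range, n)
        bk = crng.choice(braak, size=n)
        nprop = crng.beta(*cfg.neuron_prop_params, n)
        slide = np.array([f"c{c}_sl{i // cfg.samples_per_slide:03d}" for i in range(n)])
        plate = np.array([f"c{c}_p{i // 96:02d}" for i in range(n)])
        conv = np.clip(crng.normal(97.0, 2.0, n), 80.0, 100.0)
        conv = np.maximum(conv, 88.5)
        if cfg.n_low_conversion:
            low = crng.choice(n, size=min(cfg.n_low_conversion, n), replace=False)
            conv[low] = crng.uniform(80.0, 87.0, len(low))
        sheet = pd.DataFrame({
            "sex": sex, "age_at_death": age, "braak": bk, "slide": slide,
            "plate": plate, "bisulfite_conversion": conv, "neuron_prop": nprop,
        }, index=pd.Index(sids, name="sample_id"))

        slope = np.where(sex == "F", slope_f[:, None], slope_m[:, None])
        m = (baseline[:, None]
             + age_coef[:, None] * (age - age.mean())[None, :]
             + neuron_coef[:, None] * (nprop - nprop.mean())[None, :]
             + slope * bk[None, :])
        # slide batch shifts, shared by all probes on a slide per probe
        slides, slide_code = np.unique(slide, return_inverse=True)
        slide_eff = crng.normal(0.0, cfg.batch_effect_sd, (n_probes, len(slides)))
        m += slide_eff[:, slide_code]
        # within-region correlated noise via a shared latent factor
        lam = cfg.region_loading
        indep = crng.normal(0.0, 1.0, (n_probes, n))
        if lam > 0 and len(region_index) > 1:
            latent = crng.normal(0.0, 1.0, (len(region_index), n))
            shared = latent[region_codes]
            in_region = (ann["region_id"].values != "")[:, None]
            noise = np.where(in_region, lam * shared + np.sqrt(1 - lam**2) * indep, indep)
        else:
            noise = indep
        m += cfg.noise_sd * noise
        if cfg.type2_attenuation != 1.0:
            t2 = (design_type == "II")
            m[t2] *= cfg.type2_attenuation

        beta = pd.DataFrame(m_to_beta(m), index=ann.index, columns=sids)
        detp = pd.DataFrame(crng.uniform(0.0, 1e-4, (n_probes, n)),
                            index=ann.index, columns=sids)
        if len(failing):
            detp.iloc[failing] = crng.uniform(0.1, 1.0, (len(failing), n))
        cohorts.append(CohortData(name=f"cohort{c}", beta=beta, detp=detp, samples=sheet))

    return SimulatedStudy(config=cfg, cohorts=cohorts, probes=ann, truth=truth,
                          smoking_probes=smoking, cets_reference=cets,
                          _dosage_seed=int(children[-1].generate_state(1)[0] % (2**31)))


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def generate_genotypes(config: SimConfig, truth: pd.DataFrame,
                       study: SimulatedStudy) -> GenotypeData:
    """Generate imputed-style SNP dosages for the first (largest) cohort.

    ``n_mqtl`` SNPs are linked to random CpGs: their dosage shifts the
    linked CpG's methylation by ``mqtl_effect`` M-units per dosage unit
    (the shift is added to the stored cohort betas in place, so downstream
    scans can recover it). The SNP table carries position, MAF, imputation
    info score and an AD-association P-value so the candidate filters are
    exercisable; a subset of unlinked SNPs is drawn with MAF < 1%.
    """
    cfg = config
    if cfg.n_snps <= 0:
        raise ValueError("n_snps must be positive")
    rng = np.random.default_rng(study._dosage_seed)
    cohort = study.cohorts[0]
    samples = cohort.samples.index
    n = len(samples)

    cpg_pool = truth.index.values
    linked_cpgs = rng.choice(cpg_pool, size=min(cfg.n_mqtl, len(cpg_pool)), replace=False)
    ann = study.probes

    snp_ids, chs, poss, mafs, infos, pads, link_cpg, link_eff = [], [], [], [], [], [], [], []
    for i in range(cfg.n_snps):
        sid = f"rs{i:06d}"
        snp_ids.append(sid)
        if i < len(linked_cpgs):
            cpg = linked_cpgs[i]
            chs.append(ann.loc[cpg, "chr"])
            poss.append(int(ann.loc[cpg, "pos"] + rng.integers(-400_000, 400_000)))
            mafs.append(float(rng.uniform(0.05, 0.45)))
            infos.append(float(rng.uniform(0.8, 1.0)))
            pads.append(float(rng.uniform(1e-4, 0.049)))
            link_cpg.append(cpg)
            link_eff.append(cfg.mqtl_effect)
        else:
            chs.append(f"chr{int(rng.integers(1, 23))}")
            poss.append(int(rng.integers(1, 5_000_000)))
            mafs.append(float(10 ** rng.uniform(-2.7, np.log10(0.5))))
            infos.append(float(rng.uniform(0.2, 1.0)))
            pads.append(float(rng.uniform(0.0, 1.0)))
            link_cpg.append("")
            link_eff.append(0.0)
    snps = pd.DataFrame({"chr": chs, "pos": poss, "maf": mafs, "info": infos,
                         "p_AD": pads}, index=pd.Index(snp_ids, name="snp_id"))
    snp_truth = pd.DataFrame({"linked_cpg": link_cpg, "effect": link_eff},
                             index=snps.index)

    p = np.clip(np.array(mafs), 1e-3, 0.5)
    hard = rng.binomial(2, p[:, None], (cfg.n_snps, n)).astype(float)
    dosage = np.clip(hard + rng.normal(0.0, 0.05, hard.shape), 0.0, 2.0)
    dosage = pd.DataFrame(dosage, index=snps.index, columns=samples)

    # plant dosage effects into the stored cohort methylation (M scale)
    from sexewas.preprocess import beta_to_m
    m = beta_to_m(cohort.beta)
    for sid, cpg, eff in zip(snp_truth.index, link_cpg, link_eff):
        if cpg and eff:
            m.loc[cpg] = m.loc[cpg] + eff * dosage.loc[sid].values
    cohort.beta = pd.DataFrame(m_to_beta(m.values), index=m.index, columns=m.columns)

    x = dosage.values.T - dosage.values.T.mean(axis=0)
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    pcs = pd.DataFrame(u[:, :3] * s[:3], index=samples, columns=["PC1", "PC2", "PC3"])
    return GenotypeData(dosage=dosage, snps=snps, pcs=pcs, truth=snp_truth)


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

def generate_expression(config: SimConfig, truth: pd.DataFrame,
                        study: SimulatedStudy) -> ExpressionData:
    """FPKM-scale expression for the first cohort with planted eQTM effects.

    ``n_eqtm`` genes are placed with their TSS near a linked CpG; their
    log2(FPKM + 1) is linear in that CpG's methylation (slope
    ``eqtm_effect``) plus an age effect and noise. The five CNS cell-type
    marker genes (ENO2, GFAP, CD68, OLIG2, CD34) are present by name.
    """
    cfg = config
    rng = np.random.default_rng((study._dosage_seed + 7_919) % (2**31))
    cohort = study.cohorts[0]
    samples = cohort.samples.index
    n = len(samples)
    ann = study.probes

    n_named = len(MARKER_GENES)
    n_other = max(cfg.n_genes - n_named, cfg.n_eqtm)
    gene_names = list(MARKER_GENES) + [f"GENE{i:04d}" for i in range(n_other)]

    cpg_pool = truth.index.values
    anchor = rng.choice(cpg_pool, size=len(gene_names), replace=len(cpg_pool) < len(gene_names))
    tss = ann.loc[anchor, "pos"].values + rng.integers(-2_000, 2_001, len(gene_names))
    genes = pd.DataFrame({
        "chr": ann.loc[anchor, "chr"].values,
        "tss": tss,
        "strand": rng.choice(["+", "-"], len(gene_names)),
    }, index=pd.Index(gene_names, name="gene"))

    linked = {}
    eqtm_genes = [g for g in gene_names[n_named:n_named + cfg.n_eqtm]]
    for g, cpg in zip(eqtm_genes, anchor[n_named:n_named + cfg.n_eqtm]):
        if cpg not in truth.index:
            raise ValueError(f"missing linked CpG {cpg}")
        linked[g] = cpg
    gene_truth = pd.DataFrame({
        "linked_cpg": [linked.get(g, "") for g in gene_names],
        "effect": [cfg.eqtm_effect if g in linked else 0.0 for g in gene_names],
    }, index=genes.index)

    from sexewas.preprocess import beta_to_m
    m = beta_to_m(cohort.beta)
    age = cohort.samples["age_at_death"].values
    log_expr = np.empty((len(gene_names), n))
    base = rng.uniform(1.0, 6.0, len(gene_names))
    age_eff = rng.normal(0.0, 0.005, len(gene_names))
    for i, g in enumerate(gene_names):
        mu = base[i] + age_eff[i] * (age - age.mean())
        if g in linked:
            mv = m.loc[linked[g]].values
            mu = mu + cfg.eqtm_effect * (mv - mv.mean())
        log_expr[i] = mu + rng.normal(0.0, cfg.expression_noise_sd, n)
    log_expr = np.maximum(log_expr, 0.0)
    expr = pd.DataFrame(np.exp2(log_expr) - 1.0, index=genes.index, columns=samples)
    return ExpressionData(expr=expr, genes=genes, truth=gene_truth)
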