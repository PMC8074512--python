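"""Configuration-driven orchestration of the full analysis.

Stages run in a fixed order: simulate -> preprocess (per cohort) ->
cohort models (CpG + region) -> inflation correction + meta-analysis ->
discovery (BH + stagewise) -> enrichment -> integrative QTL. Each stage
writes its TSV outputs into the result directory, a manifest lists every
produced file, and a log records per-stage feature/sample counts.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from sexewas import cohort as cm
from sexewas import discovery as disc
from sexewas import enrichment as enr
from sexewas import integrate as integ
from sexewas import io as sio
from sexewas import meta as meta_mod
from sexewas import preprocess as pp
from sexewas import simulate as sim

logger = logging.getLogger("sexewas")


@dataclass
class PipelineConfig:
    """All stage toggles, thresholds and seeds for one pipeline run."""

    outdir: str = "sexewas_run"
    seed: int = 0
    # simulation
    n_cpgs: int = 20_000
    n_female: tuple = (385, 109, 84, 64)
    n_male: tuple = (233, 66, 50, 39)
    sim_overrides: dict = field(default_factory=dict)
    # stage toggles
    do_preprocess: bool = True
    do_normalize: bool = True       # QN + BMIQ (skippable for clean simulated input)
    do_regions: bool = True
    do_enrichment: bool = True
    do_integration: bool = True
    # thresholds (defaults are the study's)
    det_threshold: float = 0.01
    conv_min: float = 88.0
    pca_sd_limit: float = 3.0
    max_gap: int = 200
    rdrop_min: float = 0.4
    alpha: float = 0.05
    gsea_fdr: float = 0.25
    mqtl_window: int = 500_000
    maf_min: float = 0.01
    info_min: float = 0.4

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.n_female = tuple(cfg.n_female)
        cfg.n_male = tuple(cfg.n_male)
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["n_female"] = list(self.n_female)
        data["n_male"] = list(self.n_male)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)


def preprocess_cohort(cohort: sim.CohortData, study: sim.SimulatedStudy,
                      cfg: PipelineConfig):
    """QC -> (optional QN+BMIQ) -> M-values -> slide residualization."""
    beta, qc_p = pp.filter_probes(cohort.beta, cohort.detp, study.probes,
                                  study.smoking_probes,
                                  det_threshold=cfg.det_threshold)
    beta, sheet, qc_s = pp.filter_samples(beta, cohort.samples,
                                          conv_min=cfg.conv_min,
                                          sd_limit=cfg.pca_sd_limit)
    if cfg.do_normalize:
        beta = pp.quantile_normalize(beta)
        beta = pp.bmiq(beta, study.probes["design_type"])
    sheet = sheet.copy()
    sheet["neuron_prop"] = pp.estimate_neuron_proportion(beta, study.cets_reference)
    m = pd.DataFrame(pp.beta_to_m(beta.values), index=beta.index, columns=beta.columns)
    resid = pp.residualize(m, sheet[["slide"]])
    qc = {"probes": qc_p.as_dict(), "samples": qc_s.as_dict()}
    return resid, sheet, qc


def run(config: PipelineConfig) -> Path:
    """Execute the full pipeline; returns the result directory."""
    cfg = config
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    cfg.to_yaml(out / "config.yaml")
    manifest = [str(out / "config.yaml")]
    counts = {}

    sim_kwargs = dict(n_cpgs=cfg.n_cpgs, n_female=cfg.n_female,
                      n_male=cfg.n_male, seed=cfg.seed)
    sim_kwargs.update(cfg.sim_overrides)
    scfg = sim.SimConfig(**sim_kwargs)
    study = sim.generate_dataset(scfg)
    geno = sim.generate_genotypes(scfg, study.truth, study) if cfg.do_integration else None
    expr = sim.generate_expression(scfg, study.truth, study) if cfg.do_integration else None
    logger.info("simulated %d cohorts, %d probes", len(study.cohorts), len(study.probes))

    # --- per-cohort preprocessing and models ------------------------------
    per_cohort = {}
    cohort_stats = {a: [] for a in cm.ANALYSES}
    region_stats = {a: [] for a in cm.ANALYSES}
    region_lists = {}
    for c in study.cohorts:
        if cfg.do_preprocess:
            resid, sheet, qc = preprocess_cohort(c, study, cfg)
        else:
            sheet = c.samples
            m = pd.DataFrame(pp.beta_to_m(c.beta.values), index=c.beta.index,
                             columns=c.beta.columns)
            resid = pp.residualize(m, sheet[["slide"]])
            qc = {}
        per_cohort[c.name] = (resid, sheet)
        counts[c.name] = {"probes": resid.shape[0], "samples": resid.shape[1], "qc": qc}
        cohort_stats["female"].append(cm.fit_stratified(resid, sheet, "F", cohort=c.name))
        cohort_stats["male"].append(cm.fit_stratified(resid, sheet, "M", cohort=c.name))
        cohort_stats["interaction"].append(cm.fit_interaction(resid, sheet, cohort=c.name))
        if cfg.do_regions:
            base = cm.define_regions(study.probes.loc[resid.index],
                                     max_gap=cfg.max_gap)
            kept = []
            for r in base:
                r["name"] = cm.region_name(r)
                s = cm.select_comethylated(resid, r, rdrop_min=cfg.rdrop_min)
                if s is not None:
                    kept.append(s)
            region_lists[c.name] = kept
            for a in cm.ANALYSES:
                region_stats[a].append(cm.fit_region(resid, kept, sheet, a, cohort=c.name))
    logger.info("cohort models done")

    # --- inflation correction + meta-analysis -----------------------------
    meta_tables = {}
    inflation_rows = []
    for level, stats_by_a in (("cpg", cohort_stats), ("region", region_stats)):
        if not any(len(v) for v in stats_by_a.values()):
            continue
        for a in cm.ANALYSES:
            tabs = stats_by_a[a]
            if not tabs:
                continue
            mrow, infl = meta_mod.combine_cohort_tables(tabs, seed=cfg.seed)
            infl["analysis"] = a
            infl["level"] = level
            inflation_rows.append(infl)
            meta_tables[(level, a)] = mrow
            sio.write_table(mrow, out / f"meta_{level}_{a}.tsv.gz")
            manifest.append(str(out / f"meta_{level}_{a}.tsv.gz"))
    inflation = pd.concat(inflation_rows, ignore_index=True)
    sio.write_table(inflation, out / "inflation.tsv", index=False)
    manifest.append(str(out / "inflation.tsv"))

    # --- discovery --------------------------------------------------------
    discoveries = {}
    stagewise_tables = {}
    for level in ("cpg", "region"):
        if (level, "female") not in meta_tables:
            continue
        mf = meta_tables[(level, "female")]
        mm = meta_tables[(level, "male")]
        mi = meta_tables[(level, "interaction")]
        common = mf.index.intersection(mm.index).intersection(mi.index)
        mf, mm, mi = mf.loc[common], mm.loc[common], mi.loc[common]
        for a, tab in (("female", mf), ("male", mm)):
            dset = disc.discovery_set(tab, threshold=cfg.alpha, label=f"{level}_{a}")
            discoveries[(level, a)] = dset
            sio.write_table(dset, out / f"discovery_{level}_{a}.tsv")
            manifest.append(str(out / f"discovery_{level}_{a}.tsv"))
        sw = disc.stagewise(mf["p_final"].values, mm["p_final"].values,
                            mi["p_final"].values, alpha=cfg.alpha)
        sw.index = common
        stagewise_tables[level] = sw
        sio.write_table(sw, out / f"stagewise_{level}.tsv.gz")
        manifest.append(str(out / f"stagewise_{level}.tsv.gz"))
        counts[f"discovery_{level}"] = {
            "female": int(len(discoveries[(level, "female")])),
            "male": int(len(discoveries[(level, "male")])),
            "interaction_confirmed": int(sw["confirm_interaction"].sum()),
        }
    logger.info("discovery done")

    # --- enrichment -------------------------------------------------------
    if cfg.do_enrichment and ("cpg", "female") in discoveries:
        ann = study.probes
        bg = ann.index
        rows = []
        for sexname in ("female", "male"):
            dset = discoveries[("cpg", sexname)]
            for direction, sel in (("hyper", dset["direction"] > 0),
                                   ("hypo", dset["direction"] < 0)):
                fg = dset.index[sel]
                if len(fg) == 0:
                    continue
                fisher = enr.fisher_enrichment(fg, bg, ann["island_relation"])
                fisher["analysis"] = sexname
                fisher["direction"] = direction
                rows.append(fisher.reset_index())
        if rows:
            sio.write_table(pd.concat(rows, ignore_index=True),
                            out / "enrichment_features.tsv", index=False)
            manifest.append(str(out / "enrichment_features.tsv"))
        # gene linking + de-biased ranking (GSEA needs external gene sets)
        genes = sim.generate_expression(scfg, study.truth, study).genes \
            if expr is None else expr.genes
        feats = ann[["chr", "pos"]]
        links = enr.great_assign(feats, genes)
        if len(links):
            for sexname in ("female", "male"):
                ptab = meta_tables[("cpg", sexname)]["p_final"]
                scores = enr.gene_scores(links, ptab)
                try:
                    ranked = enr.gam_debias(scores)
                    sio.write_table(ranked, out / f"gene_ranking_{sexname}.tsv")
                    manifest.append(str(out / f"gene_ranking_{sexname}.tsv"))
                except ValueError:
                    pass
        logger.info("enrichment done")

    # --- integrative QTL --------------------------------------------------
    if cfg.do_integration and ("cpg", "female") in discoveries:
        c0 = study.cohorts[0]
        _, sheet0 = per_cohort[c0.name]
        common = sheet0.index
        m0 = pd.DataFrame(pp.beta_to_m(c0.beta.values), index=c0.beta.index,
                          columns=c0.beta.columns)[common]
        meth_res = integ.residualize_methylation(m0, sheet0)
        expr_res = integ.residualize_expression(expr.expr[common], sheet0)
        sig = discoveries[("cpg", "female")].index.union(
            discoveries[("cpg", "male")].index)
        links = enr.great_assign(study.probes.loc[study.probes.index.isin(sig),
                                                  ["chr", "pos"]], expr.genes)
        eq = integ.eqtm_scan(expr_res, meth_res[common], sheet0["braak"], links)
        sio.write_table(eq, out / "eqtm.tsv", index=False)
        manifest.append(str(out / "eqtm.tsv"))
        # mQTL: candidates per significant CpG
        pair_rows = []
        for f in sig:
            cand = integ.mqtl_candidate_filter(
                geno.snps, study.probes.loc[f, "chr"],
                int(study.probes.loc[f, "pos"]), window=cfg.mqtl_window,
                maf_min=cfg.maf_min, info_min=cfg.info_min)
            for snp in cand.index:
                pair_rows.append({"feature_id": f, "snp_id": snp})
        pairs = pd.DataFrame(pair_rows, columns=["feature_id", "snp_id"])
        for sexname in ("F", "M"):
            if len(pairs):
                mq = integ.mqtl_scan(meth_res[common], geno.dosage[common],
                                     sheet0, geno.pcs, pairs, sexname)
            else:
                mq = pd.DataFrame(columns=["feature_id", "snp_id", "slope", "se", "p", "q"])
            sio.write_table(mq, out / f"mqtl_{sexname}.tsv", index=False)
            manifest.append(str(out / f"mqtl_{sexname}.tsv"))
        logger.info("integration done")

    with open(out / "manifest.json", "w") as fh:
        json.dump({"files": manifest, "counts": counts}, fh, indent=2, default=str)
    return out
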