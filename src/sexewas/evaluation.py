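"""Replicate studies scoring the pipeline against planted ground truth.

These helpers run the modeling chain (QC -> M-values -> slide
residualization -> stratified/interaction models -> empirical-null
correction -> meta-analysis -> discovery) on simulated studies and score
recovery, false-discovery and family-wise error rates against the
generator's truth labels. Quantile/BMIQ normalization is skipped here:
simulated arrays carry no between-sample distributional shifts, so the
normalization stage is a no-op by construction and only costs time (it is
exercised separately by its own contract tests).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from sexewas import cohort as cm
from sexewas import discovery as disc
from sexewas import meta as mt
from sexewas import preprocess as pp
from sexewas import simulate as sim


def run_modelled_meta(cfg: sim.SimConfig, *, qc: bool = True,
                      correct: bool = True) -> dict:
    """Simulate one study and return CpG-level meta tables plus the truth.

    Returns a dict with keys 'female', 'male', 'interaction' (MetaRow
    tables on a common feature index) and 'truth'.
    """
    study = sim.generate_dataset(cfg)
    tabs = {a: [] for a in cm.ANALYSES}
    for c in study.cohorts:
        beta, sheet = c.beta, c.samples
        if qc:
            beta, _ = pp.filter_probes(beta, c.detp, study.probes,
                                       study.smoking_probes)
            beta, sheet, _ = pp.filter_samples(beta, sheet)
            sheet = sheet.copy()
            sheet["neuron_prop"] = pp.estimate_neuron_proportion(
                beta, study.cets_reference)
        m = pd.DataFrame(pp.beta_to_m(beta.values), index=beta.index,
                         columns=beta.columns)
        resid = pp.residualize(m, sheet[["slide"]])
        tabs["female"].append(cm.fit_stratified(resid, sheet, "F", cohort=c.name))
        tabs["male"].append(cm.fit_stratified(resid, sheet, "M", cohort=c.name))
        tabs["interaction"].append(cm.fit_interaction(resid, sheet, cohort=c.name))
    out = {}
    for a in cm.ANALYSES:
        out[a] = mt.combine_cohort_tables(tabs[a], correct=correct,
                                          seed=cfg.seed)[0]
    common = out["female"].index
    for a in ("male", "interaction"):
        common = common.intersection(out[a].index)
    for a in cm.ANALYSES:
        out[a] = out[a].loc[common]
    out["truth"] = study.truth
    return out


def score_replicate(res: dict, *, alpha: float = 0.05) -> dict:
    """Score one replicate's discovery behavior against planted truth."""
    truth = res["truth"]
    mf, mm, mi = res["female"], res["male"], res["interaction"]
    df = disc.discovery_set(mf, threshold=alpha)
    dm = disc.discovery_set(mm, threshold=alpha)
    sw = disc.stagewise(mf["p_final"].values, mm["p_final"].values,
                        mi["p_final"].values, alpha=alpha)
    sw.index = mf.index

    cls = truth["effect_class"]
    nulls = truth.index[cls == "null"]
    f_only = truth.index[cls == "female_only"]
    opposite = truth.index[cls == "opposite"]
    either = df.index.union(dm.index)
    confirmed_int = sw.index[sw["confirm_interaction"]]
    any_confirm = sw.index[sw[[f"confirm_{h}" for h in disc.HYPOTHESES]].any(axis=1)]

    n_f = len(df)
    fdp_f = float(np.isin(df.index, nulls).sum() / n_f) if n_f else 0.0
    n_m = len(dm)
    fdp_m = float(np.isin(dm.index, nulls).sum() / n_m) if n_m else 0.0
    return {
        "n_female": n_f,
        "n_male": n_m,
        "fdp_female": fdp_f,
        "fdp_male": fdp_m,
        "sens_female_only": float(np.isin(f_only, df.index).mean()) if len(f_only) else np.nan,
        "sens_interaction_opposite": float(np.isin(opposite, confirmed_int).mean()) if len(opposite) else np.nan,
        "opposite_in_neither_stratified": float((~np.isin(opposite, either)).mean()) if len(opposite) else np.nan,
        "false_confirm_rate": float(np.isin(any_confirm, nulls).sum() / max(len(nulls), 1)),
        "any_false_confirmation": bool(np.isin(any_confirm, nulls).any()),
    }


def allnull_config(n_cpgs: int = 5000, seed: int = 0) -> sim.SimConfig:
    """Default study conditions with every planted slope set to zero."""
    props = {"null": 1.0, "female_only": 0.0, "male_only": 0.0,
             "shared": 0.0, "opposite": 0.0}
    return sim.SimConfig(n_cpgs=n_cpgs, effect_class_proportions=props, seed=seed)


def error_rate_study(n_reps: int = 50, n_cpgs: int = 5000, *,
                     seed: int = 0, alpha: float = 0.05) -> dict:
    """All-null replicate study: empirical BH FDR and stagewise FWER.

    Under the global null every discovery is false, so the per-replicate
    false-discovery proportion is 1 when anything is selected and 0
    otherwise; the empirical FDR is its mean. The stagewise FWER is the
    fraction of replicates with any false confirmation.
    """
    fdps, fwer = [], []
    for r in range(n_reps):
        cfg = allnull_config(n_cpgs=n_cpgs, seed=seed + r)
        res = run_modelled_meta(cfg)
        sc = score_replicate(res, alpha=alpha)
        fdps.append(1.0 if sc["n_female"] else 0.0)
        fwer.append(1.0 if sc["any_false_confirmation"] else 0.0)
    fdps, fwer = np.array(fdps), np.array(fwer)
    return {
        "empirical_fdr": float(fdps.mean()),
        "fdr_mc_se": float(fdps.std(ddof=1) / np.sqrt(n_reps)),
        "stagewise_fwer": float(fwer.mean()),
        "fwer_mc_se": float(fwer.std(ddof=1) / np.sqrt(n_reps)),
        "n_reps": n_reps,
    }


def recovery_study(n_reps: int = 10, n_cpgs: int = 5000, *,
                   seed: int = 0, alpha: float = 0.05) -> dict:
    """Planted-effect replicate study at the default study conditions."""
    rows = []
    for r in range(n_reps):
        cfg = sim.SimConfig(n_cpgs=n_cpgs, seed=seed + r)
        rows.append(score_replicate(run_modelled_meta(cfg), alpha=alpha))
    tab = pd.DataFrame(rows)
    return {
        "sens_female_only": float(tab["sens_female_only"].mean()),
        "fdp_female": float(tab["fdp_female"].mean()),
        "sens_interaction_opposite": float(tab["sens_interaction_opposite"].mean()),
        "opposite_in_neither_stratified": float(tab["opposite_in_neither_stratified"].mean()),
        "reps_majority_neither": float((tab["opposite_in_neither_stratified"] > 0.5).mean()),
        "n_reps": n_reps,
    }
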