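"""Integration of methylation with expression (eQTM) and genotype (mQTL).

Methylation M-values are residualized on neuron proportion, batch, plate
and age; expression log2(FPKM+1) on age plus the expression of five CNS
cell-type marker genes (ENO2, GFAP, CD68, OLIG2, CD34). For every linked
(feature, gene) pair, expression residuals are regressed on methylation
residuals plus Braak stage. cis-mQTL scans regress methylation residuals
on SNP dosage plus batch and the first three genotype PCs, separately per
sex, over candidate SNPs passing window/MAF/info/AD-association filters.
BH-FDR families are (scan x sex), never pooled across sexes.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from sexewas.discovery import bh_adjust
from sexewas.preprocess import design_matrix, residualize
from sexewas.simulate import MARKER_GENES


def residualize_methylation(m: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Methylation residuals: M ~ neuron_prop + batch + plate + age."""
    cov = pd.DataFrame({
        "neuron_prop": sheet["neuron_prop"],
        "batch": sheet["slide"].astype(str) if "batch" not in sheet else sheet["batch"].astype(str),
        "plate": sheet["plate"].astype(str),
        "age_at_death": sheet["age_at_death"],
    }, index=sheet.index).loc[m.columns]
    # batch may be nested in plate (or vice versa); residuals are still
    # well-defined, so a rank-deficient design is tolerated here
    return residualize(m, cov, allow_singular=True)


def residualize_expression(expr_fpkm: pd.DataFrame, sheet: pd.DataFrame) -> pd.DataFrame:
    """Expression residuals: log2(FPKM+1) ~ age + cell-type marker genes.

    The marker-gene covariates are the log2(FPKM+1) values of ENO2, GFAP,
    CD68, OLIG2 and CD34 in the same matrix; all five must be present.
    """
    missing = [g for g in MARKER_GENES if g not in expr_fpkm.index]
    if missing:
        raise ValueError(f"missing cell-type marker genes: {missing}")
    logx = np.log2(expr_fpkm + 1.0)
    cov = pd.DataFrame({"age_at_death": sheet.loc[logx.columns, "age_at_death"]})
    for g in MARKER_GENES:
        cov[g] = logx.loc[g].values
    return residualize(logx, cov)


def _pairwise_ols(y: np.ndarray, x_main: np.ndarray, x_other: np.ndarray):
    """OLS of y on [1, x_main, x_other...]; returns main slope, se, p."""
    n = len(y)
    x = np.column_stack([np.ones(n), x_main] + ([x_other] if x_other.ndim == 1 else list(x_other.T)))
    coef, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ coef
    df = n - x.shape[1]
    sigma2 = (resid ** 2).sum() / df
    xtx_inv = np.linalg.pinv(x.T @ x)
    se = np.sqrt(sigma2 * xtx_inv[1, 1])
    t = coef[1] / se
    p = 2 * stats.t.sf(abs(t), df)
    return coef[1], se, p


def eqtm_scan(expr_resid: pd.DataFrame, meth_resid: pd.DataFrame,
              braak: pd.Series, links: pd.DataFrame) -> pd.DataFrame:
    """Association of expression residuals with methylation residuals per link.

    ``links`` has columns gene and feature_id (from the regulatory-domain
    assignment). The model is expression residual ~ methylation residual +
    Braak stage; the methylation coefficient is reported with BH q-values
    over all tested pairs.
    """
    if not expr_resid.columns.equals(meth_resid.columns):
        raise ValueError("expression and methylation samples are not aligned")
    bk = braak.loc[expr_resid.columns].values.astype(float)
    rows = []
    for _, row in links.iterrows():
        g, f = row["gene"], row["feature_id"]
        if g not in expr_resid.index or f not in meth_resid.index:
            continue
        slope, se, p = _pairwise_ols(expr_resid.loc[g].values,
                                     meth_resid.loc[f].values, bk)
        rows.append({"gene": g, "feature_id": f, "slope": slope, "se": se, "p": p})
    out = pd.DataFrame(rows, columns=["gene", "feature_id", "slope", "se", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].values)
    else:
        out["q"] = []
    return out


def mqtl_candidate_filter(snps: pd.DataFrame, feature_chr: str,
                          feature_start: int, feature_end: int | None = None, *,
                          window: int = 500_000, maf_min: float = 0.01,
                          info_min: float = 0.4, p_ad_max: float = 0.05) -> pd.DataFrame:
    """cis-candidate SNPs for one feature.

    Keeps SNPs on the feature's chromosome within ``window`` bp of its
    start/end (CpGs: position only), with MAF >= ``maf_min``, info score
    >= ``info_min`` and AD-association P < ``p_ad_max``. All boundaries
    inclusive except the AD P-value, which is strict.
    """
    if feature_end is None:
        feature_end = feature_start
    s = snps
    near = ((s["chr"] == feature_chr)
            & (s["pos"] >= feature_start - window)
            & (s["pos"] <= feature_end + window))
    keep = near & (s["maf"] >= maf_min) & (s["info"] >= info_min) & (s["p_AD"] < p_ad_max)
    return s.loc[keep]


def mqtl_scan(meth_resid: pd.DataFrame, dosage: pd.DataFrame,
              sheet: pd.DataFrame, pcs: pd.DataFrame,
              pairs: pd.DataFrame, sex: str) -> pd.DataFrame:
    """Per-(feature, SNP) mQTL model within one sex.

    ``pairs`` has columns feature_id and snp_id (candidates from
    :func:`mqtl_candidate_filter`). The model is methylation residual ~
    dosage + batch + PC1 + PC2 + PC3 restricted to samples of ``sex``;
    BH q-values are computed within this sex's scan.
    """
    sex = {"F": "F", "female": "F", "M": "M", "male": "M"}[sex]
    samples = meth_resid.columns
    sheet = sheet.loc[samples]
    mask = (sheet["sex"] == sex).values
    cols = samples[mask]
    batch_col = "batch" if "batch" in sheet else "slide"
    cov = pd.concat([pd.get_dummies(sheet.loc[cols, batch_col].astype(str),
                                    prefix="batch", drop_first=True).astype(float),
                     pcs.loc[cols, ["PC1", "PC2", "PC3"]]], axis=1)
    other = cov.values
    if np.linalg.matrix_rank(np.column_stack([np.ones(len(cols)), other])) < other.shape[1] + 1:
        raise ValueError("collinear batch/PC covariates")
    rows = []
    for _, pr in pairs.iterrows():
        f, snp = pr["feature_id"], pr["snp_id"]
        if f not in meth_resid.index or snp not in dosage.index:
            continue
        y = meth_resid.loc[f, cols].values.astype(float)
        d = dosage.loc[snp, cols].values.astype(float)
        slope, se, p = _pairwise_ols(y, d, other)
        rows.append({"feature_id": f, "snp_id": snp, "slope": slope,
                     "se": se, "p": p})
    out = pd.DataFrame(rows, columns=["feature_id", "snp_id", "slope", "se", "p"])
    if len(out):
        out["q"] = bh_adjust(out["p"].values)
    else:
        out["q"] = []
    out.attrs["sex"] = sex
    return out
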