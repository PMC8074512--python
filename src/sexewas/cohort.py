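"""Per-cohort association statistics for sex-specific methylation analysis.

Two complementary models are fitted per feature (CpG or co-methylated
region) on slide-residualized M-values:

- sex-stratified:  residual ~ age_at_death + braak + neuron_prop, fitted to
  one sex at a time; the Braak coefficient is reported.
- sex-by-Braak interaction:  residual ~ age + sex + braak + sex:braak +
  sex:age + neuron_prop with female as the reference sex, so the reported
  sex:braak coefficient is the male-minus-female Braak slope.

Region-level statistics apply the same models to the per-sample median of
member-probe residuals, after co-methylation selection of contiguous probe
clusters.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

ANALYSES = ("female", "male", "interaction")


def _ols_many(x: np.ndarray, y: np.ndarray, coef_idx: int) -> pd.DataFrame:
    """OLS of many responses on one design; report one coefficient per response.

    ``x`` is n x p, ``y`` is n x m. Returns estimate, se, t, df, p for the
    column ``coef_idx`` of the design, with two-sided t-based P-values.
    """
    n, p = x.shape
    if n <= p + 1:
        raise ValueError("too few samples for the design")
    xtx = x.T @ x
    xtx_inv = np.linalg.inv(xtx)
    coef = xtx_inv @ (x.T @ y)
    resid = y - x @ coef
    df = n - p
    sigma2 = (resid ** 2).sum(axis=0) / df
    se = np.sqrt(sigma2 * xtx_inv[coef_idx, coef_idx])
    est = coef[coef_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = est / se
    pval = 2.0 * stats.t.sf(np.abs(t), df)
    return pd.DataFrame({"estimate": est, "se": se, "t": t,
                         "df": float(df), "p": pval})


def _stratified_design(sheet: pd.DataFrame) -> np.ndarray:
    return np.column_stack([
        np.ones(len(sheet)),
        sheet["age_at_death"].values.astype(float),
        sheet["braak"].values.astype(float),
        sheet["neuron_prop"].values.astype(float),
    ])


def fit_stratified(resid: pd.DataFrame, sheet: pd.DataFrame, sex: str,
                   cohort: str = "") -> pd.DataFrame:
    """Braak-stage association per feature within one sex.

    ``sex`` is "F"/"female" or "M"/"male". Returns a table indexed by
    feature with columns (estimate, se, t, df, p) plus cohort/analysis
    labels; the estimate is the Braak coefficient in M-units per stage.
    """
    sex = {"F": "F", "female": "F", "M": "M", "male": "M"}[sex]
    sheet = sheet.loc[resid.columns]
    mask = (sheet["sex"] == sex).values
    sub = sheet.loc[mask]
    if sub["braak"].nunique() < 2:
        raise ValueError("Braak stage is constant within this sex")
    x = _stratified_design(sub)
    y = resid.values[:, mask].T
    out = _ols_many(x, y, coef_idx=2)
    out.index = resid.index
    out.insert(0, "analysis", "female" if sex == "F" else "male")
    out.insert(0, "cohort", cohort)
    return out


def fit_interaction(resid: pd.DataFrame, sheet: pd.DataFrame,
                    cohort: str = "") -> pd.DataFrame:
    """Sex-by-Braak interaction per feature using both sexes jointly.

    Female is the reference sex, so the reported coefficient is the
    difference in Braak slope (male minus female).
    """
    sheet = sheet.loc[resid.columns]
    sexes = set(sheet["sex"])
    if sexes != {"F", "M"}:
        raise ValueError("interaction model requires both sexes")
    male = (sheet["sex"] == "M").values.astype(float)
    age = sheet["age_at_death"].values.astype(float)
    braak = sheet["braak"].values.astype(float)
    x = np.column_stack([
        np.ones(len(sheet)), age, male, braak,
        male * braak, male * age,
        sheet["neuron_prop"].values.astype(float),
    ])
    out = _ols_many(x, resid.values.T, coef_idx=4)
    out.index = resid.index
    out.insert(0, "analysis", "interaction")
    out.insert(0, "cohort", cohort)
    return out


# ---------------------------------------------------------------------------
# contiguous probe clusters and co-methylated regions
# ---------------------------------------------------------------------------

def define_regions(annot: pd.DataFrame, *, max_gap: int = 200,
                   min_probes: int = 3) -> list:
    """Cluster position-sorted probes into contiguous genomic regions.

    A region is a maximal run of probes on one chromosome in which every
    gap between consecutive probes is <= ``max_gap`` bp (boundary
    inclusive); runs shorter than ``min_probes`` are dropped. Returns a
    list of dicts with chr, start, end (1-based inclusive) and the
    position-ordered member probe ids.
    """
    regions = []
    for ch, grp in annot.groupby("chr", sort=True):
        grp = grp.sort_values("pos")
        pos = grp["pos"].values
        if len(np.unique(pos)) != len(pos):
            raise ValueError(f"duplicate probe positions on {ch}")
        breaks = np.where(np.diff(pos) > max_gap)[0]
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks + 1, [len(pos)]])
        for s, e in zip(starts, ends):
            if e - s >= min_probes:
                members = list(grp.index[s:e])
                regions.append({"chr": ch, "start": int(pos[s]),
                                "end": int(pos[e - 1]), "probes": members})
    return regions


def select_comethylated(resid: pd.DataFrame, region: dict, *,
                        rdrop_min: float = 0.4) -> dict | None:
    """Keep the co-methylated core of a contiguous probe cluster.

    For each member probe the leave-one-out correlation with the mean of
    the remaining members is computed; probes below ``rdrop_min`` are
    dropped (zero-variance probes count as correlation 0) and the largest
    surviving contiguous sub-run of >= 3 probes is returned, or None.
    """
    members = [p for p in region["probes"] if p in resid.index]
    if len(members) < 3:
        return None
    x = resid.loc[members].values
    k = len(members)
    total = x.sum(axis=0)
    keep = np.zeros(k, dtype=bool)
    for i in range(k):
        rest_mean = (total - x[i]) / (k - 1)
        if x[i].std() < 1e-12 or rest_mean.std() < 1e-12:
            r = 0.0
        else:
            r = float(np.corrcoef(x[i], rest_mean)[0, 1])
        keep[i] = r >= rdrop_min
    # largest contiguous run of retained probes
    best_s = best_len = 0
    s = None
    for i in range(k + 1):
        if i < k and keep[i]:
            if s is None:
                s = i
        else:
            if s is not None and i - s > best_len:
                best_s, best_len = s, i - s
            s = None
    if best_len < 3:
        return None
    sel = members[best_s:best_s + best_len]
    pos = {p: i for i, p in enumerate(region["probes"])}
    return {"chr": region["chr"], "start": None, "end": None, "probes": sel,
            "parent": region.get("name"), "member_rank": [pos[p] for p in sel]}


def region_medians(resid: pd.DataFrame, regions: list) -> pd.DataFrame:
    """Per-sample median of member-probe residuals, one row per region."""
    if not regions:
        raise ValueError("empty region list")
    rows = []
    names = []
    for r in regions:
        members = [p for p in r["probes"] if p in resid.index]
        rows.append(np.median(resid.loc[members].values, axis=0))
        names.append(region_name(r))
    return pd.DataFrame(rows, index=pd.Index(names, name="region"),
                        columns=resid.columns)


def region_name(region: dict) -> str:
    chrom = region.get("chr", "chr?")
    probes = region["probes"]
    return f"{chrom}:{probes[0]}..{probes[-1]}" if region.get("start") is None \
        else f"{chrom}:{region['start']}-{region['end']}"


def fit_region(resid: pd.DataFrame, regions: list, sheet: pd.DataFrame,
               analysis: str, cohort: str = "") -> pd.DataFrame:
    """Apply the single-CpG models to region median residuals.

    ``analysis`` is "female", "male" or "interaction".
    """
    med = region_medians(resid, regions)
    if analysis == "interaction":
        return fit_interaction(med, sheet, cohort=cohort)
    return fit_stratified(med, sheet, analysis, cohort=cohort)
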