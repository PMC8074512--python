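"""Genomic-context enrichment, gene linking, GAM de-biasing, pre-ranked GSEA.

Foreground CpG/region sets (the FDR-significant differences) are tested
for over/under-representation in probe annotation categories and chromatin
states with Fisher's exact test, and against named BED interval databases
by region-overlap Fisher tests. Features are linked to genes by the
basal-plus-extension regulatory-domain rule (5 kb upstream / 1 kb
downstream basal domain, extended to the neighboring basal domains up to
1 Mb); each gene is scored by the smallest linked P-value, de-biased for
its number of linked features with a gamma GAM, and the residuals feed a
pre-ranked GSEA with gene-label permutations.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# Fisher enrichment against annotation categories
# ---------------------------------------------------------------------------

def fisher_enrichment(fg_ids, bg_ids, annotation: pd.Series) -> pd.DataFrame:
    """Per-category 2x2 Fisher exact tests of foreground membership.

    ``annotation`` maps every background feature to a category label.
    For each category the table [[fg_in, fg_out], [bgonly_in, bgonly_out]]
    is tested two-sided; the odds ratio is the sample OR (NaN when a
    margin is empty). Foreground must be a subset of background.
    """
    fg = pd.Index(fg_ids)
    bg = pd.Index(bg_ids)
    if len(fg.difference(bg)):
        raise ValueError("foreground is not a subset of background")
    ann = annotation.reindex(bg)
    in_fg = ann.index.isin(fg)
    rows = []
    for cat in sorted(ann.dropna().unique()):
        in_cat = (ann == cat).values
        a = int((in_fg & in_cat).sum())        # fg in category
        b = int((in_fg & ~in_cat).sum())       # fg out
        c = int((~in_fg & in_cat).sum())       # rest in
        d = int((~in_fg & ~in_cat).sum())      # rest out
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append({"category": cat, "fg_in": a, "fg_out": b,
                         "bg_in": c, "bg_out": d, "OR": np.nan, "p": np.nan})
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append({"category": cat, "fg_in": a, "fg_out": b, "bg_in": c,
                     "bg_out": d, "OR": odds, "p": p})
    return pd.DataFrame(rows).set_index("category")


# ---------------------------------------------------------------------------
# region-overlap enrichment (LOLA-style)
# ---------------------------------------------------------------------------

def _any_overlap(regions: pd.DataFrame, db: pd.DataFrame) -> np.ndarray:
    """Boolean: does each half-open [start, end) region overlap >=1 db interval."""
    hits = np.zeros(len(regions), dtype=bool)
    for ch, grp in db.groupby("chr"):
        sel = regions["chr"] == ch
        if not sel.any():
            continue
        starts = grp["start"].values
        ends = grp["end"].values
        order = np.argsort(starts)
        starts, ends = starts[order], np.maximum.accumulate(ends[order])
        rs = regions.loc[sel, "start"].values
        re_ = regions.loc[sel, "end"].values
        # index of last interval starting before region end
        idx = np.searchsorted(starts, re_, side="left") - 1
        ok = idx >= 0
        running_end = np.where(ok, ends[np.maximum(idx, 0)], -1)
        hits[np.where(sel)[0]] = ok & (running_end > rs)
    return hits


def region_overlap_enrichment(fg_names, universe: pd.DataFrame,
                              region_db: dict) -> pd.DataFrame:
    """Fisher enrichment of a foreground region set against BED databases.

    ``universe`` indexes region names with chr/start/end columns (0-based
    half-open); ``region_db`` maps database names to BED-like DataFrames.
    For each database the universe regions overlapping >= 1 bp are crossed
    with foreground membership. Results are sorted by P-value.
    """
    fg = pd.Index(fg_names)
    if len(fg.difference(universe.index)):
        raise ValueError("foreground regions not in universe")
    bad = (universe["end"] <= universe["start"])
    if bad.any():
        raise ValueError("malformed universe intervals")
    in_fg = universe.index.isin(fg)
    rows = []
    for name, db in region_db.items():
        if (db["end"] <= db["start"]).any():
            raise ValueError(f"malformed BED intervals in {name}")
        ov = _any_overlap(universe, db)
        a = int((in_fg & ov).sum())
        b = int((in_fg & ~ov).sum())
        c = int((~in_fg & ov).sum())
        d = int((~in_fg & ~ov).sum())
        if min(a + b, c + d, a + c, b + d) == 0:
            rows.append({"set": name, "fg_in": a, "fg_out": b, "bg_in": c,
                         "bg_out": d, "OR": np.nan, "p": np.nan})
            continue
        odds, p = stats.fisher_exact([[a, b], [c, d]])
        rows.append({"set": name, "fg_in": a, "fg_out": b, "bg_in": c,
                     "bg_out": d, "OR": odds, "p": p})
    out = pd.DataFrame(rows).set_index("set")
    return out.sort_values("p", na_position="last")


# ---------------------------------------------------------------------------
# regulatory-domain gene assignment (basal plus extension)
# ---------------------------------------------------------------------------

def regulatory_domains(gene_model: pd.DataFrame, *, basal_up: int = 5_000,
                       basal_down: int = 1_000, max_ext: int = 1_000_000) -> pd.DataFrame:
    """Basal-plus-extension regulatory domain per gene.

    The basal domain extends ``basal_up`` bp upstream and ``basal_down``
    bp downstream of the TSS (strand aware). Each side is then extended
    outward to the nearest neighboring gene's basal-domain boundary, but
    no further than ``max_ext`` from the TSS. Coordinates are integer,
    domain = [left, right] inclusive.
    """
    if gene_model["strand"].isna().any():
        raise ValueError("genes with missing strand")
    gm = gene_model.copy()
    plus = gm["strand"] == "+"
    gm["basal_left"] = np.where(plus, gm["tss"] - basal_up, gm["tss"] - basal_down)
    gm["basal_right"] = np.where(plus, gm["tss"] + basal_down, gm["tss"] + basal_up)
    gm["left"] = gm["basal_left"]
    gm["right"] = gm["basal_right"]
    for ch, grp in gm.groupby("chr"):
        grp = grp.sort_values("tss")
        idx = grp.index
        bl = grp["basal_left"].values
        br = grp["basal_right"].values
        tss = grp["tss"].values
        left = np.empty(len(grp))
        right = np.empty(len(grp))
        for i in range(len(grp)):
            cand_l = tss[i] - max_ext if i == 0 else max(br[i - 1], tss[i] - max_ext)
            cand_r = tss[i] + max_ext if i == len(grp) - 1 else min(bl[i + 1], tss[i] + max_ext)
            left[i] = min(bl[i], cand_l)
            right[i] = max(br[i], cand_r)
        gm.loc[idx, "left"] = left
        gm.loc[idx, "right"] = right
    return gm


def great_assign(features: pd.DataFrame, gene_model: pd.DataFrame, *,
                 basal_up: int = 5_000, basal_down: int = 1_000,
                 max_ext: int = 1_000_000) -> pd.DataFrame:
    """Link features to every gene whose regulatory domain contains them.

    ``features`` indexes feature ids with chr plus either ``pos`` (point
    features) or start/end (regions, located by their midpoint). Returns
    one row per (feature, gene) link with the distance to the TSS, signed
    relative to the gene's strand (upstream negative).
    """
    dom = regulatory_domains(gene_model, basal_up=basal_up,
                             basal_down=basal_down, max_ext=max_ext)
    if "pos" in features.columns:
        fpos = features["pos"].astype(float)
    else:
        fpos = (features["start"] + features["end"]) / 2.0
    links = []
    for ch, genes in dom.groupby("chr"):
        sel = features["chr"] == ch
        if not sel.any():
            continue
        pos = fpos[sel]
        for gene, g in genes.iterrows():
            inside = (pos >= g["left"]) & (pos <= g["right"])
            for fid, p in pos[inside].items():
                d = p - g["tss"] if g["strand"] == "+" else g["tss"] - p
                links.append({"feature_id": fid, "gene": gene,
                              "distance": int(d)})
    return pd.DataFrame(links, columns=["feature_id", "gene", "distance"])


# ---------------------------------------------------------------------------
# gene scores and GAM de-biasing
# ---------------------------------------------------------------------------

def gene_scores(links: pd.DataFrame, p_values: pd.Series) -> pd.DataFrame:
    """Smallest linked P-value per gene, with the number of links.

    ``links`` comes from :func:`great_assign`; ``p_values`` indexes feature
    ids. Y = -log10(smallest p).
    """
    merged = links.assign(p=p_values.reindex(links["feature_id"]).values).dropna(subset=["p"])
    grp = merged.groupby("gene")
    out = pd.DataFrame({
        "min_p": grp["p"].min(),
        "n_links": grp["p"].size(),
    })
    out["Y"] = -np.log10(np.maximum(out["min_p"], 1e-300))
    return out


def gam_debias(scores: pd.DataFrame, *, n_basis: int = 10,
               residual_type: str = "deviance") -> pd.DataFrame:
    """Remove the link-count bias from gene scores with a gamma GAM.

    Fits Y ~ f(n_links) with a gamma family (log link) and a penalized
    cubic B-spline (about ``n_basis`` basis functions, smoothing chosen by
    generalized cross-validation), then ranks genes by the model residual,
    descending. Genes with more linked features have stochastically larger
    minimum -log10(p) under the null; the residual removes that trend.
    Falls back to a linear gamma GLM if the spline fit fails.
    """
    import statsmodels.api as sm
    from statsmodels.gam.api import BSplines, GLMGam

    sc = scores[scores["Y"] > 0].copy()
    if len(sc) < 20:
        raise ValueError("need at least 20 genes with Y > 0")
    y = sc["Y"].values
    x = sc["n_links"].values.astype(float)[:, None]
    resid = None
    if np.unique(x).size >= n_basis:
        try:
            bs = BSplines(x, df=[n_basis], degree=[3])
            model = GLMGam(y, np.ones((len(y), 1)), smoother=bs,
                           family=sm.families.Gamma(link=sm.families.links.Log()))
            try:
                alpha = model.select_penweight(criterion="gcv")[0]
                model = GLMGam(y, np.ones((len(y), 1)), smoother=bs, alpha=alpha,
                               family=sm.families.Gamma(link=sm.families.links.Log()))
            except Exception:
                pass
            res = model.fit()
            resid = res.resid_deviance if residual_type == "deviance" else res.resid_response
        except Exception as exc:  # pragma: no cover - fallback path
            warnings.warn(f"spline GAM failed ({exc}); falling back to linear gamma GLM")
    if resid is None:
        glm = sm.GLM(y, sm.add_constant(x),
                     family=sm.families.Gamma(link=sm.families.links.Log()))
        res = glm.fit()
        resid = res.resid_deviance if residual_type == "deviance" else res.resid_response
    sc["residual"] = np.asarray(resid)
    return sc.sort_values("residual", ascending=False)


# ---------------------------------------------------------------------------
# pre-ranked GSEA
# ---------------------------------------------------------------------------

def read_gmt(path) -> dict:
    """Read a GMT gene-set file: set name, description, then member genes."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                continue
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def _es_running(metric_abs_w: np.ndarray, hit: np.ndarray):
    """Weighted KS running sum; returns (ES, index of extremum)."""
    n = len(hit)
    hit_w = np.where(hit, metric_abs_w, 0.0)
    total_hit = hit_w.sum()
    n_miss = n - hit.sum()
    if total_hit == 0 or n_miss == 0:
        return 0.0, 0
    run = np.cumsum(np.where(hit, hit_w / total_hit, -1.0 / n_miss))
    i = int(np.argmax(np.abs(run)))
    return float(run[i]), i


def gsea_preranked(ranked: pd.Series, gene_sets: dict, *, n_perm: int = 1000,
                   weight: float = 1.0, min_size: int = 10, max_size: int = 500,
                   seed: int = 0) -> pd.DataFrame:
    """Pre-ranked GSEA with the weighted Kolmogorov-Smirnov statistic.

    ``ranked`` maps genes to the ranking metric (sorted internally,
    descending). ES uses hit increments proportional to |metric|**weight
    and uniform miss decrements. Null ES values come from gene-label
    permutations (fixed seed); NES normalizes against the sign-matched
    permutation mean, nominal P is the sign-matched permutation tail with
    resolution 1/(n_perm+1), and FDR q follows the standard pre-ranked
    procedure (sign-matched pooled NES comparison). Core-enrichment genes
    are the members at or before the running-sum extremum.
    """
    if len(ranked) == 0:
        raise ValueError("empty ranked list")
    ranked = ranked.sort_values(ascending=False)
    genes = ranked.index.values
    metric = ranked.values.astype(float)
    w = np.abs(metric) ** weight
    rng = np.random.default_rng(seed)
    gene_pos = {g: i for i, g in enumerate(genes)}

    usable = {}
    for name, members in gene_sets.items():
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if min_size <= len(idx) <= max_size:
            usable[name] = idx
    if not usable:
        return pd.DataFrame(columns=["size", "ES", "NES", "p", "fdr", "core_genes"])

    n = len(genes)
    results = {}
    perm_nes = []
    obs_nes = {}
    for name, idx in usable.items():
        hit = np.zeros(n, dtype=bool)
        hit[idx] = True
        es, ext = _es_running(w, hit)
        # permutation null: random gene labels, same set size
        perm_es = np.empty(n_perm)
        k = len(idx)
        for b in range(n_perm):
            ridx = rng.choice(n, size=k, replace=False)
            h = np.zeros(n, dtype=bool)
            h[ridx] = True
            perm_es[b], _ = _es_running(w, h)
        same_sign = perm_es >= 0 if es >= 0 else perm_es < 0
        denom = np.abs(perm_es[same_sign]).mean() if same_sign.any() else np.nan
        nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
        p = ((np.abs(perm_es[same_sign]) >= abs(es)).sum() + 1) / (same_sign.sum() + 1) \
            if same_sign.any() else np.nan
        with np.errstate(invalid="ignore"):
            pn = np.where(perm_es >= 0,
                          perm_es / max(np.abs(perm_es[perm_es >= 0]).mean(), 1e-12),
                          perm_es / max(np.abs(perm_es[perm_es < 0]).mean(), 1e-12)) \
                if (perm_es >= 0).any() and (perm_es < 0).any() else perm_es / max(np.abs(perm_es).mean(), 1e-12)
        perm_nes.append(pn)
        obs_nes[name] = nes
        if es >= 0:
            core = [genes[i] for i in idx if i <= ext]
        else:
            core = [genes[i] for i in idx if i >= ext]
        results[name] = {"size": len(idx), "ES": es, "NES": nes, "p": p,
                         "core_genes": ",".join(core)}

    pool = np.concatenate(perm_nes)
    obs = np.array([obs_nes[name] for name in results])
    fdr = np.full(len(obs), np.nan)
    for i, nes in enumerate(obs):
        if not np.isfinite(nes):
            continue
        if nes >= 0:
            num = (pool >= nes).mean() / max((pool >= 0).mean(), 1e-12)
            den = (obs[np.isfinite(obs)] >= nes).mean() / max((obs[np.isfinite(obs)] >= 0).mean(), 1e-12)
        else:
            num = (pool <= nes).mean() / max((pool < 0).mean(), 1e-12)
            den = (obs[np.isfinite(obs)] <= nes).mean() / max((obs[np.isfinite(obs)] < 0).mean(), 1e-12)
        fdr[i] = min(1.0, num / max(den, 1e-12))
    out = pd.DataFrame(results).T
    out["fdr"] = fdr
    out.index.name = "gene_set"
    for col in ("size",):
        out[col] = out[col].astype(int)
    for col in ("ES", "NES", "p", "fdr"):
        out[col] = out[col].astype(float)
    return out.sort_values("p")
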