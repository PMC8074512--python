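"""Per-cohort quality control and normalization of 450K-style methylation data.

The canonical per-cohort route is::

    beta, qc1 = filter_probes(beta, detp, annot, smoking_ids)
    beta, sheet, qc2 = filter_samples(beta, sheet)
    beta = quantile_normalize(beta)
    beta = bmiq(beta, annot["design_type"])
    m = beta_to_m(beta)
    resid = residualize(m, sheet[["slide"]])

Matrices are pandas DataFrames with probes as rows and samples as columns.
QC is order dependent and the order is fixed: probes (detection -> smoking
-> SNP proximity), then samples (bisulfite conversion -> PCA outliers).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

BETA_EPS = 1e-6  # clip betas before the logit so M-values stay finite


# ---------------------------------------------------------------------------
# value-scale conversions
# ---------------------------------------------------------------------------

def beta_to_m(beta):
    """Convert methylation beta values (fractions) to M-values, M = log2(b/(1-b)).

    Betas are clipped to [BETA_EPS, 1 - BETA_EPS] first. Accepts scalars,
    arrays or DataFrames and preserves the container type.
    """
    b = np.clip(np.asarray(beta, dtype=float) if not isinstance(beta, pd.DataFrame) else beta,
                BETA_EPS, 1.0 - BETA_EPS)
    m = np.log2(b / (1.0 - b))
    if isinstance(beta, pd.DataFrame):
        return m
    return m


def m_to_beta(m):
    """Inverse of :func:`beta_to_m`: beta = 2**M / (1 + 2**M)."""
    if isinstance(m, pd.DataFrame):
        return 1.0 / (1.0 + np.exp2(-m))
    m = np.asarray(m, dtype=float)
    return 1.0 / (1.0 + np.exp2(-m))


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------

@dataclass
class QCReport:
    """Counts of probes/samples removed per rule, in application order."""

    probes_in: int = 0
    probes_detection: int = 0
    probes_smoking: int = 0
    probes_snp: int = 0
    probes_out: int = 0
    samples_in: int = 0
    samples_conversion: int = 0
    samples_pca: int = 0
    samples_out: int = 0
    pca_coordinates: pd.DataFrame | None = field(default=None, repr=False)

    def as_dict(self) -> dict:
        d = {k: getattr(self, k) for k in (
            "probes_in", "probes_detection", "probes_smoking", "probes_snp",
            "probes_out", "samples_in", "samples_conversion", "samples_pca",
            "samples_out")}
        return d


# ---------------------------------------------------------------------------
# probe / sample filters
# ---------------------------------------------------------------------------

def filter_probes(beta: pd.DataFrame, detp: pd.DataFrame, annot: pd.DataFrame,
                  smoking_ids=(), *, det_threshold: float = 0.01,
                  snp_dist: int = 5, snp_maf: float = 0.01,
                  invert_detection: bool = False) -> tuple[pd.DataFrame, QCReport]:
    """Probe-level QC: detection, smoking-associated probes, SNP proximity.

    A probe is retained when (1) its detection P-value is below
    ``det_threshold`` in every sample (``invert_detection=True`` flips the
    rule to drop probes failing in *all* samples instead), (2) it is not in
    the smoking-associated list, and (3) the annotation reports no SNP with
    MAF >= ``snp_maf`` within ``snp_dist`` bp of the probe 3' end (both
    boundaries inclusive). Annotation columns used: ``snp_dist_3p`` and
    ``snp_maf`` (NaN means no nearby SNP).
    """
    if beta.shape != detp.shape or not beta.index.equals(detp.index):
        raise ValueError("beta and detection-P matrices are not aligned")
    missing = beta.index.difference(annot.index)
    if len(missing):
        raise ValueError(f"{len(missing)} probes missing from annotation")

    report = QCReport(probes_in=beta.shape[0], samples_in=beta.shape[1],
                      samples_out=beta.shape[1])

    if invert_detection:
        keep_det = ~(detp.values >= det_threshold).all(axis=1)
    else:
        keep_det = (detp.values < det_threshold).all(axis=1)
    report.probes_detection = int((~keep_det).sum())
    beta = beta.loc[keep_det]

    smoking = pd.Index(smoking_ids)
    unknown = smoking.difference(annot.index)
    if len(unknown):
        warnings.warn(f"{len(unknown)} smoking-list probes not on the array")
    drop_smoke = beta.index.isin(smoking)
    report.probes_smoking = int(drop_smoke.sum())
    beta = beta.loc[~drop_smoke]

    ann = annot.loc[beta.index]
    dist = pd.to_numeric(ann.get("snp_dist_3p"), errors="coerce")
    maf = pd.to_numeric(ann.get("snp_maf"), errors="coerce")
    drop_snp = (dist.values <= snp_dist) & (maf.values >= snp_maf)
    drop_snp = np.nan_to_num(drop_snp.astype(float)).astype(bool)
    report.probes_snp = int(drop_snp.sum())
    beta = beta.loc[~drop_snp]

    report.probes_out = beta.shape[0]
    return beta, report


def filter_samples(beta: pd.DataFrame, sheet: pd.DataFrame, *,
                   conv_min: float = 88.0, n_top: int = 50_000,
                   sd_limit: float = 3.0) -> tuple[pd.DataFrame, pd.DataFrame, QCReport]:
    """Sample-level QC: bisulfite conversion then PCA outlier removal.

    Samples with ``bisulfite_conversion`` < ``conv_min`` are dropped first.
    PCA is then run on the centered beta values of the ``n_top``
    highest-variance probes (capped at the probe count); samples within
    mean +/- ``sd_limit`` standard deviations on both PC1 and PC2 are kept.
    """
    report = QCReport(probes_in=beta.shape[0], probes_out=beta.shape[0],
                      samples_in=beta.shape[1])
    conv = sheet.loc[beta.columns, "bisulfite_conversion"].astype(float)
    keep = conv >= conv_min
    report.samples_conversion = int((~keep).sum())
    beta = beta.loc[:, keep.values]
    if beta.shape[1] < 3:
        raise ValueError("fewer than 3 samples remain after conversion filter")

    nv = min(n_top, beta.shape[0])
    variances = beta.values.var(axis=1)
    top = np.argsort(variances)[::-1][:nv]
    x = beta.values[top].T  # samples x probes
    x = x - x.mean(axis=0)
    # PCA by SVD; PC scores for the first two components
    u, s, _ = np.linalg.svd(x, full_matrices=False)
    scores = u[:, :2] * s[:2]
    coords = pd.DataFrame(scores, index=beta.columns, columns=["PC1", "PC2"])
    sd = scores.std(axis=0, ddof=1)
    center = scores.mean(axis=0)
    with np.errstate(invalid="ignore"):
        ok = np.ones(len(scores), dtype=bool)
        for j in range(2):
            if sd[j] > 0:
                ok &= np.abs(scores[:, j] - center[j]) <= sd_limit * sd[j]
    report.samples_pca = int((~ok).sum())
    coords["retained"] = ok
    report.pca_coordinates = coords
    beta = beta.loc[:, ok]
    report.samples_out = beta.shape[1]
    sheet = sheet.loc[beta.columns]
    return beta, sheet, report


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------

def quantile_normalize(beta: pd.DataFrame) -> pd.DataFrame:
    """Force every sample (column) onto the common empirical distribution.

    The reference distribution is the row-wise mean of the sorted columns.
    Ties within a column receive the mean of the reference quantiles they
    span (midrank interpolation), which keeps the transform deterministic.
    """
    if beta.shape[1] < 2:
        raise ValueError("quantile normalization needs at least 2 samples")
    x = beta.values
    n = x.shape[0]
    ref = np.sort(x, axis=0).mean(axis=1)
    out = np.empty_like(x)
    grid = np.arange(1, n + 1, dtype=float)
    for j in range(x.shape[1]):
        ranks = stats.rankdata(x[:, j], method="average")
        out[:, j] = np.interp(ranks, grid, ref)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# BMIQ: beta-mixture quantile normalization of type II probes
# ---------------------------------------------------------------------------

def _beta_mm(mean, var):
    """Method-of-moments (a, b) for a beta distribution; variance floored."""
    var = max(var, 1e-6)
    var = min(var, mean * (1 - mean) * 0.999)
    nu = mean * (1 - mean) / var - 1.0
    return max(mean * nu, 1e-3), max((1 - mean) * nu, 1e-3)


def _fit_beta_mixture(values, max_iter=500, tol=1e-6):
    """EM fit of a 3-state beta mixture (unmethylated / hemi / methylated).

    Responsibilities are initialized from fixed beta cutpoints (0.2, 0.75);
    M-steps use posterior-weighted method-of-moments updates, which keep the
    fit monotone-stable and fast. Returns (weights, params[3 x 2], converged).
    """
    v = np.clip(values, 1e-4, 1 - 1e-4)
    resp = np.zeros((len(v), 3))
    resp[v < 0.2, 0] = 1.0
    resp[(v >= 0.2) & (v < 0.75), 1] = 1.0
    resp[v >= 0.75, 2] = 1.0
    # guard: every class needs some mass to start
    resp += 1e-3
    resp /= resp.sum(axis=1, keepdims=True)
    params = np.zeros((3, 2))
    w = resp.mean(axis=0)
    ll_old = -np.inf
    converged = False
    for _ in range(max_iter):
        for k in range(3):
            wk = resp[:, k]
            sw = wk.sum()
            mu = float((wk * v).sum() / sw)
            var = float((wk * (v - mu) ** 2).sum() / sw)
            params[k] = _beta_mm(mu, var)
        dens = np.column_stack([stats.beta.pdf(v, *params[k]) for k in range(3)])
        dens = np.maximum(dens * w, 1e-300)
        tot = dens.sum(axis=1)
        ll = float(np.log(tot).sum())
        resp = dens / tot[:, None]
        w = resp.mean(axis=0)
        if abs(ll - ll_old) < tol * (1 + abs(ll)):
            converged = True
            break
        ll_old = ll
    # order components by mean so 0=U, 1=hemi, 2=M
    means = params[:, 0] / params.sum(axis=1)
    order = np.argsort(means)
    return w[order], params[order], converged


def bmiq(beta: pd.DataFrame, design_types: pd.Series) -> pd.DataFrame:
    """Per-sample beta-mixture quantile normalization of type II probes.

    For each sample a 3-state beta mixture is fitted separately to type I
    and type II probes. Type II values assigned (posterior argmax) to the
    unmethylated and methylated classes are quantile-mapped through the
    fitted class CDFs onto the corresponding type I class distribution;
    hemimethylated values are rescaled by monotone linear interpolation
    between the transformed class boundaries. Type I probes are unchanged
    and the transform is monotone within each sample. Samples whose EM does
    not converge fall back to the identity with a warning.
    """
    types = design_types.reindex(beta.index)
    is2 = (types == "II").values
    is1 = (types == "I").values
    if not is2.any():
        return beta.copy()
    if not is1.any():
        raise ValueError("BMIQ requires both design types")
    out = beta.values.astype(float).copy()
    for j, col in enumerate(beta.columns):
        v1 = out[is1, j]
        v2 = out[is2, j]
        if np.ptp(v1) < 1e-12 or np.ptp(v2) < 1e-12:
            warnings.warn(f"constant beta column for sample {col}; BMIQ skipped")
            continue
        w1, p1, ok1 = _fit_beta_mixture(v1)
        w2, p2, ok2 = _fit_beta_mixture(v2)
        if not (ok1 and ok2):
            warnings.warn(f"BMIQ EM did not converge for sample {col}; identity used")
            continue
        v2c = np.clip(v2, 1e-4, 1 - 1e-4)
        dens = np.column_stack([w2[k] * stats.beta.pdf(v2c, *p2[k]) for k in range(3)])
        cls = dens.argmax(axis=1)
        new = v2.copy()
        # U class: map through type II U CDF onto type I U quantiles
        u_mask = cls == 0
        if u_mask.any():
            q = stats.beta.cdf(v2c[u_mask], *p2[0])
            new[u_mask] = stats.beta.ppf(np.clip(q, 1e-12, 1 - 1e-12), *p1[0])
        m_mask = cls == 2
        if m_mask.any():
            q = stats.beta.cdf(v2c[m_mask], *p2[2])
            new[m_mask] = stats.beta.ppf(np.clip(q, 1e-12, 1 - 1e-12), *p1[2])
        h_mask = cls == 1
        if h_mask.any():
            # original and transformed boundaries of the hemi band
            lo_old = v2[u_mask].max() if u_mask.any() else v2[h_mask].min()
            hi_old = v2[m_mask].min() if m_mask.any() else v2[h_mask].max()
            lo_new = new[u_mask].max() if u_mask.any() else lo_old
            hi_new = new[m_mask].min() if m_mask.any() else hi_old
            if hi_old > lo_old:
                frac = (v2[h_mask] - lo_old) / (hi_old - lo_old)
                new[h_mask] = lo_new + frac * (hi_new - lo_new)
        # enforce within-sample monotonicity of the piecewise map
        order = np.argsort(v2, kind="mergesort")
        new[order] = np.maximum.accumulate(new[order])
        out[is2, j] = np.clip(new, 1e-6, 1 - 1e-6)
    return pd.DataFrame(out, index=beta.index, columns=beta.columns)


# ---------------------------------------------------------------------------
# residualization
# ---------------------------------------------------------------------------

def design_matrix(covariates: pd.DataFrame, add_intercept: bool = True,
                  allow_singular: bool = False) -> np.ndarray:
    """One-hot encode categoricals (reference level dropped), add intercept."""
    cols = []
    for name in covariates.columns:
        col = covariates[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=name, drop_first=True)
            cols.append(dummies.values.astype(float))
        else:
            cols.append(col.values.astype(float)[:, None])
    x = np.hstack(cols) if cols else np.empty((len(covariates), 0))
    if add_intercept:
        x = np.hstack([np.ones((len(covariates), 1)), x])
    # drop constant non-intercept columns
    keep = [0] + [j for j in range(1, x.shape[1]) if np.ptp(x[:, j]) > 0]
    x = x[:, keep]
    if not allow_singular and np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("singular design after dropping constant columns")
    return x


def residualize(matrix: pd.DataFrame, covariates: pd.DataFrame,
                allow_singular: bool = False) -> pd.DataFrame:
    """Per-row OLS residuals of ``matrix`` (features x samples) on covariates.

    Categorical covariates are one-hot encoded with a reference level; an
    intercept is always included, so residual rows are centered and
    orthogonal to every design column. Residualizing twice on the same
    design is the identity.
    """
    cov = covariates.loc[matrix.columns] if not covariates.index.equals(matrix.columns) else covariates
    x = design_matrix(cov, allow_singular=allow_singular)
    y = matrix.values.T  # samples x features
    coef, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = (y - x @ coef).T
    out = pd.DataFrame(resid, index=matrix.index, columns=matrix.columns)
    out.attrs["removed_covariates"] = list(covariates.columns)
    return out


# ---------------------------------------------------------------------------
# neuron-proportion estimation from marker-probe reference profiles
# ---------------------------------------------------------------------------

def estimate_neuron_proportion(beta: pd.DataFrame,
                               reference_profiles: pd.DataFrame) -> pd.Series:
    """Estimate the neuronal fraction of each bulk sample by deconvolution.

    ``reference_profiles`` indexes cell-epigenotype marker probes with
    columns ``neuron`` and ``glia`` holding the pure-population mean betas.
    For each sample the neuron proportion p in [0, 1] minimizes the squared
    deviation of the observed marker betas from p*neuron + (1-p)*glia; the
    closed-form projection is clipped to [0, 1].
    """
    markers = reference_profiles.index.intersection(beta.index)
    if len(markers) == 0:
        raise ValueError("no marker probes overlap the beta matrix")
    nref = reference_profiles.loc[markers, "neuron"].values
    gref = reference_profiles.loc[markers, "glia"].values
    d = nref - gref
    denom = float((d ** 2).sum())
    x = beta.loc[markers].values
    p = ((x - gref[:, None]) * d[:, None]).sum(axis=0) / denom
    return pd.Series(np.clip(p, 0.0, 1.0), index=beta.columns, name="neuron_prop")
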