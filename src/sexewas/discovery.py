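"""Significance calling: BH-FDR selection, stagewise testing, direction counts.

Sex-stratified discoveries are called by Benjamini-Hochberg FDR within
each sex's meta-analysis P-values. Sex-specificity is additionally probed
by a two-stage procedure: a *screening* stage tests, per feature, the
global null that neither sex shows a Braak association (BH on the minimum
of the female and male meta P-values), and a *confirmation* stage tests
the three individual hypotheses (female, male, interaction) for each
screened feature with a Holm correction at the adjusted level
alpha_adjusted = (#screened) * alpha / (#features), which controls the
per-feature family-wise error rate.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

HYPOTHESES = ("female", "male", "interaction")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted P-values (monotone in sorted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty P-value vector")
    return multipletests(p, method="fdr_bh")[1]


def _holm_adjust_rows(p: np.ndarray) -> np.ndarray:
    """Row-wise Holm-adjusted P-values for an n x 3 array."""
    m = p.shape[1]
    order = np.argsort(p, axis=1)
    sorted_p = np.take_along_axis(p, order, axis=1)
    factors = (m - np.arange(m))[None, :]
    stepped = np.minimum(1.0, np.maximum.accumulate(sorted_p * factors, axis=1))
    out = np.empty_like(p)
    np.put_along_axis(out, order, stepped, axis=1)
    return out


def stagewise(p_f, p_m, p_int, *, alpha: float = 0.05) -> pd.DataFrame:
    """Two-stage screening/confirmation for sex-specific associations.

    Returns a table with p_screen, screened flag, alpha_adjusted, the
    within-feature Holm-adjusted P-values (holm_female/male/interaction)
    and the confirmation decisions (confirm_*). Confirmation decisions are
    made only for screened features; unscreened rows carry NaN adjusted
    P-values and False decisions.
    """
    p_f = np.asarray(p_f, dtype=float)
    p_m = np.asarray(p_m, dtype=float)
    p_int = np.asarray(p_int, dtype=float)
    if not (len(p_f) == len(p_m) == len(p_int)):
        raise ValueError("P-value vectors have different lengths")
    n = len(p_f)
    p_screen = np.minimum(p_f, p_m)
    q_screen = bh_adjust(p_screen)
    screened = q_screen < alpha
    n_r = int(screened.sum())
    alpha_adj = n_r * alpha / n

    triple = np.column_stack([p_f, p_m, p_int])
    holm = np.full((n, 3), np.nan)
    confirm = np.zeros((n, 3), dtype=bool)
    if n_r:
        holm_scr = _holm_adjust_rows(triple[screened])
        holm[screened] = holm_scr
        confirm[screened] = holm_scr <= alpha_adj
    out = pd.DataFrame({
        "p_screen": p_screen,
        "q_screen": q_screen,
        "screened": screened,
        "alpha_adjusted": alpha_adj,
    })
    for j, h in enumerate(HYPOTHESES):
        out[f"holm_{h}"] = holm[:, j]
        out[f"confirm_{h}"] = confirm[:, j]
    return out


def discovery_set(meta: pd.DataFrame, *, threshold: float = 0.05,
                  label: str = "") -> pd.DataFrame:
    """BH selection on a meta-analysis table's final P-values.

    Returns the significant rows with q-values and the direction (sign of
    the combined estimate). The threshold is recorded in ``attrs``.
    """
    q = bh_adjust(meta["p_final"].values)
    sel = q < threshold
    out = meta.loc[sel, ["estimate", "se", "p_final"]].copy()
    out["q"] = q[sel]
    out["direction"] = np.sign(out["estimate"]).astype(int)
    out.attrs["threshold"] = threshold
    out.attrs["analysis"] = label
    return out


def direction_concordance(estimates_a, estimates_b) -> dict:
    """Count sign agreement between two aligned effect-estimate vectors.

    Pairs where either estimate is exactly zero are counted separately
    under ``zero`` and belong to neither category.
    """
    a = np.asarray(estimates_a, dtype=float)
    b = np.asarray(estimates_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("estimate vectors are not aligned")
    sa, sb = np.sign(a), np.sign(b)
    nz = (sa != 0) & (sb != 0)
    return {
        "same": int((sa[nz] == sb[nz]).sum()),
        "opposite": int((sa[nz] != sb[nz]).sum()),
        "zero": int((~nz).sum()),
    }
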