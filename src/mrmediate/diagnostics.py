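"""Pleiotropy and influence diagnostics: leave-one-out IVW, the
simulation-based residual-sum-of-squares outlier test (global, per-SNP
outlier, and distortion components), and funnel-plot data export."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import HarmonizedSet
from .uvmr import MREstimate, ivw, wald_ratio


@dataclass
class PressoResult:
    """Output of the simulation-based pleiotropy residual test.

    ``global_pvalue`` tests whether total weighted residual variation
    around leave-one-out slopes exceeds what measurement error predicts;
    ``outlier_table`` carries raw and multiplicity-adjusted per-SNP
    p-values; the distortion test asks whether removing the flagged
    outliers changes the IVW estimate more than removing random subsets
    of the same size would.
    """

    global_rss_obs: float
    global_pvalue: float
    outlier_table: pd.DataFrame  # snp_id, residual2, pvalue, pvalue_adj, outlier
    outlier_indices: list[int]
    distortion_pvalue: float | None
    estimate_all: MREstimate
    estimate_outlier_corrected: MREstimate | None
    n_sims: int
    seed: int


@dataclass
class LooTable:
    """Leave-one-out IVW estimates: one row per left-out SNP plus an
    'all' row with the full-set estimate."""

    table: pd.DataFrame  # snp_id, beta, se, pvalue, n_snp


def _loo_slopes(bx: np.ndarray, by: np.ndarray, sy: np.ndarray) -> np.ndarray:
    """IVW slope with SNP j removed, for every j (vectorised totals)."""
    wx = bx / sy**2
    num = np.sum(wx * by)
    den = np.sum(wx * bx)
    num_j = num - wx * by
    den_j = den - wx * bx
    return num_j / den_j


def leave_one_out(hset: HarmonizedSet, ci_level: float = 0.95) -> LooTable:
    """Recompute the auto-model IVW estimate dropping each instrument in
    turn; detects single influential SNPs."""
    n = hset.n_snp
    if n < 3:
        raise ValueError("leave-one-out needs at least 3 instruments")
    rows = []
    for j in range(n):
        est = ivw(hset.drop_indices([j]), model="auto", ci_level=ci_level)
        rows.append((hset.snp_ids[j], est.beta, est.se, est.pvalue, est.n_snp))
    full = ivw(hset, model="auto", ci_level=ci_level)
    rows.append(("all", full.beta, full.se, full.pvalue, full.n_snp))
    return LooTable(pd.DataFrame(
        rows, columns=["snp_id", "beta", "se", "pvalue", "n_snp"]))


def mr_presso(
    hset: HarmonizedSet,
    n_sims: int = 1000,
    outlier_alpha: float = 0.05,
    seed: int = 0,
    multiplicity: str = "bonferroni",
    ci_level: float = 0.95,
) -> PressoResult:
    """Simulation-based pleiotropy residual test.

    Observed statistic: RSS = Σ_j (β_Yj − β̂₍₋ⱼ₎ β_Xj)² with β̂₍₋ⱼ₎ the
    leave-one-out IVW slope.  Null replicates redraw
    β*_Xj ~ N(β_Xj, σ_Xj) and β*_Yj ~ N(β̂₍₋ⱼ₎ β_Xj, σ_Yj) and recompute
    the statistic the same way.  Empirical p-values carry an add-one
    pseudocount so they are never zero.  Per-SNP outlier p-values are
    adjusted by Bonferroni (or Benjamini-Hochberg with
    ``multiplicity="bh"``); flagged outliers feed the distortion test,
    whose null removes random same-size SNP subsets.
    """
    n = hset.n_snp
    if n < 4:
        raise ValueError("the pleiotropy residual test needs at least 4 instruments")
    if n_sims < 100:
        raise ValueError("n_sims must be at least 100")
    if multiplicity not in ("bonferroni", "bh"):
        raise ValueError("multiplicity must be 'bonferroni' or 'bh'")
    rng = np.random.default_rng(seed)

    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome

    slopes_loo = _loo_slopes(bx, by, sy)
    resid_obs = by - slopes_loo * bx
    resid2_obs = resid_obs**2
    rss_obs = float(np.sum(resid2_obs))

    # simulate replicates under the no-pleiotropy model
    bx_star = rng.normal(bx, sx, size=(n_sims, n))
    by_star = rng.normal(slopes_loo * bx, sy, size=(n_sims, n))
    wx = bx_star / sy**2
    num = np.sum(wx * by_star, axis=1, keepdims=True)
    den = np.sum(wx * bx_star, axis=1, keepdims=True)
    slopes_star = (num - wx * by_star) / (den - wx * bx_star)
    resid2_star = (by_star - slopes_star * bx_star) ** 2
    rss_star = resid2_star.sum(axis=1)

    global_p = (1.0 + np.sum(rss_star >= rss_obs)) / (n_sims + 1.0)

    raw_p = (1.0 + np.sum(resid2_star >= resid2_obs, axis=0)) / (n_sims + 1.0)
    if multiplicity == "bonferroni":
        adj_p = np.minimum(1.0, raw_p * n)
    else:
        from statsmodels.stats.multitest import multipletests
        adj_p = multipletests(raw_p, method="fdr_bh")[1]
    outlier_mask = adj_p < outlier_alpha
    outlier_indices = [int(i) for i in np.flatnonzero(outlier_mask)]

    est_all = ivw(hset, model="auto", ci_level=ci_level)
    est_corr = None
    distortion_p = None
    if outlier_indices:
        if len(outlier_indices) == n:
            raise ValueError("all instruments flagged as outliers; set unusable")
        corrected = hset.drop_indices(outlier_indices)
        est_corr = ivw(corrected, model="auto", ci_level=ci_level)
        d_obs = est_all.beta - est_corr.beta
        n_out = len(outlier_indices)
        d_null = np.empty(n_sims)
        idx = np.arange(n)
        for s in range(n_sims):
            removed = rng.choice(idx, size=n_out, replace=False)
            d_null[s] = est_all.beta - ivw(
                hset.drop_indices(removed), model="auto").beta
        distortion_p = float(
            (1.0 + np.sum(np.abs(d_null) >= abs(d_obs))) / (n_sims + 1.0))

    table = pd.DataFrame({
        "snp_id": hset.snp_ids,
        "residual2": resid2_obs,
        "pvalue": raw_p,
        "pvalue_adj": adj_p,
        "outlier": outlier_mask,
    })
    return PressoResult(
        global_rss_obs=rss_obs,
        global_pvalue=float(global_p),
        outlier_table=table,
        outlier_indices=outlier_indices,
        distortion_pvalue=distortion_p,
        estimate_all=est_all,
        estimate_outlier_corrected=est_corr,
        n_sims=n_sims,
        seed=seed,
    )


def funnel_data(hset: HarmonizedSet) -> pd.DataFrame:
    """Per-SNP Wald ratio and its precision (1/SE) for funnel plotting;
    asymmetry around the IVW slope suggests directional pleiotropy."""
    rows = []
    for j in range(hset.n_snp):
        est = wald_ratio(hset.beta_exposure[j], hset.se_exposure[j],
                         hset.beta_outcome[j], hset.se_outcome[j])
        rows.append((hset.snp_ids[j], est.beta, 1.0 / est.se))
    return pd.DataFrame(rows, columns=["snp_id", "ratio", "precision"])
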