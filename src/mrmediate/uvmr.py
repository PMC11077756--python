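"""Univariable two-sample MR estimators.

All estimators take per-SNP exposure and outcome effects (β_Xj, σ_Xj,
β_Yj, σ_Yj) from a :class:`~mrmediate.instruments.HarmonizedSet` and
return a causal log-effect with a normal-theory p-value and an
odds-ratio-scale confidence interval.  The inverse-variance weights are
w_j = β_Xj²/σ_Yj² throughout (first-order Wald-ratio weights).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .instruments import HarmonizedSet

_P_FLOOR = 1e-300  # keep p-values strictly positive


@dataclass
class MREstimate:
    """A causal-effect estimate on the log scale with its OR transform."""

    method: str
    beta: float
    se: float
    pvalue: float
    n_snp: int
    or_point: float
    or_lower: float
    or_upper: float
    ci_level: float = 0.95
    seed: int | None = None


@dataclass
class HeterogeneityResult:
    q_statistic: float
    df: int
    pvalue: float


def normal_p(beta: float, se: float) -> float:
    """Two-sided normal p-value for beta/se."""
    if se <= 0:
        raise ValueError("se must be positive")
    z = beta / se
    return max(2.0 * stats.norm.sf(abs(z)), _P_FLOOR)


def chisq_upper_tail(q: float, df: int) -> float:
    """Upper-tail chi-square probability (heterogeneity test tail)."""
    return float(stats.chi2.sf(q, df))


def transform_to_or(beta: float, se: float, ci_level: float = 0.95):
    """Map a log-effect and SE to an odds ratio with a Wald CI.

    Returns ``(or_point, or_lower, or_upper, pvalue)``.
    """
    if se <= 0:
        raise ValueError("se must be positive")
    z = stats.norm.ppf(0.5 + ci_level / 2.0)
    return (
        float(np.exp(beta)),
        float(np.exp(beta - z * se)),
        float(np.exp(beta + z * se)),
        normal_p(beta, se),
    )


def _estimate(method: str, beta: float, se: float, n_snp: int,
              ci_level: float, seed: int | None = None) -> MREstimate:
    orp, orl, oru, p = transform_to_or(beta, se, ci_level)
    return MREstimate(method, float(beta), float(se), p, int(n_snp),
                      orp, orl, oru, ci_level, seed)


def wald_ratio(beta_x: float, se_x: float, beta_y: float, se_y: float,
               second_order: bool = False, ci_level: float = 0.95) -> MREstimate:
    """Single-SNP causal estimate β_Y/β_X.

    First-order SE is |σ_Y/β_X|; the second-order flag adds the
    exposure-uncertainty term β_Y²σ_X²/β_X⁴ under the square root.
    """
    if beta_x == 0:
        raise ValueError("beta_x must be nonzero for a Wald ratio")
    beta = beta_y / beta_x
    var = se_y**2 / beta_x**2
    if second_order:
        var += beta_y**2 * se_x**2 / beta_x**4
    return _estimate("wald_ratio", beta, np.sqrt(var), 1, ci_level)


def _ratios_weights(hset: HarmonizedSet):
    bx, by = hset.beta_exposure, hset.beta_outcome
    sy = hset.se_outcome
    if np.any(bx == 0):
        raise ValueError("zero exposure effect among instruments")
    return by / bx, bx**2 / sy**2


def ivw_point(hset: HarmonizedSet) -> tuple[float, float, float]:
    """IVW point estimate, fixed-effect SE, and Cochran's Q."""
    ratios, w = _ratios_weights(hset)
    sw = w.sum()
    beta = float(np.sum(w * ratios) / sw)
    se_fixed = float(np.sqrt(1.0 / sw))
    q = float(np.sum(w * (ratios - beta) ** 2))
    return beta, se_fixed, q


def cochran_q(hset: HarmonizedSet) -> HeterogeneityResult:
    """Cochran's Q heterogeneity test across per-SNP Wald ratios."""
    if hset.n_snp < 2:
        raise ValueError("Cochran's Q needs at least 2 instruments")
    _, _, q = ivw_point(hset)
    df = hset.n_snp - 1
    return HeterogeneityResult(q, df, chisq_upper_tail(q, df))


def ivw(hset: HarmonizedSet, model: str = "auto",
        het_p_threshold: float = 0.05, ci_level: float = 0.95) -> MREstimate:
    """Inverse-variance-weighted estimate.

    ``model``: "fixed", "random" (multiplicative overdispersion
    sqrt(max(1, Q/(n−1)))), or "auto" — fixed when the Q-test p ≥
    ``het_p_threshold``, random otherwise (single-instrument sets are
    always fixed).
    """
    if hset.n_snp < 1:
        raise ValueError("IVW needs at least 1 instrument")
    if model not in ("fixed", "random", "auto"):
        raise ValueError(f"unknown model {model!r}")
    beta, se_fixed, q = ivw_point(hset)
    n = hset.n_snp
    if model == "auto":
        if n == 1:
            model = "fixed"
        else:
            p_het = chisq_upper_tail(q, n - 1)
            model = "fixed" if p_het >= het_p_threshold else "random"
    if model == "fixed" or n == 1:
        se = se_fixed
        label = "ivw_fixed"
    else:
        se = se_fixed * np.sqrt(max(1.0, q / (n - 1)))
        label = "ivw_random"
    return _estimate(label, beta, se, n, ci_level)


def egger(hset: HarmonizedSet, ci_level: float = 0.95
          ) -> tuple[MREstimate, MREstimate]:
    """MR-Egger regression; returns (slope, intercept) estimates.

    Instruments are oriented so β_Xj ≥ 0 (jointly negating both betas),
    then β_Yj is regressed on β_Xj with intercept, weights 1/σ_Yj².  SEs
    use a multiplicative overdispersion scale floored at 1.  The
    intercept's p-value is the directional-pleiotropy test.
    """
    n = hset.n_snp
    if n < 3:
        raise ValueError("MR-Egger needs at least 3 instruments")
    sign = np.where(hset.beta_exposure < 0, -1.0, 1.0)
    bx = hset.beta_exposure * sign
    by = hset.beta_outcome * sign
    w = 1.0 / hset.se_outcome**2

    sw = w.sum()
    swx = np.sum(w * bx)
    swxx = np.sum(w * bx**2)
    swy = np.sum(w * by)
    swxy = np.sum(w * bx * by)
    det = sw * swxx - swx**2
    if det <= 0:
        raise ValueError("degenerate design in MR-Egger (constant exposure effects)")
    intercept = (swxx * swy - swx * swxy) / det
    slope = (sw * swxy - swx * swy) / det
    resid = by - intercept - slope * bx
    rss_w = float(np.sum(w * resid**2))
    scale = max(1.0, rss_w / (n - 2))
    var_intercept = swxx / det * scale
    var_slope = sw / det * scale
    return (
        _estimate("egger_slope", slope, np.sqrt(var_slope), n, ci_level),
        _estimate("egger_intercept", intercept, np.sqrt(var_intercept), n, ci_level),
    )


def _weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted-percentile interpolation at cumulative weight one-half:
    S_j = (cumsum(w) − w_j/2)/Σw over ratios sorted ascending, linear
    interpolation between the bracketing S."""
    order = np.argsort(ratios, kind="mergesort")
    r = ratios[order]
    w = weights[order] / weights.sum()
    s = np.cumsum(w) - w / 2.0
    return float(np.interp(0.5, s, r))


def _weighted_quantile(values: np.ndarray, weights: np.ndarray,
                       q: float) -> float:
    order = np.argsort(values, kind="mergesort")
    cum = np.cumsum(weights[order]) / weights.sum()
    return float(values[order][int(np.searchsorted(cum, q))]) if q < 1 else (
        float(values[order][-1]))


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of the weighted normal-kernel density of the ratio estimates.

    Bandwidth h = phi · 0.9 · min(sd, MAD/0.6745) · n^(−1/5); when one of
    sd/MAD is zero the other is used; when both are zero (all ratios
    identical) the common ratio is returned directly.  The search grid
    spans the weighted 1%–99% ratio quantiles ± 3h with a step no coarser
    than h/4, so extreme low-weight ratios cannot starve the resolution.
    """
    n = ratios.size
    sd = float(np.std(ratios, ddof=1)) if n > 1 else 0.0
    mad = float(np.median(np.abs(ratios - np.median(ratios)))) / 0.6745
    candidates = [v for v in (sd, mad) if v > 0]
    if not candidates:
        return float(ratios[0])
    h = phi * 0.9 * min(candidates) * n ** (-1.0 / 5.0)
    lo = _weighted_quantile(ratios, weights, 0.01) - 3 * h
    hi = _weighted_quantile(ratios, weights, 0.99) + 3 * h
    grid_size = int(min(8192, max(512, np.ceil(4 * (hi - lo) / h))))
    grid = np.linspace(lo, hi, grid_size)
    wn = weights / weights.sum()
    dens = np.sum(
        wn[None, :] * np.exp(-0.5 * ((grid[:, None] - ratios[None, :]) / h) ** 2),
        axis=1)
    return float(grid[int(np.argmax(dens))])


def _bootstrap_se(hset: HarmonizedSet, point_fn, reps: int, seed: int) -> float:
    """Parametric bootstrap: redraw β_Xj, β_Yj from normal(observed, se),
    recompute the point estimate; SE is the SD across draws."""
    rng = np.random.default_rng(seed)
    bx, sx = hset.beta_exposure, hset.se_exposure
    by, sy = hset.beta_outcome, hset.se_outcome
    n = bx.size
    ests = np.empty(reps)
    for r in range(reps):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        bxs = np.where(bxs == 0, np.finfo(float).tiny, bxs)
        ests[r] = point_fn(bys / bxs, bxs**2 / sy**2)
    return float(np.std(ests, ddof=1))


def weighted_median(hset: HarmonizedSet, weights: str = "inverse_variance",
                    reps: int = 1000, seed: int = 0,
                    ci_level: float = 0.95) -> MREstimate:
    """Weighted-median estimator (consistent when valid instruments carry
    more than half the weight).  ``weights="equal"`` gives the simple
    median.  SE comes from a seeded parametric bootstrap."""
    if hset.n_snp < 3:
        raise ValueError("weighted median needs at least 3 instruments")
    if weights not in ("inverse_variance", "equal"):
        raise ValueError(f"unknown weights {weights!r}")
    if reps < 100:
        import warnings
        warnings.warn("fewer than 100 bootstrap reps; SE will be unstable")
    ratios, iv_w = _ratios_weights(hset)

    if weights == "equal":
        def point_fn(r, w):
            return _weighted_median_point(r, np.ones_like(r))
        label = "simple_median"
    else:
        def point_fn(r, w):
            return _weighted_median_point(r, w)
        label = "weighted_median"

    beta = point_fn(ratios, iv_w)
    se = _bootstrap_se(hset, point_fn, reps, seed)
    return _estimate(label, beta, se, hset.n_snp, ci_level, seed)


def weighted_mode(hset: HarmonizedSet, phi: float = 1.0, reps: int = 1000,
                  seed: int = 0, ci_level: float = 0.95) -> MREstimate:
    """Mode-based estimator: the argmax of a weighted kernel density of the
    ratio estimates — consistent when the largest group of instruments
    shares the true causal effect.  SE from a seeded parametric bootstrap."""
    if hset.n_snp < 3:
        raise ValueError("weighted mode needs at least 3 instruments")
    if phi <= 0:
        raise ValueError("phi must be positive")
    ratios, iv_w = _ratios_weights(hset)
    beta = _mode_point(ratios, iv_w, phi)
    se = _bootstrap_se(hset, lambda r, w: _mode_point(r, w, phi), reps, seed)
    return _estimate("weighted_mode", beta, se, hset.n_snp, ci_level, seed)
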