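"""Multivariable MR: joint direct effects of several exposures on one
outcome, with conditional instrument-strength statistics.

The estimator is weighted least squares of the outcome effects β_Yj on
the K exposure-effect columns without intercept, weights 1/σ_Yj²;
standard errors carry a multiplicative overdispersion scale floored at 1
(Q/(n−K)).  Measurement-error covariance between exposures is assumed
zero, as the summary statistics come from separate GWAS.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .instruments import HarmonizedSet
from .uvmr import chisq_upper_tail, transform_to_or

_COND_THRESHOLD = 1e8  # condition number above which the design is collinear


@dataclass
class MvmrResult:
    """Per-exposure direct effects with conditional F statistics."""

    table: pd.DataFrame  # exposure, beta, se, pvalue, or_*, conditional_f
    n_snp: int
    df: int
    q_statistic: float
    q_pvalue: float
    ci_level: float = 0.95

    def estimate(self, exposure: str) -> pd.Series:
        row = self.table[self.table["exposure"] == exposure]
        if row.empty:
            raise KeyError(f"no exposure {exposure!r} in MVMR result")
        return row.iloc[0]


def _check_collinear(x_mat: np.ndarray, names: list[str]) -> None:
    zero_cols = np.flatnonzero(np.all(x_mat == 0, axis=0))
    if zero_cols.size:
        raise ValueError(
            f"exposure column(s) {[names[int(i)] for i in zero_cols]} are all zero")
    cond = np.linalg.cond(x_mat)
    if cond > _COND_THRESHOLD:
        # name the most correlated pair for the error message
        c = np.corrcoef(x_mat, rowvar=False)
        np.fill_diagonal(c, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(c)), c.shape)
        raise ValueError(
            f"collinear exposure effects (condition number {cond:.3g}); "
            f"most correlated pair: {names[int(i)]!r} and {names[int(j)]!r}")


def mvmr_ivw(hset: HarmonizedSet, ci_level: float = 0.95) -> MvmrResult:
    """IVW-style multivariable MR over the exposures in ``hset``."""
    names = list(hset.exposures)
    k = len(names)
    n = hset.n_snp
    if n <= k:
        raise ValueError(f"need more instruments ({n}) than exposures ({k})")
    x = hset.exposure_matrix()
    y = hset.beta_outcome
    w = 1.0 / hset.se_outcome**2
    _check_collinear(x, names)

    xtw = x.T * w
    xtwx = xtw @ x
    xtwy = xtw @ y
    beta = np.linalg.solve(xtwx, xtwy)
    resid = y - x @ beta
    q = float(np.sum(w * resid**2))
    scale = max(1.0, q / (n - k))
    cov = np.linalg.inv(xtwx) * scale
    se = np.sqrt(np.diag(cov))

    cond_f = conditional_f(hset)
    rows = []
    for i, name in enumerate(names):
        orp, orl, oru, p = transform_to_or(beta[i], se[i], ci_level)
        rows.append({
            "exposure": name, "beta": float(beta[i]), "se": float(se[i]),
            "pvalue": p, "or_point": orp, "or_lower": orl, "or_upper": oru,
            "conditional_f": cond_f[name],
        })
    return MvmrResult(
        table=pd.DataFrame(rows),
        n_snp=n,
        df=n - k,
        q_statistic=q,
        q_pvalue=chisq_upper_tail(q, n - k),
        ci_level=ci_level,
    )


def conditional_f(hset: HarmonizedSet) -> dict[str, float]:
    """Conditional instrument strength per exposure.

    For exposure k, regress its effects β_Xk on the other exposures'
    effects (no intercept, weights 1/σ_Xkj²) and form the weighted
    residual sum of squares Q_xk = Σ_j r_jk²/σ_Xkj²; the conditional F is
    Q_xk/(n − K + 1).  With K = 1 this is the mean univariable (β/σ)² F.
    An exposure whose effects are explained by the others (e.g. a
    duplicated column) has conditional F near zero.
    """
    names = list(hset.exposures)
    k = len(names)
    n = hset.n_snp
    if n <= k:
        raise ValueError(f"need more instruments ({n}) than exposures ({k})")
    x = hset.exposure_matrix()
    sx = hset.exposure_se_matrix()
    out: dict[str, float] = {}
    for i, name in enumerate(names):
        target = x[:, i]
        v = 1.0 / sx[:, i] ** 2
        others = np.delete(x, i, axis=1)
        if others.shape[1] == 0:
            resid = target
        else:
            otw = others.T * v
            coef = np.linalg.lstsq(otw @ others, otw @ target, rcond=None)[0]
            resid = target - others @ coef
        q_x = float(np.sum(v * resid**2))
        out[name] = q_x / (n - k + 1)
    return out
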