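"""Stepwise MR mediation: total effect, direct effects, and the
product-of-coefficients indirect effect with a delta-method SE.

The decomposition follows the standard four-coefficient framework for a
single mediator M on the exposure→outcome path X→Y:

* θ1 — total effect of X on Y (univariable IVW),
* θ2 — direct effect of X on Y adjusting for M (MVMR of {X, M} on Y),
* θ3 — effect of X on M (univariable IVW),
* θ4 — direct effect of M on Y (same MVMR),
* indirect effect = θ3·θ4, with SE from the multivariate delta method
  assuming zero covariance between θ3 and θ4 (they come from separate
  regressions on two-sample summary data),
* proportion mediated = indirect/θ1 on the log-odds scale, reported as %.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .instruments import (
    HarmonizedSet, apply_exclusion_list, clump, harmonize, select_significant,
)
from .io import RunConfig, TraitTable
from .mvmr import mvmr_ivw
from .uvmr import MREstimate, ivw, normal_p, transform_to_or


@dataclass
class IndirectEffect:
    beta: float
    se: float
    pvalue: float
    or_point: float
    or_lower: float
    or_upper: float
    ci_level: float = 0.95


@dataclass
class MediationResult:
    """θ1–θ4 with the derived indirect effect and proportion mediated."""

    theta1: MREstimate   # total X→Y
    theta2: MREstimate   # direct X→Y | M
    theta3: MREstimate   # X→M
    theta4: MREstimate   # direct M→Y | X
    indirect: IndirectEffect
    proportion_mediated: float  # percent of the total effect
    n_snp_total: int = 0        # instruments behind θ1
    n_snp_mediator: int = 0     # instruments behind θ3
    n_snp_mvmr: int = 0         # instruments behind θ2/θ4
    seed: int | None = None
    adding_up_z: float | None = None  # flag |z|>2: decomposition inconsistent


def indirect_effect(theta3_beta: float, theta3_se: float,
                    theta4_beta: float, theta4_se: float,
                    ci_level: float = 0.95) -> IndirectEffect:
    """Product-of-coefficients indirect effect θ3·θ4.

    Delta-method SE with zero covariance:
    sqrt(θ4²·se3² + θ3²·se4²).
    """
    if theta3_se <= 0 or theta4_se <= 0:
        raise ValueError("standard errors must be positive")
    beta = theta3_beta * theta4_beta
    se = float(np.sqrt(theta4_beta**2 * theta3_se**2
                       + theta3_beta**2 * theta4_se**2))
    if se == 0:
        raise ValueError("degenerate indirect effect (both coefficients zero)")
    orp, orl, oru, p = transform_to_or(beta, se, ci_level)
    return IndirectEffect(beta, se, p, orp, orl, oru, ci_level)


def proportion_mediated(indirect_beta: float, total_beta: float) -> float:
    """Percentage of the total effect carried by the mediated path.

    Warns on inconsistent mediation (opposite signs, or magnitude above
    100%), where the proportion loses its usual interpretation.
    """
    if total_beta == 0:
        raise ValueError("total effect is zero; proportion undefined")
    pct = 100.0 * indirect_beta / total_beta
    if pct < 0 or pct > 100:
        warnings.warn(
            f"inconsistent mediation: proportion mediated {pct:.2f}% "
            "(opposite signs or >100%)")
    return pct


def _instrument_ids(table: TraitTable, config: RunConfig,
                    ld=None, exclusion=None) -> list[str]:
    sel = select_significant(table, config.p_threshold)
    sel = clump(sel, ld=ld, r2_threshold=config.clump_r2,
                window_kb=config.clump_window_kb)
    if exclusion:
        sel = apply_exclusion_list(sel, exclusion)
    return sel.snp_ids


def run_mediation(
    exposure: TraitTable,
    mediator: TraitTable,
    outcome: TraitTable,
    config: RunConfig | None = None,
    ld=None,
    exclusion=None,
) -> MediationResult:
    """Full stepwise mediation analysis from three summary-stat tables.

    Instruments for θ1 and θ3 are the exposure's genome-wide significant,
    clumped, exclusion-screened SNPs; the MVMR leg (θ2, θ4) uses the
    union of the exposure's and the mediator's instruments, jointly
    harmonized against the outcome.
    """
    config = config or RunConfig()

    x_ids = _instrument_ids(exposure, config, ld, exclusion)
    if len(x_ids) < 2:
        raise ValueError(
            f"too few exposure instruments ({len(x_ids)}) for the total-effect leg")
    m_ids = _instrument_ids(mediator, config, ld, exclusion)
    if len(m_ids) < 2:
        raise ValueError(
            f"too few mediator instruments ({len(m_ids)}) for the MVMR leg")

    # θ1: total effect X→Y
    h_xy = harmonize(exposure.subset(x_ids), outcome,
                     palindrome_eaf_limit=config.palindrome_eaf_limit)
    if h_xy.n_snp < 2:
        raise ValueError("too few harmonized instruments for the X→Y leg")
    theta1 = ivw(h_xy, model="auto", ci_level=config.ci_level)

    # θ3: X→M
    h_xm = harmonize(exposure.subset(x_ids), mediator,
                     palindrome_eaf_limit=config.palindrome_eaf_limit)
    if h_xm.n_snp < 2:
        raise ValueError("too few harmonized instruments for the X→M leg")
    theta3 = ivw(h_xm, model="auto", ci_level=config.ci_level)

    # θ2, θ4: MVMR of {X, M} on Y over the union of instruments
    union_ids = sorted(set(x_ids) | set(m_ids))
    h_mv = harmonize(exposure.subset(union_ids), outcome, more=[mediator],
                     palindrome_eaf_limit=config.palindrome_eaf_limit)
    if h_mv.n_snp <= 2:
        raise ValueError("too few harmonized instruments for the MVMR leg")
    mv = mvmr_ivw(h_mv, ci_level=config.ci_level)
    row2 = mv.estimate(exposure.trait_name)
    row4 = mv.estimate(mediator.trait_name)
    theta2 = MREstimate("mvmr_direct_exposure", row2["beta"], row2["se"],
                        row2["pvalue"], mv.n_snp, row2["or_point"],
                        row2["or_lower"], row2["or_upper"], config.ci_level)
    theta4 = MREstimate("mvmr_direct_mediator", row4["beta"], row4["se"],
                        row4["pvalue"], mv.n_snp, row4["or_point"],
                        row4["or_lower"], row4["or_upper"], config.ci_level)

    ind = indirect_effect(theta3.beta, theta3.se, theta4.beta, theta4.se,
                          config.ci_level)
    prop = proportion_mediated(ind.beta, theta1.beta)

    # adding-up: θ1 − (θ2 + θ3·θ4) should be near zero; reported, not enforced
    gap = theta1.beta - (theta2.beta + ind.beta)
    gap_se = float(np.sqrt(theta1.se**2 + theta2.se**2 + ind.se**2))
    adding_up_z = gap / gap_se if gap_se > 0 else float("nan")
    if abs(adding_up_z) > 2:
        warnings.warn(
            f"mediation decomposition inconsistent: adding-up z = {adding_up_z:.2f}")

    return MediationResult(
        theta1=theta1, theta2=theta2, theta3=theta3, theta4=theta4,
        indirect=ind, proportion_mediated=prop,
        n_snp_total=h_xy.n_snp, n_snp_mediator=h_xm.n_snp,
        n_snp_mvmr=h_mv.n_snp, seed=config.seed, adding_up_z=adding_up_z,
    )
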