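"""Synthetic two-sample GWAS summary statistics with known causal
structure, for testing every pipeline stage without real data.

The generator works directly on the summary-statistic scale: each SNP j
has a true per-allele effect γ_j on the exposure, the observed exposure
effect is γ_j plus sampling noise with the GWAS standard-error law
σ = 1/sqrt(2·n·f(1−f)) at allele frequency f, and the outcome effect is
θ·γ_j plus an optional horizontal-pleiotropy term α_j plus its own
sampling noise.  Binary outcomes are represented through an effective
sample size in the same law (4/(1/n_cases + 1/n_controls)).

The default configuration emulates the scale of a mediation study of a
serum-biomarker exposure on a binary reproductive-endocrine outcome with
a hormone mediator: exposure GWAS n = 417,580; outcome effective
n = 14,215 (3,609 cases / 229,788 controls); mediator n = 180,386;
300 independent instruments with per-allele effect SD 0.07 (strong
instruments, mean F in the hundreds); no pleiotropy unless requested.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .instruments import HarmonizedSet
from .io import TraitTable, table_from_arrays


@dataclass
class SimConfig:
    """Generator settings; all randomness flows from ``seed``."""

    n_snps: int = 300
    theta: float = 0.3                      # true causal effect X→Y
    mediation: tuple[float, float, float] | None = None  # (θ_xm, θ_my, θ_direct)
    gamma_sd: float = 0.07                  # SD of true SNP→X effects
    gamma_m_sd: float = 0.07                # SD of mediator-specific SNP effects
    maf_range: tuple[float, float] = (0.1, 0.4)
    n_x: float = 417_580
    n_y: float = 14_215
    n_m: float = 180_386
    pleio_prob: float = 0.0
    pleio_mean: float = 0.0                 # 0 = balanced pleiotropy
    pleio_sd: float = 0.01
    palindromic_prob: float = 0.0           # fraction of A/T SNPs injected
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps < 1:
            raise ValueError("n_snps must be at least 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        for name in ("pleio_prob", "palindromic_prob"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("gamma_sd", "gamma_m_sd", "pleio_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("n_x", "n_y", "n_m"):
            if getattr(self, name) <= 2:
                raise ValueError(f"{name} must exceed 2")


def _se_law(n: float, maf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * maf * (1.0 - maf))


def _positions(m: int) -> tuple[list[str], list[int]]:
    """Spread SNPs across chromosomes > 20 Mb apart, so distance-only
    clumping at the default 10,000 kb window keeps all of them."""
    chrom = [str(j % 22 + 1) for j in range(m)]
    pos = [1_000_000 + (j // 22) * 20_000_000 for j in range(m)]
    return chrom, pos


def _alleles(rng: np.random.Generator, m: int, palindromic_prob: float):
    mask = rng.random(m) < palindromic_prob
    oa = np.where(mask, "T", "G")  # A/T injects a palindromic SNP
    return ["A"] * m, list(oa)


def _two_sided_p(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    from scipy import stats
    p = 2.0 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, 1e-300, 1.0)


def _table(name, ids, ea, oa, chrom, pos, maf, beta, se, n, trait_type):
    return table_from_arrays(
        name, ids, ea, oa, beta, se, _two_sided_p(beta, se),
        chr=chrom, pos=pos, eaf=maf, n=[n] * len(ids), trait_type=trait_type)


def _base_draws(config: SimConfig, rng: np.random.Generator):
    m = config.n_snps
    maf = rng.uniform(*config.maf_range, size=m)
    # effects are coded on the exposure-increasing allele (half-normal γ),
    # which keeps "directional pleiotropy with mean α" well defined
    gamma = np.abs(rng.normal(0.0, config.gamma_sd, size=m))
    sx = _se_law(config.n_x, maf)
    bx = rng.normal(gamma, sx)
    pleio_mask = rng.random(m) < config.pleio_prob
    alpha = np.where(pleio_mask,
                     rng.normal(config.pleio_mean, config.pleio_sd, size=m),
                     0.0)
    ids = [f"rs{j+1}" for j in range(m)]
    chrom, pos = _positions(m)
    ea, oa = _alleles(rng, m, config.palindromic_prob)
    return maf, gamma, sx, bx, alpha, ids, chrom, pos, ea, oa


def simulate_uvmr(config: SimConfig) -> tuple[TraitTable, TraitTable, dict]:
    """Exposure and outcome summary statistics under a single causal
    effect θ, plus a truth record (γ, α, θ, seed)."""
    rng = np.random.default_rng(config.seed)
    maf, gamma, sx, bx, alpha, ids, chrom, pos, ea, oa = _base_draws(config, rng)
    sy = _se_law(config.n_y, maf)
    by = rng.normal(config.theta * gamma + alpha, sy)

    exposure = _table("exposure", ids, ea, oa, chrom, pos, maf, bx, sx,
                      config.n_x, "continuous")
    outcome = _table("outcome", ids, ea, oa, chrom, pos, maf, by, sy,
                     config.n_y, "binary")
    truth = {
        "theta": config.theta, "gamma": gamma, "alpha": alpha,
        "seed": config.seed, "config": asdict(config),
    }
    return exposure, outcome, truth


def simulate_mediation(config: SimConfig
                       ) -> tuple[TraitTable, TraitTable, TraitTable, dict]:
    """Exposure, mediator, and outcome summary statistics under the
    mediation triangle X→M→Y with a direct X→Y path.

    Per SNP: β_M ~ N(θ_xm·γ + δ, σ_M²) where δ ~ N(0, gamma_m_sd²) is a
    mediator-specific genetic effect (the mediator's own instruments),
    and β_Y ~ N(θ_direct·γ + θ_my·(θ_xm·γ + δ) + α, σ_Y²).  The implied
    total effect is θ1 = θ_direct + θ_xm·θ_my and the indirect effect is
    θ_xm·θ_my.
    """
    if config.mediation is None:
        raise ValueError("config.mediation must be set: (theta_xm, theta_my, theta_direct)")
    theta_xm, theta_my, theta_direct = config.mediation
    rng = np.random.default_rng(config.seed)
    maf, gamma, sx, bx, alpha, ids, chrom, pos, ea, oa = _base_draws(config, rng)

    delta = rng.normal(0.0, config.gamma_m_sd, size=config.n_snps)
    sm = _se_law(config.n_m, maf)
    bm = rng.normal(theta_xm * gamma + delta, sm)
    sy = _se_law(config.n_y, maf)
    by = rng.normal(theta_direct * gamma + theta_my * (theta_xm * gamma + delta)
                    + alpha, sy)

    exposure = _table("exposure", ids, ea, oa, chrom, pos, maf, bx, sx,
                      config.n_x, "continuous")
    mediator = _table("mediator", ids, ea, oa, chrom, pos, maf, bm, sm,
                      config.n_m, "continuous")
    outcome = _table("outcome", ids, ea, oa, chrom, pos, maf, by, sy,
                     config.n_y, "binary")
    total = theta_direct + theta_xm * theta_my
    truth = {
        "theta_xm": theta_xm, "theta_my": theta_my, "theta_direct": theta_direct,
        "theta_total": total,
        "indirect": theta_xm * theta_my,
        "proportion_mediated": 100.0 * theta_xm * theta_my / total if total else float("nan"),
        "gamma": gamma, "delta": delta, "alpha": alpha,
        "seed": config.seed, "config": asdict(config),
    }
    return exposure, mediator, outcome, truth


def inject_outliers(hset: HarmonizedSet, indices: list[int],
                    magnitude_sd: float) -> HarmonizedSet:
    """Shift β_Yj by ``magnitude_sd`` outcome standard errors at the given
    positions; the returned set carries a boolean ``injected_outlier``
    column as the truth flag."""
    n = hset.n_snp
    for i in indices:
        if not 0 <= int(i) < n:
            raise IndexError(f"outlier index {i} out of range for {n} instruments")
    data = hset.data.copy()
    flag = np.zeros(n, dtype=bool)
    for i in indices:
        data.loc[int(i), "beta_outcome"] += magnitude_sd * data.loc[int(i), "se_outcome"]
        flag[int(i)] = True
    data["injected_outlier"] = flag
    return HarmonizedSet(data, list(hset.exposures))
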