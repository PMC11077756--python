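# mrmediate

Two-sample Mendelian randomization (MR) with mediation, from GWAS summary
statistics to a decomposed causal effect.

MR uses genetic variants as instrumental variables: a SNP that robustly
shifts an exposure X, is independent of confounders, and affects the
outcome Y only through X identifies the causal effect of X on Y from
observational data. `mrmediate` implements the full summary-statistic
workflow for this design — including the mediation extension that asks how
much of the X→Y effect flows through an intermediate trait M (for example,
how much of the effect of serum vitamin D on polycystic ovary syndrome risk
is carried by bioavailable testosterone).

## What it computes

**Instrument processing** — genome-wide-significance selection
(*P* < 5×10⁻⁸), greedy LD clumping (r² ≤ 0.001 within 10,000 kb by
default), confounder exclusion lists, allele harmonization (swapped
alleles, strand complements, frequency-resolved palindromic SNPs), and
per-instrument strength: R²ⱼ = βⱼ²/(βⱼ² + nσⱼ²) and
Fⱼ = R²ⱼ(n−2)/(1−R²ⱼ).

**Univariable estimators** — with per-SNP Wald ratios β̂ⱼ = β_Yj/β_Xj and
inverse-variance weights wⱼ = β²_Xj/σ²_Yj:

* IVW: β̂ = Σwⱼβ̂ⱼ / Σwⱼ, fixed-effect SE √(1/Σwⱼ), random-effects SE
  inflated by √max(1, Q/(J−1)); the fixed/random choice follows Cochran's
  Q test at *P* ≥ 0.05.
* MR-Egger: weighted regression of β_Yj on β_Xj with intercept; the
  intercept tests directional pleiotropy.
* Weighted and simple median: weighted-percentile interpolation at
  cumulative weight ½; parametric-bootstrap SEs.
* Weighted mode: argmax of a weighted kernel density of the ratio
  estimates; parametric-bootstrap SEs.

**Diagnostics** — Cochran's Q, leave-one-out IVW, funnel-plot data, and a
simulation-based pleiotropy residual test (global RSS test, per-SNP
outlier p-values with multiplicity adjustment, and a distortion test),
all seeded and bit-reproducible.

**Multivariable MR and mediation** — MVMR as weighted least squares of
β_Yj on several exposures' effects (no intercept) with conditional F
statistics per exposure; the four-coefficient mediation decomposition

    θ1 = total X→Y    θ2 = direct X→Y | M    θ3 = X→M    θ4 = direct M→Y | X

with indirect effect θ3·θ4, delta-method SE
√(θ4²se₃² + θ3²se₄²), and proportion mediated = θ3·θ4/θ1 (log-odds
scale, reported as a percentage).

**Enrichment tail** — cis-eQTL gene annotation (*P* < 5×10⁻⁸ and
BH-FDR < 0.05) and hypergeometric over-representation tests against GMT
gene sets.

**Synthetic data** — a generator of two-sample summary statistics with
known causal structure (configurable θ, instrument strength, balanced or
directional pleiotropy, injected outliers, and a full mediation triangle),
so every stage is testable without any data download.

## Worked example

```python
import mrmediate as mm

# a mediation triangle X -> M -> Y with a direct path:
# theta_xm = -0.3, theta_my = 0.4, theta_direct = -0.2
cfg = mm.SimConfig(n_snps=300, mediation=(-0.3, 0.4, -0.2), seed=7)
exposure, mediator, outcome, truth = mm.simulate_mediation(cfg)
res = mm.run_mediation(exposure, mediator, outcome)
```

This prints (via the `mediate` CLI or simple formatting of the result):

```
theta1: beta -0.2873 (SE 0.0282), OR 0.750 (0.710-0.793), P 0.000
theta2: beta -0.1857 (SE 0.0128), OR 0.831 (0.810-0.852), P 0.000
theta3: beta -0.2451 (SE 0.0619), OR 0.783 (0.693-0.884), P 0.000
theta4: beta  0.4126 (SE 0.0117), OR 1.511 (1.477-1.546), P 0.000
indirect: beta -0.1011 (SE 0.0257), OR 0.904 (0.859-0.950), P 0.000
proportion mediated: 35.20%
```

The generator's implied truth is a total effect of −0.32 with indirect
effect −0.12 (37.5% mediated); the pipeline recovers −0.287 and −0.101
(35.2%) from 247 exposure instruments and 290 union instruments in the
multivariable leg — within sampling error of the truth.

The odds-ratio transform reproduces standard epidemiological reporting:
a log-odds estimate of −0.2871 (SE 0.1253) maps to
OR 0.750 (95% CI 0.587–0.959), *P* = 0.022.

A bidirectional univariable analysis with diagnostics and a rendered
report:

```bash
mrmediate simulate --out sim/ --seed 7
mrmediate run --exposure sim/exposure.tsv --outcome sim/outcome.tsv --out report/
cat report/report.txt
```

## Layout

| module | contents |
|---|---|
| `mrmediate.io` | summary-stat TSV / GMT / LD-matrix / eQTL I/O, run config |
| `mrmediate.instruments` | selection, clumping, harmonization, strength |
| `mrmediate.uvmr` | Wald ratio, IVW, Egger, medians, mode, OR transform |
| `mrmediate.diagnostics` | leave-one-out, pleiotropy residual test, funnel data |
| `mrmediate.mvmr` | multivariable IVW, conditional F |
| `mrmediate.mediation` | product-of-coefficients decomposition |
| `mrmediate.enrichment` | eQTL annotation, hypergeometric ORA |
| `mrmediate.simulate` | synthetic summary-statistic generator |
| `mrmediate.pipeline` / `mrmediate.cli` | orchestration, reports, CLI |

See `docs/methods.md` for the statistical model, default parameters, and
known limitations.
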