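# Methods

## Model and assumptions

`mrmediate` operates entirely on GWAS summary statistics. For instrument
j, the observed exposure effect β_Xj and outcome effect β_Yj (with
standard errors σ_Xj, σ_Yj) come from two non-overlapping samples. The
instrumental-variable assumptions are the usual three: relevance (the SNP
affects the exposure), exchangeability (no confounding of the
SNP–outcome relationship), and exclusion restriction (no effect on the
outcome except through the exposure). Under them each Wald ratio
β_Yj/β_Xj estimates the causal effect θ, and the estimators differ in how
they behave when the exclusion restriction fails for some instruments:

* **IVW** is efficient when all instruments are valid. Weights are the
  first-order Wald weights w_j = β²_Xj/σ²_Yj, which treat β_Xj as known
  (the no-measurement-error approximation — reasonable when F ≫ 10).
* **MR-Egger** allows all instruments a directional pleiotropic effect
  provided instrument strength is independent of it (InSIDE); the
  intercept estimates the average pleiotropy, the slope the causal
  effect. Instruments are oriented so β_Xj ≥ 0 before fitting, the
  standard convention that makes the intercept's sign meaningful.
* **Weighted median** is consistent while valid instruments carry more
  than half the total weight.
* **Weighted mode** is consistent while the largest group of instruments
  sharing a ratio value is valid.

The mediation decomposition treats one mediator M on the X→Y path:
θ1 (total, univariable IVW of X on Y), θ3 (univariable IVW of X on M),
and (θ2, θ4) as the two coefficients of a multivariable MR of {X, M} on
Y. The indirect effect is the product θ3·θ4 with delta-method SE
√(θ4²se₃² + θ3²se₄²), omitting the θ3–θ4 covariance because the two
coefficients come from different regressions fitted to summary data from
separate GWAS. The proportion mediated is θ3·θ4/θ1 computed on the
log-odds scale. θ3 is estimated univariably: with a single mediator
there is no second mediator to adjust for, so the univariable and
mediator-adjusted X→M estimates coincide structurally; an MVMR variant
can be substituted by calling `mvmr_ivw` on an {X}-plus-covariates set.
An adding-up diagnostic θ1 − (θ2 + θ3·θ4), with its own delta-method SE,
is reported and flagged at |z| > 2 but never enforced.

## Instrument pipeline

Selection keeps P < 5×10⁻⁸ (strict). Clumping is greedy: sort by
ascending p (ties by snp_id, which makes the result independent of row
order), keep the best remaining SNP, and remove same-chromosome
neighbours within the window whose r² exceeds the threshold — or all
neighbours within the window when no LD matrix is supplied. The
distance-only mode exists because summary files rarely ship with an LD
reference; it is a conservative approximation that can discard
independent signals on the same chromosome.

Harmonization aligns every other trait to the exposure's effect allele:
same alleles pass through, swapped alleles negate the other trait's beta
and complement its frequency, strand-complement reports are re-keyed, and
palindromic (A/T, C/G) SNPs are resolved by allele frequency only when
both frequencies are decisive — min(eaf, 1−eaf) ≤ 0.42, the conventional
intermediate-frequency cutoff — and dropped otherwise. Every input SNP
receives exactly one provenance label (kept, flipped, or a drop reason),
and the label counts partition the input.

Instrument strength uses R²_j = β²_j/(β²_j + nσ²_j) (the
allele-frequency terms 2f(1−f) cancel) and F_j = R²_j(n−2)/(1−R²_j);
without allele frequencies the fallback is F_j = (β_j/σ_j)², which
differs only by the factor (n−2)/n. Instruments with F < 10 are flagged,
not dropped, matching how applied analyses report strength post hoc.

## Pleiotropy residual test

The global statistic is RSS = Σ_j (β_Yj − β̂₍₋ⱼ₎β_Xj)², each residual
taken against the leave-one-out IVW slope so an outlier cannot mask
itself. The null distribution is simulated: β*_Xj ~ N(β_Xj, σ_Xj),
β*_Yj ~ N(β̂₍₋ⱼ₎β_Xj, σ_Yj), with the statistic recomputed identically
per replicate. Empirical p-values use an add-one pseudocount
(1 + #{≥ observed})/(n_sims + 1) so they are never zero. Per-SNP
outlier p-values are Bonferroni-adjusted by default (Benjamini–Hochberg
available); with 1000 simulations the smallest attainable raw p is
1/1001, so detection at α = 0.05 after Bonferroni is possible for up to
~50 instruments — use more simulations for larger sets. The distortion
test compares the shift in the IVW estimate after removing the flagged
outliers against shifts from removing random subsets of the same size,
and is reported as missing when nothing is flagged.

## Multivariable MR

β_Yj is regressed on the K exposure-effect columns without intercept,
weights 1/σ²_Yj. SEs carry a multiplicative overdispersion scale
max(1, Q/(n−K)), mirroring the Egger convention of flooring at 1 (no
underdispersion). Instruments are the union of the exposures' individual
instrument sets after joint harmonization — prevailing practice; an
intersection can be obtained by subsetting before the call. Conditional
instrument strength for exposure k regresses β_Xk on the other
exposures' effects (weights 1/σ²_Xkj, no intercept) and forms
F_k = Q_xk/(n − K + 1) from the weighted residual sum of squares; at
K = 1 this reduces exactly to the mean univariable (β/σ)² F.
Measurement-error covariance between exposures is taken as zero, which
is correct for non-overlapping GWAS samples and an approximation
otherwise (a documented limitation; UK-Biobank-heavy exposure panels do
overlap in practice).

## Synthetic data generator

The generator emulates the summary-statistic layer directly — no
individual-level genotypes. Per SNP: allele frequency f ~ U(0.1, 0.4);
true effect γ_j = |N(0, 0.07²)| coded on the exposure-increasing allele
(half-normal, so that "directional pleiotropy with mean α₀" is well
defined under an arbitrary-sign coding it would not be); sampling SE
σ = 1/√(2nf(1−f)); observed effects are truth plus N(0, σ²) noise.
Horizontal pleiotropy adds α_j ~ N(α₀, σ_α²) to the outcome effect with
probability `pleio_prob` (α₀ = 0 gives balanced pleiotropy satisfying
InSIDE). In the mediation generator each SNP also carries a
mediator-specific effect δ_j ~ N(0, 0.07²) — the mediator's own
instruments, without which the {X, M} design matrix would be
signal-rank-1 and the MVMR coefficients unidentified — and
β_M = θ_xm γ + δ + noise, β_Y = θ_direct γ + θ_my(θ_xm γ + δ) + α + noise.
The implied totals are θ1 = θ_direct + θ_xm θ_my and indirect
θ_xm θ_my.

Default sample sizes mirror a mediation study of a serum biomarker on a
binary reproductive-endocrine outcome: exposure GWAS n = 417,580;
binary-outcome effective n = 14,215, i.e. 4/(1/3609 + 1/229,788) cases
and controls folded into the same SE law (a standard approximation for
log-odds summary statistics); mediator n = 180,386. The per-allele
effect SD of 0.07 puts simulated instruments in the strong regime (mean
F in the hundreds), consistent with genome-wide-significant instruments
from a ~400k-sample GWAS. SNPs are placed >20 Mb apart so default
clumping is a no-op unless an LD matrix is supplied; LD itself is not
simulated (clumping is exercised with hand-written matrices in the
tests), and there is no winner's-curse modelling — what passing recovery
tests show is correctness of the estimators under clean two-sample
sampling, not robustness to LD misspecification or selection bias in
real discovery GWAS.

## Numerical choices

* All p-values use the normal (not t) reference and are floored at
  1e-300 to stay in (0, 1].
* Wald-ratio SEs are first-order by default (matching the IVW weights);
  the second-order term is available by flag.
* The fixed/random IVW branch point is the Q-test p ≥ 0.05, configurable.
* Median/mode SEs come from a parametric bootstrap (default 1000 reps)
  redrawing β_X and β_Y from their reported SEs; results are
  bit-reproducible given (seed, reps).
* Mode bandwidth h = φ·0.9·min(sd, MAD/0.6745)·J^(−1/5) over the ratio
  estimates; when one of sd/MAD is zero the other is used, and when both
  are zero the common ratio is returned outright. The density argmax is
  searched on a grid spanning the weighted 1%–99% ratio quantiles ± 3h
  with step ≤ h/4 (512–8192 points): bounding by quantiles rather than
  the raw range keeps resolution when a few near-zero-β_X instruments
  produce extreme ratios.
* Clumping ties are broken by ascending snp_id; collinearity in MVMR is
  declared above condition number 1e8 with the most-correlated pair named.
* Degenerate inputs fail loudly: zero β_X in a Wald ratio, n ≤ K in
  MVMR, fewer instruments than an estimator's minimum (1 for IVW, 2 for
  Q, 3 for Egger/median/mode/leave-one-out, 4 for the residual test).

## Acceptance harness sizes

The recovery and calibration checks run 100–200 seeded replicates of
300-SNP (estimators, mediation) or 30-SNP (residual test, 1000
simulations each) datasets — sizes at which the Monte-Carlo error of a
replicate mean is a few times smaller than the tolerances being checked.
Estimator-recovery harnesses apply the genome-wide-significance
selection step before estimating, exactly as the pipeline does; the
estimators' guarantees presume instruments with non-degenerate Wald
ratios, and unselected near-null SNPs violate that premise by
construction.

## Known limitations

* No proxy-SNP lookup and no LD computation from reference genotypes.
* Distance-only clumping over-prunes same-chromosome independent hits.
* The binary-outcome effective-n SE law is approximate; it matters only
  for the generator, not for analysis of real summary files.
* One mediator at a time; no multi-mediator network decomposition.
* The enrichment stage is a generic over-representation test on
  user-supplied gene sets; it performs no ontology-graph propagation.
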