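# Methods

## Statistical model

Two-sample summary-data MR treats each instrument SNP *j* as providing a
noisy ratio estimate of a single causal effect β of the exposure on the
outcome. Writing ξ_j for the true SNP-exposure effect, the working model is

    β̂_xj ~ N(ξ_j, σ²_xj),    β̂_yj ~ N(β ξ_j + α_j, Ω),

with α_j a direct (pleiotropic) effect of the SNP on the outcome and Ω the
outcome-coefficient covariance. Exposure-side and outcome-side errors are
independent (the two-sample design: coefficients come from disjoint
studies). For binary traits all coefficients are log odds ratios; the data
model carries trait labels, not link functions.

### Estimators

**Wald ratio.** β̂_j = β̂_yj/β̂_xj. The default standard error is the
first-order delta approximation σ_yj/|β̂_xj|, which matches the weight
construction of the IVW estimator; `se_method="second_order"` adds the
exposure-noise term β̂²_yj σ²_xj / β̂⁴_xj.

**IVW fixed effects.** The precision-weighted mean of the Wald ratios with
weights w_j = β̂²_xj/σ²_yj, computed in closed form. The equivalence to the
zero-intercept weighted regression of β̂_y on β̂_x (weights 1/σ²_yj) is not
assumed — it is verified against an independent weighted-least-squares
implementation in the test suite to ≥10 significant figures.

**IVW random effects.** Additive DerSimonian–Laird: τ² =
max(0, (Q−df)/(Σw − Σw²/Σw)) from the fixed-effects Q, then re-weighting by
1/(σ²_yj/β̂²_xj + τ²). The additive flavour was chosen over the
multiplicative one because it is the conventional meta-analysis default and
reduces *exactly* to the fixed-effects estimate when τ² truncates to zero
(the truncation is exercised by the worked four-SNP example, where
Q ≈ 0.27 < 3 df). A multiplicative variant would be a natural extension.

**Correlated instruments (GLS).** When instruments are in LD with signed
correlations r_jk, the outcome coefficients share sampling noise:
Ω_jk = σ_yj σ_yk r_jk. Then β̂ = (β̂_xᵀΩ⁻¹β̂_x)⁻¹ β̂_xᵀΩ⁻¹β̂_y with
se = (β̂_xᵀΩ⁻¹β̂_x)^{-1/2}. With Ω diagonal this is algebraically the IVW
fixed-effects estimator (checked to machine precision). Any pair with
|r| ≥ 0.999 makes Ω numerically singular; the estimator refuses and advises
pruning rather than silently regularizing.

**Correlated instruments (profile ML).** The likelihood above is maximized
jointly over (β, ξ). For fixed β the optimal ξ solves the linear system
(Σ_x⁻¹ + β²Ω⁻¹)ξ = Σ_x⁻¹β̂_x + βΩ⁻¹β̂_y, so β is found by 1-D Brent search
on the profile log-likelihood (xtol 1e-10; a bounded fallback of ±50 around
the GLS start guards bracketing failure). The standard error is the inverse
square root of the profile curvature at the optimum, obtained by central
finite differences with step max(1e-5, 1e-4·|β̂|); the profile curvature
equals the observed information for β with ξ concentrated out. As
σ_x → 0 the profile ML estimate and its SE converge to GLS (tested within
1% of the SE); with σ_x > 0 its SE is wider than GLS, as it should be,
because GLS conditions on the observed β̂_x.

**MR-Egger.** Instruments are first oriented so every β̂_xj ≥ 0 (negating
both coefficients of a SNP is a relabelling of its effect allele, so the
fit is invariant to arbitrary pre-flips — tested). Then a weighted
regression β̂_y = α + β β̂_x with weights 1/σ²_yj, solved by the normal
equations. Standard errors use the estimated residual scale
(multiplicative overdispersion, RSS_w/(n−2)), so the intercept test remains
calibrated when balanced pleiotropy inflates residual variation beyond the
reported σ_y. Reference distribution is normal by default (1.96
multiplier, the summary-data MR convention); `use_t=True` switches to
t(n−2), which matters for very few instruments. The intercept α estimates
the average directional pleiotropic effect under InSIDE (instrument
strength independent of direct effects); its p-value is the pleiotropy
test. An exact-fit regression has zero residual scale; the degenerate
p-values (0 or 1) are handled explicitly and `MREstimate` therefore admits
se = 0.

**Heterogeneity.** Q = Σ w_j (β̂_j − β̂_IVW)² on n−1 df with the IVW
weights; I² = max(0, 100(Q−df)/Q). The I² confidence interval is the
Higgins–Thompson test-based interval on log H (H² = Q/df): for Q > df,
se(ln H) = ½(ln Q − ln df)/(√(2Q) − √(2df−1)), otherwise the small-Q
closed form; H is truncated at 1 and I² to [0, 100]. For df = 1 with
Q ≤ 1 the interval is reported as the uninformative [0, 100].

### Scale conversion and power

Per-doubling rescaling multiplies the log effect, its SE and CI by the
rounded constant **0.693** by default — deliberately not ln 2 =
0.6931… — so that published per-doubling figures reproduce digit-for-digit;
`exact_ln2=True` gives the exact constant. P-values are never recomputed
after rescaling (the z-statistic is scale-invariant).

Power for a binary outcome uses the standard normal approximation
z = |ln OR|·√(n·R²·k(1−k)), power = Φ(z − z_{1−α/2}), with k the case
fraction and R² the exposure variance explained by the instruments. At the
motivating study's stated inputs (n ≈ 150,064, k ≈ 0.2465, R² = 0.0003,
OR 1.1) this formula yields ≈ 4.6% — far from the 86% reported alongside
those inputs in the source analysis. The inputs behind that 86% are not
recoverable, so the package implements the standard formula and flags the
discrepancy here rather than tuning to reproduce the number.

## Harmonization rules

Only SNPs present in both studies are used. Outcome alleles are matched to
the exposure's effect/other alleles directly, swapped (sign flip), or via
strand complement (A↔T, C↔G) before a SNP is declared an allele mismatch —
arrays of the relevant era were not strand-consistent. Palindromic SNPs
(A/T, G/C) cannot be oriented from labels; they are oriented by comparing
effect-allele frequencies to 0.5 when both frequencies are available and
both lie outside 0.5 ± `eaf_tolerance` (default 0.08, conventional
harmonization practice), and are otherwise dropped (default) or kept as
labeled. Harmonization never changes |β̂_y| or σ_y, is idempotent, and
commutes with relabelling a variant onto its other allele; all three
properties are tested.

## Instrument selection

`prune_ld` implements stepwise pruning: repeatedly find a pair with
r² ≥ threshold (default 0.9, with "≥" as the inclusion rule), keep one
member uniformly at random, drop the other. The pair scan is lexicographic
in rsID and the random choice is driven by a seeded generator, making the
procedure reproducible and invariant to input order — a pure "pick one of
each pair at random" rule is otherwise irreproducible. `find_proxies` maps
instruments missing from the outcome panel to the available SNP with
maximal r², requiring strictly r² > 0.9 (note the deliberate asymmetry:
strict ">" for proxies, "≥" for pruning, matching the two stated rules),
ties broken to the lexicographically smallest rsID. LD matrices store
*signed* r (required by Ω); matrices supplied as r² get positive signs and
a warning.

## Synthetic-data generator

`simulate_two_sample` draws ξ_j ~ N(μ_x, s_x²), pleiotropy α_j (zero /
balanced N(0, s_α²) / directional N(μ_α, s_α²)), and observed coefficients
by adding independent Gaussian noise at the reported SEs — jointly with
covariance Ω when an LD matrix is supplied, on both sides. Pleiotropy is
independent of ξ by default (InSIDE holds by construction);
`inside_violation` ∈ [−1, 1] correlates α with ξ to exercise Egger's
failure mode. Records round-trip through the same delimited format the
reader consumes.

Defaults — n_snps = 50, ξ ~ N(0.1, 0.03), σ_x = 0.003, σ_y = 0.013,
s_α = 0.005, μ_α = 0.01 — represent strongly associated instruments from a
well-powered discovery GWAS feeding a large case-control outcome GWAS
(per-SNP exposure F ≈ (0.1/0.003)² ≈ 10³). Instrument strength was fixed at
this level so that weak-instrument attenuation of IVW (a factor
≈ 1/(1 + σ_x²/E[ξ²]) ≈ 0.999) is negligible against Monte-Carlo error in
the recovery studies; with borderline genome-wide-significant instruments
(β̂_x/σ_x ≈ 5.5) the same attenuation is ≈ 2–3% of β and real analyses in
that regime inherit it. When a noise sd of exactly 0 is requested
(noiseless checks), no noise is drawn and the *reported* SEs are floored at
1e-12 so records remain valid and weights finite.

What the generator does **not** emulate: sample overlap between the two
studies (overlap biases toward the null and is out of scope), case-control
ascertainment, allele-frequency-dependent effect sizes, winner's-curse
selection of instruments, and population stratification. Tests passing on
this generator therefore demonstrate correctness of the estimators under
the stated sampling model, not robustness to those real-data phenomena.

## Verification at a glance

- Worked four-SNP example: IVW OR 2.17 per unit (1.74–2.70), 1.71 per
  doubling; Q = 0.266 on 3 df, I² = 0. Recomputed end-to-end by the
  pipeline and by `scripts/acceptance.py`.
- Dual-route checks: closed-form IVW vs an independent WLS implementation
  (100 random instances, ≥10 significant figures); GLS with identity LD vs
  IVW (machine precision); profile ML vs GLS in the σ_x → 0 limit (≤1% of
  SE).
- Monte Carlo (sizes chosen to keep the default suite fast while leaving
  Monte-Carlo error well below the tolerances): 1000 replicates × 50 SNPs
  for IVW recovery at β ∈ {0, 0.3} and for Egger-intercept recovery of
  directional pleiotropy (within 3 MC SEs); 2000 replicates for the 5%
  calibration of the Q test (no-pleiotropy null) and the Egger intercept
  test (balanced-pleiotropy null), empirical rates required in
  [0.03, 0.07].

## Known limitations

- No weighted-median/mode estimators, multivariable MR, or Rücker Q′.
- The GLS/ML correlated estimators require a *signed* LD matrix; r²-only
  input forces a positive-sign assumption that can be wrong for variants
  whose effect alleles are negatively phased.
- The Egger intercept is only interpretable under InSIDE; the generator's
  `inside_violation` knob exists precisely to show it failing.
- Single-SNP analyses rely on the first-order Wald SE by default, which
  understates uncertainty when the instrument is weak.
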