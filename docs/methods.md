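# Methods

## Setting and model

`corrmr` estimates the causal effect of an exposure on an outcome from
two independent sets of GWAS summary statistics (two-sample MR), in the
regime where the genetic instruments are allowed to remain correlated:
instruments are thinned only to pairwise LD r² ≤ 0.30, and the residual
correlation is carried through the analysis rather than ignored.

Per harmonized variant *j* the inputs are the exposure association
(β̂ₓⱼ, σₓⱼ), the outcome association (β̂ᵧⱼ, σᵧⱼ), and a signed Pearson
correlation matrix **R** of the instrument dosages estimated from a
reference genotype panel. Under the linear causal model
βᵧⱼ = θ·βₓⱼ + αⱼ (αⱼ the horizontal-pleiotropy effect of variant *j*),
the sampling covariance of the outcome effect estimates of correlated
variants measured in one cohort is approximately

    Ω = diag(σᵧ) · R · diag(σᵧ),

and both estimators are GLS fits under Ω:

- **IVW** — regression through the origin; α ≡ 0 assumed. The estimator
  is linear in β̂ᵧ, so with Ω correct its stated SE is exact.
- **Egger** — free intercept; the intercept estimates the mean
  directional pleiotropy and the slope stays consistent when instrument
  strength is independent of pleiotropy (InSIDE).

Exposure-side sampling error is ignored (the standard first-order
two-sample approximation). This is the main reason the instrument
strength screen matters: with weak instruments, error in β̂ₓ attenuates
the slope and, because exposure effects cluster near zero, biases the
Egger intercept. The F > 24 screen keeps this second-order term
negligible at the sample sizes the package targets (see
"Synthetic-data generator" below for a quantification).

### Orientation

IVW is invariant to jointly flipping (β̂ₓⱼ, β̂ᵧⱼ, row/col *j* of **R**);
Egger is not, because the intercept's sign depends on the allele coding.
Before an Egger fit every variant is oriented so β̂ₓⱼ ≥ 0 (flipping β̂ᵧⱼ
and the signed correlations accordingly). A directional-pleiotropy mean
is therefore defined relative to the exposure-increasing allele.

## Pipeline

1. **Harmonization.** Exposure and outcome records are matched by
   variant id and aligned to the exposure's effect allele: direct match,
   orientation swap (β negated, frequency reflected), or strand
   complement. Palindromic variants (A/T, G/C) are kept only when both
   effect-allele frequencies lie outside 0.5 ± 0.08 (configurable) and
   fall on the same side of 0.5; anything ambiguous or irreconcilable is
   dropped and tallied by reason. Identity is by variant id (rsID-keyed
   sources), not chrom:pos.
2. **Selection.** F = (β̂ₓ/σₓ)² > 24 and MAF ≥ 0.01 (exposure frequency,
   falling back to the panel's); then greedy clumping: repeatedly retain
   the smallest-p candidate (ties broken lexicographically for
   determinism) and drop remaining candidates with r² > 0.30 against it.
   Clumping is genome-wide within the candidate set — no distance
   window.
3. **LD.** Signed r from the panel dosages (missing dosages mean-imputed
   per variant, which keeps the matrix PSD by construction), then
   conditioned to positive definiteness by flooring eigenvalues at
   1e-4 × λ_max and restoring the unit diagonal via the symmetric
   scaling D^(-1/2) A D^(-1/2) (overwriting the diagonal directly could
   break definiteness).
4. **Diagnostics.** Iteratively (≤ 10 rounds): compute the GLS hat
   matrix H = X(XᵀΩ⁻¹X)⁻¹XᵀΩ⁻¹; flag leverage hⱼⱼ > 3 × mean(h); flag
   outliers whose squared decorrelated residual — the elementwise square
   of L⁻¹(β̂ᵧ − ŷ), L the Cholesky factor of Ω, which reduces to
   (residual/σᵧ)² for independent instruments — exceeds 6.63, the χ²₁
   0.99 quantile. Remove flagged variants, refit; stop when nothing is
   flagged or removal would drop below the model minimum. Removing every
   instrument is a hard error.
5. **Model selection.** Both estimators are fit on the diagnostics-
   cleaned set (diagnostics run under IVW, so the Rücker/Bowden
   comparison sees identical instrument sets — the Q-difference test is
   only meaningful like-for-like); Egger is chosen when
   Q_IVW − Q_Egger > χ²₁(0.95); fewer than 3 instruments force IVW.
6. **Presentation.** Binary outcomes: OR = exp(θ̂) with Wald 95% CI
   using the fixed multiplier 1.959964; display rounding to 2 dp in the
   style `OR 0.83, 95%CI 0.79; 0.88`. Normal (not t) inference
   throughout — instrument counts in the target applications are large.
7. **Scanning.** `run_scan` runs every exposure × outcome pair, isolates
   failures as flagged rows, marks significance at α = 0.05 and a
   corrected α, and applies a per-exposure KS test of the p-values
   against U(0,1) (exact p for n ≤ 35, asymptotic above; a pooled mode
   exists). The default corrected α is 1.25×10⁻², the value quoted for
   20 outcome traits in the setting this package targets; note
   0.05/20 = 2.5×10⁻³ — the two conventions disagree, so the threshold
   is a parameter rather than a constant.

## Tunable parameters

| Parameter | Default | Meaning |
|---|---|---|
| `f_min` | 24 | single-variant F (squared z) strength screen |
| `maf_min` | 0.01 | minor-allele-frequency screen |
| `r2_max` | 0.30 | pairwise LD ceiling in clumping |
| `palindromic_eaf_window` | 0.08 | ambiguity window around eaf 0.5 |
| `epsilon` (PD floor) | 1e-4 | eigenvalue floor relative to λ_max |
| `leverage_multiplier` | 3 | hat-diagonal exclusion threshold |
| `outlier_chisq` | 6.63 | χ²₁(0.99) residual exclusion threshold |
| `max_iterations` | 10 | diagnostic refit rounds |
| `alpha_sel` | 0.05 | Rücker/Bowden Q-difference level |
| `alpha_primary` / `alpha_corrected` | 0.05 / 1.25e-2 | scan flags |

## Synthetic-data generator

The generator (`corrmr.simulate`) emulates the two-sample aggregate-data
setting: summary statistics are produced directly at the summary level
(true marginal effect + correlated Gaussian noise with analytic SEs),
while the reference panel is individual-level for LD realism.

- **Sample sizes** default to an exposure GWAS of 36,548, an outcome
  GWAS of 60,620 and a 5,000-subject panel — the scale of the
  imaging-GWAS/disease-GWAS applications the package is aimed at.
- **Effects.** Exposure effects are half-normal with
  `variant_effect_sd` = 0.1 per allele on a unit-variance trait: the
  strength of genome-wide-significant hits at these sample sizes
  (z ≈ 12), chosen so the F > 24 screen is essentially non-binding, as
  it is for published instruments. SEs are 1/√(n·2p(1−p)) for
  quantitative traits and 1/√(n·cf(1−cf)·2p(1−p)) on the log-odds scale
  for binary outcomes with case fraction cf (an approximation).
- **LD.** Binary genotype correlations are Fréchet-bounded by the allele
  frequencies, so correlated structures are built directly on the
  allele scale rather than by thresholding latent Gaussians (which
  attenuates the correlation): AR(1) uses a stationary binary Markov
  chain whose lag-ℓ correlation is exactly ρ^ℓ, with the MAF sequence
  sampled under the feasibility constraint; exchangeable blocks use a
  shared-ancestor copy construction (pairwise correlation exactly ρ,
  one MAF per block). This mirrors real data, where tightly linked
  variants necessarily have similar frequencies. Infeasible
  (ρ, maf_range) combinations raise instead of silently delivering less
  correlation than requested.
- **Noise correlation.** Effect-estimate noise across variants within
  one GWAS is drawn MVN(0, diag(se)·R·diag(se)) — the same structure
  the GLS assumes; the generative truth (slope, pleiotropy, LD, SEs) is
  returned alongside the data for recovery tests. `simulate_grid`
  extends this to one exposure against many outcomes with shared
  genetic truth, the layout of a phenome-wide scan.

What the generator does **not** emulate: realistic human LD maps,
winner's curse in the published exposure GWAS, sample overlap between
the two GWAS, allele-frequency estimation error, strand errors, or
non-linear exposure–outcome relations. Passing calibration on synthetic
data therefore demonstrates internal statistical correctness of the
estimators and pipeline under the stated model, not robustness to those
real-data pathologies.

## Validation and problem sizes

The reference calibration design (used by `tests/test_acceptance.py` and
`scripts/acceptance.py`) is: k = 50 instruments, AR(1) lag-1 correlation
0.5, exposure/outcome GWAS of 50,000, LD estimated from a 2,000-subject
panel, 500 Monte-Carlo repetitions per study — sizes chosen so a full
validation pass completes in about a minute on one core while leaving
Monte-Carlo error well below the tolerances tested. Under it the
pipeline recovers a true slope of 0.2 within Monte-Carlo error, holds
95% CI coverage in [0.92, 0.975], keeps type-I error inside the 99%
binomial band around 0.05, recovers a directional-pleiotropy mean of
0.05 in the Egger intercept, and selects Egger essentially always under
directional pleiotropy versus ≈ α under the null. A separate study at
ρ = 0.7 shows why the GLS step exists: identity-LD ("naive") IVW
coverage collapses below 0.92 while the GLS CI keeps nominal coverage.

## Numerical choices and edge cases

- Ω is factored by Cholesky; a non-PD matrix after conditioning is a
  hard error rather than a silent pseudo-inverse.
- Clump ties on p-value break lexicographically by variant id; scan row
  order is input order — outputs are byte-identical across runs at a
  fixed seed.
- LD matrices export/import at 17 significant digits and round-trip
  bit-exactly (`float_precision="round_trip"` on read).
- Single-instrument analyses reduce GLS-IVW to the Wald ratio
  (by/bx, SE σᵧ/|βₓ| first-order delta); k = 2 Egger is saturated
  (Q = 0, df 0) and model selection then forces IVW.
- p-values are floored at 1e-300 to stay within (0, 1].
- Q with df ≤ 0 reports a missing p-value rather than 1.

## Known limitations

- Exposure-side error is not propagated (NOME assumed after the F
  screen); no SIMEX correction.
- The leverage/outlier exclusion is data-driven; its effect on
  downstream inference is not adjusted for (no post-selection
  correction), matching standard practice.
- Only biallelic A/C/G/T variants; no liftover, no multi-allelic
  handling, no LD-from-summary-statistics fallback.
- Weighted-median/mode estimators, MR-PRESSO, multivariable MR and
  colocalization are out of scope.
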