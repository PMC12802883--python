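# Methods

## Model

For each distribution parameter k (location μ, scale σ, and where the family
has them, skewness ν and kurtosis τ), the linear predictor is

    η_k = g_k(θ_k) = X_k β_k + Z_k γ_k

with g_k a fixed monotone link, X_k fixed-effect columns and Z_k at most one
B-spline smooth block. Default links: NO (identity, log); BCPE (identity,
log, identity, log); BEZI (logit, logit, logit — the dispersion σ lives in
(0,1) with Var(Y|Y>0) = μ(1−μ)σ², beta shapes a = μφ, b = (1−μ)φ,
φ = 1/σ²−1); GG (log, log, identity). Any consistent monotone link preserves
the algorithm's exactness; these follow standard GAMLSS conventions for each
family. The BCPE density omits the y>0 truncation correction, as is standard;
this is numerically exact (mass < 1e−9) when σ·|ν| ≲ 0.15 and τ ≥ 1.8 —
comfortably covering anthropometric-style applications — and the family
validation suite draws from that domain. The zero-inflated beta places
probability ν on {0} and (1−ν)·Beta(μ, σ) on (0,1); the generalized gamma
uses θ = 1/(σ²ν²), z = (y/μ)^ν and reduces to the gamma at ν = 1.

## Fitting

The RS scheme is implemented once (`fedgamlss.rs`) over an abstract data
interface. The pooled backend computes X'WX and X'Wz on the full data; the
federated backend sums per-site messages containing exactly those
cross-products. Because both feed the same driver, the distributed fit
reproduces the pooled fit by construction up to float summation order; the
test-suite verifies the per-round update map agrees to 1e−10 and final
coefficients to better than 1e−6 over random partitions.

Scores u = ∂ℓ/∂η are analytic for every family and parameter. Weights
w = −∂²ℓ/∂η² are analytic observed information for the Gaussian, analytic
expected (Fisher) information for the zero-inflated beta μ and σ (observed
curvature is negative for a substantial share of tail observations under
high beta dispersion, which degrades Newton to a slow fixed-point iteration
— Fisher scoring is the classical beta-regression choice and keeps inner
cycles short), the logistic ν(1−ν) for the zero mass, and a central finite
difference of the analytic score (step 1e−5·max(1,|η|)) for BCPE and GG.
Non-positive weights fall back to the squared score; all weights are floored
at 1e−10. The choice of weights moves the step, never the fixed point: the
converged coefficients solve X'u = λP γ regardless, which is why a
weight-rule change cannot alter estimates, only iteration counts. M2 is
accumulated as X'(w∘η + u), algebraically X'Wz without forming u/w.

Initialization needs no subject rows: a round-0 exchange of counts and sums
(n, Σy, Σy², zero count, Σ_{y>0} y) gives family-specific moment starts
(e.g. BCPE starts at μ = mean, σ = CV, ν = 1, τ = 2), and a constant
predictor is encoded on a smooth by setting every basis coefficient to the
linked value (the basis columns sum to one).

Convergence follows the coefficient-proportion rule: |new−old| < c·|old|
(absolute c·1e−8 when |old| ≤ 1e−8), per coefficient; the inner cycle stops
when the active parameter passes, the outer cycle when all parameters pass
against the previous outer cycle. The default c = 0.05 balances stability
against communication cost; the closed-form-recovery tests use c ≤ 1e−6.
Step control halves the last move (≤5 times) when the *penalized* deviance
rises; the raw deviance is not monotone under penalized updates. The check
runs one round behind the move — sites report deviance at the coefficients
they receive — so it costs no extra communication, and its baseline resets
whenever λ changes.

## Smooths and penalties

A smooth's basis is determined by (global min, global max, total knot count,
degree 3): equally spaced knots, boundary knots repeated degree times, hence
n_cols = knots + degree − 1 columns. The aggregator learns the global range
in one setup round and broadcasts the basis as JSON, so all sites evaluate
identical columns — a requirement for exactness. Out-of-range values at
prediction time are clamped to the fitted range with a warning: charts are
only valid where data existed. Because the basis columns sum to one, a
parameter with a smooth gets no separate intercept (it would be exactly
collinear); categorical fixed effects use treatment contrasts against the
alphabetically first level, with the level dictionary agreed in round 0.

The roughness penalty is an order-2 difference penalty on the basis
coefficients, taken as *divided* differences at the Greville abscissae. With
repeated boundary knots the Greville sites are unevenly spaced near the
edges, and plain index differences would penalize genuinely linear functions
of x there; divided differences keep the null space exactly {affine in x},
so λ→∞ recovers the weighted linear fit and EDF→2. For uniform sites the
operator reduces to the familiar [1, −2, 1] rows (exposed separately as
`difference_penalty`).

Effective degrees of freedom are EDF(λ) = tr[(X'WX + λP̃)⁻¹ X'WX] over the
parameter's full design, inclusive of fixed-effect columns; EDF is monotone
nonincreasing in λ and `lambda_for_edf` inverts it by Brent root-finding on
log₁₀λ (|EDF−target| < 1e−4). Three regimes: fixed (λ=0), fixed penalty
(λ given, or re-solved from a target EDF once per outer cycle against the
current aggregated X'WX), automated (λ from a 20-point log grid on
[1e−4, 1e6], chosen by BIC = deviance + log(n)·EDF_total by default, GAIC(κ)
and GCV available; smallest-λ tie-break; if no candidate improves the
previous criterion value the previous λ is kept and the stall logged).
Selection happens on the first inner iteration of each outer cycle —
re-selecting every inner iteration changes the objective under the
convergence rule's feet — and each selection costs one extra evaluation
round in which sites return a deviance per candidate coefficient vector.

## Communication accounting

Rounds = 1 basis-setup (when smooths are present) + one update round per
inner-cycle iteration + one penalty-grid round per outer cycle per automated
smooth + 1 inference round. The `RoundLog` records purpose and per-site
payload bytes for every exchange. On the synthetic scenarios the counts come
out at a few tens of rounds (e.g. 31 for the nine-site four-parameter
fixed-smooth fit, ~90 for the eleven-site fixed-penalty zero-inflated beta),
the same order as real federated GAMLSS deployments report.

## Inference

Site Hessians are numerical: central differences of the site log-likelihood
with respect to the full stacked coefficient vector, step 1e−4·max(1,|b_j|),
evaluated jointly across parameters so cross-parameter curvature is kept.
Σ = (ΣᵢHᵢ)⁻¹ gives SEs and two-sided-normal Wald p-values; a
non-positive-definite sum (near-unidentified spline tails) triggers a
pseudo-inverse with a warning and NaN SEs for the affected coefficients. The
likelihood Hessian is used unpenalized, matching the pooled reference.

Smooth-term LRTs compare the full model against one that is intercept-only
for the tested parameter while all other parameters keep their smooths;
the null is χ² with df = basis columns − 1 (fixed-effect smooth) or the
smooth's EDF − 1 (fixed penalty), non-integer df allowed. For automated
penalty smooths the test is refused: a χ² reference that ignores the
data-driven λ is anti-conservative, and no corrected test is implemented.
Calibration is verified by simulation: Wald (Gaussian n=300, zero-inflated
beta n=200) and fixed-effect-smooth LRT (Gaussian n=150) null rejection
rates over 500 seeded replicates fall in [0.03, 0.07] at α = 0.05; the
replicate sizes were chosen so the χ²/normal asymptotics are accurate, since
the package offers no small-sample correction.

## Synthetic scenarios

The generator (`fedgamlss.synthgen`) emulates three application shapes with
closed-form truth curves (Gaussian bumps, logistic steps, gamma-shaped
rises) — deliberately *not* splines, so recovery tests also probe basis
approximation error:

* `bmi_like` — BCPE, 9 sites with an ICU-like size imbalance (largest ≈ 60×
  smallest), ages 18–100, hump-shaped median, age-varying spread, Box-Cox
  power < 1 (upper-tail skew); default model: smooths with 6/5/2/2 knots
  plus sex (and site on μ).
* `microbiome_like` — zero-inflated beta, 11 study sites of 8–89
  participants (569 total), zero mass 2.66 %, strong dispersion, abundance
  rising with age plus a mid-life step; default model: 20-knot smooths for
  μ and σ, intercept+sex for ν — at ~16 zero events a 20-knot smooth for
  the zero-mass parameter is not estimable, a deliberate difference from
  modeling choices feasible at consortium scale.
* `brainvol_like` — generalized gamma, 12 sites spanning 5 to 1000
  participants, rise-then-decline median volume over ages 3.2–100, higher
  relative spread in childhood; default model: 20-knot automated-penalty
  smooths on all three parameters.

Site effects are additive shifts on the location predictor (N(0, sd) with
site 1 as reference) and the matching model includes site as a fixed effect.
Sampling is inverse-transform from each family's quantile function, so a
seed fixes every byte of the output. What the presets do *not* emulate:
longitudinal repeats, missingness, measurement harmonization problems,
covariate shift beyond age-window heterogeneity, or site effects on higher
moments — so passing tests show algorithmic correctness and statistical
calibration under a well-specified model, not robustness to real-world data
pathology.

Problem sizes in the validation suite (n ≈ 5000 for the nine-site BCPE
scenario, 569 for the microbiome scenario, ≈ 4000 for the brain-volume
scenario, 20 000 for centile recovery, 500 replicates for calibration) are
desk-scale choices that keep the full suite under a minute while leaving
the Monte-Carlo error well below every tolerance tested.

## Numerical choices and degenerate inputs

* Penalized solves use Cholesky; a non-SPD system gets one ridge retry
  (1e−10 × mean diagonal, logged). Near-duplicate design columns (gram
  cosine > 1 − 1e−10) raise an error naming the columns rather than
  returning garbage.
* Links clip their inverses (exp at ±700, expit at 1e−12) so extreme
  predictors degrade gracefully during early iterations.
* Quantile functions invert the CDF analytically per family (incomplete
  gamma/beta inverses); BEZI returns exactly 0 for q ≤ ν.
* A missing site aborts a distributed fit: exactness is chosen over
  availability, and no partial rounds exist.
* Fits that hit the iteration caps return flagged, unconverged states with
  full diagnostics instead of raising.

## Known limitations

One smooth per parameter (no backfitting), cross-sectional data only, no
censoring or discrete families, no differential-privacy noise — iterative
exchange of aggregate matrices is not formally private, and small sites with
extreme values face nonzero re-identification risk. Automated-penalty
smooth-term inference is refused rather than approximated. The in-process
"federation" simulates the message protocol faithfully (sites communicate
only via serializable message objects) but provides no network transport.
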