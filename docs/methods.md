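# Methods

## Model

Both models are linear in the supplied molecular descriptors and are fitted
on mean-centered data: predictions are ŷ = (x − x̄_train)·ā + ȳ_train, so no
explicit intercept is estimated. Descriptor values are taken as given
(computing them — by DFT, group additivity or otherwise — is out of scope);
the number of descriptors K is arbitrary ≥ 1, though typical RP-LC QSRR
schemas use K = 3 (e.g. dipole moment, most negative NBO atomic charge and
solvent-accessible surface area for small organics; log of summed
amino-acid retention, log van der Waals volume and clogP for peptides).

**Control (MLR).** Ordinary least squares on the centered training data.
Rank deficiency is reported as an error naming the collinear columns
(identified by QR with column pivoting).

**Order-constrained (MLR-NLP).** The training set is sorted ascending by
experimental retention time (stable on ties) and each adjacent pair j gets
the relaxed constraint ŷ_j − ŷ_{j+1} ≤ α_j with slack α_j ≥ 0. The
objective is SSE + λ·Σα. Because at any fixed ā the optimal slack is
α_j = max(0, ŷ_j − ŷ_{j+1}), the problem is equivalent to unconstrained
minimization of a convex piecewise-quadratic "hinge" objective in ā alone.
There are m−1 slacks for m training analytes — only adjacent pairs carry
constraints. Constraints are built on the training set only; validation
analytes remain strictly external.

### Numerical solution

1. **Interior-point stage.** The QP in (ā, α) is solved with SciPy's
   `trust-constr` (analytic gradient and constant Hessian; the Hessian is
   PSD — zero curvature in the slack directions is handled fine).
2. **Active-set polish.** `trust-constr` stops with coefficients accurate
   to roughly the square root of the objective tolerance, which is not
   enough for the tight equivalences we assert. On the slack-eliminated
   objective, the minimizer over the smooth piece selected by the sign
   pattern of D·ā (D the matrix of adjacent descriptor differences) has
   the closed form (XᵀX)⁻¹(Xᵀy − (λ/2)·Σ_active d_j); iterating this to a
   fixed pattern recovers smooth optima to machine precision.
3. **Kink candidates.** The optimum can sit exactly at a kink
   (some D_j·ā = 0 — an exact predicted tie). Candidate pin sets (pairs
   near zero at several tolerances, plus each pair individually) are
   pinned to equality, the smooth remainder is minimized on the null space
   of the pinned rows, and a candidate is kept only when it lowers the
   exactly evaluated objective. Generous pin sets are therefore harmless.

The returned slacks are the closed-form hinges for the final coefficients,
so α_j = max(0, ŷ_j − ŷ_{j+1}) holds exactly and the feasibility invariant
is met by construction. By optimality of each model for its own objective,
SSE(constrained) ≥ SSE(OLS) and hinge(constrained) ≤ hinge(OLS) on every
instance; the test suite asserts this on 100 seeded instances and checks
the solver against dense grid oracles on 1-D and 2-D problems.

### Parameters

- **λ (`lambda_weight`, default 1.0)** — weight of Σα against the SSE.
  The default corresponds to the plain unweighted sum of the two terms.
  Units caveat: SSE is in min², Σα in min, so the effective pressure of
  the penalty depends on the retention scale; λ → 0 recovers OLS, λ → ∞
  drives the hinge to its constrained minimum (monotone in λ).
- **`solver_tolerance` (default 1e−8)** — `trust-constr` gtol; the polish
  stage makes the final accuracy essentially machine precision for smooth
  and pinned optima.

## Validation apparatus

**Kennard–Stone split (default fraction 0.70).** Descriptors are
autoscaled to zero mean / unit variance (ddof = 1) before distances are
computed — otherwise a large-scale descriptor such as a surface area would
dominate a dipole moment. The training set is seeded with the globally
most distant pair and grown by max–min Euclidean distance; every tie is
broken by the lowest row index, so the split is fully deterministic.
Training size is round(fraction·n), half-up: n = 62 at 70% gives 43/19.
The split itself only requires |train| ≥ 2; the fitting functions enforce
the statistically meaningful minimum |train| ≥ K + 2.

**%RMSE.** Root mean square of per-analyte relative errors × 100. The
order variant substitutes 1-based ranks (1 = earliest eluting) for
retention times; 1-based ranking keeps the denominator nonzero. Ranks are
set-relative: each scored subset is ranked within itself. Metrics are
reported for training, validation and combined subsets — published
per-column tables rarely state which subset underlies a number, so all
three are always available and the combined value is the headline.

**Applicability domain.** Leverages are the hat-matrix diagonal
h = x(X₁ᵀX₁)⁻¹xᵀ on centered descriptors without an intercept column,
consistent with the mean-centered model (training leverages then sum to
K). The default critical leverage is h* = 3(K−1)/N with a
`"conventional"` switch for the textbook 3(K+1)/N; the default follows
the convention of the benchmark source even though it degenerates to 0 at
K = 1, which is documented rather than silently corrected. Standardized
residuals are raw residuals divided by the training residual SD
(ddof = K); a numerically perfect fit reports zeros instead of 0/0. An
analyte is out of domain when h > h* or |standardized residual| > 3.

**Paired comparison.** The paired t-test is computed from the explicit
formula t = mean(d)/(SD(d)/√n) with sample (ddof = 1) variances and
two-sided critical values at α = 0.05; SciPy's `ttest_rel` serves as an
independent cross-check in the tests. The headline relative changes are
the arithmetic means of per-condition values 100·(NLP − MLR)/MLR — the
mean of relative changes, not the relative change of means. On the
packaged 19-condition RP-LC benchmark these reproduce a +29.13% mean
relative increase in retention %RMSE against a −37.29% mean relative
change in order %RMSE, and the t-test on the retention columns gives
t = −3.897 (p two-tail ≈ 0.00106, r ≈ 0.961).

## Synthetic-data generator

`simulate_dataset` draws descriptors from a multivariate normal (identity
covariance by default), forms y = baseline + X·β + ε with Gaussian noise,
and optionally applies the monotone convex warp
y → y + warp_strength·y²/max(y). Defaults emulate a small-molecule RP-LC
screen: 60 analytes, K = 3, β = (2, −1, 0.5), baseline 12 min, noise SD
0.3 min. If a draw would produce non-positive retention the whole vector
is shifted up to a 0.1 min floor.

The warp is the point of the generator: it preserves the *true* elution
order (monotone for y > 0) while bending the response away from
linearity, so the OLS fit starts misordering analytes systematically —
the regime in which order constraints help. What the generator does *not*
emulate: gradient-elution physics, peak shapes, co-elution, heteroscedastic
or non-Gaussian measurement error, and real descriptor distributions
(which are correlated and skewed). Passing tests therefore demonstrate
the mathematical behaviour of the estimators, not field performance on
real chromatographic data.

The statistical property "order %RMSE decreases on average under the
constrained fit" is evaluated in the strong-warp / low-noise regime
(warp 2.0, noise SD 0.1 min, n = 40). This is a design choice: adjacent
order constraints correct systematic, nonlinearity-induced inversions,
whereas noise-induced rank scrambling is irreducible for any fixed
predictor, so a noise-dominated regime would dilute the effect being
tested. The trade-off theorem (SSE up, hinge down), by contrast, holds on
*every* instance regardless of regime and is tested that way.

## Degenerate inputs and tie-breaks

- Retention-time ties: stable resolution by input row order everywhere
  (sorting, ranking, constraint construction), making all results
  deterministic. How tied analytes "should" be ordered is undefined in
  the field; stability is our convention.
- Zero-variance descriptor columns: rejected by the split (autoscaling
  undefined) with the column named.
- Constant response: OLS returns zero coefficients; the constrained model
  agrees (all constraints satisfied at ŷ ≡ ȳ).
- %RMSE with a zero true value, non-permutation rank vectors, length
  mismatches: explicit errors, never NaN propagation.

## Problem sizes

The shipped suites use 100 synthetic instances of 60 analytes for the
theorem checks, 50 instances of 40 analytes for the order-improvement
summary, and dense grids of 2·10⁵ (1-D) / 6.4·10⁵ (2-D) points for the
oracle equivalences; the full test suite and the acceptance script each
run in well under a minute on one CPU.

## Known limitations

- The λ = 1 default mixes min² and min units; a scale-aware weighting
  (e.g. normalizing SSE by its OLS value) may behave more uniformly
  across gradient lengths but is deliberately not the default.
- Constraints cover adjacent pairs only; a fit can satisfy all of them
  while still misranking distant pairs.
- The benchmark fixture contains published summary values; the underlying
  per-analyte retention data are not public, so per-column %RMSE values
  cannot be recomputed, only the statistics derived from the table.
- K = 1 with the default critical-leverage formula flags everything with
  h* = 0; use the conventional variant there.
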