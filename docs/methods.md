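# Methods

## Data model and pooling

The unit of analysis is a p x p Pearson correlation matrix with an
effective sample size N and a population label.  Validation is strict and
matrices are never repaired: symmetry to 1e-12, unit diagonal, |r| <= 1,
and positive definiteness (the error names the smallest eigenvalue).
Silent smoothing of an indefinite input would change every downstream
statistic, so an invalid matrix fails loudly instead.

Published batteries print per-age-band tables; these are combined by the
Fisher z transform — each off-diagonal of the pooled matrix is
tanh(mean(atanh r_k)) — with an *unweighted* mean, which presumes equal
per-table N (validated).  The pooled N is an explicit analyst input (e.g.
1000 for five tables of 200): averaging correlation tables has no single
canonical effective N, so the package never infers one.

## Estimation

Sigma(theta) = Lambda Phi Lambda' + Theta is fitted by minimizing the
Wishart ML discrepancy F = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p, with
chi^2 = (N-1) F_min.  The input correlation matrix is analysed as if it
were a covariance matrix, the convention of classical SEM programs given
matrix input.  The known caveat applies: with a correlation matrix the
diagonal is not stochastic, and standard errors of standardized estimates
are approximate.  The chi-square itself is asymptotically correct here
because every supported model has a free diagonal (scale-invariant
structure), which the calibration suite confirms empirically (mean
chi-square within ~1% of df at N=500 under the true model).

Optimization is L-BFGS-B with analytic gradients, ftol 1e-14 / internal
gtol 1e-9, up to 2000 iterations per round and up to 4 restarts (a restart
refreshes the quasi-Newton memory); convergence is declared on the
infinity norm of the *projected* gradient (bound-active coordinates
zeroed) at 1e-7, with a hard failure above 1e-5 that raises a diagnostic
error carrying the best point.  Estimation uses no randomness: a fit is a
deterministic function of (spec, sample, start).

Lower bounds: all uniquenesses and all second-order disturbances are
bounded at 0 by default.  Published analyses of these batteries bounded a
single disturbance only after observing it go negative; a global bound
reproduces that behavior whenever it activates and the active-bound set is
always reported, so nothing is hidden.  Oblique factor correlations are
kept in (-0.995, 0.995) as a numerical guard.

Starting values are deterministic: free loadings 0.5, oblique correlations
0.2, second-order loadings 0.5, disturbances 0.3, uniquenesses 0.5.  Two
situations get a smarter start.  For patterns where two or more factor
columns have identical free-masks (the fully crossed k-orthogonal models)
a uniform start is a symmetry point gradient methods cannot leave, and a
one-shot truncated eigendecomposition proved prone to genuine local minima
(it broke the chi-square nesting inequality against sub-models).  Those
patterns therefore start from an iterated principal-axis factorization
(squared-multiple-correlation communalities, then repeated truncated
eigendecompositions of the reduced matrix), which reached the
nested-consistent optimum on every fixture tried.  The stepwise search
warm-starts each refit from the previous estimates (new loadings at 0).

### Identification

Degrees of freedom are p(p+1)/2 minus free parameters; negative df raises
before any optimization.  The second-order structure fixes the general
factor's variance at 1 and leaves the first-order scales implicit in
(Gamma, Psi).  This matches the df conventions of the published tables but
leaves a per-group-factor scale indeterminacy — (c lambda_k, gamma_k / c,
psi_k / c^2) is Sigma-invariant — so raw hierarchical parameters are not
unique even at an exact fit.  Identified reports use the standardized
forms Lambda diag(sqrt(Phi_kk)) and the factor correlation matrix.  Factor
*sign* indeterminacy affects every structure; report-time output flips
each factor so its largest-magnitude loading is positive (Phi/Gamma
adjusted so Sigma is unchanged), while raw estimates are kept unflipped.

Fully crossed orthogonal patterns are additionally rotation-indeterminate;
their discrepancy, chi-square and communalities are identified, and tests
only assert those.

## Fit indices

GFI uses the ML metric 1 - tr[(Sigma^-1 S - I)^2] / tr[(Sigma^-1 S)^2];
AGFI = 1 - (q/df)(1 - GFI) with q = p(p+1)/2; CFI and RMSEA use the
max(., 0) clamps so a model beating its reference yields 1 and 0 rather
than out-of-range values; df = 0 reports AGFI and RMSEA as not applicable
(NaN).  The "Akaike's" column is chi^2 - 2 df — the legacy CALIS AIC,
identified by reconstructing published table rows — and is named
`aic_calis` to keep it distinct from the textbook -2 lnL + 2k form.  The
null model frees only the p uniquenesses; for unit-diagonal input its
chi-square has the closed form -(N-1) ln|R|, which the test suite checks
against the optimizer to 1e-6.

## Modification search

Candidates are fixed-at-zero loading cells only — no error covariances or
factor-correlation candidates, mirroring the loading-only layout of the
published modified solutions.  The Lagrange-multiplier statistic for a
candidate is the squared score over its information, partialed for all
free parameters; the Wald statistic for a free loading is
(estimate / SE)^2.  Both use the analytic *expected* (Fisher) information
evaluated at the implied matrix — the observed finite-difference Hessian
systematically overshot refit chi-square changes on planted fixtures,
while the expected form tracks them within the tested 25% — and
parameters held at an active bound are excluded from the partialing set.
Each step adds the largest LM candidate if its projected p < alpha (0.05,
per-step, uncorrected), else drops the smallest-Wald loading if its
projected p >= alpha; the model is refitted and the *actual* chi-square
change must meet the same criterion, otherwise the step is rolled back and
the search stops.  Ties break lexicographically by (subtest, factor)
order, and a cell toggling between added and dropped trips an oscillation
guard, so the search is deterministic.

## Model catalog and df bookkeeping

The catalog pins the 15-subtest battery in its published row order.  The
five-factor CHC pattern places its single cross-loading on Arithmetic
(fluid/quantitative and short-term memory); the sources say only that
exactly one subtest loads on two factors, and this placement reproduces
the published df of the nested variant (74).  Four catalog entries carry
`df_unverified=True` because their printed df cannot be reconciled from
their described structures alone: the four-factor hierarchical model
counts to 82 vs a printed 80, the hierarchical CHC to 79 vs 80, the
oblique CHC to 79 vs 78, and the modified six-independent pattern to 49 vs
a printed 47.  The literal printed patterns are shipped; no parameters are
invented to force agreement.

## Synthetic data

`exact_population_matrix` returns the implied matrix itself (uniquenesses
completed so the diagonal is exactly 1; infeasible structural variance >=
1 raises).  `sample_matrix` draws N multivariate-normal observations and
returns their Pearson correlations.  `wais_like_battery` emulates a
three-band standardization design: an estimation band of N=1000 drawn from
the modified-CHC published loadings, plus two N=400 generalization bands
whose free loadings receive independent Gaussian drift with sd 0.03 before
uniquenesses are re-completed.  The drift sd is a fixed design constant
chosen to produce cross-validation degradation of the same order as the
published generalization tables; it is a qualitative emulation only.  What
the surrogates do *not* emulate: non-normal subtest distributions,
age-specific reliability differences, sampling stratification, and any
resemblance to the actual proprietary standardization correlations — so
passing tests demonstrate correctness of the machinery and calibration
under the stated generating process, not agreement with real battery data.
`six_equal_factor_sim` generates the exchangeable six-orthogonal-factor
population (every off-diagonal 6 loading^2) used to probe how a fully
crossed fit concentrates variance in a dominant general factor with
mixed-sign secondary factors.  All generators take explicit integer seeds
and spawn one named generator per call.

## Problem sizes in the verification suite

The chi-square calibration runs 200 replicates at N=500 (observed mean
within ~1% of df = 62); the surrogate generalization check fits the full
catalog and cross-validates to both bands over 50 seeded batteries
(the generating model posted the smallest total cross-validated chi-square
in 50/50 at sd 0.03); the stepwise "large general-factor loadings survive"
property is exercised on 6 noisy replicates in the unit suite and scales
to more replicates by changing one range() bound.  Monte-Carlo agreement
of sampled with population correlations is checked at N=10^6
(max deviation < 0.005).

## Known limitations

* Standard errors inherit the correlation-as-covariance approximation; no
  correction (e.g. constrained-diagonal asymptotics) is applied.
* GLS/ULS discrepancies, mean structures, multi-group simultaneous
  estimation, measurement-invariance hierarchies and categorical-indicator
  thresholds are out of scope.
* The modification search is greedy and single-parameter; it inherits the
  usual caveats of uncorrected stepwise selection, which is exactly why
  fixed-loading cross-validation is a first-class operation here.
* Exploratory factor analysis and rotation are not provided; the
  principal-axis routine exists only to initialize ML fits.
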