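# Methods

## Model

For one trait in a multi-environment trial laid out as a randomized
complete block design within each environment,

    y_ijk = mu + E_j + B_k(j) + G_i + GE_ij + e_ijk,

where all of `E ~ N(0, s2_E)`, `B ~ N(0, s2_E/R)`, `G ~ N(0, s2_g)`,
`GE ~ N(0, s2_i)` and `e ~ N(0, s2_e)` are independent. Two
parameterizations are fitted and every output is labelled with the one it
came from: genotype random (the basis of BLUPs, genotypic values and all
stability/selection indices) and genotype fixed (the basis of the
significance report's F-test). Environments are exchangeable — the
generator and the model deliberately ignore year/location structure and
environmental covariates.

## REML engine

The restricted likelihood of the crossed variance-component model
`V = s2_e I + sum_c s2_c Z_c Z_c'` is evaluated through Gram matrices and
the Woodbury identity, so one evaluation costs O(q^3) in the number of
random-effect levels (q = 150 for the default panel) rather than O(n^3).
The analytic gradient is supplied to L-BFGS-B with non-negativity bounds;
variance components are optimized on data standardized to unit variance
and rescaled afterwards. Start values are the balanced expected-mean-square
(EMS) estimators where the layout is balanced, otherwise an equal split of
the total variance; the optimizer starts from whichever start has the
higher restricted likelihood, so the final likelihood can never fall below
the EMS start point. Components that the constrained path drives to zero
stay pinned at the bound and are logged.

Numerical choices:

* convergence: L-BFGS-B with ftol 1e-14 / projected-gradient tol 1e-10,
  iteration cap 500, one restart on a stalled line search, then fallback
  to the alternative start; the `converged` flag is optimizer success or a
  projected gradient below 1e-5 (standardized scale), and is honest —
  failures are returned flagged, never silently;
* the residual variance has a floor of 1e-10 (standardized) so degenerate
  noise-free datasets remain well-posed;
* BLUPs and fixed effects are solved through the augmented least-squares
  form of the mixed-model equations (QR), which keeps full accuracy when
  `s2_e` is many orders of magnitude below the other components;
* on balanced data with interior estimates, the REML solution coincides
  with the EMS estimators (verified to ~1e-9 relative in the tests, and
  against lme4 to ~1e-6 on a crossed fit).

Interaction BLUPs from a crossed model carry nonzero margins (part of each
genotype's main-effect information is attributed to the GE prior). The
fitted model re-expresses all BLUPs in the sum-to-zero parameterization:
GE margins are folded into `g_i` and `u_j`, leaving every genotypic value
`GV_ij = u_j + g_i + ge_ij` unchanged while making the GE matrix exactly
double-centered — the form the AMMI-style SVD expects. `u_j` is defined as
`mu_hat + BLUP(E_j)` plus the absorbed GE environment margin; because of
BLUP shrinkage it equals the empirical environment mean only as the
nuisance variances vanish.

Inference:

* likelihood-ratio tests for random terms refit without the term (same
  fixed structure) and refer `2(l_full - l_reduced)`, clipped at zero, to
  chi-square(1). Because the null `s2 = 0` lies on the boundary of the
  parameter space this reference is conservative (the asymptotic null law
  is the 50:50 mixture of a point mass at zero and chi-square(1)); the
  mixture p-value is available via `boundary_correction=True` and is what
  the calibration tests use, while the plain chi-square(1) p remains the
  default reported style;
* the genotype F-test is Wald-type at the REML estimates with containment
  denominator degrees of freedom `(g-1)(e-1)` (the genotype contrasts are
  contained in the GE term); Satterthwaite approximation is deliberately
  out of scope for v1. Single-environment mode runs the classical
  fixed-effects RCBD ANOVA per environment via statsmodels;
* heritability defaults to the genotype-mean basis
  `h2 = s2_g / (s2_g + s2_i/e + s2_e/(e r))`; the plot basis
  `s2_g / s2_p` is an option. Which basis feeds the selection gains is a
  package choice (genotype-mean), since gain reports rarely state it.

## Stability indices

The SVD of the double-centered GE BLUP matrix uses symmetric score scaling
(singular vector times sqrt of singular value) for both margins, all
min(g-1, e-1) axes by default, and a deterministic sign convention (the
largest-magnitude genotype score on each axis is positive — WAASB is
sign-invariant, so this affects biplot output only). WAASB is the
EP-weighted mean of absolute scores; environment WAASB is computed
identically from environment scores. Rescaling to 0–100 is linear with the
desirable end at 100; a constant vector rescales to all-50 with a warning.
WAASBY defaults to equal weights (theta_Y = theta_S = 50) and is fully
configurable; the weight-grid ranking sweeps theta_S over {0, 5, ..., 100}.
Biplot quadrants divide at the unweighted means, with values on a divider
assigned to the desirable side (IV = above-mean performance, below-mean
WAASB).

## Multi-trait index

The genotype x trait WAASBY matrix (each column computed with its trait's
desirability direction, so 100 is always best) is standardized with
population (ddof = 0) SDs — a choice that cancels in rankings but not in
raw distances, hence fixed and documented. Factor analysis retains
eigenvalues >= 1 of the correlation matrix (ties kept, minimum one
factor), takes principal-axis loadings `eigenvector * sqrt(eigenvalue)`,
rotates by varimax with Kaiser normalization to 1e-6, and computes
regression scores `Z R^-1 L` (isolated behind one function so a Bartlett
estimator could be swapped in). A singular or near-singular correlation
matrix gets a ridge-regularized inverse (1e-8) with a warning. The
ideotype (100 everywhere) passes through the same standardization and
score equation. MTSI is the Euclidean distance to the ideotype in factor
space; the selected set is the round-half-up of intensity x n_gen lowest
distances (floor one genotype; 15 % of 18 gives 3); factor contributions
are squared deviations over squared distance. Selection gains report
`X0, Xs, SD, %SD, SG = SD h2, %SG` per trait for both the BLUP
mean-performance and the WAASBY scale.

## Genotypic-value indices

HMGV, RPGV and HMRPGV use the fitted model's environment means `u_j` (not
raw cell means) for consistency with `GV_ij = u_j + g_i + ge_ij`; under
balance the grand mean of fitted values equals the raw grand mean, so the
`x mu` rescalings are insensitive to that choice. Non-positive genotypic
values raise a hard error naming the offending cells rather than being
silently shifted; traits with legitimate near-zero values must be shifted
explicitly by the caller.

## Synthetic trial generator

The generator emulates the default study conditions — 18 genotypes, 6
environments (2 years x 3 locations treated as exchangeable), 3 blocks —
with an eight-trait rice panel (plant height, tiller number, panicle
length, filled/unfilled grains, fertility %, hundred-grain weight, grain
yield at a 4360 kg/ha grand mean) on each trait's natural scale, and
moderate genotype-level correlations (grain number, fertility and yield
positively related; unfilled grains negatively). Variance components were
chosen once to give environment-dominated phenotypic variance for yield
with coefficients of variation typical of irrigated rice trials.

The GE interaction is by default an exact low-rank bilinear term: random
centered orthonormal vectors per axis, singular values set so that
`sum_k scale_k^2 = s2_i (g-1)(e-1)`, which makes the expected
balanced-ANOVA interaction component equal the nominal `s2_i`. The default
eigenvalue profile (68/15/10/5/2 % of the interaction sum of squares)
gives a first-axis-dominated spectrum with a slow tail. Because this
construction has exactly zero margins, it is *not* distributionally
identical to i.i.d. cell interactions: the mixed model then attributes no
interaction variance to the genotype margins, and genotype-variance
estimates are shifted by about `-s2_i/e`. `gei_structure="iid"` draws
per-cell Gaussian interactions instead and is the right choice for
estimator-recovery studies; the low-rank default is the right choice when
a controlled IPCA spectrum is the point.

Randomness flows from a single seed through per-effect-family substreams,
drawn trait-by-trait, so adding a trait never changes the draws of the
environments or of earlier traits. The realized effect vectors ride along
with the dataset (`METDataset.truth`) for parameter-recovery tests and are
not written to CSV.

What the generator does not emulate — and hence what passing tests do not
establish about real data: spatial field trends, location- or year-specific
covariance, heterogeneous residual variances across environments,
non-Gaussian traits or outliers, and missingness mechanisms beyond uniform
random deletion.

## Test and acceptance problem sizes

The Monte-Carlo suites run at the trial's own dimensions (18 x 6 x 3):
50 datasets for the REML/EMS equivalence check, 200 for variance-component
recovery, 500 for the interaction-LRT calibration, plus property suites of
100–1000 random instances for the index modules. These sizes put
Monte-Carlo standard errors comfortably inside the asserted tolerances
while keeping the full suite under a couple of minutes.

## Known limitations

* No factor-analytic covariance structure for the GE term itself, no
  heterogeneous residual variances, no Satterthwaite df.
* Classic AMMI on cell means (residual-of-additive-model) is out of scope;
  only the BLUP-based variant is implemented.
* The MTSI monotonicity intuition (improving one trait index of a genotype
  moves it closer to the ideotype) holds for frozen loadings but is not
  guaranteed once the factor model is refitted.
* Confirmatory factor analysis and oblique rotations are not provided.
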