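# Methods

## Model and estimation

The response is the natural log of annual otolith increment width (μm).
The full ("extended") model combines:

- a fixed decline in centred log age, so the age effect is a power law on
  the raw scale;
- crossed random effects for fish, formation year, and hatch cohort, each
  with a random intercept and a random age slope, correlated within factor
  ((intercept, slope) ~ bivariate normal with free correlation ρ);
- a within-individual temperature slope (response of one fish to deviations
  of the windowed temperature from its own lifetime mean), optionally in
  interaction with age, plus a fish-level random slope on the within
  component with its own variance σ²_F, uncorrelated with the fish
  intercept by default (configurable);
- an among-individual temperature slope on the fish's lifetime mean,
  main effect only;
- optional density (within-age z-score of log abundance) and harvest-rate
  covariates, each with an optional age interaction;
- i.i.d. Gaussian residuals on the log scale.

Estimation profiles out the fixed effects and the residual variance and
minimises the (restricted) profiled deviance over the per-factor relative
covariance factors Λ_g = chol(Σ_g/σ²):

    -2ℓ_ML   = log|M| + n(1 + log(2π r²/n)),
    -2ℓ_REML = log|M| + log|S| + (n−p)(1 + log(2π r²/(n−p))),

with M = Λ'Z'ZΛ + I, S = X'X − C'M⁻¹C, C = Λ'Z'X, and r² the penalised
residual sum of squares.  These are true log-likelihoods (all constants
kept), so values are directly comparable with other software.

### Numerical design

- **Fish-block elimination.** The largest grouping factor contributes a
  block-diagonal part of M (one d×d block per level, d ≤ 3).  It is
  eliminated analytically by a Schur complement, leaving a dense system in
  only the year/cohort columns (a few hundred).  One objective evaluation
  costs milliseconds at n ≈ 7000, q ≈ 3400.
- **Optimizer.** Bounded L-BFGS-B with finite-difference gradients, run
  from two standard starts (relative factors at 0.3 and 1.0); the better
  optimum is kept.  The profiled deviance can carry a shallow ridge near
  correlation boundaries that traps a single start; two starts matched an
  exhaustive derivative-free search (and lme4's optimum) on every instance
  tried during development, at roughly half the cost of one Powell run.
  Warm starts (e.g. across candidate models in a selection stage) run once
  from the supplied point.  Seeded jittered restarts fire only if no run
  converged.  Convergence: scipy defaults tightened to ftol 1e-11,
  gtol 1e-6.
- **Boundary fits.** Variance components are allowed to reach zero
  (diagonal Λ entries bounded below at 0); such fits are flagged
  `singular` rather than rejected, matching mixed-model convention.
- **AICc parameter count.** k = #fixed effects + #free (co)variance
  parameters + 1 for the residual variance.  Rankings use the parsimony
  tie rule: among models within 2 AICc of the best, fewest parameters
  first.
- **Intervals.** Fixed-effect CIs are Wald with normal quantiles.
- **Oracle.** `loglik_oracle` builds the dense marginal covariance
  V = ZGZ' + σ²I and evaluates the exact (restricted) likelihood by
  Cholesky factorisation, sharing no code with the sparse path; tests
  require agreement at the optimum to 1e-8 relative and dominance of the
  optimum over random parameter points.

## Protocol stages

1. **Random structure** is selected by REML-AICc over the eight
  combinations of age slopes on {fish, year, cohort} (intercepts always
  present), with the full intrinsic fixed part (age, and sex with its age
  interaction when a sex column is available).
2. **Fixed intrinsic part** by ML-AICc (age; ± sex; ± age:sex).
3. **Climate window**: all (open, close) month spans within 24 months back
  from December of the growth year (300 windows), each entering the
  baseline model as a mean aggregate with and without an age interaction,
  ranked by ML-AICc.  By default candidates keep the baseline's
  variance-component estimates and re-profile only fixed effects and σ²;
  the ranking is near-invariant to re-optimising the variance components
  (rank correlation > 0.99 on test data) and the winner is always refitted
  in full downstream.  `refit_theta=True` restores the expensive exact
  behaviour.  The **randomization test** permutes cohort labels among fish
  with identical age support (each fish's whole year sequence moves to
  another fish's span, preserving the year-label multiset and every
  fish's age structure), re-runs the scan, and reports the rank-based
  percentile (1 + #{null ≤ observed})/(1 + n_rand) of the observed best
  ΔAICc.  Observation-level permutation is available via `unit="record"`.
  The default n_rand is 199 in the pipeline config and 999 for full runs.
  The percentile, not the raw ΔAICc, is the calibrated quantity: selecting
  the best of hundreds of windows inflates apparent AICc support even for
  an information-free climate (a winner's curse of several AICc units,
  present equally under full per-candidate refits), and the permutation
  null reproduces exactly that selection process.
4. **Extrinsic part**: the intrinsic model plus the best-window covariate
  (with its age interaction as selected) and all combinations of density
  and harvest-rate terms (± age interactions), ML-AICc; the intrinsic-only
  model stays in the candidate set, so a signal-free simulation can reject
  every extrinsic term.
5. **Within-group centering** replaces the climate covariate by the
  fish's lifetime mean (among) and deviations from it (within; exact
  reconstruction is asserted).  Variant (a) = within (+ age interaction)
  + among; variant (b) = original + among.  When within ≡ 0 the original
  covariate equals the among term, so variant (b) is skipped and the
  within term dropped with a warning.
6. **Individual reaction norms**: fish-level random slope on the within
  component; per-fish slopes are the BLUP deviations (plus the population
  slope for totals).  Per-cohort variance of the slope BLUPs (cohorts with
  more than five fish) is Pearson-correlated with the cohort's mean
  temperature, density index, and harvest rate (df = #cohorts − 2,
  two-sided p, no multiplicity correction).  BLUP deviations rather than
  total slopes enter the variance by default (configurable), since an
  additive population slope shifts all totals equally.

Percent-change back-transformation of a slope β over an environmental
range (a, b) at centred log age x: 100·(exp((β + β_int·x)(b − a)) − 1).
Age-specific rows use the frame's stored log-age centering constant.

## Synthetic data

The generator runs the extended model forward and is the package's test
bed; its defaults are the study conditions.

- **Fixed effects** default to the literature scale for a long-lived
  demersal stock: age slope −0.645, within-temperature slope 0.020 per °C,
  among slope 0.069 per °C, age×within −0.092, density terms −0.002 and
  0.017; residual variance 0.056, fish/year/cohort intercept variances
  0.007/0.002/0.001, age-slope variances 0.012/0.001/0.004, correlations
  0.44/−0.107/0.167, individual thermal slope variance 0.005.
- **Climate** is a sinusoidal seasonal cycle (peak August) plus a
  stationary AR(1) annual anomaly (coefficient 0.6, innovation sd 0.5 °C)
  plus independent monthly noise (default sd/2).  The monthly term exists
  because an anomaly shared by all twelve months would make every
  single-month window within a year perfectly collinear and window
  identification degenerate; it is zero whenever sd is zero, so noise-free
  settings remain exact.
- **Sampling design** mimics archival selection of mature fish: catch
  years spanning the archive, age at catch 8–12 by default, cohort =
  catch year − age.  Increments are emitted on the retained support
  (ages 2..min(age at catch − 1, 10)), i.e. with first/edge increments and
  post-age-10 increments already excluded; a raw mode (ages
  1..age at catch) exercises the filtering stage itself.
- **Reproducibility.** All draws are keyed: each fish/year/cohort level
  gets its own seeded substream derived from (seed, factor, level), so the
  same truth seed produces the *same* year and cohort effect realisations
  regardless of roster size.  This makes sample-size comparisons
  common-random-number paired and tables byte-stable.  Default seed
  20141007.
- **Cohort-heterogeneous plasticity** is a mapping cohort → slope
  variance; the provided linear link clips at a small positive floor.
- **What it does not emulate**: ageing error, measurement error in widths,
  gear selectivity, spatial climate structure, or non-Gaussian residuals.
  Passing tests therefore demonstrate correctness of the estimation and
  selection machinery under the stated model, not robustness of the
  protocol to violations real archival data may carry.

## Problem sizes in the test suite

Simulation studies run at sizes chosen to give the assertions power while
keeping the suite practical on one CPU: recovery and selection-calibration
studies use 1000 fish × 20 replicate seeds (≈ 7000 increments each);
window-scan power uses 300 fish over the full 300-window grid × 10 seeds;
randomization-calibration uses 50 small scans (60 fish, windows within 2
months, 99 permutations each); cohort-variance sign recovery uses 1000
fish across ≈ 60 cohorts × 20 seeds.  Seeds are fixed arithmetic sequences
declared in the tests.

## Known limitations

- Wald CIs ignore variance-component uncertainty; profile or bootstrap
  intervals are not implemented.
- The dense oracle is quadratic in memory (n ≤ ~4000 guarded).
- The fast window screen holds variance components at the baseline
  optimum; with very strong climate signals the screening ΔAICc is
  conservative relative to a full refit (the selected window is refitted
  exactly downstream).
- Degenerate designs (a single fish per cohort everywhere, within ≡ 0)
  are detected and reported, not modelled around.
- No generalised (non-Gaussian) responses, no pedigree/'animal'
  extension, no spatial climate fields.
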