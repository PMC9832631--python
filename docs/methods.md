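# Methods

## Model and procedure

The package estimates, per dosing regimen, the probability that a patient
population meets all pre-specified benefit and risk criteria, given the
uncertainties a development team actually faces: parameter estimation error,
cross-species/in-vitro-to-in-vivo translation, and the criteria themselves.

The estimator is a nested Monte-Carlo. The outer loop draws, once per
replicate *i* ∈ 1…M, a joint realization of everything uncertain at the
*trial* level: the fixed-effect/translation parameters θᵢ, the
between-subject covariance Ωᵢ (when the magnitude of variability is itself
uncertain), and each criterion's threshold Kᵢ and required proportion nᵢ.
The inner loop simulates N subjects whose parameters are θᵢ perturbed by
ηⱼ ~ N(0, Ωᵢ) and evaluates each criterion on that population. PoPS = M′/M,
the fraction of replicates passing every criterion jointly. The two loops
must not be merged: criteria operate on population *proportions*, so the
uncertainty (outer) and variability (inner) levels play different roles and
collapsing them changes the estimand.

Assumptions inherited from this structure:

- subjects within a replicate are exchangeable (no covariate model is used
  by the bundled assemblies, though per-subject covariate draws are a
  supported extension point);
- criteria combine conjunctively; there is no weighting or utility layer —
  "how good is good enough" is deliberately left outside the estimator;
- a criterion with several per-subject conditions counts a subject only if
  all conditions hold (used for compound benefit definitions such as
  "central activity normalised AND ≥10% peripheral activity preserved").

## Distributions and conventions

- **BSV** defaults to log-normal on positive parameters: subject value =
  typical·exp(η), with the CV% convention σ = √ln(1+(CV/100)²). This
  preserves the median at the typical value. A `normal` scale
  (typical·(1+η), η SD = CV/100) exists for baselines that may cross zero.
- **Correlated priors/BSV** use a Gaussian dependence structure on the
  (log-)scale; marginals must be normal or log-normal. No other copulas.
- **Scaled beta** priors are parameterised by (mode, lower, upper,
  concentration); shapes follow analytically from α = m·(c−2)+1 with
  m the rescaled mode and c = α+β the concentration (default 4 — broad but
  unimodal). This encodes "most likely X, occasionally much more".
- **Weighted categorical** priors renormalise their weights internally;
  zero weights exclude a category exactly.
- Benefit criteria pass at the boundary (fraction ≥ n); risk criteria are
  strict (violating fraction < allowance). Both are configurable per
  criterion (`proportion_inclusive`), since stated criteria differ between
  "≥ 80%", "< 5%", "≤ 5%" and "> 50%" phrasings. Endpoint/threshold ties
  are resolved exactly by the configured comparator; no epsilon fuzzing.

## Seeding and common random numbers

One master seed governs a run. Replicate *i* draws its uncertainty
quantities from `SeedSequence((seed, 0, i))` in pinned order (fixed effects
— the correlated block first, then insertion order — then BSV realization,
then criteria in declaration order), and its subject effects from
`SeedSequence((seed, 1, i))`. Under common random numbers (default) the
same draws are reused across doses and scenario cells, so curves are smooth
and cross-cell comparisons (e.g. tightening a requirement) are monotone
replicate by replicate. An independent-draws mode
(`common_random_numbers: false`) re-draws subjects per dose via
`SeedSequence((seed, 1, i, dose_index))`. The discipline is part of the
public contract so an independent implementation can reproduce runs
bit-for-bit; the test suite holds the estimator to exactly that.

## Numerical choices

- Steady-state endpoints use closed forms wherever they exist
  (Css,avg = dose/(CL·τ); turnover steady states; Emax inversion) rather
  than long simulations — exact and fast.
- ODE integration (turnover time courses, TMDD): `solve_ivp` with
  rtol 1e-8 / atol 1e-10; LSODA for turnover, BDF for the stiff TMDD
  system. TMDD is offered as the full (kon, koff) model with bookkeeping
  states for mass-balance audits, and as the quasi-steady-state reduction
  (KSS) for speed. The one-compartment oral model switches to the
  equal-rates limiting form when ka ≈ ke instead of failing.
- Percentiles (the 90% bands of subject proportions) use linear
  interpolation between order statistics (Hyndman–Fan type 7, the numpy
  default) — pinned so golden outputs are stable.
- The PTA overlap coefficient is estimated on a shared log-spaced histogram
  grid of 64 bins spanning both samples (pinned); it is symmetric, lies in
  [0,1], and for equal-variance log-scale normals separated by δ approaches
  2·Φ(−δ/(2σ)).
- MIC logistic fits use least squares on the log₂ scale against cumulative
  frequencies (the standard presentation of MIC tables); non-monotone or
  degenerate inputs are rejected rather than fitted.
- Degenerate inputs behave exactly: point priors return their value without
  consuming random numbers; an all-zero Ω yields identical subjects; a
  zero-width band is reported when all replicates agree.
- A structural-model failure in any subject aborts the whole run with the
  replicate and dose identified; no imputation or silent dropping, which
  would bias PoPS.

## Synthetic case fixtures

No real compound data ship with the package; the four fixtures emulate the
archetypal decision situations with invented parameter values, documented
value by value in each fixture's notes (stated study condition vs synthetic
placeholder). The stated conditions — distribution families and ranges
(kp,uu uniform 0.45–0.75/0.35–0.50; fold-elevation uniform 1.5–3.0; beta
need prior with mode 2; species weights 60:30:10; required inhibition
uniform 0.70–0.95), CVs (30%), criteria proportions, and plan sizes (case 3
runs 500×500) — are used exactly. Placeholder PK/PD values were chosen once
so each case reproduces its qualitative outcome: compound A outranks B
(case 1), rise-then-fall PoPS curves whose decline is attributable to the
safety criterion via per-criterion pass rates (cases 2–3), and a
negligible-overlap benchmark comparison (case 4). Cases 1 and 2 run at
M=200, N=500 — enough for stable qualitative behaviour while keeping the
default suite fast; larger M is a one-flag override (`--m` or `plan.m`).

What the fixtures do *not* emulate: real parameter magnitudes or their
correlations, covariate structure (age, weight, disease status), dropout,
assay noise, model misspecification, or time-varying endpoints (the
bundled endpoint assemblies are steady-state closed forms; the ODE layers
are available for registering time-course assemblies). Passing fixture
tests therefore demonstrates correctness of the estimator and the
qualitative mechanics of each case type, not the predictive accuracy of
any particular translational model.

The case 3 endpoint assembly deserves a note: although the mechanistic
layer includes full TMDD, the population endpoint uses the linear-clearance
steady-state average serum concentration with an Imax tissue model. At the
fixture's dose range target occupancy is near-saturated (see
`examples/case3_antibody_tmdd.py`), so target-mediated clearance is a small
correction and the linear regime is the operative one; the closed form
keeps the nested loops vectorised over subjects.

## Design choices on genuinely open points

- Exposure driving the case 1/2 endpoints is the steady-state *average*
  concentration (free, partition-corrected), not the full profile; both
  are supported, but average exposure matches how such criteria are
  typically stated and removes absorption parameters from the endpoint.
- Criteria realizations are drawn per outer replicate and shared across
  doses under common random numbers — one (Kᵢ, nᵢ) combination per virtual
  trial.
- The translation-coefficient prior in case 3 is log-normal by default
  (configurable): positive support and multiplicative error are the
  natural assumptions for a distribution coefficient.
- n-uncertainty (d₄) machinery exists but the fixtures leave n at point
  values — no bundled case exercises it.
- The benchmark's "target efficacy level" in the PTA route enters as a
  configured quantile of the benchmark's own index distribution, since the
  underlying multi-study exposure–response meta-analysis is out of scope.
- MIC doubling-dilution quantization is available but off by default.

## Known limitations

- No parameter estimation from data: the tool simulates from supplied or
  externally fitted parameters.
- No disjunctive criteria combinations, no utility/loss layer, no
  value-of-information analysis.
- Single-process execution; the nested loop is vectorised over subjects but
  outer replicates run serially.
- Config-driven PTA supports AUC:MIC; Cmax:MIC and time-above-MIC are
  library-level (they need full profiles supplied programmatically).
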