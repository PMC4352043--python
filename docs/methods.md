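# Methods

## Model and assumptions

The package models a closed population (no migration, no loss to follow-up)
whose living members hold one of two mutually exclusive states, A and B,
with four nonnegative, smoothly varying transition hazards per person-year:
incidence *i* (A→B), remission *r* (B→A) and the state-specific mortalities
*m_A*, *m_B*.  No distributional assumptions are placed on the hazards
beyond nonnegativity and smoothness — they are nonparametric functions of
calendar time *t* and age *a*.  The prevalence *p(t, a)* of state B among
the living satisfies, along cohort lines,

    (∂/∂t + ∂/∂a) p = (1 − p){ i − p (m_B − m_A) } − r p,

derived from the balance equations of the compartment counts *S* and *C*
(both solved by the package as a cross-check: `solve_SC_system`).  An
equivalent form takes general mortality *m* and the mortality ratio
*R = m_B/m_A* instead of the state-specific pair; both right-hand sides are
exposed (`pde_rhs`, `pde_rhs_relative`) and agree to machine precision
whenever (m, R) are computed from (p, m_A, m_B).  For an irreversible state
(r ≡ 0) the solution has a closed integral representation
(`keiding_prevalence`), used throughout as an independent oracle for the
ODE solvers, never as the production path.

The directional derivative is an ordinary derivative along a cohort's
45-degree Lexis line, so all solvers integrate one-dimensional ODEs along
characteristics.

## Numerical choices

* **Integrator** — classic fixed-step 4th-order Runge–Kutta, default step
  0.1 years.  Deterministic and trivially convergence-testable (the suite
  verifies the ~16-fold error reduction per step halving against a
  closed form).  RK4 can overshoot [0, 1] by O(step⁵) at the boundary;
  solutions are projected back, which preserves the invariant range
  (the right-hand side is ≥ 0 at p = 0 and ≤ 0 at p = 1 for nonnegative
  rates).
* **Boundary condition** — p = 0 at age 0 (nobody holds the property at
  birth), overridable per call.  Characteristics leaving the rate domain
  are clipped at the edge and flagged truncated; rate surfaces refuse
  out-of-domain evaluation rather than extrapolate.
* **Keiding quadrature** — composite Simpson with shared step (default
  0.05 y) on both nested integrals.  The inner integral runs along the same
  characteristic for every outer node, so its cumulative form is
  precomputed once, keeping the cost O(n) per outer node.
* **Inversions** — `invert_incidence` refuses cells with p > 1 − 1e−9 and
  `invert_remission` cells with p < 1e−9 (a singular-inversion error naming
  the cell) instead of returning infinities.  Negative inverted rates,
  which sampling noise can produce, are returned as-is; clamping is an
  application-level policy.
* **First-exit sampling** — cumulative hazards are accumulated by the
  trapezoid rule on a 0.01-year age grid; the exponential quantile is
  inverted exactly on that piecewise-linear interpolant (monotone, so the
  root is unique).  Draws beyond the grid end are censored there; the
  register generator records them as deaths at the terminal age (110 y,
  where survival is numerically zero under the default mortality).

## Estimation conventions

Lifelines are half-open [birth, death); Lexis squares are half-open
[k, k+1) × [j, j+1), so every event lands in exactly one square and the
total person-years over a full partition equal the summed lifetimes exactly
(tested to round-off).  Segment lengths on the 45-degree lifelines are
computed exactly, with no discretization.  A survey-age bin a* covers exact
ages [a*, a*+1); diagnosis exactly at the survey instant counts as state B,
death exactly at the survey instant as dead.  Rate standard errors use the
Poisson approximation sqrt(events)/person-years with no continuity
correction; zero-event squares get SE 0.

Because a 1-year age bin represents its midpoint, the two-survey incidence
reconstruction is carried out at half-integer ages, which lines the central
quotient up exactly with the matched birth cohort observed in both surveys;
the denominator uses the midpoint prevalence (mean of the two matched
observations), second-order consistent with the quotient.  The same
midpoint convention is the default in the sign-split attribution.

In the PDE-residual pipeline, a rate entering a node must rest on at least
0.5 person-years of exposure in its square (configurable).  Below that
floor a single event produces an arbitrarily large rate estimate carrying
no information about the hazard, and one such cell can dominate the pooled
standard deviation; nodes resting on sub-floor cells are flagged invalid
and counted, not imputed.  Where a node's prevalence is exactly zero the
m_B term vanishes, so an unestimable m_B does not invalidate the node.

## Synthetic populations

**Hypothetical-disease population** (default 1,000,000 persons): births
uniform on calendar years (0, 100); a healthy newborn's life expectancy
rises affine-linearly from 55 years (t = 0) to 75 (t = 100); the lifetime
risk of the irreversible disease rises affine-linearly from 10% to 25%;
disease shortens life by ΔLE ~ U(5, 10) years and is diagnosed X ~ U(0, 12)
years before death.  Individual healthy lifespans are drawn
Normal(LE(birth), 8.0 y), truncated at 15 y: the spread makes deaths
scatter into the 70–89 age range of the survey window at the realistic
person-year exposures that drive the residual's age-dependent variance
(about 7,400 person-years with ~1,550 deaths at ages 70–79 and about 230
person-years with ~80 deaths at 80–89 in survey year 115 of a full run).
Setting the spread to zero gives the degenerate variant in which each
healthy lifespan equals the life expectancy exactly; its survey window then
contains nobody above age ~68.

**Register population** (default 7,500 persons per birth year 1900–1960,
457,500 in total): diagnosis and disease-free death compete; the first exit
from the healthy state is drawn by inverse transform from the integrated
total hazard i + m_A along the cohort's mid-year characteristic, the event
type is a diagnosis with probability i/(i + m_A) at the exit age, and
diagnosed persons draw their residual death age from m_B conditional on
survival to diagnosis.  Births are uniform within each year; the secular
mortality trend is 0.2%/yr, so using mid-year hazards within a birth year
changes hazards by at most ~0.1% and is part of the generator's definition.

**Fixture rates** stand in for external life-table and register-study
inputs that are not distributable with the package: background mortality is
Gompertz with secular decline, m_A(t, a) = 4.5e−5 · exp(0.085 a) ·
exp(−0.002 (t − 1900)) (modal death age in the late 70s–80s, ~40% survival
to 90 for mid-century cohorts — deliberately on the optimistic side so the
oldest survey bins stay populated); incidence is zero before age 60 and
exponential after it, i(a) = 7e−4 · exp(0.12 (a − 60)) (doubling every ~6
years, the canonical late-life dementia shape, reaching 2.6%/yr at 90);
diseased mortality is m_B = 2 m_A.  These values were fixed once from field
realism plus a sampling-variance budget for the old-age survey bins and are
the package's study conditions, not tuning knobs.

What the generators deliberately do **not** emulate: migration, censoring
or delayed entry, reporting error in diagnoses, within-cohort heterogeneity
of risk, and any calendar-time trend in incidence.  Passing tests therefore
demonstrate the internal consistency of the estimators under clean
closed-population sampling, not robustness to the selection and measurement
problems of real registers and surveys.

## Validation experiments

1. **PDE residual D** — cross-sections in years 95–135 estimate p; the
   cohort derivative is the central quotient with h = 1; i, m_A, m_B come
   from the person-year method on the corner-anchored square at each node;
   D is the difference between the quotient and the PDE right-hand side
   with r = 0.  All valid nodes are pooled equally into seven summary
   statistics, plus per-age means and SDs.  On noise-free analytic inputs
   (`difference_surface_analytic`) the pipeline's residual is pure O(h²)
   finite-difference error (< 5e−6 on the smooth test surface), so the
   survey-data residual isolates sampling error.
2. **Incidence reconstruction** — two cross-sections four years apart
   around year 2000; inversion with r = 0 and the known mortality
   surfaces; errors reported over ages 60–90.  On noise-free prevalences
   the error decays as O(h²) under survey-spacing refinement.  The
   reconstruction is unbiased across seed replicates (tested on twenty
   small registers).

The default suite runs the residual experiment at 200,000 persons with a
correspondingly widened spread band; the acceptance script runs the full
1,000,000.  Both full experiments complete in seconds on one CPU.

## Applications

The **habit-prevalence scenario** forward-models smoking-like prevalence
with the general-mortality PDE form: initiation rises steeply over ages
12–16 and decays thereafter, carrying a multiplicative secular decline of
0.5% per calendar year; cessation is zero below 18 with bumps at 20 and 60
(two-Gaussian mixture); the relative hazard R(a) is 1 below age 40, affine
to 2.5 at 60, affine down to 1.5 at 80 and constant beyond (the extension
past 80 is a design choice; the profile is piecewise-affine interpolation
between those knots).  The default rate shapes are qualitative stand-ins —
the package asserts boundedness, unimodality and grid-refinement stability
of the output, never specific survey values.

The **sign-split attribution** assumes equal mortality in both states and
attributes a birth cohort's prevalence increase between consecutive surveys
wholly to the acquisition rate and a decrease wholly to the loss rate:
i = dp/(1 − p̄), r = −dp/p̄, reported per 1000 person-years, with the actual
per-pair survey spacing carried in the output (the quinquennial-ish DHS
calendar is uneven).  A dp of exactly zero maps to (0, 0).  The rule is
exact when the two rates are never simultaneously active on a cohort step
and is recovered to O(Δ²) on synthetic surveys with age-disjoint learning
and forgetting; where both processes overlap it describes the cohort's net
average, not individual behaviour.

## Known limitations

* Rates below ~0.25 person-years of exposure per square are unestimable at
  these study sizes; the residual pipeline excludes them, which makes its
  pooled dispersion slightly conservative relative to a pipeline that
  retains them.
* No confidence bands are attached to reconstructed incidence; resampling
  methods would be the natural extension.
* The sign-split attribution is identified only under the equal-mortality
  assumption and the one-rate-at-a-time convention; midpoint vs endpoint
  denominators are a config switch with midpoint as the symmetric default.
* The reconstruction degrades where survey bins thin out (oldest ages) as
  1/sqrt(exposure); with the default register it is reliable to about age
  90.
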