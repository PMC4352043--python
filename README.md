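# illnessdeath

A three-state (A / B / Dead) compartment model for the prevalence of a
dichotomous trait — ill vs healthy, smoker vs non-smoker, knows vs does not
know — as a function of calendar time *t* and age *a*, for epidemiologists
and public-health modellers working with repeated cross-sectional data.

## The model

Living persons aged *a* at time *t* are in state A (count *S(t, a)*) or
state B (count *C(t, a)*) and move between them with the incidence rate
*i(t, a)* (A → B) and the remission rate *r(t, a)* (B → A); each state has
its own mortality, *m_A* and *m_B*.  The age-specific prevalence of B,
*p = C / (S + C)*, obeys a one-dimensional PDE along cohort lines (the
direction (1, 1) on the Lexis plane):

    (∂/∂t + ∂/∂a) p = (1 − p) · { i − p (m_B − m_A) } − r p

When only the general mortality *m = (1 − p) m_A + p m_B* and the mortality
ratio *R = m_B / m_A* are known, the equivalent form

    (∂/∂t + ∂/∂a) p = (1 − p) · { i − m · p (R − 1) / (p (R − 1) + 1) } − r p

applies.  For an irreversible state (*r* = 0) the solution coincides with
the classical Keiding integral, which the package implements as an
independent cross-check.  Because the PDE is algebraic in each rate, it can
be solved for any one of them — in particular, incidence can be estimated
from two cross-sectional prevalence surveys plus known mortality, without a
follow-up study.

The package provides:

* **model core** — PDE right-hand sides, 4th-order Runge–Kutta solvers along
  cohort characteristics and on (t, a) grids, the two-compartment (S, C)
  system, the Keiding integral, and exact algebraic inversions for *i* and *r*;
* **Lexis estimation** — person-year rates per 1-year time × age square with
  Poisson standard errors, cross-sectional prevalence, and cohort difference
  quotients;
* **simulation** — a hypothetical-disease population (1,000,000 births over a
  century) and a register population (457,500 persons, competing-risks
  inverse-transform sampling), plus parametric fixture rates;
* **validation pipelines** — the PDE-residual surface D and the two-survey
  incidence reconstruction;
* **applications** — a habit-prevalence forward scenario and the sign-split
  attribution of cohort prevalence change to learning/forgetting rates;
* a CLI (`illnessdeath simulate | estimate | validate | reconstruct |
  scenario | attribute`) with flat key-value configs and JSON run manifests.

## Worked example

```python
import numpy as np
from illnessdeath import (RateSet, RateSurface, solve_prevalence_cohort,
                          invert_incidence, keiding_prevalence)

# a chronic irreversible condition: incidence rising with age,
# diseased mortality twice the background
i  = RateSurface(lambda t, a: 5e-4 * np.exp(0.055 * np.asarray(a, float)), name="i")
mA = RateSurface(lambda t, a: 5e-5 * np.exp(0.09 * np.asarray(a, float)), name="mA")
mB = RateSurface(lambda t, a: 1e-4 * np.exp(0.09 * np.asarray(a, float)), name="mB")
rates = RateSet(i=i, r=RateSurface.constant(0.0), m_A=mA, m_B=mB)

# prevalence along the birth cohort of calendar year 1940
traj = solve_prevalence_cohort(rates, t0=1940.0, a0=0.0, p0=0.0, a_end=80.0)
for age in (40, 60, 80):
    print(f"age {age}: prevalence {traj.p_values[int(round(age / 0.1))]:.4f}")

# cross-check against the closed-form integral (valid because r = 0)
print(f"integral form at age 80: {keiding_prevalence(i, mA, mB, t=2020.0, a=80.0):.4f}")

# invert the PDE: recover the incidence from the prevalence change at age 60
p60, p_lo, p_hi = (traj.p_values[int(round(a / 0.1))] for a in (60, 59, 61))
i_hat = invert_incidence((p_hi - p_lo) / 2, p60, r=0.0,
                         mA=mA(2000.0, 60.0), mB=mB(2000.0, 60.0))
print(f"recovered incidence at 60: {i_hat:.5f}  (true {i(2000.0, 60.0):.5f})")
```

prints

```
age 40: prevalence 0.0696
age 60: prevalence 0.1989
age 80: prevalence 0.4002
integral form at age 80: 0.4002
recovered incidence at 60: 0.01355  (true 0.01356)
```

By age 80, 40% of the surviving cohort carries the condition; the PDE solve
and the integral representation agree to the printed precision, and
inverting the PDE on a one-year central difference of the solved prevalence
returns the input incidence to three significant digits (the residual is
the O(h²) finite-difference error).

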