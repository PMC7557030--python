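# Methods

## The decision problem

The package evaluates whether adding brentuximab vedotin to frontline
chemotherapy for advanced Hodgkin lymphoma (BREN+AVD) is cost-effective
relative to standard ABVD, from a Canadian public-payer perspective. It
implements a probabilistic state-transition (Markov cohort) model: two
structurally identical arms, six mutually exclusive health states, 6-month
cycles over a 15-year horizon, costs in 2018 CAD, effects in
quality-adjusted life years (QALYs), both discounted at 1.5% per year.

States: (i) on frontline treatment; (ii) complete remission (CR);
(iii) first progression/relapse, with possible autologous stem-cell
transplant (ASCT); (iv) remission after ASCT; (v) second progression,
treated with salvage therapy; (vi) death (absorbing). The cohort starts
entirely in the treatment state.

## Time-dependent transition probabilities

Transitions out of remission-like and salvage states are not constant:
they are derived from Weibull survival curves,
`S(t) = exp(-(t/λ)^k)` with time `t` in months, shape `k` and scale `λ`.
The per-cycle probability of the event in the cycle beginning at time `t`
is the conditional failure probability

```
p(t) = 1 - S(t + c) / S(t),        c = 6 months.
```

Five curves parameterize each arm: progression/relapse from CR, mortality
in CR, mortality during first progression/relapse, progression after ASCT,
and mortality after post-ASCT progression. Because these curves are
measured from state entry (remission date, relapse date), the engine
indexes them by *residence time* — cycles since entering the state — and
implements this with tunnel expansion of the affected states. First
progression/relapse resolves within one cycle (transplant triage), so its
tunnel is trivially one deep. Mortality after post-ASCT progression is
also residence-indexed and tunneled for the same reason.

Fitting pathways:

* **Individual-level data** (the registry pathway): censoring-aware
  maximum likelihood on `(log k, log λ)` with an analytic gradient
  (BFGS, gradient tolerance 1e-8). The parameter covariance is the inverse
  observed information — the Hessian of the negative log-likelihood at the
  optimum, computed by central differences on the log scale. A fit with
  fewer than two observed events, or a non-converged optimization with a
  materially nonzero gradient, raises an explicit error rather than
  returning defaults. The censoring-aware-MLE choice is ours: least
  squares on curve coordinates would also have been defensible, but MLE
  uses the censoring information and yields the covariance needed
  downstream.
* **Published curves** (the trial pathway): digitized survival coordinates
  plus the number-at-risk table are converted to pseudo individual-patient
  data and fitted by the same MLE. The reconstruction is deliberately
  simple — per inter-coordinate interval, the event count that best
  reproduces the survival drop given the current risk set, events spread
  evenly over the interval, censorings (whatever reconciles the risk
  table) at the interval's right edge, survivors past the last coordinate
  censored there. It guarantees that re-estimating the Kaplan–Meier curve
  from the output reproduces every input coordinate to within
  `1/n`. It is not the Guyot reconstruction algorithm and does not
  recover within-interval step placement.

Uncertainty in a per-cycle probability is the delta-method standard error:
the gradient of `p(t)` with respect to `(log k, log λ)` propagated through
the fit covariance (verified against a parametric bootstrap in the tests).
We compute the SE of the per-cycle probability, not of `S(t)` itself,
because the per-cycle probability is the quantity the sampler perturbs.
Each probability/SE pair maps to a Beta distribution by moment matching:

```
ν = m(1-m)/se² - 1,   α = mν,   β = (1-m)ν.
```

An SE too large to be feasible for a Beta with mean `m` is reduced to just
inside the boundary with a logged warning. Costs map to Gamma
distributions the same way (`shape = m²/se²`, `rate = m/se²`); a zero SE
is a flagged point mass.

## Transition structure and accrual rules

Competing risks within a state combine as death first, then the remaining
mass split by the progression probability: `P(death) = q`,
`P(progress) = (1-q)p`, `P(stay) = (1-q)(1-p)`. This guarantees valid
rows for any `p, q ∈ [0,1]`.

Treatment cycle (cycle 1): on-treatment mortality applies first;
survivors fail to reach CR with probability
`1 - (1-p₀)(1-p_disc)`, where `p₀` is the first-cycle failure probability
of the progression curve and `p_disc` the discontinuation probability —
the two routes are combined independently and both lead to first
progression/relapse. The full regimen drug cost is charged up front
regardless of discontinuation (a conservative choice); the expected
adverse-event management cost `p_AE × $12,036` is charged with it, and
the response-assessment PET scan ($1,877) is charged for the whole
starting cohort at the end of cycle 1. Adverse events are not a separate
state: the treatment-cycle utility is the expectation
`p_AE·0.59 + (1-p_AE)·0.71`.

First progression/relapse resolves in one cycle: 80% receive ASCT
($67,723, charged on entry); half of transplanted patients reach post-ASCT
remission, the rest — and the 20% not eligible — move to second
progression, where the salvage-regimen cost ($140,800) is charged once on
entry. Mortality during the relapse cycle applies concurrently.

Utilities for states the source table does not list: post-ASCT remission
uses the remission utility (0.91); both progression states use the
progressive-disease utility (0.38). No mortality curve exists for the
post-ASCT remission state, so it reuses the mortality-in-CR curve
(remission-like mortality); death from that state is otherwise only
reachable through second progression, which would understate risk.

QALYs for a cycle use the occupancy at the cycle's start × utility ×
0.5 years; an optional half-cycle correction (off by default, matching
common modeling-tool defaults) averages start- and end-of-cycle occupancy.
Discounting is evaluated at cycle start, `(1.015)^(-t)` with `t` in years;
a midpoint option shifts every factor by a quarter year. No background
general-population mortality is added beyond the fitted curves — a known
limitation for the tail of the 15-year horizon. Currency is plain float
CAD throughout; with Gamma-sampled costs there is no exact-decimal
invariant worth preserving.

## Probabilistic analysis

Monte Carlo simulation (default 10,000 iterations, seeded) samples every
uncertain parameter independently, except the two log-Weibull parameters
within one fit, which are drawn jointly from their bivariate normal with
the fit covariance. Shared parameters (utilities, downstream costs,
transplant probabilities) use one draw per iteration applied to both arms;
arm-specific parameters are drawn per arm. Each draw is a full two-arm
cohort evaluation.

Cost-effectiveness at a willingness-to-pay `λ` is defined by net monetary
benefit `λ·ΔE - ΔC > 0` — not by naive ICER comparison — so draws in the
southwest quadrant are handled correctly; an NMB of exactly zero counts as
not cost-effective (deterministic tie-break, measure-zero in theory). The
CEAC evaluates this fraction on a grid (default $0–$500,000 per QALY in
$10,000 steps). Quadrant fractions partition the plane with ties assigned
toward the standard arm. Interval summaries are 2.5th–97.5th percentile
intervals of the simulation draws (percentile, not normal-theory,
intervals — the published table's "95% confidence intervals" are
ambiguous on this point).

Failed iterations (e.g., a degenerate sampled parameter set) abort the run
by default; a permissive flag resamples and logs the count.

## Price-reduction scenarios

The scenario module scales the experimental regimen's drug cost (mean and
SE together, preserving the Gamma shape) by `(1 - f)` and re-runs the
model. ΔE is exactly invariant (the price enters only the cost stream),
and ΔC is affine in `f`, so the deterministic ICER falls monotonically
while the comparison stays in the northeast quadrant. The break-even
fraction at a threshold is found by bisection on deterministic
acceptability (NMB rule) to a fraction tolerance of 1e-4; non-bracketing
cases return the boundary with a status flag. The break-even is defined on
the deterministic ICER; the CEAC-0.5 crossing can be read from the PSA
sweep, which uses common random numbers (one seed shared across scenarios)
so that differences between scenarios reflect price, not sampling noise.

## Default standard errors

The source reports point estimates only, so defaults supply second-order
uncertainty: probabilities get the binomial SE at the trial's per-arm size
(`sqrt(p(1-p)/664)`); costs and utilities get 20% of the mean — a common
convention when only point estimates are published. Every SE is
overridable in the config file.

## The synthetic generators and the Weibull fixture

Neither original data source is available, so the package ships
generators that emulate their *statistical form*:

* the registry stand-in draws `n = 1519` event times from a known Weibull
  with administrative censoring at 180 months plus independent exponential
  censoring whose rate is calibrated (via the Weibull's Laplace transform)
  to a target censoring fraction, 20% by default;
* the trial stand-in simulates an arm of `n = 664`, estimates its
  Kaplan–Meier curve, and reports it exactly as a digitizer would: curve
  coordinates at 6-month report times to 60 months, plus the
  number-at-risk table.

What these generators do *not* emulate: covariates (age, stage),
non-proportional or non-Weibull hazards, informative censoring, digitizer
measurement error, and reporting granularity coarser than the report-time
grid. Passing recovery tests therefore demonstrate correctness of the
estimation machinery under the model's own assumptions, not robustness to
real-data violations of them.

The fitted Weibull parameters behind the original "time-dependent" entries
were never published. The shipped fixture is therefore calibrated, once,
to the clinical regime the literature describes, and documented here:

| transition | arm | shape | scale (months) | implied |
|---|---|---|---|---|
| progression/relapse from CR | ABVD | 0.75 | 600 | ≈33% progress by 15 y, early-weighted |
| progression/relapse from CR | BREN+AVD | 0.75 | 720 | hazard ratio ≈0.87 vs ABVD |
| mortality in CR | both | 1.10 | 1500 | ≈9% 15-y mortality in remission |
| mortality in progression/relapse | both | 1.00 | 120 | ≈5% per 6-month cycle |
| progression post-ASCT | both | 0.80 | 200 | ≈60% relapse by 15 y |
| mortality after 2nd progression | both | 1.00 | 60 | median ≈3.5 y on salvage |

The progression hazard ratio (0.87) lies inside the trial's reported
interval (0.60–0.98); it was chosen jointly with the cost structure so the
fixture reproduces the qualitative reference-case regime: the experimental
arm costlier and slightly more effective, deterministic ICER well above
$100,000 per QALY, and a break-even price reduction above 50%. Every fit
carries the same log-scale covariance (SD 0.05 on log-shape, 0.10 on
log-scale, mild negative correlation) — the precision typical of a
censored fit on a cohort of this size. Note the headline dollar figures of
the original analysis are *not* reproducible from published inputs alone
(its per-arm totals imply substantial cost accrual beyond the published
one-off costs), which is why fixture-dependent checks are property-based
rather than value-matching.

## Numerical choices

* Transition probabilities are computed on the cumulative-hazard scale,
  never as a ratio of underflowing survivals; if `S(t)` underflows the
  probability is reported as 1 with a logged warning.
* Weibull MLE: start at shape 1 and scale = mean event time; BFGS with
  analytic gradient; covariance by central-difference Hessian (step 1e-5).
* Trace validation: occupancy rows renormalized against accumulated
  round-off, then required to sum to 1 within 1e-9; death occupancy must
  be non-decreasing.
* Bisection: ≤60 iterations, terminates when the bracket is below the
  fraction tolerance; returns the acceptable endpoint.
* Problem sizes for the shipped diagnostics: 200 replicates at n = 1519
  for Wald coverage, single seeded replicate at n = 664 for the
  publication pipeline, 10,000 iterations for the reference probabilistic
  run.

## Known limitations

* No background general-population mortality; remission mortality at long
  horizons is whatever the fitted curve extrapolates.
* Discontinuers are routed to first progression/relapse at the end of
  cycle 1 and still incur the full regimen cost; the original's handling
  is unstated.
* Whether on-treatment progressors bypass CR entirely versus relapse from
  it is structurally ambiguous in the source; both arrive in the same
  state here, differing only in timing.
* The pseudo-IPD reconstruction shows a small finite-grid bias
  (shape high / scale low by a few percent at a 60-month report window);
  recovery stays within ~1 SE on average and the round-trip invariant is
  exact to 1/n.
* Only two comparators, no value-of-information analysis, no PET-adapted
  de-escalation strategies.
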