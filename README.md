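# hlcea

Probabilistic cost-effectiveness model for frontline therapy in advanced
Hodgkin lymphoma: brentuximab vedotin plus AVD chemotherapy (BREN+AVD)
versus standard ABVD, from a Canadian public-payer perspective.

The package is aimed at health-economics analysts and methods researchers
who want a fully scripted, testable implementation of a common model
archetype: a two-arm, six-state Markov cohort model (treatment → complete
remission → progression/relapse → post-transplant remission → second
progression → death) with 6-month cycles over 15 years, costs in 2018 CAD
and effects in QALYs, both discounted at 1.5%/year.

Its core pieces:

* **Survival machinery** — censoring-aware Weibull maximum likelihood
  (`S(t) = exp(-(t/λ)^k)`) with log-scale Hessian covariance;
  pseudo individual-patient-data reconstruction from digitized
  Kaplan–Meier curves plus number-at-risk tables; per-cycle transition
  probabilities `p(t) = 1 - S(t+c)/S(t)` with delta-method standard
  errors, moment-matched to Beta distributions.
* **Markov engine** — residence-time-dependent transitions via tunnel
  expansion, exact probability bookkeeping, configurable half-cycle
  correction and discount timing.
* **Probabilistic sensitivity analysis** — seeded Monte Carlo over
  Beta/Gamma/log-normal parameter distributions, cost-effectiveness plane,
  CEAC via the net-monetary-benefit rule `λ·ΔE − ΔC > 0`.
* **Price scenarios** — drug-price reduction sweeps and a bisection
  break-even search at a willingness-to-pay threshold.
* **Synthetic data** — generators emulating the two unavailable source
  datasets (a registry cohort of 1519 patients; published trial curves at
  n = 664 per arm), so the whole pipeline runs offline and its estimation
  steps can be validated against known truth.

## Worked example

The deterministic base case on the shipped parameter set:

```bash
hlcea run --outdir out/
cat out/base_case.json
```

```json
{
  "cost_abvd": 81982.75,
  "qalys_abvd": 9.21,
  "cost_bren_avd": 180486.77,
  "qalys_bren_avd": 9.53,
  "incremental_cost": 98504.03,
  "incremental_qalys": 0.33,
  "icer": 300662.98,
  "icer_label": "icer"
}
```

Reading: over 15 years a standard-arm patient accrues a discounted
$81,983 and 9.21 QALYs; the experimental arm costs $180,487 for
9.53 QALYs. The extra 0.33 QALYs cost $98,504, an incremental
cost-effectiveness ratio of ≈$300,663 per QALY — far above commonly cited
willingness-to-pay thresholds of $50,000–$100,000 per QALY.

The probabilistic analysis and the price analysis:

```bash
hlcea psa --iterations 10000 --seed 1 --outdir out/
hlcea price-sweep --threshold 100000 --outdir out/
```

With seed 1, 2.5% of 10,000 simulations are cost-effective at
$100,000/QALY (26.2% at $200,000), 6.2% of simulations show the
experimental arm both costlier and less effective, and the drug price
must fall by ≈57% before the deterministic ICER reaches the
$100,000/QALY threshold. Plots (`ce_plane.png`, `ceac.png`) and CSVs of
every iteration, the CEAC, and the sweep are written alongside the JSON
summaries; every summary records the seed and the config hash.

The same numbers are available as library calls (`hlcea.run_psa`,
`hlcea.ceac`, `hlcea.breakeven_reduction`, …); synthetic source data come
from `hlcea.generate_cohort` and `hlcea.generate_km_publication`.

All model inputs live in one YAML file (see
`src/hlcea/data/default_params.yaml`, schema-validated with strict
unknown-key rejection); pass `--config` to any subcommand to use your own.
Because the originally fitted Weibull parameters were never published, the
shipped defaults use a documented, calibrated fixture — see
`docs/methods.md` for the calibration rationale and every modeling
assumption.

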