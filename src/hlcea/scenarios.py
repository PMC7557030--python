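"""Price-reduction scenario analysis for the experimental regimen.

Because the intervention's drug price enters the model only as a one-off
cost, the incremental QALYs are invariant to price reductions and the
incremental cost — hence the deterministic ICER while the comparison stays
in the northeast quadrant — is affine in the reduction fraction. The
break-even search exploits neither fact: it bisects the deterministic
ICER-fraction curve directly, so it remains correct if the accrual rules
change.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .markov import ICERResult, compute_icer, evaluate_arm
from .parameters import ModelParameters
from .psa import ce_plane_summary, run_psa

__all__ = [
    "PriceScenario",
    "BreakevenResult",
    "apply_price_reduction",
    "price_sweep",
    "breakeven_reduction",
]


@dataclass(frozen=True)
class PriceScenario:
    """Model results under one drug-price reduction fraction."""

    reduction: float
    drug_cost: float
    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str
    prob_ce: dict[str, float] | None = None  # PSA mode only


@dataclass(frozen=True)
class BreakevenResult:
    """Break-even reduction fraction at a willingness-to-pay threshold.

    ``status`` is ``"bracketed"`` when the threshold is crossed inside
    (0, 1); ``"already_cost_effective"`` when the base case is at or below
    the threshold (fraction 0); ``"not_attainable"`` when even a free drug
    leaves the ICER above the threshold (fraction 1).
    """

    fraction: float
    status: str
    icer_at_fraction: float | None


def apply_price_reduction(
    params: ModelParameters, fraction: float
) -> ModelParameters:
    """Scale the experimental regimen's drug cost by ``(1 - fraction)``.

    Both the mean and the SE of the drug-cost parameter are scaled, so the
    Gamma shape is preserved and only the monetary scale changes; every
    other parameter is untouched.
    """
    if not (0.0 <= fraction <= 1.0):
        raise ValueError("reduction fraction must lie in [0, 1]")
    out = params.copy()
    dc = out.bren_avd.drug_cost
    scaled = replace(dc, mean=(1.0 - fraction) * dc.mean, se=(1.0 - fraction) * dc.se)
    bren = replace(out.bren_avd, drug_cost=scaled)
    return ModelParameters(abvd=out.abvd, bren_avd=bren, shared=out.shared)


def _deterministic_icer(params: ModelParameters) -> tuple[ICERResult, float]:
    point = params.point()
    res_a = evaluate_arm(point.abvd, point.shared)
    res_b = evaluate_arm(point.bren_avd, point.shared)
    return compute_icer(res_a, res_b), point.bren_avd.drug_cost


def price_sweep(
    params: ModelParameters,
    fractions,
    mode: str = "deterministic",
    seed: int | None = None,
    n_iter: int = 1000,
    thresholds=(100_000.0, 200_000.0),
) -> list[PriceScenario]:
    """Evaluate the model across a grid of price-reduction fractions.

    PSA mode reuses the same seed for every scenario (common random
    numbers), so differences between scenarios reflect the price change
    rather than sampling noise.
    """
    fractions = np.asarray(fractions, dtype=float)
    if np.any((fractions < 0) | (fractions > 1)):
        raise ValueError("all fractions must lie in [0, 1]")
    if mode not in ("deterministic", "psa"):
        raise ValueError("mode must be 'deterministic' or 'psa'")
    if mode == "psa" and seed is None:
        raise ValueError("psa mode requires a seed")

    scenarios = []
    for f in fractions:
        reduced = apply_price_reduction(params, float(f))
        icer_res, drug_cost = _deterministic_icer(reduced)
        prob_ce = None
        if mode == "psa":
            results = run_psa(reduced, n_iter=n_iter, seed=seed)
            summary = ce_plane_summary(results, icer_thresholds=thresholds)
            prob_ce = {
                k: v for k, v in summary.items() if k.startswith("prob_ce_at_")
            }
        scenarios.append(
            PriceScenario(
                reduction=float(f),
                drug_cost=drug_cost,
                delta_cost=icer_res.delta_cost,
                delta_qalys=icer_res.delta_qalys,
                icer=icer_res.icer,
                label=icer_res.label,
                prob_ce=prob_ce,
            )
        )
    return scenarios


def sweep_to_frame(scenarios: list[PriceScenario]) -> pd.DataFrame:
    rows = []
    for s in scenarios:
        row = {
            "fraction": s.reduction,
            "drug_cost": s.drug_cost,
            "dcost": s.delta_cost,
            "dqaly": s.delta_qalys,
            "icer": s.icer,
            "label": s.label,
        }
        if s.prob_ce:
            row.update(s.prob_ce)
        rows.append(row)
    return pd.DataFrame(rows)


def _cost_effective_at(icer_res: ICERResult, wtp: float) -> bool:
    """Deterministic acceptability by the net-monetary-benefit rule."""
    return wtp * icer_res.delta_qalys - icer_res.delta_cost > 0


def breakeven_reduction(
    params: ModelParameters,
    wtp_threshold: float,
    tol: float = 1e-4,
    max_iter: int = 60,
) -> BreakevenResult:
    """Smallest price reduction making the regimen cost-effective at ``wtp``.

    Bisection on the deterministic acceptability of the reduction fraction.
    Non-bracketing endpoints return the boundary with a status flag rather
    than raising: fraction 0 if the base case is already acceptable,
    fraction 1 if even a free drug is not.
    """
    if wtp_threshold <= 0:
        raise ValueError("willingness-to-pay threshold must be positive")
    icer0, _ = _deterministic_icer(params)
    if _cost_effective_at(icer0, wtp_threshold):
        return BreakevenResult(0.0, "already_cost_effective", icer0.icer)
    icer1, _ = _deterministic_icer(apply_price_reduction(params, 1.0))
    if not _cost_effective_at(icer1, wtp_threshold):
        return BreakevenResult(1.0, "not_attainable", icer1.icer)

    lo, hi = 0.0, 1.0  # not acceptable at lo, acceptable at hi
    hi_icer = icer1
    for _ in range(max_iter):
        if hi - lo <= tol:
            break
        mid = 0.5 * (lo + hi)
        icer_mid, _ = _deterministic_icer(apply_price_reduction(params, mid))
        if _cost_effective_at(icer_mid, wtp_threshold):
            hi, hi_icer = mid, icer_mid
        else:
            lo = mid
    return BreakevenResult(hi, "bracketed", hi_icer.icer)
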