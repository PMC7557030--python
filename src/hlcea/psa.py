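"""Probabilistic sensitivity analysis.

Monte Carlo propagation of second-order parameter uncertainty through the
two-arm cohort model: probabilities and utilities are sampled from Beta
distributions and costs from Gamma distributions matched to (mean, SE);
each time-dependent Weibull fit is sampled on the (log shape, log scale)
plane from the bivariate normal implied by its covariance, preserving the
within-fit correlation. All parameters are otherwise independent; shared
parameters use one draw per iteration applied to both arms.

Outputs follow cost-effectiveness-plane conventions: per-iteration
incremental cost and QALY pairs (experimental minus standard arm), the
cost-effectiveness acceptability curve (probability of positive net
monetary benefit across willingness-to-pay values), quadrant fractions and
percentile summaries.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .markov import evaluate_arm
from .parameters import (
    ArmParameters,
    ArmSpec,
    ModelParameters,
    ParameterDraw,
    SharedParameters,
    SharedSpec,
    UncertainValue,
)
from .survival import WeibullFit, beta_from_moments, gamma_from_moments

logger = logging.getLogger(__name__)

__all__ = [
    "PSAResults",
    "CEACCurve",
    "PSAIterationError",
    "sample_parameters",
    "run_psa",
    "ceac",
    "ce_plane_summary",
    "psa_summary",
]

RESULT_COLUMNS = (
    "iter",
    "cost_abvd",
    "qaly_abvd",
    "cost_bren",
    "qaly_bren",
    "dcost",
    "dqaly",
)


class PSAIterationError(RuntimeError):
    """A Monte Carlo iteration produced an invalid model evaluation."""


@dataclass(frozen=True)
class PSAResults:
    """Per-iteration two-arm outcomes from the Monte Carlo simulation."""

    data: pd.DataFrame
    seed: int
    n_iterations: int
    n_resampled: int = 0

    def __post_init__(self):
        if self.n_iterations <= 0:
            raise ValueError("n_iterations must be positive")
        missing = set(RESULT_COLUMNS) - set(self.data.columns)
        if missing:
            raise ValueError(f"results missing columns {sorted(missing)}")
        if len(self.data) != self.n_iterations:
            raise ValueError("row count does not match n_iterations")
        if not np.allclose(
            self.data["dcost"], self.data["cost_bren"] - self.data["cost_abvd"]
        ):
            raise ValueError("dcost must equal cost_bren - cost_abvd")
        if not np.allclose(
            self.data["dqaly"], self.data["qaly_bren"] - self.data["qaly_abvd"]
        ):
            raise ValueError("dqaly must equal qaly_bren - qaly_abvd")

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


@dataclass(frozen=True)
class CEACCurve:
    """Probability cost-effective across a willingness-to-pay grid."""

    wtp: np.ndarray
    prob_ce: np.ndarray

    def __post_init__(self):
        wtp = np.asarray(self.wtp, dtype=float)
        prob = np.asarray(self.prob_ce, dtype=float)
        if wtp.shape != prob.shape or wtp.ndim != 1:
            raise ValueError("wtp and prob_ce must be 1-d arrays of equal length")
        if np.any(wtp < 0):
            raise ValueError("willingness-to-pay values must be non-negative")
        if np.any(np.diff(wtp) <= 0):
            raise ValueError("willingness-to-pay grid must be strictly increasing")
        if np.any((prob < 0) | (prob > 1)):
            raise ValueError("probabilities must lie in [0, 1]")
        object.__setattr__(self, "wtp", wtp)
        object.__setattr__(self, "prob_ce", prob)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"wtp": self.wtp, "prob_ce": self.prob_ce})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


DEFAULT_WTP_GRID = np.arange(0, 500_001, 10_000, dtype=float)


def _sample_value(v: UncertainValue, rng: np.random.Generator) -> float:
    if v.se == 0.0 or v.dist == "fixed":
        return v.mean
    if v.dist == "beta":
        a, b = beta_from_moments(v.mean, v.se)
        return float(rng.beta(a, b))
    if v.dist == "gamma":
        if v.mean == 0.0:
            return 0.0
        shape, rate = gamma_from_moments(v.mean, v.se)
        return float(rng.gamma(shape, 1.0 / rate))
    raise ValueError(f"unknown distribution {v.dist!r}")  # pragma: no cover


def _sample_fit(fit: WeibullFit, rng: np.random.Generator) -> WeibullFit:
    if np.all(fit.cov_log == 0):
        return WeibullFit(fit.shape, fit.scale)
    mean = np.log([fit.shape, fit.scale])
    draw = rng.multivariate_normal(mean, fit.cov_log, method="cholesky")
    return WeibullFit(float(np.exp(draw[0])), float(np.exp(draw[1])))


def _sample_arm(arm: ArmSpec, rng: np.random.Generator) -> ArmParameters:
    return ArmParameters(
        name=arm.name,
        p_adverse_event=_sample_value(arm.p_adverse_event, rng),
        p_discontinuation=_sample_value(arm.p_discontinuation, rng),
        p_mortality_on_treatment=_sample_value(arm.p_mortality_on_treatment, rng),
        drug_cost=_sample_value(arm.drug_cost, rng),
        fits={k: _sample_fit(arm.fits[k], rng) for k in sorted(arm.fits)},
    )


def _sample_shared(sh: SharedSpec, rng: np.random.Generator) -> SharedParameters:
    return SharedParameters(
        p_asct_eligible=_sample_value(sh.p_asct_eligible, rng),
        p_asct_success=_sample_value(sh.p_asct_success, rng),
        cost_pet=_sample_value(sh.cost_pet, rng),
        cost_adverse_event=_sample_value(sh.cost_adverse_event, rng),
        cost_asct=_sample_value(sh.cost_asct, rng),
        cost_salvage=_sample_value(sh.cost_salvage, rng),
        u_treatment=_sample_value(sh.utilities["treatment"], rng),
        u_complete_remission=_sample_value(sh.utilities["complete_remission"], rng),
        u_adverse_event=_sample_value(sh.utilities["adverse_event"], rng),
        u_progressive_disease=_sample_value(sh.utilities["progressive_disease"], rng),
        cycle_length_months=sh.cycle_length_months,
        horizon_years=sh.horizon_years,
        discount_rate=sh.discount_rate,
        half_cycle_correction=sh.half_cycle_correction,
        discount_timing=sh.discount_timing,
    )


def sample_parameters(
    params: ModelParameters, rng: np.random.Generator
) -> ParameterDraw:
    """One Monte Carlo draw of the full parameter set.

    The draw order is fixed (shared block, then each arm alphabetically by
    field) so identical generator states yield identical draws.
    """
    shared = _sample_shared(params.shared, rng)
    abvd = _sample_arm(params.abvd, rng)
    bren = _sample_arm(params.bren_avd, rng)
    return ParameterDraw(abvd=abvd, bren_avd=bren, shared=shared)


def run_psa(
    params: ModelParameters,
    n_iter: int,
    seed: int,
    strict: bool = True,
    max_resamples: int = 100,
) -> PSAResults:
    """Monte Carlo simulation: one full two-arm evaluation per draw.

    ``strict=True`` (default) aborts on any failed iteration; the
    permissive mode logs the offending draw, resamples, and reports the
    resample count in the result.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be at least 1")
    rng = np.random.default_rng(seed)
    rows = np.empty((n_iter, len(RESULT_COLUMNS)))
    n_resampled = 0
    for i in range(n_iter):
        attempts = 0
        while True:
            draw = sample_parameters(params, rng)
            try:
                res_a = evaluate_arm(draw.abvd, draw.shared)
                res_b = evaluate_arm(draw.bren_avd, draw.shared)
                break
            except Exception as exc:
                if strict:
                    raise PSAIterationError(
                        f"iteration {i} failed: {exc}; draw={draw}"
                    ) from exc
                attempts += 1
                n_resampled += 1
                logger.warning("iteration %d resampled after failure: %s", i, exc)
                if attempts > max_resamples:
                    raise PSAIterationError(
                        f"iteration {i} exceeded {max_resamples} resamples"
                    ) from exc
        rows[i] = (
            i,
            res_a.cost,
            res_a.qalys,
            res_b.cost,
            res_b.qalys,
            res_b.cost - res_a.cost,
            res_b.qalys - res_a.qalys,
        )
    df = pd.DataFrame(rows, columns=list(RESULT_COLUMNS))
    df["iter"] = df["iter"].astype(int)
    if n_resampled:
        logger.info("PSA completed with %d resampled draws", n_resampled)
    return PSAResults(
        data=df, seed=seed, n_iterations=n_iter, n_resampled=n_resampled
    )


def ceac(results: PSAResults, thresholds) -> CEACCurve:
    """Cost-effectiveness acceptability curve for the experimental arm.

    At each willingness-to-pay value ``lam``, the probability cost-effective
    is the fraction of iterations with strictly positive net monetary
    benefit ``lam * dQALY - dCost`` (ties count as not cost-effective).
    """
    lam = np.asarray(thresholds, dtype=float)
    if np.any(lam < 0):
        raise ValueError("willingness-to-pay thresholds must be non-negative")
    de = results.data["dqaly"].to_numpy()
    dc = results.data["dcost"].to_numpy()
    nmb = lam[:, None] * de[None, :] - dc[None, :]
    prob = (nmb > 0).mean(axis=1)
    return CEACCurve(wtp=lam, prob_ce=prob)


def ce_plane_summary(
    results: PSAResults, icer_thresholds=(100_000.0, 200_000.0)
) -> dict:
    """Quadrant fractions and threshold acceptance on the CE plane.

    Quadrants partition the plane with ties assigned to the axis-adjacent
    quadrant that favors the standard arm: northeast is dQALY > 0 and
    dCost > 0; southeast (dominant) is dQALY > 0 and dCost <= 0; northwest
    (dominated) is dQALY <= 0 and dCost > 0; southwest collects the rest.
    Threshold fractions use the net-monetary-benefit rule, matching
    :func:`ceac`.
    """
    de = results.data["dqaly"].to_numpy()
    dc = results.data["dcost"].to_numpy()
    n = de.size
    ne = float(np.sum((de > 0) & (dc > 0)) / n)
    se_ = float(np.sum((de > 0) & (dc <= 0)) / n)
    nw = float(np.sum((de <= 0) & (dc > 0)) / n)
    sw = float(np.sum((de <= 0) & (dc <= 0)) / n)
    out = {
        "northeast": ne,
        "southeast_dominant": se_,
        "northwest_dominated": nw,
        "southwest": sw,
    }
    for lam in icer_thresholds:
        frac = float(np.mean(lam * de - dc > 0))
        out[f"prob_ce_at_{int(lam)}"] = frac
    return out


def psa_summary(results: PSAResults) -> pd.DataFrame:
    """Per-arm and incremental means with 2.5th-97.5th percentile intervals."""
    rows = []
    for label, cost_col, qaly_col in (
        ("abvd", "cost_abvd", "qaly_abvd"),
        ("bren_avd", "cost_bren", "qaly_bren"),
        ("incremental", "dcost", "dqaly"),
    ):
        for quantity, col in (("cost", cost_col), ("qalys", qaly_col)):
            x = results.data[col].to_numpy()
            lo, hi = np.percentile(x, [2.5, 97.5])
            rows.append(
                {
                    "arm": label,
                    "quantity": quantity,
                    "mean": float(x.mean()),
                    "p2.5": float(lo),
                    "p97.5": float(hi),
                }
            )
    return pd.DataFrame(rows)


def plot_ce_plane(results: PSAResults, path, wtp_reference: float = 100_000.0):
    """Scatter of incremental cost vs incremental QALYs with a WTP line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    de = results.data["dqaly"].to_numpy()
    dc = results.data["dcost"].to_numpy()
    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(de, dc, s=4, alpha=0.3, linewidths=0)
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    xs = np.linspace(min(de.min(), 0), max(de.max(), 0), 50)
    ax.plot(xs, wtp_reference * xs, "r--", lw=1,
            label=f"WTP ${wtp_reference:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (2018 CAD)")
    ax.set_title("Cost-effectiveness plane")
    ax.legend(loc="best", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def plot_ceac(curve: CEACCurve, path):
    """Cost-effectiveness acceptability curve plot."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(curve.wtp, curve.prob_ce)
    ax.set_xlabel("Willingness-to-pay (CAD per QALY)")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
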