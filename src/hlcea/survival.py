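"""Time-to-event primitives behind the model's time-dependent transitions.

Every "time-dependent" transition probability in the Markov model is derived
from a parametric Weibull survival curve, fitted either to individual-level
right-censored data (the real-world registry pathway) or to survival
coordinates digitized from a published Kaplan-Meier figure (the trial
pathway, via pseudo individual-patient-data reconstruction).

Conventions used throughout the package:

* Weibull survival ``S(t) = exp(-(t / scale)**shape)`` with time in months;
  ``shape`` is dimensionless, ``scale`` is in months.
* Maximum likelihood is performed on ``(log shape, log scale)``; the
  parameter covariance is the inverse observed information (the Hessian of
  the negative log-likelihood at the optimum) on that log scale.
* A per-cycle transition probability over a cycle of length ``c`` starting
  at time ``t`` is ``p = 1 - S(t + c) / S(t)``, the conditional probability
  of the event during the cycle given event-free survival to its start.
* Parameter uncertainty on probabilities is expressed as a Beta
  distribution matched to (mean, SE); cost uncertainty as a Gamma
  distribution matched the same way.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy import optimize

logger = logging.getLogger(__name__)

__all__ = [
    "EventTable",
    "KMPublication",
    "WeibullFit",
    "TransitionProbEstimate",
    "WeibullFitError",
    "km_estimate",
    "km_survival_at",
    "reconstruct_ipd",
    "fit_weibull_mle",
    "weibull_survival",
    "transition_prob",
    "tp_standard_error",
    "beta_from_moments",
    "gamma_from_moments",
]


class WeibullFitError(RuntimeError):
    """Raised when the Weibull maximum-likelihood fit cannot be completed."""


@dataclass(frozen=True)
class EventTable:
    """Right-censored time-to-event data: one row per subject.

    ``time`` is the follow-up duration in months; ``event`` is 1 if the
    event of interest was observed at ``time`` and 0 if the subject was
    right-censored there.
    """

    time: np.ndarray
    event: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.time, dtype=float)
        e = np.asarray(self.event, dtype=int)
        if t.ndim != 1 or e.ndim != 1 or t.shape != e.shape:
            raise ValueError("time and event must be 1-d arrays of equal length")
        if t.size == 0:
            raise ValueError("EventTable must contain at least one subject")
        if np.any(t < 0):
            raise ValueError("all times must be non-negative")
        if not np.isin(e, (0, 1)).all():
            raise ValueError("event indicators must be 0 or 1")
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "event", e)

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "EventTable":
        df = pd.read_csv(path)
        missing = {"time", "event"} - set(df.columns)
        if missing:
            raise ValueError(f"event-table CSV missing columns: {sorted(missing)}")
        return cls(df["time"].to_numpy(), df["event"].to_numpy())


@dataclass(frozen=True)
class KMPublication:
    """A published Kaplan-Meier curve as a digitizer would capture it.

    ``coords`` are (time in months, survival probability) pairs read off the
    figure; ``risk_table`` is the number-at-risk table printed beneath it;
    ``total_n`` is the arm's sample size.
    """

    coords: np.ndarray
    risk_table: np.ndarray
    total_n: int

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=float)
        risk = np.asarray(self.risk_table, dtype=float)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
            raise ValueError("coords must be an (m, 2) array with m >= 2")
        if risk.ndim != 2 or risk.shape[1] != 2 or risk.shape[0] < 1:
            raise ValueError("risk_table must be an (r, 2) array")
        if self.total_n <= 0:
            raise ValueError("total_n must be positive")
        t, s = coords[:, 0], coords[:, 1]
        if np.any(np.diff(t) <= 0):
            raise ValueError("coordinate times must be strictly increasing")
        if np.any(np.diff(s) > 1e-12):
            raise ValueError("survival probabilities must be non-increasing")
        if s[0] > 1 or np.any(s < 0) or np.any(s > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(risk[:, 0]) <= 0):
            raise ValueError("risk-table times must be strictly increasing")
        if np.any(np.diff(risk[:, 1]) > 0):
            raise ValueError("numbers at risk must be non-increasing")
        if np.any(risk[:, 1] > self.total_n):
            raise ValueError("numbers at risk cannot exceed total_n")
        if np.any(risk[:, 1] < 0):
            raise ValueError("numbers at risk must be non-negative")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "risk_table", risk)

    def risk_at(self, t: float) -> float:
        """Number at risk at time ``t`` (last reported value at or before t)."""
        times = self.risk_table[:, 0]
        idx = np.searchsorted(times, t, side="right") - 1
        if idx < 0:
            return float(self.total_n)
        return float(self.risk_table[idx, 1])

    def to_csv(self, coords_path, risk_path) -> None:
        pd.DataFrame(self.coords, columns=["time", "survival"]).to_csv(
            coords_path, index=False
        )
        pd.DataFrame(self.risk_table, columns=["time", "n_at_risk"]).to_csv(
            risk_path, index=False
        )

    @classmethod
    def from_csv(cls, coords_path, risk_path, total_n: int) -> "KMPublication":
        coords = pd.read_csv(coords_path)[["time", "survival"]].to_numpy()
        risk = pd.read_csv(risk_path)[["time", "n_at_risk"]].to_numpy()
        return cls(coords, risk, total_n)


@dataclass(frozen=True)
class WeibullFit:
    """Fitted Weibull parameters with log-scale covariance.

    ``cov_log`` is the 2x2 covariance of ``(log shape, log scale)``; an
    all-zero matrix denotes a fixed (uncertainty-free) curve.
    """

    shape: float
    scale: float
    cov_log: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))

    def __post_init__(self):
        if not (self.shape > 0 and self.scale > 0):
            raise ValueError("shape and scale must be positive")
        cov = np.asarray(self.cov_log, dtype=float)
        if cov.shape != (2, 2):
            raise ValueError("cov_log must be 2x2")
        if not np.allclose(cov, cov.T, atol=1e-10):
            raise ValueError("cov_log must be symmetric")
        eigvals = np.linalg.eigvalsh(cov)
        if eigvals.min() < -1e-10:
            raise ValueError("cov_log must be positive semi-definite")
        object.__setattr__(self, "cov_log", cov)


@dataclass(frozen=True)
class TransitionProbEstimate:
    """A per-cycle transition probability with its sampling distribution."""

    mean: float
    se: float
    alpha: float
    beta: float

    def __post_init__(self):
        if not (0.0 <= self.mean <= 1.0):
            raise ValueError("mean must lie in [0, 1]")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")
        implied = self.alpha / (self.alpha + self.beta)
        if abs(implied - self.mean) > 1e-9:
            raise ValueError("Beta mean does not match the stated mean")

    @classmethod
    def from_fit(
        cls, fit: WeibullFit, t: float, cycle: float
    ) -> "TransitionProbEstimate":
        mean = float(transition_prob(fit, t, cycle))
        se = float(tp_standard_error(fit, t, cycle))
        a, b = beta_from_moments(mean, se)
        return cls(mean=mean, se=se, alpha=a, beta=b)


# ---------------------------------------------------------------------------
# Nonparametric estimation


def km_estimate(data: EventTable) -> np.ndarray:
    """Kaplan-Meier product-limit curve as an (m, 2) step-function array.

    The first row is always ``(0, 1)``; each subsequent row gives the
    survival value from that time onward (right-continuous steps).
    """
    kmf = KaplanMeierFitter()
    kmf.fit(data.time, event_observed=data.event)
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    if times[0] != 0:
        times = np.concatenate([[0.0], times])
        surv = np.concatenate([[1.0], surv])
    return np.column_stack([times, surv])


def km_survival_at(km: np.ndarray, t) -> np.ndarray:
    """Evaluate a km_estimate step function at times ``t``."""
    t = np.atleast_1d(np.asarray(t, dtype=float))
    idx = np.searchsorted(km[:, 0], t, side="right") - 1
    idx = np.clip(idx, 0, km.shape[0] - 1)
    return km[idx, 1]


def reconstruct_ipd(pub: KMPublication) -> EventTable:
    """Reconstruct pseudo individual-patient data from a published curve.

    Interval-wise scheme: within each interval between adjacent digitized
    coordinates, the event count is the one that best reproduces the
    survival drop given the current risk set; events are spread evenly over
    the interval and censorings (whatever reconciles the number-at-risk
    table) are placed at the interval's right endpoint. Subjects still at
    risk after the final coordinate are censored there. This deliberately
    simplified reconstruction (no within-interval step recovery) suffices
    for the round-trip guarantee: re-estimating the Kaplan-Meier curve from
    the output reproduces every input coordinate to within ``1/total_n``.
    """
    times_out: list[float] = []
    events_out: list[int] = []
    coords = pub.coords
    if abs(coords[0, 1] - 1.0) > 1e-9 and coords[0, 0] == 0:
        raise ValueError("survival at time 0 must be 1")

    n_cur = float(pub.total_n)
    s_achieved = 1.0
    for i in range(1, coords.shape[0]):
        t0, t1 = coords[i - 1, 0], coords[i, 0]
        s_target = coords[i, 1]
        if n_cur <= 0 or s_achieved <= 0:
            break
        d_exact = n_cur * (1.0 - s_target / s_achieved)
        d = int(round(d_exact))
        d = max(0, min(d, int(round(n_cur))))
        if d > 0:
            width = t1 - t0
            ev_times = t0 + width * (np.arange(1, d + 1) - 0.5) / d
            times_out.extend(ev_times.tolist())
            events_out.extend([1] * d)
            s_achieved *= (n_cur - d) / n_cur
        n_reported = pub.risk_at(t1)
        c = int(round(n_cur - d - n_reported))
        c = max(0, min(c, int(round(n_cur)) - d))
        if c > 0:
            times_out.extend([t1] * c)
            events_out.extend([0] * c)
        n_cur = n_cur - d - c

    if n_cur > 0:
        t_last = max(coords[-1, 0], pub.risk_table[-1, 0])
        remaining = int(round(n_cur))
        times_out.extend([t_last] * remaining)
        events_out.extend([0] * remaining)

    table = EventTable(np.asarray(times_out), np.asarray(events_out))
    if table.n != pub.total_n:
        raise ValueError(
            f"reconstruction produced {table.n} subjects, expected {pub.total_n}"
        )
    return table


# ---------------------------------------------------------------------------
# Parametric fitting


def _weibull_nll_and_grad(theta: np.ndarray, t: np.ndarray, e: np.ndarray):
    """Negative log-likelihood and gradient in (log shape, log scale).

    Censored-data Weibull log-likelihood:
    ``ll = sum_events [log k - log lam + (k-1) log(t/lam)] - sum_all (t/lam)^k``.
    """
    log_k, log_lam = theta
    k = np.exp(log_k)
    # guard: censored subjects at t == 0 contribute nothing; events need t > 0
    t_safe = np.maximum(t, 1e-300)
    u = np.log(t_safe) - log_lam
    z = np.exp(np.clip(k * u, -745.0, 700.0))
    ll = np.sum(e * (log_k - log_lam + (k - 1.0) * np.log(t_safe) - (k - 1.0) * log_lam)) - np.sum(z)
    # gradient of ll wrt (log k, log lam)
    g_logk = np.sum(e * (1.0 + k * u) - z * k * u)
    g_loglam = np.sum(k * (z - e))
    return -ll, -np.array([g_logk, g_loglam])


def _numeric_hessian(fun, theta: np.ndarray, h: float = 1e-5) -> np.ndarray:
    """Central-difference Hessian of a scalar function of two parameters."""
    n = theta.size
    hess = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            tpp = theta.copy(); tpp[i] += h; tpp[j] += h
            tpm = theta.copy(); tpm[i] += h; tpm[j] -= h
            tmp = theta.copy(); tmp[i] -= h; tmp[j] += h
            tmm = theta.copy(); tmm[i] -= h; tmm[j] -= h
            hess[i, j] = hess[j, i] = (
                fun(tpp) - fun(tpm) - fun(tmp) + fun(tmm)
            ) / (4.0 * h * h)
    return hess


def fit_weibull_mle(data: EventTable) -> WeibullFit:
    """Censoring-aware Weibull maximum-likelihood fit.

    Optimizes the right-censored log-likelihood over ``(log shape,
    log scale)`` with an analytic gradient; the covariance is the inverse of
    the observed information (Hessian of the negative log-likelihood) at the
    optimum, on the log-parameter scale.
    """
    if data.n_events < 2:
        raise WeibullFitError(
            f"need at least 2 observed events to fit (got {data.n_events})"
        )
    t = data.time
    e = data.event.astype(float)
    if np.any((t <= 0) & (e == 1)):
        raise WeibullFitError("observed events must have strictly positive times")

    # moment-style start: scale near the event-time mean, shape 1 (exponential)
    t_events = t[e == 1]
    theta0 = np.array([0.0, np.log(max(t_events.mean(), 1e-6))])

    res = optimize.minimize(
        _weibull_nll_and_grad,
        theta0,
        args=(t, e),
        jac=True,
        method="BFGS",
        options={"gtol": 1e-8, "maxiter": 500},
    )
    if not np.isfinite(res.fun):
        raise WeibullFitError("Weibull likelihood diverged")
    grad_norm = float(np.max(np.abs(res.jac)))
    # BFGS can report failure on flat likelihoods while the gradient is tiny;
    # accept only when the first-order condition genuinely holds.
    if not res.success and grad_norm > 1e-4 * max(1.0, data.n):
        raise WeibullFitError(f"Weibull MLE did not converge: {res.message}")

    theta = res.x
    nll = lambda th: _weibull_nll_and_grad(th, t, e)[0]
    hess = _numeric_hessian(nll, theta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate data
        raise WeibullFitError("observed information matrix is singular") from exc
    cov = 0.5 * (cov + cov.T)
    if np.linalg.eigvalsh(cov).min() < 0:
        raise WeibullFitError("observed information is not positive definite")
    return WeibullFit(
        shape=float(np.exp(theta[0])), scale=float(np.exp(theta[1])), cov_log=cov
    )


# ---------------------------------------------------------------------------
# Curve evaluation and per-cycle probabilities


def _cum_hazard(fit: WeibullFit, t: np.ndarray) -> np.ndarray:
    return (t / fit.scale) ** fit.shape


def weibull_survival(fit: WeibullFit, t) -> np.ndarray | float:
    """S(t) = exp(-(t/scale)^shape); ``t`` in months, scalar or array."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    out = np.exp(-_cum_hazard(fit, t_arr))
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def transition_prob(fit: WeibullFit, t, cycle: float) -> np.ndarray | float:
    """Conditional per-cycle event probability ``1 - S(t+cycle)/S(t)``.

    Computed on the cumulative-hazard scale for numerical stability. When
    S(t) underflows to zero the conditional probability is returned as 1
    with a logged warning (the cohort mass there is already negligible).
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    if cycle <= 0:
        raise ValueError("cycle length must be positive")
    a = _cum_hazard(fit, t_arr)
    b = _cum_hazard(fit, t_arr + cycle)
    p = 1.0 - np.exp(np.minimum(a - b, 0.0))
    underflow = a > 745.0  # exp(-a) == 0 in double precision
    if np.any(underflow):
        logger.warning(
            "S(t) underflowed to 0 at t=%s for Weibull(shape=%.4g, scale=%.4g); "
            "returning transition probability 1",
            np.atleast_1d(t_arr)[np.atleast_1d(underflow)],
            fit.shape,
            fit.scale,
        )
        p = np.where(underflow, 1.0, p)
    return float(p) if np.isscalar(t) or t_arr.ndim == 0 else p


def _tp_gradient_log(fit: WeibullFit, t: float, cycle: float) -> np.ndarray:
    """Gradient of the per-cycle probability wrt (log shape, log scale)."""
    k, lam = fit.shape, fit.scale
    t = float(t)
    a = (t / lam) ** k if t > 0 else 0.0
    b = ((t + cycle) / lam) ** k
    # d a / d log k = a * k * log(t/lam); zero at t == 0 by continuity
    da_dlogk = a * k * np.log(t / lam) if t > 0 else 0.0
    db_dlogk = b * k * np.log((t + cycle) / lam)
    da_dloglam = -k * a
    db_dloglam = -k * b
    surv_ratio = np.exp(a - b)
    dp_dlogk = -surv_ratio * (da_dlogk - db_dlogk)
    dp_dloglam = -surv_ratio * (da_dloglam - db_dloglam)
    return np.array([dp_dlogk, dp_dloglam])


def tp_standard_error(fit: WeibullFit, t: float, cycle: float) -> float:
    """Delta-method standard error of the per-cycle transition probability.

    Propagates the log-parameter covariance through the gradient of
    ``p = 1 - S(t+cycle)/S(t)`` with respect to (log shape, log scale).
    """
    cov = fit.cov_log
    if np.all(cov == 0):
        return 0.0
    if np.linalg.matrix_rank(cov, tol=1e-300) < 2 and not np.all(np.diag(cov) >= 0):
        raise ValueError("covariance matrix is singular")
    g = _tp_gradient_log(fit, t, cycle)
    var = float(g @ cov @ g)
    return float(np.sqrt(max(var, 0.0)))


# ---------------------------------------------------------------------------
# Moment matching for the probabilistic analysis


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the requested mean and standard error.

    ``alpha = mean * nu``, ``beta = (1-mean) * nu`` with
    ``nu = mean (1-mean) / se^2 - 1``. An infeasible SE (``se^2 >=
    mean(1-mean)``) is reduced to just inside the feasible boundary with a
    logged warning.
    """
    if not (0.0 < mean < 1.0):
        raise ValueError("mean must lie strictly in (0, 1)")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        raise ValueError("se = 0 has no finite Beta representation; treat as fixed")
    var = se * se
    bound = mean * (1.0 - mean)
    if var >= bound:
        logger.warning(
            "beta_from_moments: se^2=%.4g infeasible for mean=%.4g; "
            "reduced to the boundary",
            var,
            mean,
        )
        var = bound * (1.0 - 1e-9)
    nu = bound / var - 1.0
    return mean * nu, (1.0 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma(shape, rate) with the requested mean and standard error.

    ``shape = mean^2/se^2``, ``rate = mean/se^2``. A zero SE is flagged as
    degenerate (point mass at the mean) by returning infinite parameters
    with a warning; callers sampling distributions treat it as fixed.
    """
    if mean <= 0:
        raise ValueError("mean must be positive")
    if se < 0:
        raise ValueError("se must be non-negative")
    if se == 0:
        warnings.warn(
            "gamma_from_moments: se = 0 is a degenerate point mass at the mean",
            RuntimeWarning,
            stacklevel=2,
        )
        return np.inf, np.inf
    return mean * mean / (se * se), mean / (se * se)
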