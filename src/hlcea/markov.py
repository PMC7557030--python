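"""Six-state cohort Markov engine.

States: (i) on frontline treatment, (ii) complete remission, (iii) first
progression/relapse (with possible autologous stem-cell transplant, ASCT),
(iv) remission after ASCT, (v) second progression (salvage therapy),
(vi) death (absorbing). Cycles are 6 months; the horizon is 15 years
(30 cycles); costs in 2018 CAD and effects in QALYs, both discounted at
1.5% per year.

Time-dependent transition probabilities are indexed by residence time — the
number of cycles since entering the state — because the underlying survival
curves are measured from state entry (remission date, relapse date). The
engine therefore runs on a tunnel-expanded state space internally (one
sub-state per residence cycle for remission, post-ASCT remission and second
progression) and reports the collapsed six-state occupancy. First
progression/relapse resolves within a single cycle (transplant triage), so
it needs no tunnel.

Combination rule for competing risks within a state: death is applied
first, then the remaining mass is split between progression and staying:
``P(death) = q``, ``P(progress) = (1-q) p``, ``P(stay) = (1-q)(1-p)``.

Accrual conventions (all configurable points documented in the methods
note):

* The full regimen drug cost and the expected adverse-event cost are
  charged at model start (cycle 1, undiscounted); the PET response-
  assessment scan is charged to the whole starting cohort at the end of
  cycle 1 (discounted at 0.5 years).
* The transplant cost is charged on entry into first progression/relapse
  for the transplant-eligible fraction; the salvage-regimen cost on entry
  into second progression.
* QALYs for a cycle use the state occupancy at the cycle's start, weighted
  by utility and half a year; discounting is evaluated at cycle start
  (midpoint available via ``discount_timing="midpoint"``). The treatment-
  state utility blends the adverse-event disutility in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import IntEnum

import numpy as np

from .parameters import ArmParameters, SharedParameters
from .survival import WeibullFit, transition_prob

__all__ = [
    "HealthState",
    "CohortTrace",
    "ArmResult",
    "ICERResult",
    "MarkovStructureError",
    "build_transition_row",
    "run_cohort",
    "discount_factor",
    "accumulate_outcomes",
    "compute_icer",
]


class HealthState(IntEnum):
    TREATMENT = 0
    COMPLETE_REMISSION = 1
    PROGRESSION_RELAPSE = 2
    REMISSION_POST_ASCT = 3
    SECOND_PROGRESSION = 4
    DEATH = 5


N_STATES = len(HealthState)


class MarkovStructureError(ValueError):
    """Raised when a transition row would leave the simplex."""


@dataclass(frozen=True)
class CohortTrace:
    """Per-cycle cohort bookkeeping for one arm.

    ``occupancy[m]`` is the state distribution at time ``m`` cycles from
    model start (row 0: everyone on treatment); ``entries[m]`` the mass
    newly arriving in each state at that time. Cost and QALY streams are
    indexed the same way: element ``m`` holds the amounts accrued at (costs)
    or over the cycle starting at (QALYs) time ``m``.
    """

    occupancy: np.ndarray
    entries: np.ndarray
    cycle_cost: np.ndarray
    cycle_qaly: np.ndarray
    cycle_cost_discounted: np.ndarray
    cycle_qaly_discounted: np.ndarray

    def __post_init__(self):
        occ = self.occupancy
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError("occupancy must be (cycles+1, 6)")
        row_sums = occ.sum(axis=1)
        if np.any(np.abs(row_sums - 1.0) > 1e-9):
            raise ValueError("occupancy rows must sum to 1 within 1e-9")
        if np.any(occ < -1e-12) or np.any(occ > 1 + 1e-12):
            raise ValueError("occupancy entries must lie in [0, 1]")
        death = occ[:, HealthState.DEATH]
        if np.any(np.diff(death) < -1e-12):
            raise ValueError("death occupancy must be non-decreasing")

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def to_frame(self):
        import pandas as pd

        cols = {s.name.lower(): self.occupancy[:, s] for s in HealthState}
        cols["cost"] = self.cycle_cost
        cols["qaly"] = self.cycle_qaly
        cols["cost_discounted"] = self.cycle_cost_discounted
        cols["qaly_discounted"] = self.cycle_qaly_discounted
        df = pd.DataFrame(cols)
        df.index.name = "cycle"
        return df


@dataclass(frozen=True)
class ArmResult:
    """Total discounted cost (CAD) and QALYs for one arm."""

    cost: float
    qalys: float

    def __post_init__(self):
        if self.cost < 0:
            raise ValueError("total cost must be non-negative")


@dataclass(frozen=True)
class ICERResult:
    """Incremental comparison of two arms (comparator minus reference)."""

    delta_cost: float
    delta_qalys: float
    icer: float | None
    label: str  # "icer" | "dominant" | "dominated" | "southwest" | "undefined"


def discount_factor(rate: float, t_years: float, timing_offset_years: float = 0.0):
    """Discrete-time discount factor ``(1 + rate)**-(t + offset)``."""
    if rate < 0:
        raise ValueError("discount rate must be non-negative")
    t = np.asarray(t_years, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be non-negative")
    out = (1.0 + rate) ** -(t + timing_offset_years)
    return float(out) if out.ndim == 0 else out


def _cycle_probs(fit: WeibullFit, residence_cycles, cycle_months: float):
    """Per-cycle event probabilities at the given residence cycles."""
    t = np.asarray(residence_cycles, dtype=float) * cycle_months
    return np.asarray(transition_prob(fit, t, cycle_months))


def _treatment_failure_prob(arm: ArmParameters, cycle_months: float) -> float:
    """P(no complete remission | survived treatment).

    Early progression over the first cycle (from the progression-free
    survival curve at residence 0) combined independently with treatment
    discontinuation; both route to first progression/relapse.
    """
    p_prog0 = float(_cycle_probs(arm.fits["progression_cr"], 0.0, cycle_months))
    return 1.0 - (1.0 - p_prog0) * (1.0 - arm.p_discontinuation)


def build_transition_row(
    state: HealthState,
    arm: ArmParameters,
    shared: SharedParameters,
    residence_cycle: int = 0,
) -> np.ndarray:
    """One row of the (collapsed) transition matrix for a state at a given
    residence time, following the model's edge structure."""
    if residence_cycle < 0:
        raise ValueError("residence_cycle must be non-negative")
    c = shared.cycle_length_months
    row = np.zeros(N_STATES)
    S = HealthState
    if state == S.DEATH:
        row[S.DEATH] = 1.0
        return row
    if state == S.TREATMENT:
        q = arm.p_mortality_on_treatment
        fail = _treatment_failure_prob(arm, c)
        row[S.DEATH] = q
        row[S.PROGRESSION_RELAPSE] = (1.0 - q) * fail
        row[S.COMPLETE_REMISSION] = (1.0 - q) * (1.0 - fail)
    elif state == S.COMPLETE_REMISSION:
        q = float(_cycle_probs(arm.fits["mortality_cr"], residence_cycle, c))
        p = float(_cycle_probs(arm.fits["progression_cr"], residence_cycle, c))
        row[S.DEATH] = q
        row[S.PROGRESSION_RELAPSE] = (1.0 - q) * p
        row[S.COMPLETE_REMISSION] = (1.0 - q) * (1.0 - p)
    elif state == S.PROGRESSION_RELAPSE:
        # resolves in one cycle: transplant triage for survivors
        q = float(
            _cycle_probs(arm.fits["mortality_progression"], residence_cycle, c)
        )
        pe, ps = shared.p_asct_eligible, shared.p_asct_success
        row[S.DEATH] = q
        row[S.REMISSION_POST_ASCT] = (1.0 - q) * pe * ps
        row[S.SECOND_PROGRESSION] = (1.0 - q) * (1.0 - pe * ps)
    elif state == S.REMISSION_POST_ASCT:
        # remission-like mortality; progression risk from the post-ASCT curve
        q = float(_cycle_probs(arm.fits["mortality_cr"], residence_cycle, c))
        p = float(
            _cycle_probs(arm.fits["progression_post_asct"], residence_cycle, c)
        )
        row[S.DEATH] = q
        row[S.SECOND_PROGRESSION] = (1.0 - q) * p
        row[S.REMISSION_POST_ASCT] = (1.0 - q) * (1.0 - p)
    elif state == S.SECOND_PROGRESSION:
        q = float(
            _cycle_probs(
                arm.fits["mortality_second_progression"], residence_cycle, c
            )
        )
        row[S.DEATH] = q
        row[S.SECOND_PROGRESSION] = 1.0 - q
    else:  # pragma: no cover
        raise ValueError(f"unknown state {state}")

    if np.any(row < -1e-12):
        bad = HealthState(int(np.argmin(row)))
        raise MarkovStructureError(
            f"negative transition mass to {bad.name} from {state.name} "
            f"at residence cycle {residence_cycle}"
        )
    total = row.sum()
    if abs(total - 1.0) > 1e-12:
        raise MarkovStructureError(
            f"transition row from {state.name} at residence cycle "
            f"{residence_cycle} sums to {total!r}"
        )
    return np.clip(row, 0.0, 1.0)


def run_cohort(arm: ArmParameters, shared: SharedParameters) -> CohortTrace:
    """Propagate the full cohort over the horizon and accrue outcomes.

    Residence-dependent probabilities are applied via tunnel vectors; the
    returned trace is collapsed to the six observable states.
    """
    H = shared.n_cycles
    c = shared.cycle_length_months
    S = HealthState
    res = np.arange(H, dtype=float)

    q_cr = _cycle_probs(arm.fits["mortality_cr"], res, c)
    p_cr = _cycle_probs(arm.fits["progression_cr"], res, c)
    q_pr0 = float(_cycle_probs(arm.fits["mortality_progression"], 0.0, c))
    q_rpa = q_cr  # remission-like mortality applies post-ASCT as well
    p_rpa = _cycle_probs(arm.fits["progression_post_asct"], res, c)
    q_sp = _cycle_probs(arm.fits["mortality_second_progression"], res, c)

    q_tx = arm.p_mortality_on_treatment
    fail = _treatment_failure_prob(arm, c)
    pe, ps = shared.p_asct_eligible, shared.p_asct_success

    stay_cr = (1.0 - q_cr) * (1.0 - p_cr)
    to_pr_from_cr = (1.0 - q_cr) * p_cr
    stay_rpa = (1.0 - q_rpa) * (1.0 - p_rpa)
    to_sp_from_rpa = (1.0 - q_rpa) * p_rpa
    stay_sp = 1.0 - q_sp

    tr = 1.0
    cr = np.zeros(H)
    pr = 0.0
    rpa = np.zeros(H)
    sp = np.zeros(H)
    dead = 0.0

    occupancy = np.zeros((H + 1, N_STATES))
    entries = np.zeros((H + 1, N_STATES))
    occupancy[0, S.TREATMENT] = 1.0
    entries[0, S.TREATMENT] = 1.0

    for m in range(1, H + 1):
        d_dead = (
            tr * q_tx
            + cr @ q_cr
            + pr * q_pr0
            + rpa @ q_rpa
            + sp @ q_sp
        )
        new_pr = tr * (1.0 - q_tx) * fail + cr @ to_pr_from_cr
        new_cr = np.zeros(H)
        new_cr[0] = tr * (1.0 - q_tx) * (1.0 - fail)
        new_cr[1:] = cr[:-1] * stay_cr[:-1]
        pr_surv = pr * (1.0 - q_pr0)
        new_rpa = np.zeros(H)
        new_rpa[0] = pr_surv * pe * ps
        new_rpa[1:] = rpa[:-1] * stay_rpa[:-1]
        new_sp = np.zeros(H)
        new_sp[0] = pr_surv * (1.0 - pe * ps) + rpa @ to_sp_from_rpa
        new_sp[1:] = sp[:-1] * stay_sp[:-1]

        dead += d_dead
        tr = 0.0
        cr, pr, rpa, sp = new_cr, new_pr, new_rpa, new_sp

        occupancy[m] = (tr, cr.sum(), pr, rpa.sum(), sp.sum(), dead)
        entries[m] = (0.0, new_cr[0], new_pr, new_rpa[0], new_sp[0], d_dead)

    # guard against accumulated round-off before trace validation
    occupancy = occupancy / occupancy.sum(axis=1, keepdims=True)

    cost, qaly, cost_d, qaly_d = _accrue_streams(occupancy, entries, arm, shared)
    return CohortTrace(
        occupancy=occupancy,
        entries=entries,
        cycle_cost=cost,
        cycle_qaly=qaly,
        cycle_cost_discounted=cost_d,
        cycle_qaly_discounted=qaly_d,
    )


def _utility_vector(shared: SharedParameters, arm: ArmParameters) -> np.ndarray:
    """Per-state utilities; treatment blends the adverse-event disutility."""
    u = np.zeros(N_STATES)
    p_ae = arm.p_adverse_event
    u[HealthState.TREATMENT] = (
        p_ae * shared.u_adverse_event + (1.0 - p_ae) * shared.u_treatment
    )
    u[HealthState.COMPLETE_REMISSION] = shared.u_complete_remission
    u[HealthState.REMISSION_POST_ASCT] = shared.u_complete_remission
    u[HealthState.PROGRESSION_RELAPSE] = shared.u_progressive_disease
    u[HealthState.SECOND_PROGRESSION] = shared.u_progressive_disease
    u[HealthState.DEATH] = 0.0
    return u


def _accrue_streams(
    occupancy: np.ndarray,
    entries: np.ndarray,
    arm: ArmParameters,
    shared: SharedParameters,
):
    """Per-row cost and QALY streams (undiscounted and discounted)."""
    H = occupancy.shape[0] - 1
    S = HealthState
    cy = shared.cycle_years
    t_rows = np.arange(H + 1) * cy
    offset = 0.5 * cy if shared.discount_timing == "midpoint" else 0.0
    df = discount_factor(shared.discount_rate, t_rows, timing_offset_years=offset)

    cost = np.zeros(H + 1)
    # up-front regimen and expected adverse-event management cost
    start_mass = occupancy[0, S.TREATMENT]
    cost[0] += start_mass * (
        arm.drug_cost + arm.p_adverse_event * shared.cost_adverse_event
    )
    if H >= 1:
        # response-assessment PET at end of cycle 1, whole starting cohort
        cost[1] += start_mass * shared.cost_pet
    # one-off costs on state entry
    cost += entries[:, S.PROGRESSION_RELAPSE] * shared.p_asct_eligible * shared.cost_asct
    cost += entries[:, S.SECOND_PROGRESSION] * shared.cost_salvage

    u = _utility_vector(shared, arm)
    qaly = np.zeros(H + 1)
    if shared.half_cycle_correction:
        mid = 0.5 * (occupancy[:-1] + occupancy[1:])
        qaly[:-1] = (mid @ u) * cy
    else:
        qaly[:-1] = (occupancy[:-1] @ u) * cy

    return cost, qaly, cost * df, qaly * df


def accumulate_outcomes(
    trace: CohortTrace, arm: ArmParameters, shared: SharedParameters
) -> ArmResult:
    """Total discounted cost and QALYs, recomputed from the trace."""
    cost, qaly, cost_d, qaly_d = _accrue_streams(
        trace.occupancy, trace.entries, arm, shared
    )
    return ArmResult(cost=float(cost_d.sum()), qalys=float(qaly_d.sum()))


def evaluate_arm(arm: ArmParameters, shared: SharedParameters) -> ArmResult:
    """Convenience: run the cohort and total its discounted streams."""
    trace = run_cohort(arm, shared)
    return ArmResult(
        cost=float(trace.cycle_cost_discounted.sum()),
        qalys=float(trace.cycle_qaly_discounted.sum()),
    )


def compute_icer(ref: ArmResult, comp: ArmResult) -> ICERResult:
    """Incremental cost-effectiveness of ``comp`` versus ``ref``.

    Returns a ratio when both increments are positive; dominance labels
    otherwise. Southwest-quadrant results (cheaper and less effective)
    report the ratio with a ``"southwest"`` flag since a plain ICER is not
    interpretable there. A zero QALY increment is flagged ``"undefined"``.
    """
    dc = comp.cost - ref.cost
    de = comp.qalys - ref.qalys
    if de == 0.0:
        return ICERResult(dc, de, None, "undefined")
    if de > 0 and dc < 0:
        return ICERResult(dc, de, None, "dominant")
    if de < 0 and dc > 0:
        return ICERResult(dc, de, None, "dominated")
    label = "southwest" if (de < 0 and dc <= 0) else "icer"
    return ICERResult(dc, de, dc / de, label)
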