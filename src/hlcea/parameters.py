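"""Model parameter containers.

Two layers are kept deliberately distinct:

* ``ModelParameters`` (built from the config file or the shipped fixture)
  carries every input with its uncertainty: scalar parameters as
  ``UncertainValue`` (mean, SE, sampling family) and time-dependent
  transitions as :class:`~hlcea.survival.WeibullFit` objects whose log-scale
  covariance encodes the fit uncertainty.
* ``ArmParameters`` / ``SharedParameters`` are plain point-valued structures
  consumed by the Markov engine — either the means (base case) or one Monte
  Carlo draw (probabilistic analysis).

Default standard errors, applied when the config gives only a point value:
20% of the mean for costs and utilities, and the binomial SE at the trial's
per-arm sample size (n = 664) for probabilities. Both are overridable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .survival import WeibullFit

TRIAL_ARM_N = 664  # per-arm size used for default binomial SEs on probabilities

#: The five residence-time-dependent transitions, per arm.
TIME_DEP_TRANSITIONS = (
    "progression_cr",            # progression/relapse while in complete remission
    "mortality_cr",              # mortality while in complete remission
    "mortality_progression",     # mortality during first progression/relapse
    "progression_post_asct",     # progression/relapse after transplant remission
    "mortality_second_progression",  # mortality after post-transplant progression
)

UTILITY_STATES = (
    "treatment",
    "complete_remission",
    "adverse_event",
    "progressive_disease",
)


@dataclass(frozen=True)
class UncertainValue:
    """A scalar input with its second-order (parameter) uncertainty.

    ``dist`` selects the sampling family for the probabilistic analysis:
    ``"beta"`` for probabilities and utilities, ``"gamma"`` for costs,
    ``"fixed"`` for quantities sampled as their mean. ``se = 0`` always
    degenerates to the mean regardless of family.
    """

    mean: float
    se: float
    dist: str = "beta"

    def __post_init__(self):
        if self.dist not in ("beta", "gamma", "fixed"):
            raise ValueError(f"unknown distribution family: {self.dist!r}")
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if self.dist == "beta" and not (0.0 <= self.mean <= 1.0):
            raise ValueError(f"beta-distributed mean {self.mean} outside [0, 1]")
        if self.dist == "gamma" and self.mean < 0:
            raise ValueError("gamma-distributed mean must be non-negative")


def default_probability_se(mean: float, n: int = TRIAL_ARM_N) -> float:
    """Binomial standard error sqrt(p(1-p)/n) at the trial per-arm size."""
    return float(np.sqrt(mean * (1.0 - mean) / n))


def default_relative_se(mean: float, fraction: float = 0.2) -> float:
    """Default SE for costs/utilities: a fixed fraction of the mean."""
    return fraction * mean


@dataclass(frozen=True)
class ArmParameters:
    """Point-valued per-arm inputs consumed by the Markov engine."""

    name: str
    p_adverse_event: float
    p_discontinuation: float
    p_mortality_on_treatment: float
    drug_cost: float
    fits: dict[str, WeibullFit]

    def __post_init__(self):
        for p in (
            self.p_adverse_event,
            self.p_discontinuation,
            self.p_mortality_on_treatment,
        ):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"arm {self.name}: probability {p} outside [0, 1]")
        if self.drug_cost < 0:
            raise ValueError("drug cost must be non-negative")
        missing = set(TIME_DEP_TRANSITIONS) - set(self.fits)
        if missing:
            raise ValueError(f"arm {self.name}: missing fits {sorted(missing)}")


@dataclass(frozen=True)
class SharedParameters:
    """Point-valued arm-independent inputs (Table-style shared block)."""

    p_asct_eligible: float
    p_asct_success: float
    cost_pet: float
    cost_adverse_event: float
    cost_asct: float
    cost_salvage: float
    u_treatment: float
    u_complete_remission: float
    u_adverse_event: float
    u_progressive_disease: float
    cycle_length_months: float = 6.0
    horizon_years: float = 15.0
    discount_rate: float = 0.015
    half_cycle_correction: bool = False
    discount_timing: str = "start"  # "start" | "midpoint"

    def __post_init__(self):
        if self.discount_timing not in ("start", "midpoint"):
            raise ValueError("discount_timing must be 'start' or 'midpoint'")
        for p in (self.p_asct_eligible, self.p_asct_success):
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"probability {p} outside [0, 1]")
        for u in (
            self.u_treatment,
            self.u_complete_remission,
            self.u_adverse_event,
            self.u_progressive_disease,
        ):
            if not (0.0 <= u <= 1.0):
                raise ValueError(f"utility {u} outside [0, 1]")
        for c in (
            self.cost_pet,
            self.cost_adverse_event,
            self.cost_asct,
            self.cost_salvage,
        ):
            if c < 0:
                raise ValueError("costs must be non-negative")
        if self.cycle_length_months <= 0 or self.horizon_years <= 0:
            raise ValueError("cycle length and horizon must be positive")
        n_cycles = self.horizon_years * 12.0 / self.cycle_length_months
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValueError("horizon must be an integer number of cycles")
        if self.discount_rate < 0:
            raise ValueError("discount rate must be non-negative")

    @property
    def n_cycles(self) -> int:
        return int(round(self.horizon_years * 12.0 / self.cycle_length_months))

    @property
    def cycle_years(self) -> float:
        return self.cycle_length_months / 12.0


@dataclass(frozen=True)
class ParameterDraw:
    """One point-valued realization of the full model (base case or draw)."""

    abvd: ArmParameters
    bren_avd: ArmParameters
    shared: SharedParameters


@dataclass(frozen=True)
class ArmSpec:
    """Per-arm inputs with uncertainty."""

    name: str
    p_adverse_event: UncertainValue
    p_discontinuation: UncertainValue
    p_mortality_on_treatment: UncertainValue
    drug_cost: UncertainValue
    fits: dict[str, WeibullFit]

    def __post_init__(self):
        missing = set(TIME_DEP_TRANSITIONS) - set(self.fits)
        if missing:
            raise ValueError(f"arm {self.name}: missing fits {sorted(missing)}")


@dataclass(frozen=True)
class SharedSpec:
    """Arm-independent inputs with uncertainty plus model settings."""

    p_asct_eligible: UncertainValue
    p_asct_success: UncertainValue
    cost_pet: UncertainValue
    cost_adverse_event: UncertainValue
    cost_asct: UncertainValue
    cost_salvage: UncertainValue
    utilities: dict[str, UncertainValue]
    cycle_length_months: float = 6.0
    horizon_years: float = 15.0
    discount_rate: float = 0.015
    half_cycle_correction: bool = False
    discount_timing: str = "start"

    def __post_init__(self):
        missing = set(UTILITY_STATES) - set(self.utilities)
        if missing:
            raise ValueError(f"missing utilities {sorted(missing)}")


@dataclass(frozen=True)
class ModelParameters:
    """The complete two-arm parameter set with uncertainty."""

    abvd: ArmSpec
    bren_avd: ArmSpec
    shared: SharedSpec

    def point(self) -> ParameterDraw:
        """The deterministic base case: every parameter at its mean."""
        return ParameterDraw(
            abvd=_point_arm(self.abvd),
            bren_avd=_point_arm(self.bren_avd),
            shared=_point_shared(self.shared),
        )

    def with_zero_uncertainty(self) -> "ModelParameters":
        """A copy with every SE and covariance set to zero (degenerate PSA)."""

        def _fix_arm(arm: ArmSpec) -> ArmSpec:
            return ArmSpec(
                name=arm.name,
                p_adverse_event=replace(arm.p_adverse_event, se=0.0),
                p_discontinuation=replace(arm.p_discontinuation, se=0.0),
                p_mortality_on_treatment=replace(
                    arm.p_mortality_on_treatment, se=0.0
                ),
                drug_cost=replace(arm.drug_cost, se=0.0),
                fits={
                    k: WeibullFit(f.shape, f.scale, np.zeros((2, 2)))
                    for k, f in arm.fits.items()
                },
            )

        sh = self.shared
        shared = SharedSpec(
            p_asct_eligible=replace(sh.p_asct_eligible, se=0.0),
            p_asct_success=replace(sh.p_asct_success, se=0.0),
            cost_pet=replace(sh.cost_pet, se=0.0),
            cost_adverse_event=replace(sh.cost_adverse_event, se=0.0),
            cost_asct=replace(sh.cost_asct, se=0.0),
            cost_salvage=replace(sh.cost_salvage, se=0.0),
            utilities={k: replace(v, se=0.0) for k, v in sh.utilities.items()},
            cycle_length_months=sh.cycle_length_months,
            horizon_years=sh.horizon_years,
            discount_rate=sh.discount_rate,
            half_cycle_correction=sh.half_cycle_correction,
            discount_timing=sh.discount_timing,
        )
        return ModelParameters(
            abvd=_fix_arm(self.abvd), bren_avd=_fix_arm(self.bren_avd), shared=shared
        )

    def copy(self) -> "ModelParameters":
        return copy.deepcopy(self)


def _point_arm(arm: ArmSpec) -> ArmParameters:
    return ArmParameters(
        name=arm.name,
        p_adverse_event=arm.p_adverse_event.mean,
        p_discontinuation=arm.p_discontinuation.mean,
        p_mortality_on_treatment=arm.p_mortality_on_treatment.mean,
        drug_cost=arm.drug_cost.mean,
        fits={k: WeibullFit(f.shape, f.scale) for k, f in arm.fits.items()},
    )


def _point_shared(sh: SharedSpec) -> SharedParameters:
    return SharedParameters(
        p_asct_eligible=sh.p_asct_eligible.mean,
        p_asct_success=sh.p_asct_success.mean,
        cost_pet=sh.cost_pet.mean,
        cost_adverse_event=sh.cost_adverse_event.mean,
        cost_asct=sh.cost_asct.mean,
        cost_salvage=sh.cost_salvage.mean,
        u_treatment=sh.utilities["treatment"].mean,
        u_complete_remission=sh.utilities["complete_remission"].mean,
        u_adverse_event=sh.utilities["adverse_event"].mean,
        u_progressive_disease=sh.utilities["progressive_disease"].mean,
        cycle_length_months=sh.cycle_length_months,
        horizon_years=sh.horizon_years,
        discount_rate=sh.discount_rate,
        half_cycle_correction=sh.half_cycle_correction,
        discount_timing=sh.discount_timing,
    )
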