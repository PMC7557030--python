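"""YAML configuration: schema, strict validation, lossless round-trip.

The config file is the on-disk form of :class:`~hlcea.parameters.ModelParameters`
plus optional run settings. Every scalar parameter is a mapping with a
``mean`` and an optional ``se``; when ``se`` is omitted the package default
is applied (binomial SE at the trial per-arm size for probabilities, 20% of
the mean for costs and utilities). Unknown keys anywhere in the file are
rejected with a listing, and out-of-range values are rejected naming the
bound, so a typo cannot silently fall back to a default.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from .parameters import (
    TIME_DEP_TRANSITIONS,
    UTILITY_STATES,
    ArmSpec,
    ModelParameters,
    SharedSpec,
    UncertainValue,
    default_probability_se,
    default_relative_se,
)
from .survival import WeibullFit

__all__ = [
    "ConfigError",
    "RunConfig",
    "load_config",
    "load_default_config",
    "default_config_path",
    "params_to_dict",
    "save_config",
    "config_hash",
]

SCHEMA_VERSION = 1

ARM_NAMES = ("abvd", "bren_avd")

_SHARED_PROBS = {"asct_eligible": "p_asct_eligible", "asct_success": "p_asct_success"}
_SHARED_COSTS = {
    "pet_scan": "cost_pet",
    "adverse_event": "cost_adverse_event",
    "asct": "cost_asct",
    "salvage": "cost_salvage",
}
_ARM_PROBS = {
    "serious_adverse_event": "p_adverse_event",
    "treatment_discontinuation": "p_discontinuation",
    "mortality_on_treatment": "p_mortality_on_treatment",
}
_MODEL_KEYS = {
    "cycle_length_months",
    "horizon_years",
    "discount_rate",
    "half_cycle_correction",
    "discount_timing",
}
_RUN_KEYS = {"iterations", "seed", "wtp_grid", "price_fractions", "strict_psa"}
_WEIBULL_KEYS = {"shape", "scale", "var_log_shape", "var_log_scale", "cov"}


class ConfigError(ValueError):
    """Invalid, incomplete, or unrecognized configuration content."""


@dataclass(frozen=True)
class RunConfig:
    """Run settings: iteration counts, seed, grids, mode flags."""

    iterations: int = 10_000
    seed: int = 0
    wtp_grid: tuple[float, float, float] = (0.0, 500_000.0, 10_000.0)
    price_fractions: tuple[float, ...] = (0.0, 0.25, 0.5, 0.75)
    strict_psa: bool = True

    def __post_init__(self):
        if self.iterations < 1:
            raise ConfigError("iterations must be at least 1")
        start, stop, step = self.wtp_grid
        if start < 0 or stop <= start or step <= 0:
            raise ConfigError("wtp_grid must satisfy 0 <= start < stop, step > 0")
        for f in self.price_fractions:
            if not (0.0 <= f <= 1.0):
                raise ConfigError(f"price fraction {f} outside [0, 1]")

    def wtp_values(self) -> np.ndarray:
        start, stop, step = self.wtp_grid
        return np.arange(start, stop + 0.5 * step, step)


def _require_mapping(node, where: str) -> dict:
    if not isinstance(node, dict):
        raise ConfigError(f"{where}: expected a mapping, got {type(node).__name__}")
    return node


def _reject_unknown(node: dict, allowed, where: str) -> None:
    unknown = sorted(set(node) - set(allowed))
    if unknown:
        raise ConfigError(f"{where}: unknown keys {unknown}")


def _get(node: dict, key: str, where: str):
    if key not in node:
        raise ConfigError(f"{where}: missing required parameter '{key}'")
    return node[key]


def _parse_value(node, where: str, dist: str, default_se) -> UncertainValue:
    node = _require_mapping(node, where)
    _reject_unknown(node, {"mean", "se"}, where)
    mean = float(_get(node, "mean", where))
    if dist == "beta" and not (0.0 <= mean <= 1.0):
        raise ConfigError(f"{where}: mean {mean} violates the bound [0, 1]")
    if dist == "gamma" and mean < 0:
        raise ConfigError(f"{where}: mean {mean} violates the bound mean >= 0")
    se = float(node["se"]) if "se" in node else default_se(mean)
    if se < 0:
        raise ConfigError(f"{where}: se {se} violates the bound se >= 0")
    return UncertainValue(mean=mean, se=se, dist=dist)


def _parse_weibull(node, where: str) -> WeibullFit:
    node = _require_mapping(node, where)
    _reject_unknown(node, _WEIBULL_KEYS, where)
    shape = float(_get(node, "shape", where))
    scale = float(_get(node, "scale", where))
    if shape <= 0 or scale <= 0:
        raise ConfigError(f"{where}: shape and scale must be > 0")
    v_k = float(node.get("var_log_shape", 0.0))
    v_l = float(node.get("var_log_scale", 0.0))
    c = float(node.get("cov", 0.0))
    cov = np.array([[v_k, c], [c, v_l]])
    try:
        return WeibullFit(shape=shape, scale=scale, cov_log=cov)
    except ValueError as exc:
        raise ConfigError(f"{where}: {exc}") from exc


def _parse_arm(name: str, node, where: str) -> ArmSpec:
    node = _require_mapping(node, where)
    _reject_unknown(node, {"probabilities", "costs", "weibull"}, where)
    probs = _require_mapping(_get(node, "probabilities", where), f"{where}.probabilities")
    _reject_unknown(probs, _ARM_PROBS, f"{where}.probabilities")
    costs = _require_mapping(_get(node, "costs", where), f"{where}.costs")
    _reject_unknown(costs, {"regimen"}, f"{where}.costs")
    weib = _require_mapping(_get(node, "weibull", where), f"{where}.weibull")
    _reject_unknown(weib, TIME_DEP_TRANSITIONS, f"{where}.weibull")

    kwargs = {
        attr: _parse_value(
            _get(probs, key, f"{where}.probabilities"),
            f"{where}.probabilities.{key}",
            "beta",
            default_probability_se,
        )
        for key, attr in _ARM_PROBS.items()
    }
    drug_cost = _parse_value(
        _get(costs, "regimen", f"{where}.costs"),
        f"{where}.costs.regimen",
        "gamma",
        default_relative_se,
    )
    fits = {
        t: _parse_weibull(_get(weib, t, f"{where}.weibull"), f"{where}.weibull.{t}")
        for t in TIME_DEP_TRANSITIONS
    }
    return ArmSpec(name=name, drug_cost=drug_cost, fits=fits, **kwargs)


def _parse_shared(node, model_node, where: str = "shared") -> SharedSpec:
    node = _require_mapping(node, where)
    _reject_unknown(node, {"probabilities", "costs", "utilities"}, where)
    probs = _require_mapping(_get(node, "probabilities", where), f"{where}.probabilities")
    _reject_unknown(probs, _SHARED_PROBS, f"{where}.probabilities")
    costs = _require_mapping(_get(node, "costs", where), f"{where}.costs")
    _reject_unknown(costs, _SHARED_COSTS, f"{where}.costs")
    utils = _require_mapping(_get(node, "utilities", where), f"{where}.utilities")
    _reject_unknown(utils, UTILITY_STATES, f"{where}.utilities")

    kwargs = {}
    for key, attr in _SHARED_PROBS.items():
        kwargs[attr] = _parse_value(
            _get(probs, key, f"{where}.probabilities"),
            f"{where}.probabilities.{key}",
            "beta",
            default_probability_se,
        )
    for key, attr in _SHARED_COSTS.items():
        kwargs[attr] = _parse_value(
            _get(costs, key, f"{where}.costs"),
            f"{where}.costs.{key}",
            "gamma",
            default_relative_se,
        )
    utilities = {
        key: _parse_value(
            _get(utils, key, f"{where}.utilities"),
            f"{where}.utilities.{key}",
            "beta",
            default_relative_se,
        )
        for key in UTILITY_STATES
    }
    for key, u in utilities.items():
        if not (0.0 <= u.mean <= 1.0):  # redundant with beta bound; explicit message
            raise ConfigError(
                f"{where}.utilities.{key}: {u.mean} violates the bound [0, 1]"
            )

    model = _require_mapping(model_node, "model")
    _reject_unknown(model, _MODEL_KEYS, "model")
    try:
        return SharedSpec(
            utilities=utilities,
            cycle_length_months=float(model.get("cycle_length_months", 6.0)),
            horizon_years=float(model.get("horizon_years", 15.0)),
            discount_rate=float(model.get("discount_rate", 0.015)),
            half_cycle_correction=bool(model.get("half_cycle_correction", False)),
            discount_timing=str(model.get("discount_timing", "start")),
            **kwargs,
        )
    except ValueError as exc:
        raise ConfigError(f"model: {exc}") from exc


def _parse_run(node) -> RunConfig:
    if node is None:
        return RunConfig()
    node = _require_mapping(node, "run")
    _reject_unknown(node, _RUN_KEYS, "run")
    kwargs = {}
    if "iterations" in node:
        kwargs["iterations"] = int(node["iterations"])
    if "seed" in node:
        kwargs["seed"] = int(node["seed"])
    if "wtp_grid" in node:
        g = _require_mapping(node["wtp_grid"], "run.wtp_grid")
        _reject_unknown(g, {"start", "stop", "step"}, "run.wtp_grid")
        kwargs["wtp_grid"] = (
            float(g.get("start", 0.0)),
            float(g.get("stop", 500_000.0)),
            float(g.get("step", 10_000.0)),
        )
    if "price_fractions" in node:
        kwargs["price_fractions"] = tuple(float(f) for f in node["price_fractions"])
    if "strict_psa" in node:
        kwargs["strict_psa"] = bool(node["strict_psa"])
    return RunConfig(**kwargs)


def load_config(path) -> tuple[ModelParameters, RunConfig]:
    """Parse and validate a YAML parameter file."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text)
    raw = _require_mapping(raw, "config")
    _reject_unknown(raw, {"schema_version", "model", "shared", "arms", "run"}, "config")
    version = raw.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ConfigError(
            f"config: schema_version must be {SCHEMA_VERSION} (got {version!r})"
        )
    arms_node = _require_mapping(_get(raw, "arms", "config"), "arms")
    _reject_unknown(arms_node, ARM_NAMES, "arms")
    try:
        shared = _parse_shared(_get(raw, "shared", "config"), raw.get("model", {}))
        abvd = _parse_arm("abvd", _get(arms_node, "abvd", "arms"), "arms.abvd")
        bren = _parse_arm(
            "bren_avd", _get(arms_node, "bren_avd", "arms"), "arms.bren_avd"
        )
    except ConfigError:
        raise
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc
    params = ModelParameters(abvd=abvd, bren_avd=bren, shared=shared)
    run = _parse_run(raw.get("run"))
    return params, run


def default_config_path() -> Path:
    """Path to the packaged default parameter file."""
    return Path(resources.files("hlcea") / "data" / "default_params.yaml")


def load_default_config() -> tuple[ModelParameters, RunConfig]:
    return load_config(default_config_path())


# ---------------------------------------------------------------------------
# Serialization


def _value_dict(v: UncertainValue) -> dict:
    return {"mean": float(v.mean), "se": float(v.se)}


def _weibull_dict(f: WeibullFit) -> dict:
    return {
        "shape": float(f.shape),
        "scale": float(f.scale),
        "var_log_shape": float(f.cov_log[0, 0]),
        "var_log_scale": float(f.cov_log[1, 1]),
        "cov": float(f.cov_log[0, 1]),
    }


def _arm_dict(arm: ArmSpec) -> dict:
    return {
        "probabilities": {
            key: _value_dict(getattr(arm, attr)) for key, attr in _ARM_PROBS.items()
        },
        "costs": {"regimen": _value_dict(arm.drug_cost)},
        "weibull": {t: _weibull_dict(arm.fits[t]) for t in TIME_DEP_TRANSITIONS},
    }


def params_to_dict(params: ModelParameters, run: RunConfig | None = None) -> dict:
    """Serializable form of the full parameter set (resolved SEs included)."""
    sh = params.shared
    out = {
        "schema_version": SCHEMA_VERSION,
        "model": {
            "cycle_length_months": float(sh.cycle_length_months),
            "horizon_years": float(sh.horizon_years),
            "discount_rate": float(sh.discount_rate),
            "half_cycle_correction": bool(sh.half_cycle_correction),
            "discount_timing": sh.discount_timing,
        },
        "shared": {
            "probabilities": {
                key: _value_dict(getattr(sh, attr))
                for key, attr in _SHARED_PROBS.items()
            },
            "costs": {
                key: _value_dict(getattr(sh, attr))
                for key, attr in _SHARED_COSTS.items()
            },
            "utilities": {
                key: _value_dict(sh.utilities[key]) for key in UTILITY_STATES
            },
        },
        "arms": {
            "abvd": _arm_dict(params.abvd),
            "bren_avd": _arm_dict(params.bren_avd),
        },
    }
    if run is not None:
        start, stop, step = run.wtp_grid
        out["run"] = {
            "iterations": run.iterations,
            "seed": run.seed,
            "wtp_grid": {"start": start, "stop": stop, "step": step},
            "price_fractions": list(run.price_fractions),
            "strict_psa": run.strict_psa,
        }
    return out


def save_config(params: ModelParameters, path, run: RunConfig | None = None) -> None:
    Path(path).write_text(
        yaml.safe_dump(params_to_dict(params, run), sort_keys=False)
    )


def config_hash(path) -> str:
    """SHA-256 of the config file's bytes, recorded in every output."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()
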