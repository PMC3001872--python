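"""Configuration files: strict YAML/JSON model configs and run options.

A config document holds up to four maps/scalars::

    rates:    {alpha_1: 1e-5, ..., alpha_r: 1.0}   # 1/year
    initial:  {Ns: 1e4, Nd: 1e2, Aq: 1e5, Ap: 1e3, M1: 1e3, M2: 1e5, Abeta: 1e3}
    horizon:  20.0                                  # years
    run:      {sampling: 0.1, band: 0.05, fraction: 0.025, factor: 10.0}

Missing entries fall back to the published defaults; unknown keys are an
error (strict mode), so typos cannot silently leave a parameter at its
default.  YAML is a superset of JSON, so both file types parse through the
same loader.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import yaml

from .model import (
    DEFAULT_HORIZON_YEARS,
    DEFAULT_INITIAL,
    RATE_IDS,
    SPECIES,
    ModelSpec,
    RateTable,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "write_config"]

logger = logging.getLogger("adnet")


class ConfigError(ValueError):
    """Malformed configuration: parse failure, unknown key, or bad value."""


@dataclass(frozen=True)
class RunConfig:
    """Run options resolved from the config file (all overridable on the
    command line)."""

    sampling: float = 0.1      # years between samples
    band: float = 0.05         # stabilization band (fraction of final value)
    fraction: float = 0.025    # rate-perturbation fraction
    factor: float = 10.0       # initial-value perturbation factor

    def __post_init__(self):
        if not self.sampling > 0:
            raise ConfigError(f"run.sampling must be > 0 (got {self.sampling})")
        if not 0 < self.band < 1:
            raise ConfigError(f"run.band must be in (0, 1) (got {self.band})")
        if not 0 < self.fraction < 0.5:
            raise ConfigError(
                f"run.fraction must be in (0, 0.5) (got {self.fraction})"
            )
        if not self.factor > 1:
            raise ConfigError(f"run.factor must be > 1 (got {self.factor})")


_RUN_KEYS = ("sampling", "band", "fraction", "factor")


def _check_keys(section: str, given, allowed) -> None:
    unknown = sorted(set(given) - set(allowed))
    if unknown:
        raise ConfigError(f"unknown key(s) in {section}: {', '.join(unknown)}")


def _as_map(section: str, value) -> dict:
    if value is None:
        return {}
    if not isinstance(value, dict):
        raise ConfigError(f"{section} must be a mapping")
    return value


def load_config(path) -> tuple[ModelSpec, RunConfig]:
    """Parse a YAML or JSON config into a model and run options.

    Unspecified entries fall back to the published defaults.  The fully
    resolved parameter set is logged at INFO for provenance.
    """
    with open(path) as fh:
        try:
            doc = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse {path}: {exc}") from exc
    doc = _as_map("config", doc)
    _check_keys("config", doc, ("rates", "initial", "horizon", "run"))

    rates_map = _as_map("rates", doc.get("rates"))
    _check_keys("rates", rates_map, RATE_IDS)
    for key, value in rates_map.items():
        if not isinstance(value, (int, float)) or not value > 0:
            raise ConfigError(f"rates.{key} must be a positive number (got {value!r})")

    initial_map = _as_map("initial", doc.get("initial"))
    _check_keys("initial", initial_map, SPECIES)
    for key, value in initial_map.items():
        if not isinstance(value, (int, float)) or value < 0:
            raise ConfigError(
                f"initial.{key} must be a non-negative number (got {value!r})"
            )

    horizon = doc.get("horizon", DEFAULT_HORIZON_YEARS)
    if not isinstance(horizon, (int, float)) or not horizon > 0:
        raise ConfigError(f"horizon must be a positive number (got {horizon!r})")

    run_map = _as_map("run", doc.get("run"))
    _check_keys("run", run_map, _RUN_KEYS)

    initial = np.array(
        [float(initial_map.get(s, DEFAULT_INITIAL[s])) for s in SPECIES]
    )
    model = ModelSpec(
        rates=RateTable({k: float(v) for k, v in rates_map.items()}),
        initial=initial,
        horizon=float(horizon),
    )
    run = RunConfig(**{k: float(v) for k, v in run_map.items()})

    logger.info("resolved rates: %s", model.rates.as_dict())
    logger.info(
        "resolved initial: %s",
        dict(zip(SPECIES, model.initial.tolist())),
    )
    logger.info("resolved horizon: %g years; run options: %s", model.horizon, run)
    return model, run


def write_config(model: ModelSpec, path, run: RunConfig | None = None) -> None:
    """Serialize a model (and optionally run options) as YAML; the output
    round-trips through :func:`load_config` exactly."""
    doc = {
        "rates": model.rates.as_dict(),
        "initial": {s: float(v) for s, v in zip(SPECIES, model.initial)},
        "horizon": float(model.horizon),
    }
    if run is not None:
        doc["run"] = {k: getattr(run, k) for k in _RUN_KEYS}
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)
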