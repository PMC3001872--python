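"""Local finite-difference sensitivity analysis.

Two perturbation schemes are used, mirroring how the model's outputs are
probed:

* ``central-fractional`` — each pathway rate is perturbed by a small
  fraction ``f`` (default +/-2.5%) and the coefficient is the central
  difference quotient of the horizon value,
  ``S = [X(T; a(1+f)) - X(T; a(1-f))] / (2 f a)``.
* ``tenfold`` — each initial value is multiplied by a large factor
  (default 10) and the coefficient is the forward difference quotient
  ``S = [X(T; c X0) - X(T; X0)] / (c X0 - X0)``; the reciprocal (0.1x)
  variant is computed alongside and carried on the same record.

Because the three cell-state pairs are conserved, the coefficients obey an
exact structure: within a pair the rate coefficients are exact negatives,
and for an initial-value perturbation the pair coefficients sum to 1 when
the perturbed species belongs to the pair and to 0 otherwise.

A perturbed run that engages a non-negativity clamp makes the difference
quotient non-smooth; such records are flagged ``clamped`` rather than
suppressed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .model import RATE_IDS, SPECIES, ModelSpec, _fluxes
from .simulate import DEFAULT_SAMPLING_YEARS, Trajectory, simulate

__all__ = [
    "SensitivityRecord",
    "sens_rate",
    "sens_ic",
    "sens_table",
    "classify",
    "write_sensitivity_csv",
    "write_class_csv",
    "SCHEME_CENTRAL",
    "SCHEME_TENFOLD",
    "CLASS_STRONG",
    "CLASS_MODERATE",
    "CLASS_WEAK",
]

SCHEME_CENTRAL = "central-fractional"
SCHEME_TENFOLD = "tenfold"

CLASS_STRONG = "Strong"
CLASS_MODERATE = "Moderate"
CLASS_WEAK = "Weak"

#: |S| thresholds on the strongest of the four monitored outputs.
DEFAULT_STRONG_THRESHOLD = 1e4
DEFAULT_MODERATE_THRESHOLD = 1e3

#: Outputs tabulated for the rate scheme.
RATE_OUTPUTS: tuple[str, ...] = ("Ns", "Nd", "M1", "M2")


@dataclass(frozen=True)
class SensitivityRecord:
    """One sensitivity coefficient S = dX(T)/d(parameter).

    For the tenfold scheme ``value`` is the 10x (headline) quotient and
    ``value_down`` the 0.1x variant; for the central scheme ``value_down``
    is ``None``.  ``clamped`` marks records whose underlying runs engaged a
    non-negativity clamp or the neuron-flux floor.
    """

    output: str
    parameter: str
    scheme: str
    horizon: float
    value: float
    value_down: float | None = None
    clamped: bool = False


def _clamp_engaged(traj: Trajectory) -> bool:
    """True if any sampled state sits on a clamp (floor or zero boundary)."""
    model = traj.model
    for state in traj.states:
        raw = _fluxes(state, model.rates, floor_neuron_flux=False,
                      clamp_nonnegative=False)
        eff = _fluxes(state, model.rates,
                      floor_neuron_flux=model.floor_neuron_flux,
                      clamp_nonnegative=model.clamp_nonnegative)
        if any(r != e for r, e in zip(raw, eff)):
            return True
    return False


def _final(model: ModelSpec, cache: dict | None = None,
           key=None) -> tuple[np.ndarray, bool]:
    if cache is not None and key in cache:
        return cache[key]
    traj = simulate(model, sampling=DEFAULT_SAMPLING_YEARS)
    result = (traj.final_state, _clamp_engaged(traj))
    if cache is not None:
        cache[key] = result
    return result


def sens_rate(
    model: ModelSpec,
    rate_id: str,
    output: str,
    fraction: float = 0.025,
    _cache: dict | None = None,
) -> SensitivityRecord:
    """Central fractional difference of one output with respect to one rate."""
    if rate_id not in model.rates:
        raise KeyError(f"unknown rate id: {rate_id}")
    if output not in SPECIES:
        raise KeyError(f"unknown species: {output}")
    if not 0.0 < fraction < 0.5:
        raise ValueError(f"fraction must be in (0, 0.5) (got {fraction})")
    alpha = model.rates[rate_id]
    j = SPECIES.index(output)
    up, cl_up = _final(model.with_scaled_rate(rate_id, 1.0 + fraction),
                       _cache, (rate_id, "+", fraction))
    dn, cl_dn = _final(model.with_scaled_rate(rate_id, 1.0 - fraction),
                       _cache, (rate_id, "-", fraction))
    value = (up[j] - dn[j]) / (2.0 * fraction * alpha)
    return SensitivityRecord(
        output=output,
        parameter=rate_id,
        scheme=SCHEME_CENTRAL,
        horizon=model.horizon,
        value=float(value),
        clamped=cl_up or cl_dn,
    )


def sens_ic(
    model: ModelSpec,
    initial_name: str,
    output: str,
    factor: float = 10.0,
    _cache: dict | None = None,
) -> SensitivityRecord:
    """Forward difference of one output with respect to one initial value,
    for a ``factor``-fold increase; the ``1/factor`` variant is carried on
    ``value_down``."""
    if initial_name not in SPECIES:
        raise KeyError(f"unknown initial-value name: {initial_name}")
    if output not in SPECIES:
        raise KeyError(f"unknown species: {output}")
    if not factor > 1.0:
        raise ValueError(f"factor must be > 1 (got {factor})")
    x0 = model.initial_value(initial_name)
    if x0 == 0.0:
        raise ValueError(f"initial value {initial_name} is zero; "
                         "a multiplicative perturbation has no effect")
    j = SPECIES.index(output)
    base, cl_b = _final(model, _cache, ("base",))
    up, cl_up = _final(model.with_scaled_initial(initial_name, factor),
                       _cache, (initial_name, "x", factor))
    dn, cl_dn = _final(model.with_scaled_initial(initial_name, 1.0 / factor),
                       _cache, (initial_name, "/", factor))
    s_up = (up[j] - base[j]) / (factor * x0 - x0)
    s_dn = (dn[j] - base[j]) / (x0 / factor - x0)
    return SensitivityRecord(
        output=output,
        parameter=initial_name,
        scheme=SCHEME_TENFOLD,
        horizon=model.horizon,
        value=float(s_up),
        value_down=float(s_dn),
        clamped=cl_b or cl_up or cl_dn,
    )


def sens_table(
    model: ModelSpec,
    fraction: float = 0.025,
    factor: float = 10.0,
) -> list[SensitivityRecord]:
    """Full sensitivity table: every rate crossed with the four monitored
    outputs under the central scheme (68 records), then every initial value
    crossed with every output under the tenfold scheme (49 records).

    Perturbed simulations are shared across outputs, so the table costs
    2x17 + 15 runs rather than one pair per record.
    """
    cache: dict = {}
    records: list[SensitivityRecord] = []
    for rate_id in RATE_IDS:
        for output in RATE_OUTPUTS:
            records.append(
                sens_rate(model, rate_id, output, fraction, _cache=cache)
            )
    for initial_name in SPECIES:
        for output in SPECIES:
            records.append(
                sens_ic(model, initial_name, output, factor, _cache=cache)
            )
    return records


def classify(
    records: list[SensitivityRecord],
    strong: float = DEFAULT_STRONG_THRESHOLD,
    moderate: float = DEFAULT_MODERATE_THRESHOLD,
) -> str:
    """Classify one rate's record set (its four monitored outputs) by the
    maximum |S|: Strong / Moderate / Weak."""
    if not records:
        raise ValueError("empty record set")
    params = {r.parameter for r in records}
    if len(params) != 1:
        raise ValueError(f"records mix parameters: {sorted(params)}")
    outputs = {r.output for r in records}
    missing = set(RATE_OUTPUTS) - outputs
    if missing:
        raise ValueError(f"incomplete record set; missing outputs {sorted(missing)}")
    peak = max(abs(r.value) for r in records if r.output in RATE_OUTPUTS)
    if peak >= strong:
        return CLASS_STRONG
    if peak >= moderate:
        return CLASS_MODERATE
    return CLASS_WEAK


def classify_table(
    records: list[SensitivityRecord],
    strong: float = DEFAULT_STRONG_THRESHOLD,
    moderate: float = DEFAULT_MODERATE_THRESHOLD,
) -> dict[str, str]:
    """Classification for every rate present in a full sensitivity table."""
    out: dict[str, str] = {}
    for rate_id in RATE_IDS:
        subset = [r for r in records
                  if r.parameter == rate_id and r.scheme == SCHEME_CENTRAL]
        if subset:
            out[rate_id] = classify(subset, strong, moderate)
    return out


def write_sensitivity_csv(records: list[SensitivityRecord], path) -> None:
    """Write ``parameter,output,scheme,horizon_years,S,clamped`` rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["parameter", "output", "scheme", "horizon_years", "S", "clamped"])
        for r in records:
            w.writerow([r.parameter, r.output, r.scheme,
                        f"{r.horizon:g}", f"{r.value:.17g}",
                        str(r.clamped).lower()])


def write_class_csv(classes: dict[str, str], path) -> None:
    """Write ``rate,class`` rows."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["rate", "class"])
        for rate_id, label in classes.items():
            w.writerow([rate_id, label])
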