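"""Time integration of the model and trajectory containers.

Integration uses an adaptive explicit Runge-Kutta method (``scipy``'s RK45)
with dense output: the system is integrated once over the horizon and the
dense interpolant is evaluated on the requested sample grid, which avoids
restart artifacts at sample boundaries.  The non-negativity projection makes
the right-hand side non-smooth at the zero boundaries, so the maximum step
is capped to keep the solver from striding across a switching surface.

A fixed-step classical 4th-order Runge-Kutta integrator is provided as an
independent numerical cross-check (:func:`simulate_rk4`).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .model import SPECIES, ModelSpec, _rhs_unchecked, species_index, validate

__all__ = [
    "Trajectory",
    "simulate",
    "simulate_rk4",
    "stabilization_time",
    "IntegrationError",
    "DEFAULT_SAMPLING_YEARS",
    "DEFAULT_RTOL",
    "DEFAULT_ATOL",
]

DEFAULT_SAMPLING_YEARS = 0.1
DEFAULT_RTOL = 1e-8
DEFAULT_ATOL = 1e-6
# Cap on the adaptive step so clamp-boundary crossings are resolved.
_MAX_STEP_YEARS = 0.5


_PAIRS = ((0, 1), (2, 3), (4, 5))  # (Ns,Nd), (Aq,Ap), (M1,M2)


def _project_nonnegative(states: np.ndarray) -> None:
    """Clip integrator-tolerance undershoots to zero, in place.

    For a conversion pair the partner absorbs the clipped amount so the
    pair total is untouched; amyloid has no partner and is clipped plainly.
    """
    for i, j in _PAIRS:
        for a, b in ((i, j), (j, i)):
            neg = states[..., a] < 0.0
            if np.any(neg):
                states[neg, b] += states[neg, a]
                states[neg, a] = 0.0
    np.clip(states[..., 6], 0.0, None, out=states[..., 6])


class IntegrationError(RuntimeError):
    """Integrator failure; carries the last successfully reached time."""

    def __init__(self, message: str, last_time: float):
        super().__init__(f"{message} (last good time: {last_time:g} years)")
        self.last_time = last_time


@dataclass(frozen=True)
class Trajectory:
    """Sampled solution of the model over its horizon.

    ``times`` (years) is strictly increasing and starts at 0; ``states`` has
    one row per time point, columns in the canonical species order.
    """

    times: np.ndarray
    states: np.ndarray
    model: ModelSpec

    def species(self, name: str) -> np.ndarray:
        """Time series of one species."""
        return self.states[:, species_index(name)]

    @property
    def final_state(self) -> np.ndarray:
        return self.states[-1]

    def final_value(self, name: str) -> float:
        return float(self.states[-1, species_index(name)])

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.states, columns=list(SPECIES))
        df.insert(0, "time", self.times)
        return df

    def to_csv(self, path) -> None:
        """Write ``time,Ns,Nd,Aq,Ap,M1,M2,Abeta`` rows at full precision."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.17g")

    def to_json(self, path) -> None:
        payload = {"time": self.times.tolist()}
        payload.update({s: self.species(s).tolist() for s in SPECIES})
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @staticmethod
    def read_csv(path, model: ModelSpec) -> "Trajectory":
        df = pd.read_csv(path)
        return Trajectory(
            times=df["time"].to_numpy(),
            states=df[list(SPECIES)].to_numpy(),
            model=model,
        )


def _sample_grid(horizon: float, sampling: float) -> np.ndarray:
    n = int(round(horizon / sampling))
    grid = np.linspace(0.0, n * sampling, n + 1)
    if grid[-1] < horizon - 1e-12:
        grid = np.append(grid, horizon)
    else:
        grid[-1] = horizon
    return grid


def simulate(
    model: ModelSpec,
    sampling: float = DEFAULT_SAMPLING_YEARS,
    rtol: float = DEFAULT_RTOL,
    atol: float = DEFAULT_ATOL,
) -> Trajectory:
    """Integrate the model over ``[0, horizon]`` and sample every ``sampling``
    years.

    Sampled states are projected onto the non-negative orthant (the
    projection only ever removes integrator-tolerance-sized undershoots).

    Raises
    ------
    ValueError
        If the model fails validation or ``sampling`` is not positive.
    IntegrationError
        If the adaptive solver cannot reach the horizon.
    """
    problems = validate(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    if not sampling > 0.0:
        raise ValueError(f"sampling interval must be > 0 (got {sampling})")

    def f(t, y):
        return _rhs_unchecked(
            y, model.rates, model.floor_neuron_flux, model.clamp_nonnegative
        )

    sol = solve_ivp(
        f,
        (0.0, model.horizon),
        model.initial,
        method="RK45",
        rtol=rtol,
        atol=atol,
        max_step=_MAX_STEP_YEARS,
        dense_output=True,
    )
    if sol.status != 0:
        raise IntegrationError(sol.message, float(sol.t[-1]))

    times = _sample_grid(model.horizon, sampling)
    states = sol.sol(times).T
    states[0] = model.initial  # exact, not interpolated
    if model.clamp_nonnegative:
        _project_nonnegative(states)
    return Trajectory(times=times, states=states, model=model)


def simulate_rk4(
    model: ModelSpec,
    dt: float = 1e-3,
    sampling: float = DEFAULT_SAMPLING_YEARS,
) -> Trajectory:
    """Fixed-step classical RK4 integration; numerical cross-check for
    :func:`simulate`.

    Steps with constant ``dt`` (years) and records every sample point of the
    regular grid.  ``sampling`` must be an integer multiple of ``dt``.
    """
    problems = validate(model)
    if problems:
        raise ValueError("invalid model: " + "; ".join(problems))
    per_sample = int(round(sampling / dt))
    if abs(per_sample * dt - sampling) > 1e-12 * sampling or per_sample < 1:
        raise ValueError("sampling must be an integer multiple of dt")

    def f(y):
        return _rhs_unchecked(
            y, model.rates, model.floor_neuron_flux, model.clamp_nonnegative
        )

    times = _sample_grid(model.horizon, sampling)
    states = np.empty((len(times), len(SPECIES)))
    y = model.initial.copy()
    states[0] = y
    for i in range(1, len(times)):
        h = (times[i] - times[i - 1]) / per_sample
        for _ in range(per_sample):
            k1 = f(y)
            k2 = f(y + 0.5 * h * k1)
            k3 = f(y + 0.5 * h * k2)
            k4 = f(y + h * k3)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if model.clamp_nonnegative:
                _project_nonnegative(y[None, :])
        states[i] = y
    return Trajectory(times=times, states=states, model=model)


def stabilization_time(traj: Trajectory, species: str, band: float = 0.05) -> float:
    """Earliest sampled time after which a species stays within ``band`` of
    its final sampled value.

    Returns the horizon if the species never settles into the band.  The
    band is relative to the final sampled value; a final value of exactly
    zero degenerates to requiring exact zeros.
    """
    if not 0.0 < band < 1.0:
        raise ValueError(f"band must be in (0, 1) (got {band})")
    x = traj.species(species)
    final = x[-1]
    tol = band * abs(final)
    inside = np.abs(x - final) <= tol
    # last index that is outside the band determines the settling point
    outside = np.flatnonzero(~inside)
    if len(outside) == 0:
        return float(traj.times[0])
    k = outside[-1] + 1
    if k >= len(x):
        return float(traj.times[-1])
    return float(traj.times[k])


def conservation_drift(traj: Trajectory) -> dict[str, float]:
    """Maximum relative drift of each conserved pair total over the run."""
    drifts = {}
    for label, (a, b) in {
        "Ns+Nd": ("Ns", "Nd"),
        "Aq+Ap": ("Aq", "Ap"),
        "M1+M2": ("M1", "M2"),
    }.items():
        tot = traj.species(a) + traj.species(b)
        drifts[label] = float(np.max(np.abs(tot - tot[0])) / tot[0])
    return drifts
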