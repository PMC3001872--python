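"""Species, pathway network, and rate equations of the AD neuroinflammation model.

The model tracks seven species in an arbitrary, well-mixed local tissue
volume: surviving and dead neurons (``Ns``, ``Nd``), quiescent and
proliferating astroglia (``Aq``, ``Ap``), pro-inflammatory (reactive) and
anti-inflammatory (resting) microglia (``M1``, ``M2``), and the number of
amyloid-beta molecules (``Abeta``).  Sixteen directed pathways plus a
first-order amyloid removal path couple the species; each pathway either
promotes or inhibits its target and carries a rate ``alpha`` in 1/year.

Cell-state changes are conversions within fixed pools, so the totals
``Ns + Nd``, ``Aq + Ap`` and ``M1 + M2`` are conserved along every
trajectory.  Neuronal death is irreversible; the astroglia and microglia
conversions are reversible.

Each pathway contributes a term that is first order in its *source*
species.  Writing ``a_i`` for the pathway rates, the net conversion fluxes
are::

    phi_N = a2*Ap + a3*M1 - a1*Aq                       (Ns -> Nd, floored at 0)
    phi_A = a5*M1 - a4*M2                               (Aq -> Ap)
    phi_M = (a8 + a13)*Abeta + a9*M1 + a10*Nd
            - (a6 + a11)*Ns - (a7 + a12)*Aq - a14*M2    (M2 -> M1)

and the amyloid balance is production by surviving neurons against
clearance by resting microglia and first-order removal::

    dAbeta/dt = a15*Ns - a16*M2 - ar*Abeta

The right-hand side is assembled in :func:`rhs`, kept behind a single
replaceable function so an alternative reading of the equations can be
swapped in without touching the simulator or analysis layers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SPECIES",
    "PROMOTE",
    "INHIBIT",
    "Pathway",
    "RateTable",
    "ModelSpec",
    "build_default_model",
    "rhs",
    "validate",
    "InvalidStateError",
]

#: Canonical species order used for every state vector and output column.
SPECIES: tuple[str, ...] = ("Ns", "Nd", "Aq", "Ap", "M1", "M2", "Abeta")

_IDX = {name: i for i, name in enumerate(SPECIES)}

PROMOTE = "promote"
INHIBIT = "inhibit"


class InvalidStateError(ValueError):
    """Raised when a state vector violates non-negativity."""


@dataclass(frozen=True)
class Pathway:
    """One directed influence in the network.

    ``mode`` is ``"promote"`` for an activating arrow or ``"inhibit"`` for a
    blunt-headed (inhibitory) one; ``rate`` is in 1/year.
    """

    id: str
    source: str
    target: str
    mode: str
    rate: float


# Default pathway table: id -> (source, target, mode, rate / (1/year)).
_DEFAULT_PATHWAYS: tuple[tuple[str, str, str, str, float], ...] = (
    ("alpha_1", "Aq", "Ns", PROMOTE, 1e-5),
    ("alpha_2", "Ap", "Nd", PROMOTE, 1e-3),
    ("alpha_3", "M1", "Nd", PROMOTE, 1e-2),
    ("alpha_4", "M2", "Aq", PROMOTE, 1e-4),
    ("alpha_5", "M1", "Ap", PROMOTE, 1e-2),
    ("alpha_6", "Ns", "M2", PROMOTE, 1e-2),
    ("alpha_7", "Aq", "M2", PROMOTE, 1e-4),
    ("alpha_8", "Abeta", "M2", INHIBIT, 1e-2),
    ("alpha_9", "M1", "M2", INHIBIT, 1e-2),
    ("alpha_10", "Nd", "M1", PROMOTE, 1e-2),
    ("alpha_11", "Ns", "M1", INHIBIT, 1e-2),
    ("alpha_12", "Aq", "M1", INHIBIT, 1e-4),
    ("alpha_13", "Abeta", "M1", PROMOTE, 1e-2),
    ("alpha_14", "M2", "M1", INHIBIT, 1e-4),
    ("alpha_15", "Ns", "Abeta", PROMOTE, 1.0),
    ("alpha_16", "M2", "Abeta", INHIBIT, 1e-2),
    ("alpha_r", "Abeta", "Abeta", INHIBIT, 1.0),
)

RATE_IDS: tuple[str, ...] = tuple(p[0] for p in _DEFAULT_PATHWAYS)

#: Default initial populations (counts per local volume), canonical order.
DEFAULT_INITIAL: dict[str, float] = {
    "Ns": 1e4,
    "Nd": 1e2,
    "Aq": 1e5,
    "Ap": 1e3,
    "M1": 1e3,
    "M2": 1e5,
    "Abeta": 1e3,
}

DEFAULT_HORIZON_YEARS = 20.0


class RateTable:
    """Ordered collection of the 17 pathways, keyed by rate id.

    The default construction carries the published pathway topology; only the
    rates vary between instances.  Access by id returns the rate value;
    :meth:`pathway` returns the full :class:`Pathway` record.
    """

    def __init__(self, rates: dict[str, float] | None = None):
        base = {pid: r for pid, _, _, _, r in _DEFAULT_PATHWAYS}
        if rates is not None:
            unknown = set(rates) - set(base)
            if unknown:
                raise KeyError(f"unknown rate id(s): {sorted(unknown)}")
            base.update(rates)
        self._rates = {pid: float(base[pid]) for pid in RATE_IDS}

    def __getitem__(self, rate_id: str) -> float:
        return self._rates[rate_id]

    def __contains__(self, rate_id: str) -> bool:
        return rate_id in self._rates

    def __iter__(self):
        return iter(RATE_IDS)

    def __len__(self) -> int:
        return len(self._rates)

    def __eq__(self, other) -> bool:
        return isinstance(other, RateTable) and self._rates == other._rates

    def __repr__(self) -> str:
        return f"RateTable({self._rates!r})"

    def as_dict(self) -> dict[str, float]:
        return dict(self._rates)

    def pathway(self, rate_id: str) -> Pathway:
        for pid, src, tgt, mode, _ in _DEFAULT_PATHWAYS:
            if pid == rate_id:
                return Pathway(pid, src, tgt, mode, self._rates[pid])
        raise KeyError(rate_id)

    def pathways(self) -> list[Pathway]:
        return [self.pathway(pid) for pid in RATE_IDS]

    def with_rate(self, rate_id: str, value: float) -> "RateTable":
        """Return a copy with one rate replaced."""
        if rate_id not in self._rates:
            raise KeyError(f"unknown rate id: {rate_id}")
        new = dict(self._rates)
        new[rate_id] = float(value)
        return RateTable(new)

    def scaled(self, rate_id: str, factor: float) -> "RateTable":
        """Return a copy with one rate multiplied by ``factor``."""
        return self.with_rate(rate_id, self._rates[rate_id] * factor)


@dataclass(frozen=True)
class ModelSpec:
    """A fully specified model: rates, initial state, horizon, and options.

    ``initial`` is a length-7 array in the canonical :data:`SPECIES` order.
    ``floor_neuron_flux`` enforces irreversible neuronal death (the net
    Ns -> Nd flux never runs backwards); ``clamp_nonnegative`` projects
    species onto the non-negative orthant (a species held at zero stops
    exporting flux, and its conversion partner freezes with it so the pair
    total is conserved).
    """

    rates: RateTable
    initial: np.ndarray
    horizon: float = DEFAULT_HORIZON_YEARS
    floor_neuron_flux: bool = True
    clamp_nonnegative: bool = True

    def __post_init__(self):
        arr = np.asarray(self.initial, dtype=float)
        if arr.shape != (len(SPECIES),):
            raise ValueError(f"initial must have shape ({len(SPECIES)},)")
        object.__setattr__(self, "initial", arr)

    def initial_value(self, species: str) -> float:
        return float(self.initial[_IDX[species]])

    def with_initial(self, species: str, value: float) -> "ModelSpec":
        arr = self.initial.copy()
        arr[_IDX[species]] = value
        return replace(self, initial=arr)

    def with_scaled_initial(self, species: str, factor: float) -> "ModelSpec":
        return self.with_initial(species, self.initial_value(species) * factor)

    def with_rates(self, rates: RateTable) -> "ModelSpec":
        return replace(self, rates=rates)

    def with_scaled_rate(self, rate_id: str, factor: float) -> "ModelSpec":
        return replace(self, rates=self.rates.scaled(rate_id, factor))

    def scale_parameter(self, parameter: str, factor: float) -> "ModelSpec":
        """Scale either a rate (``alpha_*``) or an initial value by ``factor``."""
        if parameter in self.rates:
            return self.with_scaled_rate(parameter, factor)
        if parameter in _IDX:
            return self.with_scaled_initial(parameter, factor)
        raise KeyError(f"unknown parameter: {parameter}")


def build_default_model() -> ModelSpec:
    """The published model: default rate table, default initial populations,
    20-year horizon."""
    initial = np.array([DEFAULT_INITIAL[s] for s in SPECIES])
    return ModelSpec(rates=RateTable(), initial=initial)


def _fluxes(state: np.ndarray, rates: RateTable,
            floor_neuron_flux: bool, clamp_nonnegative: bool):
    """Net conversion fluxes (phi_N, phi_A, phi_M) and the amyloid derivative.

    phi_N is the Ns -> Nd flux, phi_A the Aq -> Ap flux, phi_M the M2 -> M1
    flux.  Clamping: when a species sits at (or below) zero and the flux
    would drain it further, the flux is zeroed, freezing the pair.
    """
    Ns, Nd, Aq, Ap, M1, M2, Ab = state
    a = rates

    phi_N = a["alpha_2"] * Ap + a["alpha_3"] * M1 - a["alpha_1"] * Aq
    if floor_neuron_flux and phi_N < 0.0:
        phi_N = 0.0

    phi_A = a["alpha_5"] * M1 - a["alpha_4"] * M2

    phi_M = (
        (a["alpha_8"] + a["alpha_13"]) * Ab
        + a["alpha_9"] * M1
        + a["alpha_10"] * Nd
        - (a["alpha_6"] + a["alpha_11"]) * Ns
        - (a["alpha_7"] + a["alpha_12"]) * Aq
        - a["alpha_14"] * M2
    )

    d_Ab = a["alpha_15"] * Ns - a["alpha_16"] * M2 - a["alpha_r"] * Ab

    if clamp_nonnegative:
        if Ns <= 0.0 and phi_N > 0.0:
            phi_N = 0.0
        if Aq <= 0.0 and phi_A > 0.0:
            phi_A = 0.0
        if Ap <= 0.0 and phi_A < 0.0:
            phi_A = 0.0
        if M2 <= 0.0 and phi_M > 0.0:
            phi_M = 0.0
        if M1 <= 0.0 and phi_M < 0.0:
            phi_M = 0.0
        if Ab <= 0.0 and d_Ab < 0.0:
            d_Ab = 0.0

    return phi_N, phi_A, phi_M, d_Ab


def _rhs_unchecked(state: np.ndarray, rates: RateTable,
                   floor_neuron_flux: bool = True,
                   clamp_nonnegative: bool = True) -> np.ndarray:
    phi_N, phi_A, phi_M, d_Ab = _fluxes(
        state, rates, floor_neuron_flux, clamp_nonnegative
    )
    # Pair derivatives are exact negatives, so the three pair totals are
    # conserved to roundoff by any Runge-Kutta step.
    return np.array([-phi_N, phi_N, -phi_A, phi_A, phi_M, -phi_M, d_Ab])


def rhs(state, rates: RateTable, *, floor_neuron_flux: bool = True,
        clamp_nonnegative: bool = True) -> np.ndarray:
    """Instantaneous derivative of each species, in counts per year.

    Parameters
    ----------
    state : array-like, shape (7,)
        Species abundances in the canonical order.
    rates : RateTable
        Pathway rates.
    floor_neuron_flux, clamp_nonnegative : bool
        See :class:`ModelSpec`.

    Raises
    ------
    InvalidStateError
        If any state component is negative.
    """
    state = np.asarray(state, dtype=float)
    if state.shape != (len(SPECIES),):
        raise InvalidStateError(f"state must have shape ({len(SPECIES)},)")
    if np.any(state < 0.0):
        bad = [SPECIES[i] for i in np.flatnonzero(state < 0.0)]
        raise InvalidStateError(f"negative state component(s): {bad}")
    return _rhs_unchecked(state, rates, floor_neuron_flux, clamp_nonnegative)


def validate(model: ModelSpec) -> list[str]:
    """Check every model invariant; return a list of violation messages.

    An empty list means the model is valid.  Violations are returned rather
    than raised so a caller can report all of them at once.
    """
    violations: list[str] = []
    try:
        table = model.rates.as_dict()
    except AttributeError:
        return ["rates: not a RateTable"]
    missing = [pid for pid in RATE_IDS if pid not in table]
    for pid in missing:
        violations.append(f"rates.{pid}: missing pathway")
    for pid, value in table.items():
        if value < 0.0:
            violations.append(f"rates.{pid}: rate must be >= 0 (got {value})")
    initial = np.asarray(model.initial, dtype=float)
    for name, value in zip(SPECIES, initial):
        if value < 0.0:
            violations.append(f"initial.{name}: must be >= 0 (got {value})")
    if not model.horizon > 0.0:
        violations.append(f"horizon: must be > 0 (got {model.horizon})")
    return violations


def species_index(name: str) -> int:
    """Index of a species name in the canonical order."""
    try:
        return _IDX[name]
    except KeyError:
        raise KeyError(f"unknown species: {name!r}; expected one of {SPECIES}")
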