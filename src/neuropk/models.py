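"""Linear compartmental PK models with a CSF lag pathway.

Drug amounts X(t) (mg) in a small set of notional compartments obey a
linear system dX/dt = A X + u(t), where A collects first-order rate
constants (1/h) and u(t) is the zero-order infusion input into the
central compartment. Concentrations are amounts divided by the
compartment volume (mg/liter == ug/ml).

The full structure has four states:

    central (X1) --K12/K21--> peripheral (X2)
    central (X1) --K13--> lag (X3) --K34--> CSF (X4) --K41--> central
    central (X1) --kel--> eliminated

Plasma concentration is X1/Vc and CSF concentration is X4/V_CSF; the lag
state is unobserved. Simpler nested structures drop the peripheral
and/or the lag pathway.

Units throughout: time h, amounts mg, volumes liters, concentrations
ug/ml. Time zero is the start of the first dose.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace
from typing import Sequence

import numpy as np
from scipy.linalg import expm

__all__ = [
    "DoseEvent",
    "Observation",
    "SubjectRecord",
    "ModelStructure",
    "PKParams",
    "StructureMismatchError",
    "InvalidParameterError",
    "Propagator",
    "get_structure",
    "list_structures",
    "build_rate_matrix",
    "solve_amounts",
    "predict_concentrations",
    "standard_regimen",
    "PLASMA",
    "CSF",
    "TWO_MINUTE_INFUSION_H",
]

PLASMA = "plasma"
CSF = "csf"

#: a 2-minute IV push expressed as a zero-order infusion duration (h)
TWO_MINUTE_INFUSION_H = 1.0 / 30.0


class InvalidParameterError(ValueError):
    """A required rate constant or volume is missing or out of range."""


class StructureMismatchError(ValueError):
    """An output channel was requested from a structure that lacks it."""


@dataclass(frozen=True)
class DoseEvent:
    """One IV administration.

    Parameters
    ----------
    start_time : hours since the first dose of the study.
    amount : dose in mg.
    infusion_duration : zero-order input duration in hours; 0 means an
        instantaneous bolus. A 2-minute push is 1/30 h.
    """

    start_time: float
    amount: float
    infusion_duration: float = TWO_MINUTE_INFUSION_H

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"dose start_time must be >= 0, got {self.start_time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")
        if self.infusion_duration < 0:
            raise ValueError(
                f"infusion_duration must be >= 0, got {self.infusion_duration}"
            )

    @property
    def end_time(self) -> float:
        return self.start_time + self.infusion_duration

    @property
    def rate(self) -> float:
        """Zero-order input rate in mg/h (inf for a bolus)."""
        if self.infusion_duration == 0:
            return math.inf
        return self.amount / self.infusion_duration


@dataclass(frozen=True)
class Observation:
    """One measured concentration in one output channel.

    ``extra`` carries unknown dataset columns through a CSV round-trip
    (for example a below-LLOQ flag emitted by the study generator).
    """

    time: float
    value: float
    output: str
    excluded: bool = False
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.output not in (PLASMA, CSF):
            raise ValueError(f"unknown output channel {self.output!r}")
        if not self.excluded and self.value < 0:
            raise ValueError(
                f"non-excluded observation value must be >= 0, got {self.value}"
            )


@dataclass
class SubjectRecord:
    """One animal: body weight, dosing history and observations."""

    id: str
    weight: float  # grams
    doses: list[DoseEvent] = field(default_factory=list)
    observations: list[Observation] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError(f"subject weight must be > 0 g, got {self.weight}")
        if not self.doses:
            raise ValueError(f"subject {self.id!r} has no dose events")
        # canonical event order so construction path does not matter
        self.doses = sorted(self.doses, key=lambda d: d.start_time)
        self.observations = sorted(
            self.observations, key=lambda o: (o.time, o.output)
        )

    def active_observations(self, output: str | None = None) -> list[Observation]:
        """Non-excluded observations, optionally for one channel."""
        obs = [o for o in self.observations if not o.excluded]
        if output is not None:
            obs = [o for o in obs if o.output == output]
        return obs


_PARAM_NAMES = ("kel", "Vc", "V_CSF", "K12", "K21", "K13", "K34", "K41")
_VOLUME_PARAMS = frozenset({"Vc", "V_CSF"})


@dataclass(frozen=True)
class PKParams:
    """Rate constants (1/h) and volumes (liters) of a model structure.

    Only the parameters active in the chosen structure need to be set;
    the rest may stay ``None``.
    """

    kel: float | None = None
    Vc: float | None = None
    V_CSF: float | None = None
    K12: float | None = None
    K21: float | None = None
    K13: float | None = None
    K34: float | None = None
    K41: float | None = None

    def get(self, name: str) -> float | None:
        return getattr(self, name)

    def to_vector(self, structure: "ModelStructure") -> np.ndarray:
        """Active parameters as an array ordered like ``structure.active_params``."""
        vals = []
        for name in structure.active_params:
            v = self.get(name)
            if v is None:
                raise InvalidParameterError(
                    f"parameter {name!r} required by {structure.name} is missing"
                )
            vals.append(float(v))
        return np.array(vals)

    @classmethod
    def from_vector(cls, theta: Sequence[float], structure: "ModelStructure") -> "PKParams":
        return cls(**dict(zip(structure.active_params, map(float, theta))))

    def as_dict(self, drop_none: bool = True) -> dict[str, float]:
        d = {f.name: getattr(self, f.name) for f in fields(self)}
        if drop_none:
            d = {k: v for k, v in d.items() if v is not None}
        return d

    def replace(self, **kw) -> "PKParams":
        return replace(self, **kw)


@dataclass(frozen=True)
class ModelStructure:
    """Wiring of one candidate compartmental structure.

    ``transfers`` lists first-order edges ``(rate_param, from_state,
    to_state)``; elimination at rate ``kel`` always leaves from the
    central compartment. ``outputs`` maps each observable channel to the
    ``(state, volume_param)`` pair that produces its concentration.
    """

    name: str
    states: tuple[str, ...]
    transfers: tuple[tuple[str, str, str], ...]
    outputs: dict[str, tuple[str, str]]

    @property
    def n_state(self) -> int:
        return len(self.states)

    @property
    def active_params(self) -> tuple[str, ...]:
        names = ["kel"] + sorted(
            {t[0] for t in self.transfers}, key=_PARAM_NAMES.index
        )
        vols = sorted({v for _, v in self.outputs.values()}, key=_PARAM_NAMES.index)
        # canonical order: kel, volumes, then rate constants
        ordered = ["kel"] + vols + [n for n in names if n != "kel"]
        return tuple(ordered)

    def state_index(self, state: str) -> int:
        return self.states.index(state)

    def output_index(self, output: str) -> tuple[int, str]:
        """(state index, volume parameter name) for an output channel."""
        if output not in self.outputs:
            raise StructureMismatchError(
                f"structure {self.name!r} has no {output!r} output "
                f"(available: {sorted(self.outputs)})"
            )
        state, vol = self.outputs[output]
        return self.states.index(state), vol


def _make_registry() -> dict[str, ModelStructure]:
    central_out = {PLASMA: ("central", "Vc")}
    csf_out = {CSF: ("csf", "V_CSF")}
    reg = {}
    reg["one_compartment"] = ModelStructure(
        "one_compartment", ("central",), (), dict(central_out)
    )
    reg["two_compartment"] = ModelStructure(
        "two_compartment",
        ("central", "csf"),
        (("K13", "central", "csf"), ("K41", "csf", "central")),
        {**central_out, **csf_out},
    )
    reg["three_compartment"] = ModelStructure(
        "three_compartment",
        ("central", "peripheral", "csf"),
        (
            ("K12", "central", "peripheral"),
            ("K21", "peripheral", "central"),
            ("K13", "central", "csf"),
            ("K13", "csf", "central"),
        ),
        {**central_out, **csf_out},
    )
    reg["three_compartment_lag_constant"] = ModelStructure(
        "three_compartment_lag_constant",
        ("central", "peripheral", "csf"),
        (
            ("K12", "central", "peripheral"),
            ("K21", "peripheral", "central"),
            ("K13", "central", "csf"),
            ("K41", "csf", "central"),
        ),
        {**central_out, **csf_out},
    )
    reg["four_compartment_lag"] = ModelStructure(
        "four_compartment_lag",
        ("central", "peripheral", "lag", "csf"),
        (
            ("K12", "central", "peripheral"),
            ("K21", "peripheral", "central"),
            ("K13", "central", "lag"),
            ("K34", "lag", "csf"),
            ("K41", "csf", "central"),
        ),
        {**central_out, **csf_out},
    )
    return reg


_STRUCTURES = _make_registry()


def list_structures() -> list[str]:
    return sorted(_STRUCTURES)


def get_structure(name: str | ModelStructure) -> ModelStructure:
    if isinstance(name, ModelStructure):
        return name
    try:
        return _STRUCTURES[name]
    except KeyError:
        raise KeyError(
            f"unknown model structure {name!r}; choose from {list_structures()}"
        ) from None


def _theta_matrix(params, structure: ModelStructure) -> np.ndarray:
    """Coerce PKParams | mapping | vector | (P,k) array to a (P,k) float array."""
    if isinstance(params, PKParams):
        return params.to_vector(structure)[None, :]
    if isinstance(params, dict):
        return PKParams(**params).to_vector(structure)[None, :]
    arr = np.asarray(params, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    if arr.shape[1] != len(structure.active_params):
        raise InvalidParameterError(
            f"expected {len(structure.active_params)} parameters "
            f"({structure.active_params}), got shape {arr.shape}"
        )
    return arr


def _validate_theta(theta: np.ndarray, structure: ModelStructure) -> None:
    names = structure.active_params
    if not np.all(np.isfinite(theta)):
        raise InvalidParameterError("non-finite parameter value")
    for j, name in enumerate(names):
        col = theta[:, j]
        if name in _VOLUME_PARAMS:
            if np.any(col <= 0):
                raise InvalidParameterError(f"parameter {name!r} must be > 0")
        elif np.any(col < 0):
            # rate constants of 0 are allowed (they switch a pathway off)
            raise InvalidParameterError(f"parameter {name!r} must be >= 0")


def build_rate_matrices(theta, structure) -> np.ndarray:
    """Stacked rate matrices, shape (P, n_state, n_state).

    Vectorized over parameter vectors; used by the population fitter.
    """
    structure = get_structure(structure)
    theta = _theta_matrix(theta, structure)
    _validate_theta(theta, structure)
    names = structure.active_params
    col = {name: theta[:, j] for j, name in enumerate(names)}
    P = theta.shape[0]
    n = structure.n_state
    A = np.zeros((P, n, n))
    for rate, src, dst in structure.transfers:
        i, j = structure.state_index(dst), structure.state_index(src)
        A[:, i, j] += col[rate]
        A[:, j, j] -= col[rate]
    i_central = structure.state_index("central")
    A[:, i_central, i_central] -= col["kel"]
    return A


def build_rate_matrix(params, structure) -> np.ndarray:
    """Rate matrix A of dX/dt = A X + u(t) for one parameter set.

    Off-diagonal entries are the first-order transfer rates into each
    state; every column sums to minus the elimination rate leaving the
    system from that state (only the central compartment eliminates).
    """
    structure = get_structure(structure)
    return build_rate_matrices(params, structure)[0]


def _segment_breakpoints(doses: Sequence[DoseEvent], times: np.ndarray) -> np.ndarray:
    pts = {0.0}
    pts.update(float(t) for t in times)
    for d in doses:
        pts.add(float(d.start_time))
        if d.infusion_duration > 0:
            pts.add(float(d.end_time))
    return np.array(sorted(pts))


def _amounts_stacked(
    As: np.ndarray,
    doses: Sequence[DoseEvent],
    times: np.ndarray,
    central_index: int,
) -> np.ndarray:
    """Piecewise matrix-exponential propagation; returns (P, n_times, n).

    Within each segment the infusion input is constant, so the exact
    update is the exponential of the augmented matrix [[A, u], [0, 0]].
    Doses with zero duration enter as instantaneous state jumps.
    """
    P, n, _ = As.shape
    out = np.zeros((P, len(times), n))
    if len(times) == 0:
        return out
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    if t_sorted[0] < 0:
        raise ValueError("observation times must be nonnegative")
    breaks = _segment_breakpoints(doses, t_sorted)
    boluses: dict[float, float] = {}
    for d in doses:
        if d.infusion_duration == 0 and d.amount > 0:
            boluses[float(d.start_time)] = boluses.get(float(d.start_time), 0.0) + d.amount

    x = np.zeros((P, n))
    qi = 0  # next query index into t_sorted

    def record(t_now: float) -> None:
        nonlocal qi
        while qi < len(t_sorted) and t_sorted[qi] == t_now:
            out[:, order[qi], :] = x
            qi += 1

    t_prev = breaks[0]
    if t_prev in boluses:
        x[:, central_index] += boluses[t_prev]
    record(t_prev)
    for t_next in breaks[1:]:
        dt = t_next - t_prev
        rate = sum(
            d.rate
            for d in doses
            if d.infusion_duration > 0
            and d.start_time <= t_prev
            and d.end_time >= t_next
            and d.amount > 0
        )
        if dt > 0:
            if rate > 0:
                M = np.zeros((P, n + 1, n + 1))
                M[:, :n, :n] = As * dt
                M[:, central_index, n] = rate * dt
                E = expm(M)
                x = np.einsum("pij,pj->pi", E[:, :n, :n], x) + E[:, :n, n]
            else:
                E = expm(As * dt)
                x = np.einsum("pij,pj->pi", E, x)
        if t_next in boluses:
            x[:, central_index] += boluses[t_next]
        record(t_next)
        t_prev = t_next
    # numerical noise can leave tiny negatives
    np.clip(out, 0.0, None, out=out)
    return out


def _phi1(z: np.ndarray) -> np.ndarray:
    """(e^z - 1)/z elementwise for complex z, stable near z = 0."""
    out = np.empty_like(z)
    small = np.abs(z) < 1e-4
    zs = z[small]
    out[small] = 1.0 + zs / 2.0 + zs**2 / 6.0 + zs**3 / 24.0
    zb = z[~small]
    out[~small] = (np.exp(zb) - 1.0) / zb
    return out


class Propagator:
    """Reusable exact propagator for a stack of parameter vectors.

    Diagonalizes each rate matrix once so that repeated propagation
    (many subjects, many time grids) costs only elementwise work.
    Points whose eigenvector matrix is ill-conditioned (repeated or
    near-defective eigenvalues) automatically fall back to the
    augmented matrix-exponential path, so results are exact either way.
    """

    _COND_LIMIT = 1e10

    def __init__(self, theta, structure):
        self.structure = get_structure(structure)
        self.theta = _theta_matrix(theta, self.structure)
        self.As = build_rate_matrices(self.theta, self.structure)
        self.central = self.structure.state_index("central")
        lam, V = np.linalg.eig(self.As)
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            cond = np.linalg.cond(V)
        self.bad = ~np.isfinite(cond) | (cond > self._COND_LIMIT)
        good = ~self.bad
        self.lam = lam[good]
        self.V = V[good]
        self.Vinv = np.linalg.inv(V[good]) if good.any() else None

    def amounts(self, doses: Sequence[DoseEvent], times) -> np.ndarray:
        """Per-state amounts (mg), shape (P, n_times, n_state)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        if np.any(times < 0):
            raise ValueError("times must be nonnegative")
        P, n = self.As.shape[0], self.As.shape[1]
        out = np.zeros((P, len(times), n))
        good = ~self.bad
        if good.any():
            out[good] = self._amounts_spectral(list(doses), times)
        if self.bad.any():
            out[self.bad] = _amounts_stacked(
                self.As[self.bad], list(doses), times, self.central
            )
        return out

    def concentrations(self, doses, times, output: str) -> np.ndarray:
        """Concentrations (ug/ml) for one channel, shape (P, n_times)."""
        state_idx, vol_name = self.structure.output_index(output)
        amounts = self.amounts(doses, times)
        vols = self.theta[:, self.structure.active_params.index(vol_name)]
        return amounts[:, :, state_idx] / vols[:, None]

    def _amounts_spectral(self, doses, times) -> np.ndarray:
        lam, V, Vinv = self.lam, self.V, self.Vinv
        P, n = V.shape[0], V.shape[1]
        c = self.central
        out = np.zeros((P, len(times), n))
        order = np.argsort(times, kind="stable")
        t_sorted = times[order]
        breaks = _segment_breakpoints(doses, t_sorted)
        boluses: dict[float, float] = {}
        for d in doses:
            if d.infusion_duration == 0 and d.amount > 0:
                boluses[float(d.start_time)] = (
                    boluses.get(float(d.start_time), 0.0) + d.amount
                )
        vinv_c = Vinv[:, :, c]  # eigen-coordinates of the input direction
        y = np.zeros((P, n), dtype=complex)  # state in eigen-coordinates
        qi = 0

        def record(t_now: float) -> None:
            nonlocal qi
            while qi < len(t_sorted) and t_sorted[qi] == t_now:
                x = np.einsum("pij,pj->pi", V, y).real
                out[:, order[qi], :] = x
                qi += 1

        t_prev = breaks[0]
        if t_prev in boluses:
            y += boluses[t_prev] * vinv_c
        record(t_prev)
        for t_next in breaks[1:]:
            dt = t_next - t_prev
            if dt > 0:
                rate = sum(
                    d.rate
                    for d in doses
                    if d.infusion_duration > 0
                    and d.start_time <= t_prev
                    and d.end_time >= t_next
                    and d.amount > 0
                )
                z = lam * dt
                y = np.exp(z) * y
                if rate > 0:
                    y = y + rate * dt * _phi1(z) * vinv_c
            if t_next in boluses:
                y += boluses[t_next] * vinv_c
            record(t_next)
            t_prev = t_next
        np.clip(out, 0.0, None, out=out)
        return out


def solve_amounts(params, structure, doses: Sequence[DoseEvent], times) -> np.ndarray:
    """Exact drug amounts (mg) per state at each requested time.

    Returns an array of shape (n_times, n_state). The solution is the
    exact piecewise propagation of the linear system under superposed
    zero-order infusions; overlapping infusion windows simply add.
    """
    structure = get_structure(structure)
    return Propagator(params, structure).amounts(doses, times)[0]


def predict_concentrations_stacked(
    theta, structure, doses: Sequence[DoseEvent], times, output: str
) -> np.ndarray:
    """Concentrations (ug/ml) for stacked parameter vectors; shape (P, n_times)."""
    return Propagator(theta, structure).concentrations(doses, times, output)


def predict_concentrations(
    params, structure, doses: Sequence[DoseEvent], times, output: str
) -> np.ndarray:
    """Predicted concentration-time course for one output channel."""
    structure = get_structure(structure)
    if isinstance(params, PKParams):
        theta = params.to_vector(structure)
    else:
        theta = params
    return predict_concentrations_stacked(theta, structure, doses, times, output)[0]


def standard_regimen(
    weight_g: float = 306.0,
    dose_mg_per_kg: float = 150.0,
    n_days: int = 4,
    interval_h: float = 24.0,
    infusion_h: float = TWO_MINUTE_INFUSION_H,
) -> list[DoseEvent]:
    """The study regimen: weight-based daily IV doses over 2 minutes.

    The default 306 g animal receives 45.9 mg per dose.
    """
    amount = dose_mg_per_kg * weight_g / 1000.0
    return [
        DoseEvent(start_time=i * interval_h, amount=amount, infusion_duration=infusion_h)
        for i in range(n_days)
    ]
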