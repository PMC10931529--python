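"""Benchmark ODE systems and their gray-box variants.

Two systems-biology models are bundled:

* a single-dose compartmental pharmacokinetics (PK) model — drug amount in
  the GI tract ``G``, bloodstream ``B`` and eliminated compartment ``U``,
  with first-order transfer rates ``kg`` (absorption) and ``kb``
  (elimination), in hours;
* the six-state ultradian glucose–insulin model — plasma insulin ``Ip``,
  interstitial insulin ``Ii``, glucose ``G`` and a three-stage linear delay
  filter ``h1, h2, h3``, driven by exponential meal pulses, in minutes.

A model is described by an :class:`ODESystemSpec`: state names, a vectorised
right-hand side, its analytic state Jacobian, free parameters with search
ranges, and *removable terms*.  Removing a term turns the model into a
gray-box variant in which that part of the dynamics is treated as an unknown
time function to be recovered from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np

__all__ = [
    "PKParams",
    "EndocrineParams",
    "ODESystemSpec",
    "RemovableTerm",
    "TrueTerm",
    "pk",
    "ultradian",
    "pk_rhs",
    "endocrine_rhs",
    "meal_input",
    "make_graybox_spec",
    "true_unknown_terms",
]


# ---------------------------------------------------------------------------
# parameter containers


@dataclass(frozen=True)
class PKParams:
    """Rates (1/h) and initial GI-tract dose (μg) of the PK model."""

    kg: float = 0.72
    kb: float = 0.15
    dose: float = 0.1

    def __post_init__(self) -> None:
        if not (self.kg > 0 and self.kb > 0 and self.dose > 0):
            raise ValueError("PK parameters kg, kb, dose must be positive")


@dataclass(frozen=True)
class EndocrineParams:
    """Nominal parameter set of the ultradian glucose–insulin model.

    Volumes in litres, time constants in minutes, secretion/utilisation
    scales in mU/min or mg/min; ``meals`` is the exogenous glucose schedule
    as ``(time_min, carbohydrate_g)`` pairs, sorted by time.
    """

    Vp: float = 3.0
    Vi: float = 11.0
    Vg: float = 10.0
    E: float = 0.2
    tp: float = 6.0
    ti: float = 100.0
    td: float = 12.0
    k: float = 0.0083
    Rm: float = 209.0
    a1: float = 6.6
    C1: float = 300.0
    C2: float = 144.0
    C3: float = 100.0
    C4: float = 80.0
    C5: float = 26.0
    Ub: float = 72.0
    U0: float = 4.0
    Um: float = 90.0
    Rg: float = 180.0
    alpha: float = 7.5
    beta: float = 1.772
    meals: tuple[tuple[float, float], ...] = ((300.0, 60.0), (650.0, 40.0), (1100.0, 50.0))

    def __post_init__(self) -> None:
        for name in ("Vp", "Vi", "Vg", "E", "tp", "ti", "td", "k", "Rm",
                     "C1", "C2", "C3", "C4", "C5", "Ub", "U0", "Um", "Rg"):
            if not getattr(self, name) > 0:
                raise ValueError(f"endocrine parameter {name} must be positive")
        times = [t for t, _ in self.meals]
        if list(times) != sorted(times):
            raise ValueError("meal events must be sorted by time")

    @property
    def kappa(self) -> float:
        """Insulin scaling inside f3: (1/C4)(1/Vi + 1/(E·ti))."""
        return (1.0 / self.C4) * (1.0 / self.Vi + 1.0 / (self.E * self.ti))


# nominal search ranges for the discoverable parameters
PK_SEARCH_RANGES: dict[str, tuple[float, float]] = {
    "kg": (0.01, 2.0),
    "kb": (0.01, 2.0),
}
ENDOCRINE_SEARCH_RANGES: dict[str, tuple[float, float]] = {
    "E": (0.1, 0.3),
    "tp": (4.0, 8.0),
    "ti": (60.0, 140.0),
    "Rm": (41.8, 376.2),
    "a1": (1.32, 11.88),
}


# ---------------------------------------------------------------------------
# right-hand sides


def _exp(x):
    """exp with the argument clipped to avoid overflow when solvers probe
    far-from-physical states; the clip is inert on the physical range."""
    return np.exp(np.clip(x, -500.0, 500.0))


def _check_finite(y: np.ndarray) -> None:
    if not np.all(np.isfinite(y)):
        raise ValueError("non-finite state passed to RHS evaluation")


def pk_rhs(t, state, params: PKParams) -> np.ndarray:
    """PK derivatives (dB/dt, dG/dt, dU/dt) = (kg·G − kb·B, −kg·G, kb·B).

    ``state`` may be a single ``(3,)`` vector or an ``(N, 3)`` batch; the
    three components always sum to zero (mass conservation).
    """
    y = np.asarray(state, dtype=float)
    _check_finite(y)
    B, G = y[..., 0], y[..., 1]
    out = np.empty_like(y)
    out[..., 0] = params.kg * G - params.kb * B
    out[..., 1] = -params.kg * G
    out[..., 2] = params.kb * B
    return out


def pk_jac_state(t, state, params: PKParams) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    J = np.zeros(y.shape + (3,))
    J[..., 0, 0] = -params.kb
    J[..., 0, 1] = params.kg
    J[..., 1, 1] = -params.kg
    J[..., 2, 0] = params.kb
    return J


def f1(G, p: EndocrineParams):
    """Insulin secretion Rm / (1 + exp(−G/(Vg·C1) + a1)); bounded by (0, Rm)."""
    return p.Rm / (1.0 + _exp(-np.asarray(G, dtype=float) / (p.Vg * p.C1) + p.a1))


def f2(G, p: EndocrineParams):
    """Insulin-independent glucose utilisation Ub(1 − exp(−G/(C2·Vg)))."""
    return p.Ub * (1.0 - _exp(-np.asarray(G, dtype=float) / (p.C2 * p.Vg)))


def f3(Ii, p: EndocrineParams):
    """Insulin-dependent utilisation factor (1/(C3·Vg))(U0 + Um/(1+(κIi)^−β)).

    The power law is only defined for positive insulin; iterative solvers may
    probe transiently negative states, so the argument is floored at a tiny
    positive value (the limit Ii→0⁺ of the factor is U0/(C3·Vg)).
    """
    x = np.maximum(p.kappa * np.asarray(Ii, dtype=float), 1e-9)
    return (1.0 / (p.C3 * p.Vg)) * (p.U0 + p.Um / (1.0 + x ** (-p.beta)))


def f4(h3, p: EndocrineParams):
    """Delayed glucose production Rg / (1 + exp(α(h3/(C5·Vp) − 1)))."""
    return p.Rg / (1.0 + _exp(p.alpha * (np.asarray(h3, dtype=float) / (p.C5 * p.Vp) - 1.0)))


def meal_input(t, params: EndocrineParams):
    """Exogenous glucose delivery rate IG(t) = Σⱼ mⱼ·k·exp(k(tⱼ − t))·1[t ≥ tⱼ].

    Each nutrition event contributes only after its own time tⱼ (unit-step
    causality), so the rate is non-negative and decays between meals.
    """
    tt = np.asarray(t, dtype=float)
    out = np.zeros_like(tt, dtype=float)
    for tj, mj in params.meals:
        active = tt >= tj
        # exp argument is ≤ 0 where active; compute only there to avoid overflow
        out = out + np.where(active, mj * params.k * np.exp(np.minimum(params.k * (tj - tt), 0.0)), 0.0)
    return out if out.ndim else float(out)


def endocrine_rhs(t, state, params: EndocrineParams) -> np.ndarray:
    """Six coupled derivatives of the ultradian glucose–insulin model."""
    y = np.asarray(state, dtype=float)
    _check_finite(y)
    Ip, Ii, G, h1, h2, h3 = (y[..., i] for i in range(6))
    p = params
    exch = p.E * (Ip / p.Vp - Ii / p.Vi)
    out = np.empty_like(y)
    out[..., 0] = f1(G, p) - exch - Ip / p.tp
    out[..., 1] = exch - Ii / p.ti
    out[..., 2] = f4(h3, p) + meal_input(t, p) - f2(G, p) - f3(Ii, p) * G
    out[..., 3] = (Ip - h1) / p.td
    out[..., 4] = (h1 - h2) / p.td
    out[..., 5] = (h2 - h3) / p.td
    return out


def _df1(G, p: EndocrineParams):
    v = f1(G, p)
    return v * (1.0 - v / p.Rm) / (p.Vg * p.C1)


def _df2(G, p: EndocrineParams):
    return p.Ub * _exp(-np.asarray(G, dtype=float) / (p.C2 * p.Vg)) / (p.C2 * p.Vg)


def _df3(Ii, p: EndocrineParams):
    x = np.maximum(p.kappa * np.asarray(Ii, dtype=float), 1e-9)
    xb = x ** (-p.beta)
    return (p.Um / (p.C3 * p.Vg)) * p.beta * p.kappa * x ** (-p.beta - 1.0) / (1.0 + xb) ** 2


def _df4(h3, p: EndocrineParams):
    v = f4(h3, p)
    return -v * (1.0 - v / p.Rg) * p.alpha / (p.C5 * p.Vp)


def endocrine_jac_state(t, state, params: EndocrineParams) -> np.ndarray:
    y = np.asarray(state, dtype=float)
    Ip, Ii, G, h1, h2, h3 = (y[..., i] for i in range(6))
    p = params
    J = np.zeros(y.shape + (6,))
    J[..., 0, 0] = -p.E / p.Vp - 1.0 / p.tp
    J[..., 0, 1] = p.E / p.Vi
    J[..., 0, 2] = _df1(G, p)
    J[..., 1, 0] = p.E / p.Vp
    J[..., 1, 1] = -p.E / p.Vi - 1.0 / p.ti
    J[..., 2, 1] = -_df3(Ii, p) * G
    J[..., 2, 2] = -_df2(G, p) - f3(Ii, p)
    J[..., 2, 5] = _df4(h3, p)
    J[..., 3, 0] = 1.0 / p.td
    J[..., 3, 3] = -1.0 / p.td
    J[..., 4, 3] = 1.0 / p.td
    J[..., 4, 4] = -1.0 / p.td
    J[..., 5, 4] = 1.0 / p.td
    J[..., 5, 5] = -1.0 / p.td
    return J


# ---------------------------------------------------------------------------
# model specification


@dataclass(frozen=True)
class RemovableTerm:
    """A named RHS contribution that a gray-box variant may replace.

    ``value(t, y, params)`` returns the term's contribution to equation
    ``equation`` (added to the remaining RHS); ``jac(t, y, params)`` its
    gradient with respect to the state vector.
    """

    equation: int
    value: Callable
    jac: Callable


@dataclass(frozen=True)
class TrueTerm:
    """Closed-form reduction of a removed term over named state variables."""

    variables: tuple[str, ...]
    coefficients: dict[str, float]

    def __call__(self, **states):
        return sum(c * np.asarray(states[v], dtype=float) for v, c in self.coefficients.items())

    def expression(self) -> str:
        parts = []
        for v, c in self.coefficients.items():
            parts.append(f"{c:+.6g}*{v}")
        return " ".join(parts).lstrip("+")


@dataclass(frozen=True)
class ODESystemSpec:
    """Declarative description of a (possibly gray-box) dynamical system."""

    name: str
    state_names: tuple[str, ...]
    params: object
    initial_conditions: np.ndarray
    t_span: tuple[float, float]
    time_unit: str
    rhs_full: Callable
    jac_state_full: Callable
    removable_terms: Mapping[str, RemovableTerm] = field(default_factory=dict)
    free_params: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    removed: tuple[str, ...] = ()

    def __post_init__(self):
        object.__setattr__(self, "initial_conditions",
                           np.asarray(self.initial_conditions, dtype=float))
        for slot in self.removed:
            if slot not in self.removable_terms:
                raise KeyError(f"unknown removable term {slot!r} for model {self.name!r}")
        for pname, rng in self.free_params.items():
            lo, hi = rng
            if not (np.isfinite(lo) and np.isfinite(hi) and lo < hi):
                raise ValueError(f"free parameter {pname!r} needs a finite range")
        y0 = self.rhs(self.t_span[0], self.initial_conditions, self.params)
        if not np.all(np.isfinite(y0)):
            raise ValueError("RHS is not finite at the initial conditions")

    # -- unknown slots ----------------------------------------------------
    @property
    def unknown_slots(self) -> dict[str, int]:
        """Slot label → index of the equation the unknown function enters."""
        return {s: self.removable_terms[s].equation for s in self.removed}

    @property
    def n_states(self) -> int:
        return len(self.state_names)

    # -- evaluation -------------------------------------------------------
    def rhs(self, t, y, params=None):
        """Known part of the RHS: the full model minus any removed terms."""
        p = self.params if params is None else params
        out = self.rhs_full(t, y, p)
        for slot in self.removed:
            term = self.removable_terms[slot]
            out[..., term.equation] -= term.value(t, y, p)
        return out

    def jac_state(self, t, y, params=None):
        p = self.params if params is None else params
        J = self.jac_state_full(t, y, p)
        for slot in self.removed:
            term = self.removable_terms[slot]
            J[..., term.equation, :] -= term.jac(t, y, p)
        return J

    # -- parameter plumbing ----------------------------------------------
    def with_params(self, **updates) -> "ODESystemSpec":
        return replace(self, params=replace(self.params, **updates))

    def param_values(self, names: Sequence[str]) -> np.ndarray:
        return np.array([getattr(self.params, n) for n in names], dtype=float)


def _pk_removable() -> dict[str, RemovableTerm]:
    return {
        "h": RemovableTerm(
            equation=0,
            value=lambda t, y, p: p.kg * np.asarray(y)[..., 1] - p.kb * np.asarray(y)[..., 0],
            jac=lambda t, y, p: np.stack(
                [np.full(np.asarray(y).shape[:-1], -p.kb),
                 np.full(np.asarray(y).shape[:-1], p.kg),
                 np.zeros(np.asarray(y).shape[:-1])], axis=-1),
        )
    }


def _endocrine_removable() -> dict[str, RemovableTerm]:
    def f_val(t, y, p):
        y = np.asarray(y)
        Ip, Ii = y[..., 0], y[..., 1]
        return -p.E * (Ip / p.Vp - Ii / p.Vi) - Ip / p.tp

    def f_jac(t, y, p):
        y = np.asarray(y)
        J = np.zeros(y.shape[:-1] + (6,))
        J[..., 0] = -p.E / p.Vp - 1.0 / p.tp
        J[..., 1] = p.E / p.Vi
        return J

    def g_val(t, y, p):
        y = np.asarray(y)
        Ip, Ii = y[..., 0], y[..., 1]
        return p.E * (Ip / p.Vp - Ii / p.Vi) - Ii / p.ti

    def g_jac(t, y, p):
        y = np.asarray(y)
        J = np.zeros(y.shape[:-1] + (6,))
        J[..., 0] = p.E / p.Vp
        J[..., 1] = -p.E / p.Vi - 1.0 / p.ti
        return J

    return {"f": RemovableTerm(0, f_val, f_jac), "g": RemovableTerm(1, g_val, g_jac)}


def pk(params: PKParams | None = None, t_span: tuple[float, float] = (0.0, 50.0)) -> ODESystemSpec:
    """Single-dose compartmental pharmacokinetics model (time in hours)."""
    p = params or PKParams()
    return ODESystemSpec(
        name="pk",
        state_names=("B", "G", "U"),
        params=p,
        initial_conditions=np.array([0.0, p.dose, 0.0]),
        t_span=t_span,
        time_unit="h",
        rhs_full=pk_rhs,
        jac_state_full=pk_jac_state,
        removable_terms=_pk_removable(),
        free_params=dict(PK_SEARCH_RANGES),
    )


def ultradian(params: EndocrineParams | None = None,
              t_span: tuple[float, float] = (0.0, 1800.0)) -> ODESystemSpec:
    """Six-state ultradian glucose–insulin model (time in minutes)."""
    p = params or EndocrineParams()
    return ODESystemSpec(
        name="ultradian",
        state_names=("Ip", "Ii", "G", "h1", "h2", "h3"),
        params=p,
        initial_conditions=np.array([36.0, 44.0, 110.0, 0.0, 0.0, 0.0]),
        t_span=t_span,
        time_unit="min",
        rhs_full=endocrine_rhs,
        jac_state_full=endocrine_jac_state,
        removable_terms=_endocrine_removable(),
        free_params=dict(ENDOCRINE_SEARCH_RANGES),
    )


def make_graybox_spec(base_model: ODESystemSpec, slots: Sequence[str]) -> ODESystemSpec:
    """Replace the named removable terms of ``base_model`` by unknown slots."""
    for s in slots:
        if s not in base_model.removable_terms:
            raise KeyError(f"model {base_model.name!r} has no removable term {s!r}")
    return replace(base_model, removed=tuple(slots))


def true_unknown_terms(model: ODESystemSpec, params=None) -> dict[str, TrueTerm]:
    """Ground-truth closed forms of the removed terms, per slot.

    PK: h = kg·G − kb·B.  Endocrine: f = −(E/Vp + 1/tp)·Ip + (E/Vi)·Ii and
    g = (E/Vp)·Ip − (E/Vi + 1/ti)·Ii.
    """
    p = params if params is not None else model.params
    if model.name == "pk":
        return {"h": TrueTerm(("G", "B"), {"G": p.kg, "B": -p.kb})}
    if model.name == "ultradian":
        return {
            "f": TrueTerm(("Ip", "Ii"), {"Ip": -(p.E / p.Vp + 1.0 / p.tp), "Ii": p.E / p.Vi}),
            "g": TrueTerm(("Ip", "Ii"), {"Ip": p.E / p.Vp, "Ii": -(p.E / p.Vi + 1.0 / p.ti)}),
        }
    raise ValueError(f"no ground-truth reduction known for model {model.name!r}")
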