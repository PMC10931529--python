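"""Random-projection collocation solver with exact initial-condition embedding.

Each state is represented by a *constrained expression*

    u(t) = (σ(t) − σ(t0))ᵀ β + u(t0),      du/dt = c σ'(t)ᵀ β,

where σ is a single hidden layer of ``L`` tanh neurons with randomly fixed
input weights and biases (an extreme learning machine) and β are the only
trainable coefficients.  The expression satisfies the initial condition
identically for any β, so the solve reduces to (iterated) linear least
squares on the ODE residuals at ``N`` collocation points plus, for inverse
problems, data residuals at the observation times.  Unknown right-hand-side
terms are expanded in the same basis without the constraint, h(t) = σ(t)ᵀ βₕ.
Long horizons are handled by sequential time-domain decomposition: the value
of each constrained expression at a subdomain's end becomes the next
subdomain's initial condition, so the concatenated solution is continuous by
construction.

Free parameters can be estimated jointly with the β's; they are optimised on
a unit-box scaling of their search range with a Levenberg–Marquardt damped
step and box projection.  Rank-deficient systems (common when neurons far
outnumber residuals) take the minimum-norm pseudoinverse step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .models import ODESystemSpec
from .recovery import GrayBoxRecovery
from .synthetic_data import ObservationSet

__all__ = [
    "XTFCConfig",
    "XTFCBasis",
    "ConstrainedSolution",
    "build_basis",
    "constrained_expression",
    "assemble_residuals",
    "jacobian",
    "iterate_least_squares",
    "solve_subdomain",
    "solve_decomposed",
]


# ---------------------------------------------------------------------------
# configuration and basis


@dataclass(frozen=True)
class XTFCConfig:
    """Solver hyperparameters: collocation points ``N``, neurons ``L``,
    subdomain length ``t_step`` (model time units), iteration tolerance and
    cap, LM damping seed, and the sampling interval for the random input
    weights/biases."""

    N: int = 100
    L: int = 100
    t_step: float = 50.0
    tol: float = 1e-6
    max_iter: int = 100
    damping: float = 1e-2
    rcond: float | None = None
    residual_scaling: bool = True
    unobserved_loosening: float = 50.0
    weight_range: tuple[float, float] = (-1.0, 1.0)
    activation_interval: tuple[float, float] = (0.0, 1.0)
    activation: str = "tanh"
    seed: int = 0

    def __post_init__(self):
        if self.N < 2 or self.L < 1:
            raise ValueError("need N >= 2 collocation points and L >= 1 neurons")
        if self.t_step <= 0 or self.tol <= 0:
            raise ValueError("t_step and tol must be positive")


@dataclass(frozen=True)
class XTFCBasis:
    """Random tanh features on one subdomain.

    The subdomain ``[t0, tf]`` is mapped linearly onto the activation-domain
    interval ``[z0, zf]`` with slope ``c = (zf − z0)/(tf − t0)``; feature j is
    ``tanh(wⱼ z + bⱼ)`` and its time derivative carries the factor ``c·wⱼ``.
    """

    w: np.ndarray
    b: np.ndarray
    t0: float
    tf: float
    z0: float = 0.0
    zf: float = 1.0

    @property
    def L(self) -> int:
        return self.w.size

    @property
    def c(self) -> float:
        return (self.zf - self.z0) / (self.tf - self.t0)

    def _z(self, t) -> np.ndarray:
        return self.z0 + self.c * (np.atleast_1d(np.asarray(t, dtype=float)) - self.t0)

    def value(self, t) -> np.ndarray:
        """σ(t), shape (len(t), L)."""
        return np.tanh(np.outer(self._z(t), self.w) + self.b)

    def deriv(self, t) -> np.ndarray:
        """dσ/dt = c·w·tanh'(wz+b), shape (len(t), L)."""
        s = np.tanh(np.outer(self._z(t), self.w) + self.b)
        return (1.0 - s ** 2) * (self.c * self.w)

    def shifted(self, t0: float, tf: float) -> "XTFCBasis":
        """Same random weights remapped onto another subdomain."""
        return replace(self, t0=t0, tf=tf)


def sample_weights(config: XTFCConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    lo, hi = config.weight_range
    return rng.uniform(lo, hi, config.L), rng.uniform(lo, hi, config.L)


def build_basis(t_grid, config: XTFCConfig, rng: np.random.Generator | None = None,
                max_resample: int = 5) -> XTFCBasis:
    """Sample random input weights/biases for the subdomain covered by ``t_grid``.

    The basis matrix is checked for (numerical) full rank on the grid and
    resampled if degenerate.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.size < 2 or t_grid[-1] <= t_grid[0]:
        raise ValueError("t_grid must contain at least two increasing points")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    z0, zf = config.activation_interval
    for _ in range(max_resample):
        w, b = sample_weights(config, rng)
        basis = XTFCBasis(w=w, b=b, t0=t_grid[0], tf=t_grid[-1], z0=z0, zf=zf)
        S = basis.value(t_grid)
        if np.all(np.isfinite(S)) and np.linalg.matrix_rank(S) >= min(*S.shape) - 0:
            return basis
    return basis  # last resort: hand back the final sample


def constrained_expression(basis: XTFCBasis, beta, ic: float, t) -> tuple[np.ndarray, np.ndarray]:
    """Evaluate one constrained expression and its analytic derivative.

    Returns ``(u(t), du/dt)`` with ``u(t0) = ic`` exactly for any β.
    """
    beta = np.asarray(beta, dtype=float)
    if beta.size != basis.L:
        raise ValueError(f"beta has length {beta.size}, expected {basis.L}")
    S0 = basis.value(np.array([basis.t0]))
    u = (basis.value(t) - S0) @ beta + ic
    du = basis.deriv(t) @ beta
    return u, du


# ---------------------------------------------------------------------------
# subdomain problem: residuals, Jacobian, unknown-vector layout


class SubdomainProblem:
    """Stacked residuals/Jacobian for one subdomain.

    Unknown vector layout: per-state β's, then per-slot β's, then (optional)
    free parameters on their unit-box scaling.
    """

    def __init__(self, model: ODESystemSpec, basis: XTFCBasis, ic: np.ndarray,
                 t_colloc: np.ndarray, obs: ObservationSet | None,
                 fit_params: bool = False,
                 state_scales: np.ndarray | str | None = "auto",
                 unobserved_loosening: float = 50.0):
        self.model = model
        self.basis = basis
        self.ic = np.asarray(ic, dtype=float)
        self.t_colloc = np.asarray(t_colloc, dtype=float)
        self.slots = list(model.unknown_slots)
        self.slot_eq = model.unknown_slots
        self.fit_params = fit_params
        self.param_names = list(model.free_params) if fit_params else []
        self.S = model.n_states
        self.L = basis.L

        # precompute feature matrices
        self.S0 = basis.value(np.array([basis.t0]))
        self.Sc = basis.value(self.t_colloc)
        self.Sc0 = self.Sc - self.S0
        self.dSc = basis.deriv(self.t_colloc)

        # restrict observations to this subdomain
        if obs is not None and len(obs):
            tol = 1e-12 * max(1.0, abs(basis.tf))
            mask = (obs.times >= basis.t0 - tol) & (obs.times <= basis.tf + tol)
            self.t_data = obs.times[mask]
            self.data = obs.values[mask]
            self.obs_states = [model.state_names.index(s) for s in obs.observed_states]
        else:
            self.t_data = np.empty(0)
            self.data = np.empty((0, 0))
            self.obs_states = []
        self.Sd0 = (basis.value(self.t_data) - self.S0) if self.t_data.size else None

        self.n_beta = self.S * self.L + len(self.slots) * self.L
        self.n_unknowns = self.n_beta + len(self.param_names)
        self.n_residuals = self.S * self.t_colloc.size + len(self.obs_states) * self.t_data.size

        # per-state scaling equalises equations whose states differ by orders
        # of magnitude (insulin vs. glucose); weights multiply residual rows.
        # The same scales weight the minimum-norm objective per column so that
        # "smallest" output weights mean smallest in relative state units —
        # without this, chained subdomains can amplify errors in unobserved
        # states whose absolute magnitude is far below the dominant state.
        # Scales are local to the subdomain (initial condition and in-window
        # data), since state magnitudes can change by orders over a long run.
        if isinstance(state_scales, str) and state_scales == "auto":
            state_scales = np.maximum(np.abs(self.ic), 1.0)
            for k, s in enumerate(self.obs_states):
                if self.t_data.size:
                    state_scales[s] = max(state_scales[s],
                                          float(np.max(np.abs(self.data[:, k]))))
            if self.obs_states:
                # states with no data are anchored an order of magnitude more
                # loosely: their level must come from the coupled equations,
                # and a stiff anchor to the chained initial condition turns
                # small interface errors into a growing oscillatory mode
                for s in range(self.S):
                    if s not in self.obs_states:
                        state_scales[s] *= unobserved_loosening
        elif state_scales is None:
            state_scales = np.ones(self.S)
        w_state = 1.0 / np.asarray(state_scales, dtype=float)
        N, M = self.t_colloc.size, self.t_data.size
        self.row_weights = np.concatenate(
            [np.repeat(w_state, N)] +
            ([np.concatenate([np.full(M, w_state[s]) for s in self.obs_states])]
             if self.obs_states else []))
        self.col_scales = np.concatenate(
            [np.repeat(np.asarray(state_scales, dtype=float), self.L),
             np.ones(len(self.slots) * self.L + len(self.param_names))])

    # -- packing ----------------------------------------------------------
    def initial_guess(self) -> np.ndarray:
        x = np.zeros(self.n_unknowns)
        x[self.n_beta:] = 0.5  # free params start at the range midpoint
        return x

    def split(self, x):
        L, S = self.L, self.S
        betas = x[: S * L].reshape(S, L)
        slot_betas = {s: x[(S + i) * L: (S + i + 1) * L] for i, s in enumerate(self.slots)}
        q = x[self.n_beta:]
        return betas, slot_betas, q

    def params_from(self, q) -> object:
        if not self.param_names:
            return self.model.params
        updates = {}
        for name, qi in zip(self.param_names, q):
            lo, hi = self.model.free_params[name]
            updates[name] = lo + float(np.clip(qi, 0.0, 1.0)) * (hi - lo)
        return replace(self.model.params, **updates)

    def bounds(self) -> list[tuple[int, float, float]]:
        return [(self.n_beta + j, 0.0, 1.0) for j in range(len(self.param_names))]

    # -- evaluation -------------------------------------------------------
    def states_at(self, betas, matrix) -> np.ndarray:
        return matrix @ betas.T + self.ic

    def residuals(self, x) -> np.ndarray:
        return self.row_weights * self._residuals_raw(x)

    def jacobian(self, x) -> np.ndarray:
        return self.row_weights[:, None] * self._jacobian_raw(x)

    def _residuals_raw(self, x) -> np.ndarray:
        betas, slot_betas, q = self.split(x)
        p = self.params_from(q)
        Y = self.states_at(betas, self.Sc0)
        dY = self.dSc @ betas.T
        F = self.model.rhs(self.t_colloc, Y, p)
        for s, beta_s in slot_betas.items():
            F[:, self.slot_eq[s]] += self.Sc @ beta_s
        r_ode = (dY - F).T.ravel()  # per-equation blocks of N residuals
        if self.obs_states:
            pred = self.states_at(betas, self.Sd0)[:, self.obs_states]
            r_data = (pred - self.data).T.ravel()
            return np.concatenate([r_ode, r_data])
        return r_ode

    def _jacobian_raw(self, x) -> np.ndarray:
        betas, slot_betas, q = self.split(x)
        p = self.params_from(q)
        N, L, S = self.t_colloc.size, self.L, self.S
        Y = self.states_at(betas, self.Sc0)
        Jst = self.model.jac_state(self.t_colloc, Y, p)  # (N, S, S)
        J = np.zeros((self.n_residuals, self.n_unknowns))
        for s in range(S):
            rows = slice(s * N, (s + 1) * N)
            J[rows, s * L:(s + 1) * L] += self.dSc
            for r in range(S):
                block = -Jst[:, s, r][:, None] * self.Sc0
                J[rows, r * L:(r + 1) * L] += block
        for i, slot in enumerate(self.slots):
            rows = slice(self.slot_eq[slot] * N, (self.slot_eq[slot] + 1) * N)
            J[rows, (S + i) * L:(S + i + 1) * L] = -self.Sc
        if self.param_names:
            # central finite differences on the unit-box parameter scaling
            h = 1e-6
            for j in range(len(self.param_names)):
                qp, qm = q.copy(), q.copy()
                qp[j] += h
                qm[j] -= h
                Fp = self.model.rhs(self.t_colloc, Y, self.params_from(qp))
                Fm = self.model.rhs(self.t_colloc, Y, self.params_from(qm))
                dF = (Fp - Fm) / (2 * h)
                for s in range(S):
                    J[s * N:(s + 1) * N, self.n_beta + j] = -dF[:, s]
        if self.obs_states:
            base = S * N
            M = self.t_data.size
            for k, s in enumerate(self.obs_states):
                J[base + k * M: base + (k + 1) * M, s * L:(s + 1) * L] = self.Sd0
        return J


@dataclass
class ConstrainedSolution:
    """Fitted output weights for one subdomain plus parameter estimates."""

    problem: SubdomainProblem
    betas: np.ndarray                 # (S, L)
    slot_betas: dict[str, np.ndarray]
    params: dict[str, float]
    n_iter: int
    subdomain: tuple[int, tuple[float, float]] = (0, (0.0, 0.0))

    def states(self, t) -> np.ndarray:
        basis = self.problem.basis
        S0 = basis.value(np.array([basis.t0]))
        return (basis.value(t) - S0) @ self.betas.T + self.problem.ic

    def unknown_terms(self, t) -> dict[str, np.ndarray]:
        basis = self.problem.basis
        return {s: basis.value(t) @ b for s, b in self.slot_betas.items()}

    @property
    def end_state(self) -> np.ndarray:
        return self.states(np.array([self.problem.basis.tf]))[0]


def assemble_residuals(model: ODESystemSpec, solution: ConstrainedSolution,
                       obs: ObservationSet | None = None) -> np.ndarray:
    """Stacked ODE + data residual vector at the solution's current weights."""
    prob = solution.problem
    x = np.concatenate([solution.betas.ravel(),
                        *[solution.slot_betas[s] for s in prob.slots],
                        [  # invert the unit-box map for stored params
                            (solution.params[n] - model.free_params[n][0])
                            / (model.free_params[n][1] - model.free_params[n][0])
                            for n in prob.param_names]])
    return prob.residuals(x)


def jacobian(model: ODESystemSpec, solution: ConstrainedSolution,
             obs: ObservationSet | None = None) -> np.ndarray:
    """Jacobian of the stacked residuals with respect to all unknowns."""
    prob = solution.problem
    x = np.concatenate([solution.betas.ravel(),
                        *[solution.slot_betas[s] for s in prob.slots],
                        [(solution.params[n] - model.free_params[n][0])
                         / (model.free_params[n][1] - model.free_params[n][0])
                         for n in prob.param_names]])
    return prob.jacobian(x)


# ---------------------------------------------------------------------------
# iterative least squares


def iterate_least_squares(residual_fn: Callable, jacobian_fn: Callable,
                          beta0: np.ndarray, config: XTFCConfig,
                          bounds: Sequence[tuple[int, float, float]] = (),
                          col_scales: np.ndarray | None = None) -> tuple[np.ndarray, int]:
    """Gauss–Newton / Levenberg–Marquardt iteration on a residual system.

    Without ``bounds`` each step is the minimum-norm least-squares solution
    of J·Δ = −r (exact in one step for affine residuals).  With ``bounds``
    (free-parameter components) the step is damped and the bounded
    components are projected back onto their box after each update.
    Converges when the step's max-norm or the change of ‖r‖₂ drops below
    ``config.tol``; raises on sustained divergence.
    """
    x = np.asarray(beta0, dtype=float).copy()
    cs = np.ones(x.size) if col_scales is None else np.asarray(col_scales, dtype=float)
    r = residual_fn(x)
    norm = float(np.linalg.norm(r))
    if not np.isfinite(norm):
        raise RuntimeError("residual is not finite at the starting point")
    best = norm
    mu = config.damping if bounds else 0.0
    rcond = config.rcond
    bad_streak = 0
    trace = [norm]
    n_iter = 0
    for _ in range(config.max_iter):
        J = jacobian_fn(x) * cs  # columns in scaled units
        if not np.all(np.isfinite(J)):
            raise RuntimeError("non-finite Jacobian in iterative least squares")
        # Each iteration solves the linearised problem J·x_lin = J·x − r for
        # the next iterate directly, so rank deficiency resolves to the
        # minimum-Euclidean-norm *solution* (pseudoinverse practice, in the
        # scaled units), not merely a minimum-norm update: null-space
        # components of the output weights are re-regularised every iteration
        # instead of drifting.
        xs = x / cs
        rhs_lin = J @ xs - r
        if bounds:
            # the box-bounded parameter block is excluded from the norm
            # objective (its natural anchor is the current iterate, not 0)
            # and carries Levenberg-Marquardt damping on its movement
            idxs = np.array([i for i, _, _ in bounds], dtype=int)
            d = np.sqrt(np.sum(J[:, idxs] ** 2, axis=0))
            d = np.maximum(d, 1e-12 * (d.max() if d.size and d.max() > 0 else 1.0))
            rhs_lin = rhs_lin.copy()
            rhs_lin -= J[:, idxs] @ xs[idxs]  # damped block solves for its step
            accepted = False
            for _try in range(25):
                aug = np.zeros((idxs.size, x.size))
                aug[np.arange(idxs.size), idxs] = math.sqrt(mu) * d
                A = np.vstack([J, aug])
                rhs = np.concatenate([rhs_lin, np.zeros(idxs.size)])
                sol = np.linalg.lstsq(A, rhs, rcond=rcond)[0]
                x_new = sol * cs
                x_new[idxs] += x[idxs]
                for idx, lo, hi in bounds:
                    x_new[idx] = min(max(x_new[idx], lo), hi)
                try:
                    with np.errstate(over="ignore", invalid="ignore"):
                        r_new = residual_fn(x_new)
                        norm_new = float(np.linalg.norm(r_new))
                    if not np.isfinite(norm_new):
                        norm_new = float("inf")
                except (ValueError, FloatingPointError):
                    norm_new = float("inf")
                if np.isfinite(norm_new) and norm_new <= norm * (1 + 1e-12):
                    accepted = True
                    mu = max(mu / 3.0, 1e-10)
                    break
                mu = min(max(mu, config.damping) * 10.0, 1e10)
            if not accepted:  # no downhill damped step: we are at a (local) optimum
                break
            step = x_new - x
        else:
            x_lin = np.linalg.lstsq(J, rhs_lin, rcond=rcond)[0] * cs
            if not np.all(np.isfinite(x_lin)):
                raise RuntimeError("least-squares iterate is not finite")
            step = x_lin - x
            # backtracking keeps the full Gauss-Newton step on (near-)affine
            # problems but damps overshoot on strongly nonlinear ones
            alpha = 1.0
            accepted = False
            for _bt in range(25):
                x_new = x + alpha * step
                try:
                    with np.errstate(over="ignore", invalid="ignore"):
                        r_new = residual_fn(x_new)
                        norm_new = float(np.linalg.norm(r_new))
                    if not np.isfinite(norm_new):
                        norm_new = float("inf")
                except (ValueError, FloatingPointError):
                    norm_new = float("inf")
                if np.isfinite(norm_new) and norm_new <= norm * (1 + 1e-12):
                    accepted = True
                    break
                alpha *= 0.5
            if not accepted:  # no downhill step along the GN direction
                break
            step = alpha * step
        if float(np.max(np.abs(step))) < config.tol:
            break
        n_iter += 1
        if norm_new > max(100.0 * best, trace[0]) and norm_new > 1e-8:
            bad_streak += 1
            if bad_streak >= 3:
                raise RuntimeError(
                    f"iterative least squares diverged; residual trace {trace + [norm_new]}")
        else:
            bad_streak = 0
        converged = abs(norm - norm_new) < config.tol
        x, r, norm = x_new, r_new, norm_new
        best = min(best, norm)
        trace.append(norm)
        if converged:
            break
    return x, n_iter


# ---------------------------------------------------------------------------
# subdomain and decomposed solves


def _collocation_grid(t0: float, tf: float, N: int) -> np.ndarray:
    return np.linspace(t0, tf, N)


def solve_subdomain(model: ODESystemSpec, obs: ObservationSet | None,
                    config: XTFCConfig, ic, mode: str = "forward",
                    interval: tuple[float, float] | None = None,
                    basis: XTFCBasis | None = None,
                    index: int = 0,
                    warm_start: np.ndarray | None = None) -> ConstrainedSolution:
    """Fit the constrained expressions (and optionally parameters) on one subdomain."""
    if mode not in ("forward", "params", "graybox", "both", "fit"):
        raise ValueError(f"unknown mode {mode!r}")
    if interval is None:
        interval = model.t_span
    t0, tf = interval
    t_colloc = _collocation_grid(t0, tf, config.N)
    if basis is None:
        basis = build_basis(t_colloc, config)
    fit_params = mode in ("params", "both")
    if mode == "forward":
        obs = None
    prob = SubdomainProblem(model, basis, np.asarray(ic, dtype=float), t_colloc, obs,
                            fit_params=fit_params,
                            state_scales="auto" if config.residual_scaling else None,
                            unobserved_loosening=config.unobserved_loosening)
    if fit_params and prob.obs_states == [] and prob.t_data.size == 0:
        raise ValueError("parameter discovery requires data in the subdomain")
    x0 = prob.initial_guess()
    if warm_start is not None and warm_start.size == prob.n_beta:
        # continuation: the previous subdomain's output weights are a good
        # first iterate because the shared basis is identical in scaled time
        x0[: prob.n_beta] = warm_start
    x, n_iter = iterate_least_squares(prob.residuals, prob.jacobian, x0, config,
                                      bounds=prob.bounds() if fit_params else (),
                                      col_scales=prob.col_scales)
    betas, slot_betas, q = prob.split(x)
    p = prob.params_from(q)
    params = {n: getattr(p, n) for n in prob.param_names}
    return ConstrainedSolution(problem=prob, betas=betas, slot_betas=slot_betas,
                               params=params, n_iter=n_iter,
                               subdomain=(index, (t0, tf)))


def solve_decomposed(model: ODESystemSpec, obs: ObservationSet | None,
                     config: XTFCConfig, mode: str = "forward",
                     t_eval: np.ndarray | None = None,
                     params_first_subdomain_only: bool = True) -> GrayBoxRecovery:
    """Sequential solve over equispaced subdomains of length ``t_step``.

    Each subdomain's terminal state seeds the next one, so state values are
    continuous at the interfaces by construction.  In parameter-discovery
    modes the free parameters are, by default, estimated in the first
    subdomain only and frozen thereafter.  Returns the concatenated
    trajectory, recovered unknown-term series, parameter estimates and the
    per-subdomain iteration counts.
    """
    t0, tf = model.t_span
    n_sub = max(1, int(math.ceil((tf - t0) / config.t_step - 1e-9)))
    edges = [t0 + k * config.t_step for k in range(n_sub)] + [tf]
    if t_eval is None:
        t_eval = np.linspace(t0, tf, 1001)
    t_eval = np.asarray(t_eval, dtype=float)

    rng = np.random.default_rng(config.seed)
    base_grid = _collocation_grid(edges[0], edges[1], config.N)
    shared = build_basis(base_grid, config, rng=rng)

    ic = model.initial_conditions.copy()
    current = model
    solutions: list[ConstrainedSolution] = []
    iters: list[int] = []
    params: dict[str, float] = {}
    sub_mode = mode
    for k in range(n_sub):
        a, b = edges[k], edges[k + 1]
        basis = shared.shifted(a, b)
        try:
            # each subdomain starts from zero output weights: iterations
            # re-anchor to the minimum-norm solution, so carrying the previous
            # subdomain's weights adds nothing and can destabilise the chain
            sol = solve_subdomain(current, obs, config, ic, mode=sub_mode,
                                  interval=(a, b), basis=basis, index=k)
        except RuntimeError as exc:
            raise RuntimeError(f"subdomain {k} on [{a:g}, {b:g}] failed: {exc}") from exc
        solutions.append(sol)
        iters.append(sol.n_iter)
        if sol.params:
            params = sol.params
            if params_first_subdomain_only and sub_mode in ("params", "both"):
                current = current.with_params(**params)
                sub_mode = "graybox" if current.removed else "fit"
        ic = sol.end_state

    # evaluate on the global grid; boundary points belong to the earlier subdomain
    inner = np.array(edges[1:-1])
    which = np.searchsorted(inner, t_eval, side="left")
    Y = np.empty((t_eval.size, model.n_states))
    terms = {s: np.empty(t_eval.size) for s in model.unknown_slots}
    for k, sol in enumerate(solutions):
        m = which == k
        if not np.any(m):
            continue
        Y[m] = sol.states(t_eval[m])
        for s, series in sol.unknown_terms(t_eval[m]).items():
            terms[s][m] = series

    traj = pd.DataFrame({"t": t_eval})
    for j, s in enumerate(model.state_names):
        traj[s] = Y[:, j]
    return GrayBoxRecovery(model_name=model.name, trajectory=traj, terms=terms,
                           params=params, iterations=iters)
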