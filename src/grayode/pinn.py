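"""Physics-informed neural network solver for parameter discovery and
gray-box recovery.

Two fully connected tanh networks are trained jointly: a *main* network
mapping time to all state variables and an *auxiliary* network mapping time
to the unknown right-hand-side terms.  The composite loss is

    L = λ_IC·L_IC + λ_data·L_data + Σ_s λ_ode,s·L_ode,s

with the initial-condition and data losses supervised and the ODE-residual
loss unsupervised; state derivatives come from exact forward-mode tangents
propagated alongside the network evaluation (no finite differences).  The
per-equation ODE weights λ_ode can be trained by gradient ascent (a max–min
saddle objective) while the network weights descend; λ_data = λ_IC = 1.

The input pipeline follows scale-aware design: time is divided by a scale
``T``, an optional feature layer exposes oscillatory patterns, and outputs
are multiplied by per-state magnitudes so the trainable signals are O(1).
Free ODE parameters are trained as unconstrained reals mapped onto their
search ranges through a scaled sigmoid.

Training is staged: a supervised warm-up on data + IC losses, a full-loss
Adam stage, and an optional L-BFGS polish (scipy's implementation driven by
the same autodiff gradient).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.optimize import minimize

from . import autodiff as ad
from .autodiff import Var
from .models import ODESystemSpec
from .recovery import GrayBoxRecovery
from .synthetic_data import ObservationSet

__all__ = ["PINNConfig", "AdaptiveWeights", "MLP", "PINNResult",
           "forward_nets", "total_loss", "adaptive_update", "train",
           "evaluate_unknown_terms"]


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class PINNConfig:
    """Architecture and training schedule.

    ``main_net``/``aux_net`` are (width, depth) of the state and unknown-term
    networks; iteration counts cover the supervised warm-up stage, the
    full-loss stage, and the L-BFGS polish.  ``T`` is the input time scale;
    ``features`` may be ``()`` (raw scaled time), ``("t", "sin", "cos")``
    with ``omega``, or ``"auto"`` to pick ω from the dominant oscillation of
    the data.  ``output_scales`` of ``None`` means per-state magnitudes are
    taken from the data (observed) or initial conditions (unobserved).
    """

    main_net: tuple[int, int] = (50, 7)
    aux_net: tuple[int, int] = (20, 5)
    activation: str = "tanh"
    lr_main: float = 1e-3
    lr_aux: float = 1e-4
    iters_stage1: int = 5000
    iters_stage2: int = 25000
    iters_lbfgs: int = 100
    N_collocation: int = 500
    T: float = 10.0
    features: tuple[str, ...] | str = ()
    omega: float | None = None
    output_scales: dict[str, float] | None = None
    anchor: bool = False
    adaptive_weights: bool = True
    lambda_lr: float | None = None
    two_stage: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.main_net[0] < 1 or self.main_net[1] < 1 or self.aux_net[0] < 1 or self.aux_net[1] < 1:
            raise ValueError("network width/depth must be >= 1")
        if self.T <= 0:
            raise ValueError("input time scale T must be positive")


@dataclass
class AdaptiveWeights:
    """Per-equation ODE weights (trainable); data/IC weights fixed at 1."""

    lambda_ode: np.ndarray
    lambda_data: float = 1.0
    lambda_ic: float = 1.0


# ---------------------------------------------------------------------------
# network


class MLP:
    """Dense tanh network; weights stored as plain numpy arrays."""

    def __init__(self, in_dim: int, width: int, depth: int, out_dim: int,
                 rng: np.random.Generator):
        dims = [in_dim] + [width] * depth + [out_dim]
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for a, b in zip(dims[:-1], dims[1:]):
            bound = math.sqrt(6.0 / (a + b))  # Glorot uniform
            self.weights.append(rng.uniform(-bound, bound, (a, b)))
            self.biases.append(np.zeros(b))

    def parameters(self) -> list[np.ndarray]:
        out = []
        for W, b in zip(self.weights, self.biases):
            out.extend([W, b])
        return out

    def set_parameters(self, arrays: Sequence[np.ndarray]) -> None:
        it = iter(arrays)
        for i in range(len(self.weights)):
            self.weights[i] = next(it)
            self.biases[i] = next(it)

    def forward_tangent(self, x0: np.ndarray, v0: np.ndarray,
                        params: Sequence[Var]) -> tuple[Var, Var]:
        """Evaluate the network and its directional derivative along ``v0``.

        ``x0`` is the (N, F) input, ``v0`` = dx/dt so the returned tangent is
        the exact time derivative of the output.
        """
        a, v = Var(x0), Var(v0)
        n_layers = len(self.weights)
        for i in range(n_layers):
            W, b = params[2 * i], params[2 * i + 1]
            z = ad.matmul(a, W) + b
            vz = ad.matmul(v, W)
            if i < n_layers - 1:
                a = ad.tanh(z)
                v = vz * (1.0 - a * a)
            else:
                a, v = z, vz
        return a, v


# ---------------------------------------------------------------------------
# feature layer and scaling


def _detect_omega(obs: ObservationSet, T: float) -> float:
    """Dominant angular frequency (in scaled-time units) of the first
    observed series, from the FFT of the detrended signal."""
    y = obs.values[:, 0] - np.mean(obs.values[:, 0])
    if y.size < 8 or np.allclose(y, 0):
        return 2 * math.pi
    dt = np.median(np.diff(obs.times)) / T
    freqs = np.fft.rfftfreq(y.size, d=dt)
    power = np.abs(np.fft.rfft(y)) ** 2
    k = int(np.argmax(power[1:]) + 1)
    return max(2 * math.pi * freqs[k], 1e-3)


def _feature_matrix(t: np.ndarray, config: PINNConfig, omega: float):
    """Feature values and their time derivatives, shape (N, F) each."""
    ts = t / config.T
    feats = config.features
    if not feats:
        return ts[:, None], np.full((t.size, 1), 1.0 / config.T)
    cols, dcols = [], []
    for f in feats:
        if f == "t":
            cols.append(ts)
            dcols.append(np.full_like(ts, 1.0 / config.T))
        elif f == "sin":
            cols.append(np.sin(omega * ts))
            dcols.append(omega * np.cos(omega * ts) / config.T)
        elif f == "cos":
            cols.append(np.cos(omega * ts))
            dcols.append(-omega * np.sin(omega * ts) / config.T)
        else:
            raise ValueError(f"unknown feature {f!r}")
    return np.column_stack(cols), np.column_stack(dcols)


# ---------------------------------------------------------------------------
# result container


@dataclass
class PINNResult:
    model: ODESystemSpec
    config: PINNConfig
    main: MLP
    aux: MLP | None
    params: dict[str, float]
    weights: AdaptiveWeights
    loss_history: list[dict[str, float]]
    scales: np.ndarray
    aux_scales: np.ndarray
    omega: float
    anchor_data: tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray] | None

    def predict_states(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x0, v0 = _feature_matrix(t, self.config, self.omega)
        u, _ = self.main.forward_tangent(x0, v0, [Var(p) for p in self.main.parameters()])
        return self._scale_states(u.value, t)

    def _scale_states(self, raw: np.ndarray, t: np.ndarray) -> np.ndarray:
        u = raw * self.scales
        if self.anchor_data is not None:
            t0, tf, y0, yf = self.anchor_data
            frac = ((t - t0) / (tf - t0))[:, None]
            lin = y0 + (yf - y0) * frac
            mask = np.tanh(((t - t0) / (tf - t0))[:, None] / 0.05)
            u = lin + raw * self.scales * mask
        return u

    def predict_terms(self, t) -> dict[str, np.ndarray]:
        if self.aux is None:
            return {}
        t = np.asarray(t, dtype=float)
        x0, v0 = _feature_matrix(t, self.config, self.omega)
        h, _ = self.aux.forward_tangent(x0, v0, [Var(p) for p in self.aux.parameters()])
        vals = h.value * self.aux_scales
        return {s: vals[:, i] for i, s in enumerate(self.model.unknown_slots)}

    def recovery(self, t_grid=None) -> GrayBoxRecovery:
        import pandas as pd
        if t_grid is None:
            t_grid = np.linspace(*self.model.t_span, 1001)
        t_grid = np.asarray(t_grid, dtype=float)
        Y = self.predict_states(t_grid)
        traj = pd.DataFrame({"t": t_grid})
        for j, s in enumerate(self.model.state_names):
            traj[s] = Y[:, j]
        return GrayBoxRecovery(model_name=self.model.name, trajectory=traj,
                               terms=self.predict_terms(t_grid), params=dict(self.params),
                               iterations=[len(self.loss_history)])


# ---------------------------------------------------------------------------
# loss assembly


class _Problem:
    """Precomputed tensors and loss graph builder for one training run."""

    def __init__(self, model: ODESystemSpec, obs: ObservationSet, config: PINNConfig,
                 mode: str):
        if mode not in ("params", "graybox", "both"):
            raise ValueError(f"unknown PINN mode {mode!r}")
        self.model = model
        self.obs = obs
        self.config = config
        self.mode = mode
        self.slots = list(model.unknown_slots)
        if mode in ("graybox", "both") and not self.slots:
            raise ValueError("gray-box mode requires a spec with unknown slots")
        self.param_names = list(model.free_params) if mode in ("params", "both") else []
        t0, tf = model.t_span
        self.t_coll = np.linspace(t0, tf, config.N_collocation)
        self.t_data = obs.times
        self.obs_idx = [model.state_names.index(s) for s in obs.observed_states]
        self.omega = (config.omega if config.omega is not None
                      else (_detect_omega(obs, config.T) if config.features else 2 * math.pi))

        # per-state output scales: data magnitude for observed states,
        # initial-condition magnitude otherwise
        S = model.n_states
        self.scales = np.ones(S)
        for j in range(S):
            self.scales[j] = max(abs(model.initial_conditions[j]), 1e-3)
        if config.output_scales:
            for name, v in config.output_scales.items():
                if name in model.state_names:
                    self.scales[model.state_names.index(name)] = v
        else:
            for k, j in enumerate(self.obs_idx):
                self.scales[j] = max(self.scales[j], float(np.max(np.abs(obs.values[:, k]))))
            if self.obs_idx:
                # unobserved states default to the smallest observed magnitude
                # (their own level is unknown before the fit); explicit
                # output_scales override this when magnitudes are known
                floor = min(self.scales[j] for j in self.obs_idx)
                for j in range(S):
                    if j not in self.obs_idx:
                        self.scales[j] = max(self.scales[j], floor)
        # unknown-term scale: magnitude of the finite-difference derivative of
        # the slot equation's observed data when available, else 1
        self.aux_scales = np.ones(max(len(self.slots), 1))
        for i, slot in enumerate(self.slots):
            eq = model.unknown_slots[slot]
            if eq in self.obs_idx and len(obs) > 2:
                col = obs.values[:, self.obs_idx.index(eq)]
                d = np.gradient(col, obs.times)
                self.aux_scales[i] = max(float(np.max(np.abs(d))), 1e-6)

        self.anchor_data = None
        if config.anchor and self.obs_idx:
            y0 = model.initial_conditions.copy()
            yf = model.initial_conditions.copy()
            for k, j in enumerate(self.obs_idx):
                y0[j] = obs.values[0, k]
                yf[j] = obs.values[-1, k]
            self.anchor_data = (t0, tf, y0, yf)

        self.x_coll, self.v_coll = _feature_matrix(self.t_coll, config, self.omega)
        self.x_data, self.v_data = _feature_matrix(self.t_data, config, self.omega)
        self.x_ic, self.v_ic = _feature_matrix(np.array([t0]), config, self.omega)
        rng = np.random.default_rng(config.seed)
        self.main = MLP(self.x_coll.shape[1], *config.main_net, S, rng)
        self.aux = (MLP(self.x_coll.shape[1], *config.aux_net, len(self.slots), rng)
                    if self.slots else None)
        self.p_raw = np.zeros(len(self.param_names))  # sigmoid(0) = range midpoint

    # -- parameter flattening --------------------------------------------
    def parameter_arrays(self) -> list[np.ndarray]:
        arrays = self.main.parameters()
        if self.aux is not None:
            arrays = arrays + self.aux.parameters()
        if self.param_names:
            arrays = arrays + [self.p_raw]
        return arrays

    def set_parameter_arrays(self, arrays: list[np.ndarray]) -> None:
        n_main = 2 * len(self.main.weights)
        self.main.set_parameters(arrays[:n_main])
        k = n_main
        if self.aux is not None:
            n_aux = 2 * len(self.aux.weights)
            self.aux.set_parameters(arrays[k:k + n_aux])
            k += n_aux
        if self.param_names:
            self.p_raw = arrays[k]

    def param_values(self, p_raw: np.ndarray) -> dict[str, float]:
        out = {}
        for j, name in enumerate(self.param_names):
            lo, hi = self.model.free_params[name]
            out[name] = lo + (hi - lo) / (1.0 + math.exp(-float(p_raw[j])))
        return out

    # -- scaled state pipeline -------------------------------------------
    def _states(self, raw: Var, draw: Var, t: np.ndarray) -> tuple[Var, Var]:
        u = raw * self.scales
        du = draw * self.scales
        if self.anchor_data is not None:
            t0, tf, y0, yf = self.anchor_data
            frac = ((t - t0) / (tf - t0))[:, None]
            lin = y0 + (yf - y0) * frac
            dlin = np.broadcast_to((yf - y0) / (tf - t0), (t.size, y0.size))
            z = ((t - t0) / (tf - t0))[:, None] / 0.05
            mask = np.tanh(z)
            dmask = (1 - np.tanh(z) ** 2) / (0.05 * (tf - t0))
            u = Var(lin) + raw * self.scales * mask
            du = draw * self.scales * mask + raw * self.scales * dmask + Var(dlin)
        return u, du

    # -- loss graph -------------------------------------------------------
    def loss(self, param_vars: list[Var], lam: AdaptiveWeights,
             stage: int) -> tuple[Var, dict[str, float], list[Var]]:
        """Build the loss graph; returns (total, components, ode component Vars)."""
        n_main = 2 * len(self.main.weights)
        main_vars = param_vars[:n_main]
        k = n_main
        aux_vars = None
        if self.aux is not None:
            aux_vars = param_vars[k:k + 2 * len(self.aux.weights)]
            k += 2 * len(self.aux.weights)
        p_var = param_vars[k] if self.param_names else None

        comp: dict[str, float] = {}
        S = self.model.n_states

        raw_ic, draw_ic = self.main.forward_tangent(self.x_ic, self.v_ic, main_vars)
        u_ic, _ = self._states(raw_ic, draw_ic, np.array([self.model.t_span[0]]))
        res_ic = (u_ic - self.model.initial_conditions) * (1.0 / self.scales)
        L_ic = ad.mean_(res_ic * res_ic)

        raw_d, draw_d = self.main.forward_tangent(self.x_data, self.v_data, main_vars)
        u_d, _ = self._states(raw_d, draw_d, self.t_data)
        res_d = (u_d[:, self.obs_idx] - self.obs.values) * (1.0 / self.scales[self.obs_idx])
        L_data = ad.mean_(res_d * res_d)

        total = lam.lambda_ic * L_ic + lam.lambda_data * L_data
        comp["L_ic"] = float(L_ic.value)
        comp["L_data"] = float(L_data.value)
        ode_comps: list[Var] = []
        if stage >= 2:
            raw_c, draw_c = self.main.forward_tangent(self.x_coll, self.v_coll, main_vars)
            u_c, du_c = self._states(raw_c, draw_c, self.t_coll)
            h_c = None
            if self.aux is not None:
                h_raw, _ = self.aux.forward_tangent(self.x_coll, self.v_coll, aux_vars)
                h_c = h_raw * self.aux_scales
            F = self._rhs_node(u_c, h_c, p_var)
            res = (du_c - F) * (1.0 / self.scales)
            L_ode_total = 0.0
            for s in range(S):
                L_s = ad.mean_(res[:, s] * res[:, s])
                ode_comps.append(L_s)
                total = total + float(lam.lambda_ode[s]) * L_s
                L_ode_total += float(L_s.value)
            comp["L_ode"] = L_ode_total
        comp["total"] = float(total.value)
        return total, comp, ode_comps

    def _rhs_node(self, u: Var, h: Var | None, p_var: Var | None) -> Var:
        """ODE right-hand side as a graph node with analytic state pull-back."""
        model, t = self.model, self.t_coll
        p_raw = p_var.value if p_var is not None else None
        params = (replace(model.params, **self.param_values(p_raw))
                  if p_raw is not None else model.params)
        uv = u.value
        F = model.rhs(t, uv, params)
        if h is not None:
            for i, slot in enumerate(self.slots):
                F[:, model.unknown_slots[slot]] += h.value[:, i]
        Jst = model.jac_state(t, uv, params)
        inputs, pulls = [u], []

        def vjp(g):
            grads = [np.einsum("ns,nsr->nr", g, Jst)]
            if h is not None:
                gh = np.zeros_like(h.value)
                for i, slot in enumerate(self.slots):
                    gh[:, i] = g[:, model.unknown_slots[slot]]
                grads.append(gh)
            if p_raw is not None:
                gp = np.zeros_like(p_raw)
                eps = 1e-6
                for j in range(p_raw.size):
                    rp, rm = p_raw.copy(), p_raw.copy()
                    rp[j] += eps
                    rm[j] -= eps
                    Fp = model.rhs(t, uv, replace(model.params, **self.param_values(rp)))
                    Fm = model.rhs(t, uv, replace(model.params, **self.param_values(rm)))
                    gp[j] = float(np.sum(g * (Fp - Fm) / (2 * eps)))
                grads.append(gp)
            return tuple(grads)

        if h is not None:
            inputs.append(h)
        if p_var is not None:
            inputs.append(p_var)
        return ad.custom_jacobian_op(inputs, F, vjp)


# ---------------------------------------------------------------------------
# spec-surface operations


def forward_nets(t, theta1: MLP, theta2: MLP | None, config: PINNConfig,
                 scales=None, aux_scales=None, omega: float | None = None):
    """Raw pipeline evaluation: scaled-time features → trunks → output scaling."""
    t = np.asarray(t, dtype=float)
    om = omega if omega is not None else (config.omega or 2 * math.pi)
    x0, v0 = _feature_matrix(t, config, om)
    u, _ = theta1.forward_tangent(x0, v0, [Var(p) for p in theta1.parameters()])
    u_val = u.value * (scales if scales is not None else 1.0)
    h_val = None
    if theta2 is not None:
        h, _ = theta2.forward_tangent(x0, v0, [Var(p) for p in theta2.parameters()])
        h_val = h.value * (aux_scales if aux_scales is not None else 1.0)
    return u_val, h_val


def total_loss(problem: _Problem, lam: AdaptiveWeights, stage: int = 2):
    """Loss components at the problem's current parameters (no training)."""
    pv = [Var(a) for a in problem.parameter_arrays()]
    total, comp, _ = problem.loss(pv, lam, stage)
    return float(total.value), comp


def adaptive_update(lam: AdaptiveWeights, ode_components: Sequence[float],
                    lr: float) -> AdaptiveWeights:
    """Gradient ascent on the saddle objective: λ_s grows with its residual."""
    new = lam.lambda_ode + lr * np.asarray(ode_components, dtype=float)
    new = np.maximum(new, 1e-6)  # clamp at a small positive floor
    return AdaptiveWeights(lambda_ode=new, lambda_data=lam.lambda_data,
                           lambda_ic=lam.lambda_ic)


class _Adam:
    def __init__(self, arrays: list[np.ndarray], lrs: list[float]):
        self.m = [np.zeros_like(a) for a in arrays]
        self.v = [np.zeros_like(a) for a in arrays]
        self.lrs = lrs
        self.t = 0

    def step(self, arrays: list[np.ndarray], grads: list[np.ndarray]) -> list[np.ndarray]:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        out = []
        for i, (a, g) in enumerate(zip(arrays, grads)):
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
            mh = self.m[i] / (1 - b1 ** self.t)
            vh = self.v[i] / (1 - b2 ** self.t)
            out.append(a - self.lrs[i] * mh / (np.sqrt(vh) + eps))
        return out


def train(model: ODESystemSpec, obs: ObservationSet, config: PINNConfig,
          mode: str = "graybox") -> PINNResult:
    """Two-stage Adam training with optional self-adaptive ODE weights and
    L-BFGS refinement; returns the trained networks and parameter estimates."""
    prob = _Problem(model, obs, config, mode)
    S = model.n_states
    lam = AdaptiveWeights(lambda_ode=np.ones(S))
    lam_lr = config.lambda_lr if config.lambda_lr is not None else config.lr_main
    history: list[dict[str, float]] = []

    arrays = prob.parameter_arrays()
    n_main = 2 * len(prob.main.weights)
    lrs = [config.lr_main] * n_main
    if prob.aux is not None:
        lrs += [config.lr_aux] * (2 * len(prob.aux.weights))
    if prob.param_names:
        lrs += [config.lr_main]

    def loss_and_grads(arrays, stage):
        pv = [Var(a) for a in arrays]
        total, comp, ode_comps = prob.loss(pv, lam, stage)
        ad.backward(total)
        grads = [np.zeros_like(a) if v.grad is None else v.grad for a, v in zip(arrays, pv)]
        return total, comp, grads, [float(c.value) for c in ode_comps]

    stages = []
    if config.two_stage and config.iters_stage1 > 0:
        stages.append((1, config.iters_stage1))
    stages.append((2, config.iters_stage2))
    opt = _Adam(arrays, lrs)
    for stage, iters in stages:
        for it in range(iters):
            total, comp, grads, ode_vals = loss_and_grads(arrays, stage)
            if not np.isfinite(comp["total"]):
                raise RuntimeError(f"non-finite loss during stage {stage}: {comp}")
            arrays = opt.step(arrays, grads)
            if stage >= 2 and config.adaptive_weights and ode_vals:
                lam = adaptive_update(lam, ode_vals, lam_lr)
            if it % 100 == 0 or it == iters - 1:
                history.append({"stage": stage, "iter": it, **comp})
    prob.set_parameter_arrays(arrays)

    if config.iters_lbfgs > 0:
        shapes = [a.shape for a in arrays]
        sizes = [a.size for a in arrays]

        def unflatten(x):
            out, k = [], 0
            for sh, sz in zip(shapes, sizes):
                out.append(x[k:k + sz].reshape(sh))
                k += sz
            return out

        def fun(x):
            arrs = unflatten(x)
            total, comp, grads, _ = loss_and_grads(arrs, 2)
            return float(total.value), np.concatenate([g.ravel() for g in grads])

        x0 = np.concatenate([a.ravel() for a in arrays])
        res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                       options={"maxiter": config.iters_lbfgs, "maxcor": 50,
                                "ftol": 1e-18, "gtol": 1e-14})
        arrays = unflatten(res.x)
        prob.set_parameter_arrays(arrays)
        _, comp, _, _ = loss_and_grads(arrays, 2)
        history.append({"stage": 3, "iter": int(res.nit), **comp})

    params = prob.param_values(prob.p_raw) if prob.param_names else {}
    return PINNResult(model=model, config=config, main=prob.main, aux=prob.aux,
                      params=params, weights=lam, loss_history=history,
                      scales=prob.scales, aux_scales=prob.aux_scales,
                      omega=prob.omega, anchor_data=prob.anchor_data)


def evaluate_unknown_terms(result: PINNResult, t_grid) -> GrayBoxRecovery:
    """Dense unknown-term series for downstream symbolic distillation."""
    return result.recovery(t_grid)
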