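"""Synthetic data generation: forward trajectories, subsampling, noise.

Every experiment in this package runs on data manufactured here — a clean
forward solve of one of the benchmark models, an equispaced subsample of a
subset of states, and optionally uniform multiplicative noise
``y_noise = y·(1 + n·ξ)`` with ``ξ ~ U(−1, 1)``, the single noise mechanism
supported.  Trajectories are plain :class:`pandas.DataFrame` tables with a
``t`` column plus one column per state.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .models import ODESystemSpec

__all__ = ["ObservationSet", "simulate_forward", "subsample", "add_noise"]


@dataclass(frozen=True)
class ObservationSet:
    """Sampled (possibly noisy) time series of observed states."""

    times: np.ndarray
    values: np.ndarray  # shape (len(times), len(observed_states))
    observed_states: tuple[str, ...]
    noise_level: float = 0.0
    seed: int | None = None

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        v = np.atleast_2d(np.asarray(self.values, dtype=float))
        if v.shape[0] != t.size:
            raise ValueError("values must align with times")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("observation times must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("observation values must be finite")
        if self.noise_level < 0:
            raise ValueError("noise_level must be non-negative")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "observed_states", tuple(self.observed_states))

    def __len__(self) -> int:
        return self.times.size

    def column(self, state: str) -> np.ndarray:
        return self.values[:, self.observed_states.index(state)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"t": self.times})
        for j, s in enumerate(self.observed_states):
            df[s] = self.values[:, j]
        return df

    def write_csv(self, path: str | Path) -> None:
        """CSV with a sidecar ``<path>.meta.json`` recording noise and seed."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False)
        meta = {"observed_states": list(self.observed_states),
                "noise_level": self.noise_level, "seed": self.seed}
        path.with_suffix(path.suffix + ".meta.json").write_text(json.dumps(meta))

    @classmethod
    def read_csv(cls, path: str | Path) -> "ObservationSet":
        path = Path(path)
        df = pd.read_csv(path)
        meta_path = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        states = tuple(c for c in df.columns if c != "t")
        return cls(df["t"].to_numpy(), df[list(states)].to_numpy(), states,
                   noise_level=meta.get("noise_level", 0.0), seed=meta.get("seed"))


def simulate_forward(model: ODESystemSpec, params=None, t_grid=None,
                     method: str = "adaptive-rk", rtol: float = 1e-10,
                     atol: float = 1e-12, **solver_kwargs) -> pd.DataFrame:
    """Forward-solve a fully specified model on ``t_grid``.

    ``method`` selects the integrator: ``"adaptive-rk"`` uses an adaptive
    Runge–Kutta scheme (``scipy.solve_ivp`` RK45 at tight tolerance) while
    ``"xtfc-forward"`` uses the random-projection collocation solver, so the
    two routes are mutually independent checks.
    """
    if model.removed:
        raise ValueError("cannot forward-solve a gray-box spec with open slots; "
                         "fill the slots or use the base model")
    p = params if params is not None else model.params
    if t_grid is None:
        t_grid = np.linspace(*model.t_span, 1001)
    t_grid = np.asarray(t_grid, dtype=float)

    if method == "adaptive-rk":
        sol = solve_ivp(lambda t, y: model.rhs_full(t, y, p), (t_grid[0], t_grid[-1]),
                        model.initial_conditions, t_eval=t_grid, method="RK45",
                        rtol=rtol, atol=atol, dense_output=False)
        if not sol.success:
            raise RuntimeError(f"forward solve failed: {sol.message}")
        Y = sol.y.T
    elif method == "xtfc-forward":
        from .xtfc import XTFCConfig, solve_decomposed  # local import avoids a cycle

        cfg = solver_kwargs.pop("config", None)
        if cfg is None:
            span = t_grid[-1] - t_grid[0]
            cfg = XTFCConfig(N=40, L=60, t_step=span / max(1, int(round(span / 10.0))),
                             seed=solver_kwargs.pop("seed", 0))
        rec = solve_decomposed(model, obs=None, config=cfg, mode="forward", t_eval=t_grid)
        Y = rec.trajectory[list(model.state_names)].to_numpy()
    else:
        raise ValueError(f"unknown forward method {method!r}")

    df = pd.DataFrame({"t": t_grid})
    for j, s in enumerate(model.state_names):
        df[s] = Y[:, j]
    return df


def subsample(trajectory: pd.DataFrame, M: int,
              states: Sequence[str] | None = None,
              times: Sequence[float] | None = None) -> ObservationSet:
    """Pick ``M`` equispaced rows (including t0) of the requested states.

    Explicit ``times`` override the equispaced rule; they must be members of
    the trajectory grid.
    """
    if M < 2:
        raise ValueError("need at least two observation points")
    t = trajectory["t"].to_numpy()
    if states is None:
        states = [c for c in trajectory.columns if c != "t"]
    if times is None:
        if M > t.size:
            raise ValueError(f"M={M} exceeds the trajectory grid ({t.size} points)")
        idx = np.round(np.linspace(0, t.size - 1, M)).astype(int)
    else:
        idx = np.searchsorted(t, np.asarray(times, dtype=float))
        if not np.allclose(t[idx], times, rtol=0, atol=1e-9 * max(1.0, t[-1])):
            raise ValueError("requested times are not on the trajectory grid")
    vals = trajectory[list(states)].to_numpy()[idx]
    return ObservationSet(t[idx], vals, tuple(states))


def add_noise(obs: ObservationSet, n: float, seed: int | None = None) -> ObservationSet:
    """Perturb each value to ``y·(1 + n·ξ)``, ξ i.i.d. uniform on (−1, 1)."""
    if n < 0:
        raise ValueError("noise fraction must be non-negative")
    if n == 0:
        return replace(obs, noise_level=0.0, seed=seed)
    rng = np.random.default_rng(seed)
    xi = rng.uniform(-1.0, 1.0, size=obs.values.shape)
    return ObservationSet(obs.times, obs.values * (1.0 + n * xi),
                          obs.observed_states, noise_level=n, seed=seed)
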