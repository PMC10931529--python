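"""Symbolic distillation of recovered unknown-term series.

A genetic-programming engine evolves expression trees over the designated
state variables with binary operators {+, −, ×} and real constants, then a
per-complexity Pareto front (best loss at each tree size) is scored by the
negative slope of log-loss versus complexity and a single candidate is
selected — either the highest score among expressions whose loss is within
1.5× of the best ("score band"), or the first expression beyond which loss
improvement per added node stagnates ("loss plateau").  Constants are
refined by least squares after the genetic search proposes a structure,
which is what makes the printed coefficient precision attainable.

For noisy targets an L1 fitness with a complexity regulariser scaled by the
reciprocal noise scale is available (``loss_kind="l1_noise"``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import sympy

from .recovery import GrayBoxRecovery

__all__ = [
    "SRConfig",
    "SymbolicExpressionRecord",
    "build_regression_table",
    "evolve",
    "score_front",
    "select_candidate",
    "noisy_loss",
    "distill",
    "DistillationReport",
]

# features used for each benchmark's unknown terms
SLOT_FEATURES = {
    ("pk", "h"): ("G", "B"),
    ("ultradian", "f"): ("Ip", "Ii"),
    ("ultradian", "g"): ("Ip", "Ii"),
}


# ---------------------------------------------------------------------------
# expression trees


class Node:
    """Expression tree node: an operator with children, a variable, or a constant."""

    __slots__ = ("op", "children", "value")

    def __init__(self, op: str, children: tuple = (), value: float | int | None = None):
        self.op = op  # 'add' | 'sub' | 'mul' | 'var' | 'const'
        self.children = children
        self.value = value

    def copy(self) -> "Node":
        return Node(self.op, tuple(c.copy() for c in self.children), self.value)

    def complexity(self) -> int:
        return 1 + sum(c.complexity() for c in self.children)

    def evaluate(self, X: np.ndarray, consts: list[float] | None = None,
                 _idx: list[int] | None = None) -> np.ndarray:
        if self.op == "var":
            return X[:, self.value]
        if self.op == "const":
            if consts is not None:
                v = consts[_idx[0]]
                _idx[0] += 1
                return np.full(X.shape[0], v)
            return np.full(X.shape[0], self.value)
        a = self.children[0].evaluate(X, consts, _idx)
        b = self.children[1].evaluate(X, consts, _idx)
        if self.op == "add":
            return a + b
        if self.op == "sub":
            return a - b
        return a * b

    def constants(self) -> list[float]:
        out = []
        if self.op == "const":
            out.append(float(self.value))
        for c in self.children:
            out.extend(c.constants())
        return out

    def with_constants(self, consts: Sequence[float]) -> "Node":
        it = iter(consts)

        def rebuild(n: Node) -> Node:
            if n.op == "const":
                return Node("const", value=float(next(it)))
            return Node(n.op, tuple(rebuild(c) for c in n.children), n.value)

        return rebuild(self)

    def to_sympy(self, names: Sequence[str]):
        if self.op == "var":
            return sympy.Symbol(names[self.value])
        if self.op == "const":
            return sympy.Float(self.value)
        a = self.children[0].to_sympy(names)
        b = self.children[1].to_sympy(names)
        return {"add": a + b, "sub": a - b, "mul": a * b}[self.op]

    def infix(self, names: Sequence[str]) -> str:
        if self.op == "var":
            return names[self.value]
        if self.op == "const":
            return f"{self.value:.6g}"
        a = self.children[0].infix(names)
        b = self.children[1].infix(names)
        sym = {"add": "+", "sub": "-", "mul": "*"}[self.op]
        return f"({a} {sym} {b})"


@dataclass
class SymbolicExpressionRecord:
    """A Pareto-front entry: expression tree, size, fit loss, and score."""

    tree: Node
    complexity: int
    loss: float
    score: float = 0.0
    variable_names: tuple[str, ...] = ()

    def expression(self) -> str:
        return self.tree.infix(self.variable_names)

    def sympy_expr(self):
        return sympy.expand(self.tree.to_sympy(self.variable_names))

    def linear_coefficients(self) -> dict[str, float]:
        """Coefficients of each variable in the expanded expression
        (only meaningful when the expression is (close to) linear)."""
        expr = self.sympy_expr()
        coeffs = expr.as_coefficients_dict()
        out = {}
        for name in self.variable_names:
            out[name] = float(coeffs.get(sympy.Symbol(name), 0))
        return out

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.tree.evaluate(np.asarray(X, dtype=float))


@dataclass(frozen=True)
class SRConfig:
    operators: tuple[str, ...] = ("add", "sub", "mul")
    population_size: int = 300
    generations: int = 30
    parsimony: float = 1e-8
    loss_kind: str = "mse"  # 'mse' | 'rmse' | 'l1_noise'
    noise_scale: float = 1.0
    max_complexity: int = 15
    tournament: int = 5
    p_crossover: float = 0.7
    p_mutation: float = 0.25
    anneal: bool = False
    selection_rule: str = "score_band"
    plateau_threshold: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.population_size < 2:
            raise ValueError("population_size must be >= 2")
        if self.loss_kind == "l1_noise" and not self.noise_scale > 0:
            raise ValueError("noise scale s must be positive for the L1 noisy loss")
        bad = set(self.operators) - {"add", "sub", "mul"}
        if bad:
            raise ValueError(f"unsupported operators {bad}; only +, -, x are allowed")


# ---------------------------------------------------------------------------
# losses


def noisy_loss(predicted, actual, s: float, complexity: int = 0,
               regularize: bool = True) -> float:
    """Sum of absolute residuals plus a complexity penalty scaled by 1/s.

    The regulariser reads the noise-scaled term as (1/s)·(tree node count):
    noisier targets push harder toward compact expressions.  Disable with
    ``regularize=False``.
    """
    if s <= 0:
        raise ValueError("noise scale s must be positive")
    base = float(np.sum(np.abs(np.asarray(actual) - np.asarray(predicted))))
    return base + (complexity / s if regularize else 0.0)


def _fit_loss(pred: np.ndarray, y: np.ndarray, kind: str, s: float,
              complexity: int) -> float:
    err = y - pred
    if kind == "mse":
        return float(np.mean(err ** 2))
    if kind == "rmse":
        return float(np.sqrt(np.mean(err ** 2)))
    if kind == "l1_noise":
        return noisy_loss(pred, y, s, complexity)
    raise ValueError(f"unknown loss kind {kind!r}")


# ---------------------------------------------------------------------------
# regression table


def build_regression_table(recovery: GrayBoxRecovery, trajectories: pd.DataFrame,
                           slot: str, features: Sequence[str] | None = None,
                           ) -> tuple[pd.DataFrame, np.ndarray]:
    """Feature table (state values) and target (recovered term series).

    Rows are time points shared by the recovery and the trajectory table;
    features default to the benchmark's designated variables.
    """
    t_rec = recovery.times
    t_tr = trajectories["t"].to_numpy()
    if t_rec.size != t_tr.size or not np.allclose(t_rec, t_tr, atol=1e-9 * max(1, t_tr[-1])):
        raise ValueError("recovery and trajectories must share a time grid")
    if features is None:
        features = SLOT_FEATURES.get((recovery.model_name, slot))
        if features is None:
            raise ValueError(f"no default feature set for {recovery.model_name}/{slot}")
    X = trajectories[list(features)].copy()
    y = np.asarray(recovery.terms[slot], dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# genetic programming engine


def _random_tree(rng, n_vars: int, ops: Sequence[str], depth: int,
                 const_sd: float) -> Node:
    if depth == 0 or rng.random() < 0.3:
        if rng.random() < 0.7:
            return Node("var", value=int(rng.integers(n_vars)))
        return Node("const", value=float(rng.normal(0, const_sd)))
    op = ops[int(rng.integers(len(ops)))]
    return Node(op, (_random_tree(rng, n_vars, ops, depth - 1, const_sd),
                     _random_tree(rng, n_vars, ops, depth - 1, const_sd)))


def _all_nodes(tree: Node, path=()) -> list[tuple]:
    out = [(path, tree)]
    for i, c in enumerate(tree.children):
        out.extend(_all_nodes(c, path + (i,)))
    return out


def _replace_at(tree: Node, path: tuple, sub: Node) -> Node:
    if not path:
        return sub
    children = list(tree.children)
    children[path[0]] = _replace_at(children[path[0]], path[1:], sub)
    return Node(tree.op, tuple(children), tree.value)


def _crossover(rng, a: Node, b: Node) -> Node:
    nodes_a = _all_nodes(a)
    nodes_b = _all_nodes(b)
    pa = nodes_a[int(rng.integers(len(nodes_a)))][0]
    sb = nodes_b[int(rng.integers(len(nodes_b)))][1]
    return _replace_at(a, pa, sb.copy())


def _mutate(rng, tree: Node, n_vars: int, ops: Sequence[str], const_sd: float) -> Node:
    nodes = _all_nodes(tree)
    path, node = nodes[int(rng.integers(len(nodes)))]
    r = rng.random()
    if r < 0.4:  # subtree replacement
        return _replace_at(tree, path, _random_tree(rng, n_vars, ops, 2, const_sd))
    if r < 0.7 and node.op == "const":  # constant jitter
        return _replace_at(tree, path,
                           Node("const", value=node.value + rng.normal(0, 0.3 * (abs(node.value) + 0.1))))
    if node.op in ("add", "sub", "mul"):  # operator swap
        return _replace_at(tree, path, Node(ops[int(rng.integers(len(ops)))], node.children, None))
    # terminal swap
    return _replace_at(tree, path, _random_tree(rng, n_vars, ops, 0, const_sd))


def _refine_constants(tree: Node, X: np.ndarray, y: np.ndarray,
                      kind: str, s: float) -> tuple[Node, float]:
    """Least-squares polish of the tree's constants (structure fixed)."""
    from scipy.optimize import least_squares

    c0 = tree.constants()
    comp = tree.complexity()
    if not c0:
        pred = tree.evaluate(X)
        return tree, _fit_loss(pred, y, kind, s, comp)

    def resid(c):
        return tree.evaluate(X, consts=list(c), _idx=[0]) - y

    try:
        sol = least_squares(resid, c0, method="lm", max_nfev=200)
        refined = tree.with_constants(sol.x)
        loss = _fit_loss(refined.evaluate(X), y, kind, s, comp)
        if np.isfinite(loss):
            return refined, loss
    except Exception:
        pass
    return tree, _fit_loss(tree.evaluate(X), y, kind, s, comp)


def evolve(table: tuple[pd.DataFrame, np.ndarray] | pd.DataFrame,
           config: SRConfig, target: np.ndarray | None = None,
           ) -> list[SymbolicExpressionRecord]:
    """Run the GP search; return the per-complexity Pareto front.

    ``table`` is either the (features, target) pair from
    :func:`build_regression_table` or a feature frame with ``target`` given
    separately.  The front holds the best-loss expression at each complexity
    (constants refined), loss non-increasing in complexity, deterministic
    for a given seed.
    """
    if isinstance(table, tuple):
        Xf, y = table
    else:
        Xf, y = table, target
    if Xf is None or len(Xf) == 0:
        raise ValueError("empty regression table")
    names = tuple(Xf.columns)
    X = Xf.to_numpy(dtype=float)
    y = np.asarray(y, dtype=float)

    rng = np.random.default_rng(config.seed)
    ops = list(config.operators)
    n_vars = X.shape[1]
    const_sd = max(float(np.std(y)), 1e-3)

    # seed the population with generic simple structures (bare variables,
    # scaled variables, pairwise scaled sums) so the search starts from the
    # same primitives a GP library's ramped initialisation would produce;
    # their constants are free and must still win on fitness
    def _cv(i):
        return Node("mul", (Node("const", value=float(rng.normal(0, const_sd + 1.0))),
                            Node("var", value=i)))

    pop: list[Node] = []
    for i in range(n_vars):
        pop.append(Node("var", value=i))
        pop.append(_cv(i))
        for j in range(n_vars):
            if i != j and "add" in ops:
                pop.append(Node("add", (_cv(i), _cv(j))))
    pop = pop[: config.population_size]
    while len(pop) < config.population_size:
        pop.append(_random_tree(rng, n_vars, ops, 1 + len(pop) % 3, const_sd))

    def raw_fitness(tree: Node) -> float:
        comp = tree.complexity()
        if comp > config.max_complexity:
            return float("inf")
        with np.errstate(all="ignore"):
            pred = tree.evaluate(X)
        if not np.all(np.isfinite(pred)):
            return float("inf")
        return _fit_loss(pred, y, config.loss_kind, config.noise_scale, comp) \
            + config.parsimony * comp

    fitness = [raw_fitness(t) for t in pop]

    # Pareto hall of fame: complexity -> (loss, tree) with refined constants
    front: dict[int, tuple[float, Node]] = {}

    def consider(tree: Node, fit: float):
        if not np.isfinite(fit):
            return
        comp = tree.complexity()
        if comp > config.max_complexity:
            return
        best = front.get(comp)
        if best is None or fit < best[0] * (1 - 1e-12):
            refined, loss = _refine_constants(tree, X, y, config.loss_kind,
                                              config.noise_scale)
            if best is None or loss < best[0]:
                front[comp] = (loss, refined)

    for t, f in zip(pop, fitness):
        consider(t, f)

    temperature = 1.0
    for gen in range(config.generations):
        new_pop: list[Node] = []
        new_fit: list[float] = []
        best_i = int(np.argmin(fitness))  # elitism
        new_pop.append(pop[best_i].copy())
        new_fit.append(fitness[best_i])
        while len(new_pop) < config.population_size:
            idx = rng.integers(len(pop), size=config.tournament)
            parent_i = int(idx[np.argmin([fitness[i] for i in idx])])
            child = pop[parent_i].copy()
            r = rng.random()
            if r < config.p_crossover:
                idx2 = rng.integers(len(pop), size=config.tournament)
                other_i = int(idx2[np.argmin([fitness[i] for i in idx2])])
                child = _crossover(rng, child, pop[other_i])
            elif r < config.p_crossover + config.p_mutation:
                child = _mutate(rng, child, n_vars, ops, const_sd)
            f_child = raw_fitness(child)
            if config.anneal and np.isfinite(f_child) and f_child > fitness[parent_i]:
                # simulated-annealing acceptance of worsening offspring
                accept = math.exp(-(f_child - fitness[parent_i])
                                  / max(temperature * abs(fitness[parent_i]) + 1e-12, 1e-12))
                if rng.random() > accept:
                    child, f_child = pop[parent_i].copy(), fitness[parent_i]
            new_pop.append(child)
            new_fit.append(f_child)
        pop, fitness = new_pop, new_fit
        for t, f in zip(pop, fitness):
            consider(t, f)
        temperature *= 0.9

    if not front:
        raise RuntimeError("all candidate expressions evaluated to NaN")

    # enforce loss non-increasing in complexity
    records: list[SymbolicExpressionRecord] = []
    best_so_far = float("inf")
    for comp in sorted(front):
        loss, tree = front[comp]
        if loss < best_so_far:
            best_so_far = loss
            records.append(SymbolicExpressionRecord(
                tree=tree, complexity=comp, loss=loss, variable_names=names))
    return score_front(records)


def score_front(front: list[SymbolicExpressionRecord]) -> list[SymbolicExpressionRecord]:
    """Score = −Δ(log loss)/Δ(complexity) along the complexity-sorted front."""
    floor = 1e-300
    out = []
    for i, rec in enumerate(front):
        if i == 0:
            score = 0.0
        else:
            prev = front[i - 1]
            dloss = math.log(max(rec.loss, floor)) - math.log(max(prev.loss, floor))
            dcomp = rec.complexity - prev.complexity
            score = -dloss / dcomp if dcomp > 0 else 0.0
        out.append(replace(rec, score=score))
    return out


def select_candidate(front: list[SymbolicExpressionRecord],
                     rule: str = "score_band",
                     plateau_threshold: float = 0.05) -> SymbolicExpressionRecord:
    """Pick one expression from a scored front.

    ``score_band``: highest score among records with loss ≤ 1.5× the minimum
    (ties broken toward lower complexity).  ``loss_plateau``: the record
    after which relative loss improvement per added node falls below the
    threshold.
    """
    if not front:
        raise ValueError("empty front")
    front = sorted(front, key=lambda r: r.complexity)
    if len(front) == 1:
        return front[0]
    if rule == "score_band":
        min_loss = min(r.loss for r in front)
        band = [r for r in front if r.loss <= 1.5 * min_loss]
        return max(band, key=lambda r: (r.score, -r.complexity))
    if rule == "loss_plateau":
        chosen = front[0]
        for prev, nxt in zip(front, front[1:]):
            rel_gain = (prev.loss - nxt.loss) / max(prev.loss, 1e-300)
            per_node = rel_gain / max(nxt.complexity - prev.complexity, 1)
            if per_node < plateau_threshold:
                return prev
            chosen = nxt
        return chosen
    raise ValueError(f"unknown selection rule {rule!r}")


# ---------------------------------------------------------------------------
# end-to-end distillation


@dataclass
class DistillationReport:
    slot: str
    selected: SymbolicExpressionRecord
    front: list[SymbolicExpressionRecord]

    def front_table(self) -> pd.DataFrame:
        return pd.DataFrame([{"complexity": r.complexity, "loss": r.loss,
                              "score": r.score, "expression": r.expression()}
                             for r in self.front])


def distill(recovery: GrayBoxRecovery, trajectories: pd.DataFrame,
            config: SRConfig, slot: str | None = None,
            features: Sequence[str] | None = None,
            max_rows: int = 400) -> DistillationReport:
    """Full pipeline: regression table → GP evolution → scoring → selection.

    Long series are thinned to ``max_rows`` equispaced rows before the GP
    search (the fit is over states, not time, so thinning loses little).
    """
    if slot is None:
        if len(recovery.terms) != 1:
            raise ValueError("specify a slot when the recovery holds several terms")
        slot = next(iter(recovery.terms))
    Xf, y = build_regression_table(recovery, trajectories, slot, features)
    if len(Xf) > max_rows:
        idx = np.round(np.linspace(0, len(Xf) - 1, max_rows)).astype(int)
        Xf, y = Xf.iloc[idx], y[idx]
    front = evolve((Xf, y), config)
    selected = select_candidate(front, config.selection_rule, config.plateau_threshold)
    return DistillationReport(slot=slot, selected=selected, front=front)
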