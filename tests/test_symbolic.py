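"""Genetic-programming symbolic regression: trees, fronts, scoring, selection."""

import numpy as np
import pandas as pd
import pytest

from grayode.recovery import GrayBoxRecovery
from grayode.symbolic import (Node, SRConfig, SymbolicExpressionRecord,
                              build_regression_table, distill, evolve,
                              noisy_loss, score_front, select_candidate)


def _record(complexity, loss, score=0.0):
    return SymbolicExpressionRecord(tree=Node("var", value=0), complexity=complexity,
                                    loss=loss, score=score, variable_names=("x",))


def _linear_table(n=120, seed=0, a=0.72, b=-0.15, noise=0.0):
    rng = np.random.default_rng(seed)
    G = np.exp(-0.72 * np.linspace(0, 5, n)) * 0.1
    B = 0.9 * G + 0.01 * rng.normal(size=n)
    y = a * G + b * B + noise * rng.normal(size=n)
    return pd.DataFrame({"G": G, "B": B}), y


class TestScore:
    def test_order_of_magnitude_drop(self):
        front = score_front([_record(1, 1.0), _record(2, 0.1)])
        assert front[0].score == 0.0
        assert front[1].score == pytest.approx(np.log(10))

    def test_plateau_scores_zero(self):
        front = score_front([_record(1, 0.5), _record(3, 0.5)])
        assert front[1].score == pytest.approx(0.0)

    def test_halving_gives_constant_log2(self):
        front = score_front([_record(c, 2.0 ** -c) for c in (1, 2, 3)])
        assert all(r.score == pytest.approx(np.log(2)) for r in front[1:])


class TestSelection:
    def test_single_record(self):
        rec = _record(3, 0.5)
        assert select_candidate([rec]) is rec

    def test_score_band_example(self):
        # band = records with loss <= 1.5 * 0.009; 1.0 excluded, both small in
        front = score_front([_record(1, 1.0), _record(5, 0.01), _record(9, 0.009)])
        chosen = select_candidate(front)
        assert chosen.complexity == 5  # highest score within the band

    def test_selection_invariant_to_front_order(self):
        front = score_front([_record(1, 1.0), _record(5, 0.01), _record(9, 0.009)])
        shuffled = [front[2], front[0], front[1]]
        assert select_candidate(shuffled).complexity == \
            select_candidate(front).complexity

    def test_loss_plateau_rule(self):
        front = score_front([_record(1, 1.0), _record(5, 0.01), _record(9, 0.0099)])
        chosen = select_candidate(front, rule="loss_plateau")
        assert chosen.complexity == 5

    def test_empty_front_rejected(self):
        with pytest.raises(ValueError):
            select_candidate([])


class TestNoisyLoss:
    def test_zero_for_perfect_fit(self):
        assert noisy_loss([1.0, 2.0], [1.0, 2.0], s=0.5, regularize=False) == 0.0

    def test_absolute_residual_sum(self):
        assert noisy_loss([0.0, 0.0], [1.0, -2.0], s=1.0, regularize=False) == 3.0

    def test_regulariser_monotone_in_scale(self):
        losses = [noisy_loss([0.0], [0.0], s=s, complexity=5) for s in (0.5, 1.0, 2.0)]
        assert losses[0] > losses[1] > losses[2]

    def test_invalid_scale_rejected(self):
        with pytest.raises(ValueError):
            noisy_loss([0.0], [0.0], s=-1.0)


class TestRegressionTable:
    def _recovery(self, n=50):
        t = np.linspace(0, 50, n)
        G = 0.1 * np.exp(-0.72 * t)
        B = 0.72 * 0.1 / 0.57 * (np.exp(-0.15 * t) - np.exp(-0.72 * t))
        traj = pd.DataFrame({"t": t, "B": B, "G": G, "U": 0.1 - B - G})
        rec = GrayBoxRecovery(model_name="pk", trajectory=traj,
                              terms={"h": 0.72 * G - 0.15 * B})
        return rec, traj

    def test_rows_satisfy_true_relation(self):
        rec, traj = self._recovery()
        X, y = build_regression_table(rec, traj, "h")
        assert list(X.columns) == ["G", "B"]
        assert np.allclose(y, 0.72 * X["G"] - 0.15 * X["B"])

    def test_grid_mismatch_rejected(self):
        rec, traj = self._recovery()
        other = traj.copy()
        other["t"] = other["t"] + 1.0
        with pytest.raises(ValueError):
            build_regression_table(rec, other, "h")

    def test_constant_target_column(self):
        rec, traj = self._recovery()
        rec.terms["h"] = np.full(len(traj), 3.0)
        _, y = build_regression_table(rec, traj, "h")
        assert np.all(y == 3.0)


class TestEvolve:
    def test_identity_target_found_at_complexity_one(self):
        X = pd.DataFrame({"a": np.linspace(-1, 1, 40), "b": np.random.default_rng(0).normal(size=40)})
        front = evolve((X, X["a"].to_numpy()), SRConfig(population_size=60, generations=5, seed=0))
        assert front[0].complexity == 1 and front[0].loss < 1e-20

    @pytest.mark.parametrize("seed", range(5))
    def test_linear_form_recovered_exactly(self, seed):
        """Noiseless linear target: selected coefficients within 1e-3."""
        table = _linear_table(seed=seed)
        front = evolve(table, SRConfig(population_size=150, generations=15, seed=seed))
        sel = select_candidate(front)
        c = sel.linear_coefficients()
        assert c["G"] == pytest.approx(0.72, abs=1e-3)
        assert c["B"] == pytest.approx(-0.15, abs=1e-3)

    def test_front_loss_non_increasing_and_positive(self):
        table = _linear_table(noise=0.001)
        front = evolve(table, SRConfig(population_size=100, generations=10, seed=2))
        losses = [r.loss for r in front]
        assert all(a >= b for a, b in zip(losses, losses[1:]))
        assert all(l > 0 for l in losses)

    def test_deterministic_given_seed(self):
        table = _linear_table()
        cfg = SRConfig(population_size=80, generations=8, seed=5)
        f1 = evolve(table, cfg)
        f2 = evolve(table, cfg)
        assert [r.expression() for r in f1] == [r.expression() for r in f2]

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            evolve((pd.DataFrame({"x": []}), np.array([])), SRConfig(seed=0))

    def test_annealed_engine_still_recovers(self):
        table = _linear_table()
        front = evolve(table, SRConfig(population_size=150, generations=15,
                                       seed=1, anneal=True))
        c = select_candidate(front).linear_coefficients()
        assert c["G"] == pytest.approx(0.72, abs=1e-2)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            SRConfig(population_size=1)
        with pytest.raises(ValueError):
            SRConfig(loss_kind="l1_noise", noise_scale=0.0)
        with pytest.raises(ValueError):
            SRConfig(operators=("add", "div"))


class TestDistill:
    def test_end_to_end_on_synthetic_recovery(self):
        t = np.linspace(0, 50, 200)
        G = 0.1 * np.exp(-0.72 * t)
        B = 0.72 * 0.1 / 0.57 * (np.exp(-0.15 * t) - np.exp(-0.72 * t))
        traj = pd.DataFrame({"t": t, "B": B, "G": G, "U": 0.1 - B - G})
        rec = GrayBoxRecovery(model_name="pk", trajectory=traj,
                              terms={"h": 0.72 * G - 0.15 * B})
        report = distill(rec, traj, SRConfig(population_size=120, generations=12, seed=0))
        c = report.selected.linear_coefficients()
        assert c["G"] == pytest.approx(0.72, abs=1e-3)
        assert c["B"] == pytest.approx(-0.15, abs=1e-3)
        table = report.front_table()
        assert {"complexity", "loss", "score", "expression"} <= set(table.columns)
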