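"""Loss functions, optimizer/freeze interaction, seeded training loop."""

from __future__ import annotations

import numpy as np
import pytest

from ethoseg.nn.models import (
    ArchitectureSpec,
    FreezePlan,
    Scenario,
    apply_freeze_plan,
    build_model,
    clone_model,
)
from ethoseg.training import (
    TrainConfig,
    TrainingDivergedError,
    cross_entropy_loss,
    generalized_dice_loss,
    loss_and_dlogits,
    repeat_runs,
    train,
)
from ethoseg.windows import WindowBatch


def _gdl_oracle(r: np.ndarray, p: np.ndarray, eps: float = 1e-6) -> float:
    """Independent direct-sum evaluation of the Generalized Dice formula."""
    num = den = 0.0
    for cls in range(r.shape[1]):
        r_sum = sum(r[n, cls] for n in range(r.shape[0]))
        if r_sum == 0:
            continue
        w = 1.0 / (r_sum + eps) ** 2
        num += w * sum(r[n, cls] * p[n, cls] for n in range(r.shape[0]))
        den += w * sum(r[n, cls] + p[n, cls] for n in range(r.shape[0]))
    return 1.0 - 2.0 * num / den


class TestGeneralizedDice:
    def test_perfect_prediction_is_zero(self):
        r = np.eye(4)[np.array([0, 1, 2, 3, 0, 1])]
        assert generalized_dice_loss(r, r) == pytest.approx(0.0, abs=1e-4)

    def test_balanced_uniform_probs(self):
        """Two balanced classes with uniform 0.5 probabilities: the
        inverse-square weights are equal and the formula reduces to 1/2."""
        n = 20
        r = np.zeros((n, 2))
        r[: n // 2, 0] = 1
        r[n // 2:, 1] = 1
        p = np.full((n, 2), 0.5)
        val = generalized_dice_loss(r, p)
        assert val == pytest.approx(0.5, abs=1e-6)
        assert val == pytest.approx(_gdl_oracle(r, p), abs=1e-12)

    def test_absent_class_keeps_loss_finite(self):
        r = np.zeros((10, 3))
        r[:, 0] = 1  # classes 1, 2 absent
        p = np.full((10, 3), 1.0 / 3)
        val = generalized_dice_loss(r, p)
        assert np.isfinite(val)
        assert 0.0 <= val <= 1.0

    def test_matches_direct_sum_oracle_on_random_inputs(self, rng):
        for _ in range(20):
            n, c = int(rng.integers(4, 40)), int(rng.integers(2, 6))
            r = np.eye(c)[rng.integers(0, c, n)]
            p = rng.dirichlet(np.ones(c), size=n)
            assert generalized_dice_loss(r, p) == pytest.approx(
                _gdl_oracle(r, p), abs=1e-12)

    def test_bounds_on_distribution_valued_probs(self, rng):
        for _ in range(50):
            n, c = int(rng.integers(2, 30)), int(rng.integers(2, 8))
            r = np.eye(c)[rng.integers(0, c, n)]
            p = rng.dirichlet(np.full(c, 0.3), size=n)
            val = generalized_dice_loss(r, p)
            assert 0.0 <= val <= 1.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            generalized_dice_loss(np.zeros((4, 3)), np.zeros((4, 2)))


class TestCrossEntropy:
    def test_perfect_prediction_near_zero(self):
        r = np.eye(3)[np.array([0, 1, 2])]
        assert cross_entropy_loss(r, r) == pytest.approx(0.0, abs=1e-9)

    def test_uniform_probs_log_c(self):
        r = np.eye(4)[np.array([0, 1, 2, 3])]
        p = np.full((4, 4), 0.25)
        assert cross_entropy_loss(r, p) == pytest.approx(np.log(4), abs=1e-9)


def _toy_batch(seed: int, n: int = 48, ws: int = 16, c: int = 2) -> WindowBatch:
    """Linearly separable 2-class task: the sign of channel 0 is the class.
    Labels are piecewise-constant in blocks of 4 samples, like behavior
    bouts."""
    rng = np.random.default_rng(seed)
    labels = np.repeat(rng.integers(0, c, (n, ws // 4)), 4, axis=1)
    inputs = rng.normal(0, 0.1, (n, 1, ws)).astype(np.float32)
    inputs[:, 0] += np.where(labels == 0, -1.0, 1.0)
    targets = np.zeros((n, ws, c), dtype=np.float32)
    for i in range(n):
        targets[i, np.arange(ws), labels[i]] = 1.0
    return WindowBatch(inputs=inputs, targets=targets)


def _toy_model(seed: int = 0):
    return build_model(ArchitectureSpec("vnet", 16, 1, 2, 2), seed=seed)


class TestTrainingLoop:
    def test_loss_decreases_on_separable_task(self):
        model = _toy_model(1)
        cfg = TrainConfig(epochs=10, batch_size=16, learning_rate=1e-2,
                          loss="gdl", seed=0)
        model, record = train(model, lambda e: _toy_batch(100 + e),
                              _toy_batch(999), cfg)
        assert record.train_loss[record.best_epoch] < record.train_loss[0]
        assert record.best_val_metric > 70.0  # well above 2-class chance

    def test_zero_learning_rate_changes_nothing(self):
        model = _toy_model(2)
        h0 = model.weights_hash()
        cfg = TrainConfig(epochs=2, batch_size=16, learning_rate=0.0, seed=0)
        model, record = train(model, lambda e: _toy_batch(e), _toy_batch(9), cfg)
        assert model.weights_hash() == h0
        assert record.val_metric[0] == record.val_metric[1]

    def test_identical_seed_gives_identical_curves(self):
        curves = []
        for _ in range(2):
            model = _toy_model(3)
            cfg = TrainConfig(epochs=3, batch_size=16, learning_rate=1e-3,
                              seed=7)
            _, record = train(model, lambda e: _toy_batch(e), _toy_batch(9), cfg)
            curves.append((record.train_loss, record.val_metric))
        assert curves[0] == curves[1]

    def test_best_weights_reloadable(self):
        model = _toy_model(4)
        cfg = TrainConfig(epochs=3, batch_size=16, learning_rate=1e-2, seed=1)
        model, record = train(model, lambda e: _toy_batch(e), _toy_batch(9), cfg)
        twin = _toy_model(99)
        twin.set_weights(record.best_weights)
        assert twin.weights_hash() == model.weights_hash()

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_diverged_training_reports_epoch(self):
        model = _toy_model(5)
        bad = _toy_batch(0)
        bad.inputs[:] = np.inf
        cfg = TrainConfig(epochs=1, batch_size=16, learning_rate=1e-3, seed=0)
        with pytest.raises(TrainingDivergedError, match="epoch 0"):
            train(model, lambda e: bad, bad, cfg)


class TestFreezeInteraction:
    @pytest.mark.parametrize("scenario", [Scenario.TL_FREEZE_ENCODER,
                                          Scenario.TL_FREEZE_DECODER,
                                          Scenario.TL_HEAD_ONLY])
    def test_frozen_groups_bit_identical_after_training(self, scenario):
        source = _toy_model(6)
        model = clone_model(source)
        plan = FreezePlan.for_model(scenario, model)
        apply_freeze_plan(model, plan)
        before = {g: model.weights_hash(g) for g in model.groups}
        cfg = TrainConfig(epochs=2, batch_size=16, learning_rate=1e-2, seed=2)
        model, _ = train(model, lambda e: _toy_batch(e), _toy_batch(9), cfg)
        for g, frozen_ok in plan.trainable.items():
            if not frozen_ok:
                assert model.weights_hash(g) == before[g], g

    def test_head_only_updates_exactly_head_arrays(self):
        model = clone_model(_toy_model(7))
        apply_freeze_plan(model, FreezePlan.for_model(Scenario.TL_HEAD_ONLY,
                                                      model))
        before = model.get_weights()
        cfg = TrainConfig(epochs=1, batch_size=16, learning_rate=1e-2, seed=3)
        model, _ = train(model, lambda e: _toy_batch(e), _toy_batch(9), cfg)
        head_names = {p.name for p in model.groups["head"]}
        changed = {name for name, val in model.get_weights().items()
                   if not np.array_equal(val, before[name])}
        assert changed == head_names

    def test_tl_all_one_step_changes_every_group(self):
        model = clone_model(_toy_model(8))
        apply_freeze_plan(model, FreezePlan.for_model(Scenario.TL_ALL, model))
        before = {g: model.weights_hash(g) for g in model.groups}
        cfg = TrainConfig(epochs=1, batch_size=48, learning_rate=1e-2, seed=4)
        model, _ = train(model, lambda e: _toy_batch(e), _toy_batch(9), cfg)
        for g in model.groups:
            assert model.weights_hash(g) != before[g], g


class TestRepeatRuns:
    def test_returns_requested_number_of_records(self):
        records = repeat_runs(lambda seed: seed, n_runs=20, master_seed=1)
        assert len(records) == 20

    def test_single_run_allowed(self):
        assert len(repeat_runs(lambda seed: seed, n_runs=1)) == 1

    def test_master_seed_determinism_and_distinct_run_seeds(self):
        a = repeat_runs(lambda seed: seed, n_runs=6, master_seed=5)
        b = repeat_runs(lambda seed: seed, n_runs=6, master_seed=5)
        assert a == b
        assert len(set(a)) == 6
        assert all(0 <= s < 2**31 for s in a)
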