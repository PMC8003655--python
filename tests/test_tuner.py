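"""Freezing strategies, fine-tuning bit-identity, loss and training sanity."""
import numpy as np
import pytest

from gliomaft.blocknet import NetConfig, build_network
from gliomaft.tuner import (
    FINE_TUNE_SPEC,
    FreezeStrategy,
    TrainSpec,
    apply_freeze,
    fine_tune,
    sample_finetune_cases,
    soft_dice_loss,
    train_base,
)

TINY_CFG = NetConfig(depth=3, base_channels=2, dropout_rate=0.0, target_shape=(8, 8, 8))


def tiny_cases(n, seed, shape=(8, 8, 8)):
    rng = np.random.default_rng(seed)
    cases = []
    for _ in range(n):
        x = rng.standard_normal((4,) + shape).astype(np.float32)
        center = rng.integers(2, 6, size=3)
        y = np.zeros(shape, np.float32)
        y[tuple(slice(c - 2, c + 2) for c in center)] = 1.0
        x[1] += 1.5 * y  # learnable signal on the T2 channel
        cases.append((x, y))
    return cases


class TestFreezeStrategy:
    def test_fine_all_down_up_sets(self):
        assert FreezeStrategy("fine_all").learnable_blocks(3) == {
            "1st down", "2nd down", "3rd down", "1st up", "2nd up", "3rd up"}
        assert FreezeStrategy("down_only").learnable_blocks(3) == {
            "1st down", "2nd down", "3rd down"}
        assert FreezeStrategy("up_only").learnable_blocks(3) == {
            "1st up", "2nd up", "3rd up"}

    def test_down2_up2_literal_naming(self):
        # literal reading: "1st up"/"2nd up" are the deepest up blocks
        assert FreezeStrategy("down2_up2", up_convention="literal").learnable_blocks(5) == {
            "1st down", "2nd down", "1st up", "2nd up"}

    def test_down2_up2_shallow_default(self):
        # default reading: the shallowest two up blocks (named 4th/5th at depth 5)
        assert FreezeStrategy("down2_up2").learnable_blocks(5) == {
            "1st down", "2nd down", "4th up", "5th up"}

    def test_down1_up1_sets(self):
        assert FreezeStrategy("down1_up1", up_convention="literal").learnable_blocks(5) == {
            "1st down", "1st up"}
        assert FreezeStrategy("down1_up1").learnable_blocks(5) == {"1st down", "5th up"}

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="unknown strategy"):
            FreezeStrategy("everything")

    def test_depth_too_small_rejected(self):
        with pytest.raises(ValueError, match="depth"):
            FreezeStrategy("down2_up2").learnable_blocks(1)


class TestApplyFreeze:
    def test_fine_all_freezes_nothing(self):
        model, reg = build_network(TINY_CFG)
        n_train, n_frozen = apply_freeze(model, reg, FreezeStrategy("fine_all"))
        assert n_frozen == 0 and n_train == reg.total

    def test_down1_up1_trainable_set_matches_registry(self):
        model, reg = build_network(TINY_CFG)
        strat = FreezeStrategy("down1_up1", up_convention="literal")
        apply_freeze(model, reg, strat)
        expect = set(reg.param_names("1st down")) | set(reg.param_names("1st up"))
        got = {n for n, p in model.param_dict().items() if p.trainable}
        assert got == expect

    @pytest.mark.parametrize("name", ["fine_all", "down_only", "up_only",
                                      "down1_up1", "down2_up2"])
    def test_partition_counts(self, name):
        model, reg = build_network(TINY_CFG)
        n_train, n_frozen = apply_freeze(model, reg, FreezeStrategy(name))
        assert n_train + n_frozen == reg.total
        assert n_train > 0

    def test_capacity_ordering_of_strategies(self):
        model, reg = build_network(TINY_CFG)
        counts = {}
        for name in ("down1_up1", "down2_up2", "fine_all"):
            counts[name], _ = apply_freeze(model, reg, FreezeStrategy(name))
        assert counts["down1_up1"] < counts["down2_up2"] < counts["fine_all"]


class TestSoftDiceLoss:
    def test_perfect_prediction_near_zero(self):
        ones = np.ones((4, 4, 4))
        assert soft_dice_loss(ones, ones) == pytest.approx(0.0, abs=0.01)

    def test_empty_prediction_near_one(self):
        truth = np.ones((4, 4, 4))
        assert soft_dice_loss(np.zeros((4, 4, 4)), truth) == pytest.approx(
            1.0 - 1.0 / 65.0)

    def test_hand_computed_2x2x2(self):
        prob = np.array([0.5, 1.0, 0.0, 0.25, 0.75, 0.0, 1.0, 0.5]).reshape(2, 2, 2)
        truth = np.array([1, 1, 0, 0, 1, 1, 0, 0], dtype=float).reshape(2, 2, 2)
        # direct summation: inter = .5+1+.75 = 2.25; sum p = 4; sum t = 4
        expect = 1.0 - (2 * 2.25 + 1.0) / (4.0 + 4.0 + 1.0)
        assert soft_dice_loss(prob, truth) == pytest.approx(expect, abs=1e-12)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            soft_dice_loss(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)))


class TestTraining:
    def test_all_blocks_update_during_base_training(self):
        model, reg = build_network(TINY_CFG, seed=0)
        before = model.state_dict()
        cases = tiny_cases(2, 1)
        train_base(model, cases, cases[:1], TrainSpec(epochs=1, seed=0))
        for block, names in reg.blocks.items():
            assert any(not np.array_equal(before[n], model.param_dict()[n].data)
                       for n in names), f"no update in {block}"

    def test_same_seed_reproduces_parameters(self):
        cases = tiny_cases(3, 2)
        results = []
        for _ in range(2):
            model, _ = build_network(TINY_CFG, seed=5)
            train_base(model, cases, cases[:1], TrainSpec(epochs=2, seed=7))
            results.append(model.state_dict())
        for n in results[0]:
            assert np.array_equal(results[0][n], results[1][n])

    def test_loss_decreases_over_training(self):
        model, _ = build_network(TINY_CFG, seed=1)
        cases = tiny_cases(1, 3)
        hist = train_base(model, cases, cases, TrainSpec(epochs=50, seed=1))
        assert hist[-1]["train_loss"] < hist[0]["train_loss"]

    def test_overfit_single_case_high_dice(self):
        cfg = NetConfig(depth=2, base_channels=4, dropout_rate=0.0,
                        target_shape=(8, 8, 8))
        model, _ = build_network(cfg, seed=2)
        cases = tiny_cases(1, 4)
        train_base(model, cases, cases, TrainSpec(epochs=200, seed=2))
        x, y = cases[0]
        pred = model.forward(x) >= 0.5
        t = y > 0
        d = 2 * np.logical_and(pred, t).sum() / (pred.sum() + t.sum())
        assert d > 0.9

    def test_empty_dataset_rejected(self):
        model, _ = build_network(TINY_CFG)
        with pytest.raises(ValueError):
            train_base(model, [], tiny_cases(1, 0))

    def test_zero_epochs_rejected(self):
        with pytest.raises(ValueError):
            TrainSpec(epochs=0)


@pytest.fixture(scope="module")
def base_model():
    model, reg = build_network(TINY_CFG, seed=3)
    cases = tiny_cases(3, 5)
    train_base(model, cases, cases[:1], TrainSpec(epochs=2, seed=3))
    return model, reg, cases


class TestFineTune:
    def test_frozen_blocks_bit_identical_literal_depth3(self, base_model):
        model, reg, cases = base_model
        strat = FreezeStrategy("down2_up2", up_convention="literal")
        tuned = fine_tune(model, reg, cases[:2], strat, FINE_TUNE_SPEC)
        frozen_blocks = {"3rd down", "3rd up"}
        for block in frozen_blocks:
            for n in reg.param_names(block):
                assert np.array_equal(tuned.param_dict()[n].data,
                                      model.param_dict()[n].data), n
        learnable = strat.learnable_blocks(3)
        for block in learnable:
            assert any(
                not np.array_equal(tuned.param_dict()[n].data, model.param_dict()[n].data)
                for n in reg.param_names(block)
            ), f"no update in {block}"

    def test_down2_up2_updates_fewer_parameters_than_fine_all(self, base_model):
        model, reg, cases = base_model
        spec = FINE_TUNE_SPEC
        t_small = fine_tune(model, reg, cases[:2], FreezeStrategy("down2_up2"), spec)
        t_all = fine_tune(model, reg, cases[:2], FreezeStrategy("fine_all"), spec)

        def changed(tuned):
            return {n for n in model.param_dict()
                    if not np.array_equal(tuned.param_dict()[n].data,
                                          model.param_dict()[n].data)}

        assert changed(t_small) < changed(t_all)  # strict subset

    def test_too_many_cases_rejected(self, base_model):
        model, reg, cases = base_model
        with pytest.raises(ValueError, match="max_cases"):
            fine_tune(model, reg, cases * 10, FreezeStrategy("down2_up2"),
                      FINE_TUNE_SPEC, max_cases=5)

    def test_base_model_untouched_by_fine_tuning(self, base_model):
        model, reg, cases = base_model
        before = model.state_dict()
        fine_tune(model, reg, cases[:1], FreezeStrategy("fine_all"), FINE_TUNE_SPEC)
        for n in before:
            assert np.array_equal(before[n], model.param_dict()[n].data)

    def test_sampler_deterministic_and_bounded(self):
        cases = list(range(30))
        a = sample_finetune_cases(cases, 10, seed=4)
        b = sample_finetune_cases(cases, 10, seed=4)
        assert a == b and len(a) == 10
        assert sample_finetune_cases(cases[:5], 10, seed=4) == cases[:5]


class TestRecoveryProperty:
    def test_domain_shift_degrades_and_finetuning_recovers(self, recovery_results):
        """Across seeds: a source-trained model underperforms a target-trained
        model on target data, and down2_up2 fine-tuning recovers accuracy."""
        s = recovery_results["summary"]
        assert s["seeds_degraded"] >= 4
        assert s["seeds_recovered"] >= 4
        assert s["mean_dice_finetuned"] > s["mean_dice_source"]
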