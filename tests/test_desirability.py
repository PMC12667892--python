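"""Desirability pipeline: softmax, goods terms, mixture weights, scene evaluation."""

import numpy as np
import pytest

import reachmix as rm
from conftest import make_canonical_scene


class TestActionComponent:
    def test_equal_costs_uniform(self):
        np.testing.assert_allclose(rm.action_component([3.0, 3.0, 3.0], 7.0), [1 / 3] * 3)

    def test_two_option_values(self):
        out = rm.action_component([1.0, 2.0], 1.0)
        np.testing.assert_allclose(out, [0.7311, 0.2689], atol=5e-5)

    def test_dominant_option_limit(self):
        out = rm.action_component([0.0, 1e6], 1.0)
        assert out[0] == pytest.approx(1.0)
        assert out[1] == pytest.approx(0.0, abs=1e-12)

    def test_lower_cost_strictly_more_probable(self):
        out = rm.action_component([5.0, 4.0, 3.0], 2.0)
        assert out[2] > out[1] > out[0]

    def test_huge_costs_do_not_underflow_to_nan(self):
        out = rm.action_component([1e8, 2e8], 0.1)
        assert np.isfinite(out).all()
        assert out.sum() == pytest.approx(1.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rm.action_component([], 1.0)


class TestGoodsComponents:
    def test_target_complement(self):
        assert rm.goods_component_target(0.3) == pytest.approx(0.7)

    def test_no_risk_certain_reward(self):
        assert rm.goods_component_target(0.0, 1.0) == 1.0

    def test_obstacle_free_mode_returns_reward_alone(self):
        assert rm.goods_component_target(0.9, 0.25, mode="obstacle_free") == 0.25

    @pytest.mark.parametrize("p", [0.0, 0.42, 1.0])
    def test_obstacle_identity(self, p):
        assert rm.goods_component_obstacle(p) == p

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            rm.goods_component_target(1.5)
        with pytest.raises(ValueError):
            rm.goods_component_obstacle(-0.1)


class TestRelativeDesirability:
    def test_product_values(self):
        assert rm.relative_desirability(1.0, 1.0) == 1.0
        assert rm.relative_desirability(0.9, 0.0) == 0.0
        assert rm.relative_desirability(0.7311, 0.7) == pytest.approx(0.5118, abs=5e-5)


class TestMixtureWeights:
    def test_alpha_one_zeroes_obstacles(self):
        wt, wo = rm.mixture_weights([0.2, 0.6], [0.5], alpha=1.0)
        np.testing.assert_allclose(wt, [0.25, 0.75])
        np.testing.assert_allclose(wo, [0.0])

    def test_alpha_zero_zeroes_targets(self):
        wt, wo = rm.mixture_weights([0.9], [0.3, 0.1], alpha=0.0)
        np.testing.assert_allclose(wt, [0.0])
        np.testing.assert_allclose(wo, [0.75, 0.25])

    def test_balanced_arithmetic(self):
        wt, wo = rm.mixture_weights([0.6], [0.4], alpha=0.5)
        assert wt[0] == pytest.approx(0.6)
        assert wo[0] == pytest.approx(0.4)

    def test_weights_sum_to_one(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            vt = rng.uniform(size=3)
            vo = rng.uniform(size=2)
            alpha = rng.uniform()
            wt, wo = rm.mixture_weights(vt, vo, alpha)
            assert wt.sum() + wo.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.all(wt >= 0) and np.all(wo >= 0)

    def test_zero_denominator_raises(self):
        with pytest.raises(rm.DegenerateSceneError):
            rm.mixture_weights([0.0], [0.0], alpha=0.5)
        with pytest.raises(rm.DegenerateSceneError):
            rm.mixture_weights([0.7], [0.0], alpha=0.0)  # alpha kills the only mass


class TestSceneValidation:
    def test_alpha_lambda_ranges(self):
        with pytest.raises(ValueError):
            make_canonical_scene(alpha=1.5)
        with pytest.raises(ValueError):
            make_canonical_scene(lam=0.0)

    def test_empty_scene_rejected(self):
        with pytest.raises(ValueError):
            rm.Scene(goals=[], obstacles=[])


class TestEvaluateScene:
    def test_no_obstacles_alpha_one_reduces_to_normalised_desirability(self, quiet_plant):
        scene = rm.Scene(
            goals=[rm.Goal(position=(10.0, 0.0)), rm.Goal(position=(0.0, 20.0))],
            alpha=1.0,
        )
        st = rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))
        bd = rm.evaluate_scene(scene, st, quiet_plant)
        v = bd.v_target
        np.testing.assert_allclose(bd.weights_target, v / v.sum(), atol=1e-12)
        assert bd.weights_obstacle.size == 0

    def test_symmetric_two_target_scene_splits_evenly(self, quiet_plant):
        scene = rm.Scene(
            goals=[rm.Goal(position=(10.0, 5.0)), rm.Goal(position=(5.0, 10.0))],
            alpha=1.0,
        )
        st = rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))
        bd = rm.evaluate_scene(scene, st, quiet_plant)
        np.testing.assert_allclose(bd.weights_target, [0.5, 0.5], atol=1e-6)

    def test_obstacle_beyond_target_reduces_target_goods(self, quiet_plant):
        # obstacle on the same axis immediately past the target: the reach
        # plan grazes its zone, so the goods term drops below 1
        scene = rm.Scene(
            goals=[rm.Goal(position=(20.0, 0.0))],
            obstacles=[
                rm.Obstacle(
                    goal=rm.ObstacleGoal(position=(26.0, 0.0)),
                    zone=rm.CollisionZone(center=(26.0, 0.0), d_inner=8.0, d_outer=16.0),
                )
            ],
        )
        st = rm.State(position=(0.0, 0.0), velocity=(0.0, 0.0))
        bd = rm.evaluate_scene(scene, st, quiet_plant)
        assert bd.goods_target[0] < 1.0

    def test_normalisation_invariants(self, quiet_plant, canonical_scene):
        rng = np.random.default_rng(2)
        for _ in range(25):
            st = rm.State(position=rng.uniform(-5, 35, 2), velocity=rng.uniform(-20, 20, 2))
            bd = rm.evaluate_scene(canonical_scene, st, quiet_plant)
            assert bd.action_target.sum() == pytest.approx(1.0, abs=1e-12)
            assert bd.action_obstacle.sum() == pytest.approx(1.0, abs=1e-12)
            total = bd.weights_target.sum() + bd.weights_obstacle.sum()
            assert total == pytest.approx(1.0, abs=1e-12)
            for arr in (bd.v_target, bd.v_obstacle, bd.goods_target, bd.goods_obstacle):
                assert np.all(arr >= 0.0) and np.all(arr <= 1.0)

    def test_higher_risk_lowers_target_raises_obstacle_desirability(self):
        # ceteris paribus monotonicity straight from the algebra
        act = 1.0
        v_t = [rm.relative_desirability(act, rm.goods_component_target(p)) for p in (0.1, 0.5, 0.9)]
        v_o = [rm.relative_desirability(act, rm.goods_component_obstacle(p)) for p in (0.1, 0.5, 0.9)]
        assert v_t[0] > v_t[1] > v_t[2]
        assert v_o[0] < v_o[1] < v_o[2]

    def test_degenerate_fallback_flagged(self, quiet_plant, canonical_scene):
        # far from everything with outward velocity: risk 0, alpha=0 kills all mass
        scene = make_canonical_scene(alpha=0.0)
        st = rm.State(position=(-20.0, -20.0), velocity=(-10.0, -10.0))
        with pytest.raises(rm.DegenerateSceneError):
            rm.evaluate_scene(scene, st, quiet_plant)
        bd = rm.evaluate_scene(scene, st, quiet_plant, on_degenerate="fallback")
        assert bd.degenerate
        assert bd.weights_target.sum() + bd.weights_obstacle.sum() == pytest.approx(1.0)


class TestSweep:
    def test_sweep_matches_pointwise_evaluation(self, quiet_plant, canonical_scene):
        rng = np.random.default_rng(4)
        pos = rng.uniform(-10, 50, size=(20, 2))
        vel = rng.uniform(-30, 30, size=(20, 2))
        res = rm.sweep_desirability(
            canonical_scene, pos, vel, lams=[canonical_scene.lam], alphas=[0.5], plant=quiet_plant
        )
        for i in range(20):
            st = rm.State(position=pos[i], velocity=vel[i])
            bd = rm.evaluate_scene(canonical_scene, st, quiet_plant)
            np.testing.assert_allclose(res.v_target[0, i], bd.v_target, atol=1e-10)
            np.testing.assert_allclose(res.v_obstacle[0, i], bd.v_obstacle, atol=1e-10)

    def test_sweep_bounds_small(self, quiet_plant, canonical_scene):
        rng = np.random.default_rng(9)
        pos = rng.uniform(-10, 50, size=(200, 2))
        vel = rng.uniform(-40, 40, size=(200, 2))
        res = rm.sweep_desirability(
            canonical_scene, pos, vel, lams=[0.1, 1.0, 10.0],
            alphas=[0.0, 0.5, 1.0], plant=quiet_plant,
        )
        assert res.v_max <= 1.0 + 1e-12
        assert res.v_min >= 0.0
        finite = res.weight_sum[np.isfinite(res.weight_sum)]
        np.testing.assert_allclose(finite, 1.0, atol=1e-12)
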