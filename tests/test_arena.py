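import numpy as np
import pytest

from homeoforage import (
    ArenaConfig,
    ConsumptionEvent,
    ForagingEnv,
    MetabolicRule,
    NutritionalState,
    make_training_foods,
    run_session,
)
from homeoforage.arena import rangefinder
from homeoforage.policies import GreedyForager, StillPolicy


def make_env(**kwargs):
    cfg = ArenaConfig(**kwargs)
    return ForagingEnv(cfg, MetabolicRule.CD, make_training_foods())


def place_agent(env, xy=(0.0, 0.0), heading=0.0):
    env.agent_xy = np.array(xy, dtype=float)
    env.heading = heading


def move_food_away(env):
    # park all food in a far corner, outside any consumption radius of origin
    env.food_red[:] = np.array([4.9, 4.9])
    env.food_blue[:] = np.array([-4.9, 4.9])


class TestReset:
    def test_same_seed_identical_configuration(self):
        e1, e2 = make_env(), make_env()
        o1, o2 = e1.reset(seed=42), e2.reset(seed=42)
        assert np.array_equal(o1.as_vector(), o2.as_vector())
        assert np.array_equal(e1.food_red, e2.food_red)
        assert np.array_equal(e1.food_blue, e2.food_blue)
        assert np.array_equal(e1.agent_xy, e2.agent_xy)

    def test_initial_state_within_stated_range(self):
        env = make_env(compute_extero=False)
        for seed in range(2000):
            env.reset(seed=seed)
            assert abs(env.state.s_red) <= 1 / 6
            assert abs(env.state.s_blue) <= 1 / 6

    def test_food_counts(self):
        env = make_env()
        env.reset(seed=0)
        assert env.food_red.shape == (10, 2)
        assert env.food_blue.shape == (10, 2)

    def test_intero_mirrors_internal_state(self):
        env = make_env()
        obs = env.reset(seed=7)
        assert obs.intero[0] == env.state.s_blue
        assert obs.intero[1] == env.state.s_red

    def test_too_small_arena_rejected(self):
        with pytest.raises(ValueError):
            ArenaConfig(half_width=0.5, consume_radius=0.5, n_food_per_type=10)


class TestRangefinder:
    CFG = ArenaConfig()

    def test_half_range_food_reads_half(self):
        # food dead ahead at 2.5 m with d_max 5 -> 0.5 in the forward bin
        bins = rangefinder(np.zeros(2), 0.0, np.array([[2.5, 0.0]]), self.CFG)
        assert bins[9] == pytest.approx(0.5)
        assert np.count_nonzero(bins) == 1

    def test_out_of_range_food_reads_zero(self):
        cfg = ArenaConfig(half_width=10)
        bins = rangefinder(np.zeros(2), 0.0, np.array([[6.0, 0.0]]), cfg)
        assert np.all(bins == 0)

    def test_contact_food_reads_one(self):
        bins = rangefinder(np.zeros(2), 0.0, np.array([[0.0, 0.0]]), self.CFG)
        assert bins.max() == pytest.approx(1.0)

    def test_readings_bounded_and_monotone_in_distance(self):
        prev = 2.0
        for d in np.linspace(0.1, 6.0, 25):
            bins = rangefinder(np.zeros(2), 0.0, np.array([[d, 0.0]]), self.CFG)
            assert np.all((bins >= 0) & (bins <= 1))
            assert bins.max() <= prev + 1e-12
            prev = bins.max()

    def test_nearest_food_in_bin_wins(self):
        bins = rangefinder(
            np.zeros(2), 0.0, np.array([[2.5, 0.0], [4.0, 0.001]]), self.CFG
        )
        assert bins[9] == pytest.approx(0.5)

    def test_egocentric_rotation(self):
        # same food, agent rotated by 90 degrees -> reading moves bins
        food = np.array([[2.5, 0.0]])
        ahead = rangefinder(np.zeros(2), 0.0, food, self.CFG)
        rotated = rangefinder(np.zeros(2), np.pi / 2, food, self.CFG)
        assert ahead[9] == pytest.approx(0.5)
        assert rotated[9] == 0.0
        assert rotated[4] == pytest.approx(0.5)  # bearing -90 deg


class TestConsumption:
    def test_no_contact_no_event(self):
        env = make_env(compute_extero=False)
        env.reset(seed=1)
        move_food_away(env)
        place_agent(env, (0, 0))
        sr = env.step(np.zeros(2))
        assert sr.info["i_red"] == 0 and sr.info["i_blue"] == 0

    def test_contact_consumes_and_respawns(self):
        env = make_env(compute_extero=False)
        env.reset(seed=1)
        move_food_away(env)
        env.food_red[0] = np.array([0.0, 0.0])
        place_agent(env, (0, 0))
        sr = env.step(np.zeros(2))
        assert sr.info["i_red"] == 1
        assert env.food_red.shape == (10, 2)
        # respawned food is no longer at the agent
        d = np.hypot(*(env.food_red - env.agent_xy).T)
        assert np.all(d > env.config.consume_radius)

    def test_simultaneous_red_and_blue(self):
        env = make_env(compute_extero=False)
        env.reset(seed=1)
        move_food_away(env)
        env.food_red[0] = np.array([0.1, 0.0])
        env.food_blue[0] = np.array([-0.1, 0.0])
        place_agent(env, (0, 0))
        sr = env.step(np.zeros(2))
        assert sr.info["i_red"] == 1 and sr.info["i_blue"] == 1

    def test_at_most_one_per_color_per_tick(self):
        env = make_env(compute_extero=False)
        env.reset(seed=1)
        move_food_away(env)
        env.food_red[0] = np.array([0.1, 0.0])
        env.food_red[1] = np.array([0.0, 0.1])
        place_agent(env, (0, 0))
        sr = env.step(np.zeros(2))
        assert sr.info["i_red"] == 1  # indicator, not a count


class TestEpisode:
    def test_death_by_decay_at_closed_form_step(self):
        env = make_env(compute_extero=False)
        env.reset(seed=3)
        move_food_away(env)
        env.state = NutritionalState(0.0, 0.0)
        place_agent(env, (0, 0))
        t = 0
        while True:
            sr = env.step(np.zeros(2))
            t += 1
            if sr.terminated:
                break
        assert t == 6667  # ceil(1/0.00015)

    def test_truncation_at_step_cap(self):
        env = make_env(compute_extero=False, max_steps=50)
        env.reset(seed=3)
        move_food_away(env)
        for _ in range(49):
            sr = env.step(np.zeros(2))
            assert not (sr.terminated or sr.truncated)
        sr = env.step(np.zeros(2))
        assert sr.truncated and not sr.terminated

    def test_step_after_terminal_raises(self):
        env = make_env(compute_extero=False, max_steps=2)
        env.reset(seed=3)
        move_food_away(env)
        env.step(np.zeros(2))
        env.step(np.zeros(2))
        with pytest.raises(RuntimeError):
            env.step(np.zeros(2))

    def test_bad_action_shape_rejected(self):
        env = make_env(compute_extero=False)
        env.reset(seed=0)
        with pytest.raises(ValueError):
            env.step(np.zeros(3))

    def test_agent_stays_inside_walls(self):
        env = make_env(compute_extero=False)
        env.reset(seed=0)
        for _ in range(300):
            sr = env.step([env.config.v_max, 0.0])
            if sr.terminated or sr.truncated:
                break
            assert np.all(np.abs(env.agent_xy) <= env.config.half_width)

    def test_still_agent_zero_metabolism_zero_reward(self):
        from homeoforage import FoodComposition

        comp = FoodComposition(0.1, 0, 0, 0.1, delta_default=0.0)
        env = ForagingEnv(ArenaConfig(compute_extero=False), MetabolicRule.CD, comp)
        env.reset(seed=0)
        move_food_away(env)
        sr = env.step(np.zeros(2))
        assert sr.reward == 0.0 and not sr.terminated


class TestRunSession:
    def test_starving_still_policy_dies(self, fast_arena):
        env = ForagingEnv(fast_arena, MetabolicRule.CD, make_training_foods())
        # session with unreachable food: park it away right after each reset
        policy = StillPolicy()
        orig_reset = env.reset

        def reset_and_park(seed=None):
            obs = orig_reset(seed=seed)
            move_food_away(env)
            place_agent(env, (0, 0))
            return obs

        env.reset = reset_and_park
        res = run_session(policy, env, 8000, seed=11)
        assert not res.survived
        assert res.intake_red == 0 and res.intake_blue == 0
        assert res.steps_lived < 8000

    def test_session_reproducible(self, fast_arena):
        results = []
        for _ in range(2):
            env = ForagingEnv(fast_arena, MetabolicRule.CD, make_training_foods())
            res = run_session(GreedyForager(), env, 2000, seed=9)
            results.append((res.intake_red, res.intake_blue, res.steps_lived, res.total_reward))
        assert results[0] == results[1]

    def test_cd_intake_accounting_exact(self, fast_arena):
        # s_final = s_0 + intake - n*delta per component, over a real trajectory
        env = ForagingEnv(fast_arena, MetabolicRule.CD, make_training_foods())
        probe = ForagingEnv(fast_arena, MetabolicRule.CD, make_training_foods())
        probe.reset(seed=21)
        s0 = probe.state
        res = run_session(GreedyForager(), env, 3000, seed=21)
        assert res.survived
        n = res.steps_lived
        assert env.state.s_red == pytest.approx(s0.s_red + res.intake_red - n * 0.00015, abs=1e-9)
        assert env.state.s_blue == pytest.approx(s0.s_blue + res.intake_blue - n * 0.00015, abs=1e-9)

    def test_ed_intake_accounting_component_sum(self, fast_arena):
        # ED transfers cancel in the component sum
        env = ForagingEnv(fast_arena, MetabolicRule.ED, make_training_foods())
        probe = ForagingEnv(fast_arena, MetabolicRule.ED, make_training_foods())
        probe.reset(seed=22)
        s0 = probe.state
        res = run_session(GreedyForager(), env, 3000, seed=22)
        n = res.steps_lived
        lhs = env.state.s_red + env.state.s_blue
        rhs = s0.s_red + s0.s_blue + res.intake_red + res.intake_blue - 2 * n * 0.00015
        assert lhs == pytest.approx(rhs, abs=1e-9)

    def test_identical_test_foods_put_intake_on_rail(self, fast_arena):
        from homeoforage import make_test_foods

        env = ForagingEnv(fast_arena, MetabolicRule.CD, make_test_foods(0.3))
        res = run_session(GreedyForager(), env, 4000, seed=5)
        assert res.intake_red > 0
        # every meal contributes (0.03, 0.07): ratio fixed
        assert res.intake_blue * 0.3 == pytest.approx(res.intake_red * 0.7, abs=1e-9)

    def test_n_steps_beyond_cap_rejected(self, fast_arena):
        env = ForagingEnv(fast_arena, MetabolicRule.CD, make_training_foods())
        with pytest.raises(ValueError):
            run_session(StillPolicy(), env, fast_arena.max_steps + 1, seed=0)
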