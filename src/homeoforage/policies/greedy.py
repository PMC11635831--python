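"""Greedy drive-minimizing oracle forager.

A deterministic policy with privileged access to the environment state (true
food positions and internal nutrient levels).  Each tick it asks: for each
food color, what would the drive be one metabolic step after eating one of
those foods, versus after a decay-only step?  If the best post-meal drive is
strictly lower than the decay-only drive it steers toward the nearest food
of the winning color at full speed; otherwise it stays still.

The oracle exists to validate the environment, metabolism and nutritional
geometry analysis without the cost and variance of reinforcement learning:
it is a one-step-lookahead stand-in for a converged drive-reducing agent.
Because the post-meal state depends only on the food's color, the lookahead
evaluates two candidate meals, ties broken by nearest distance then lowest
food index.
"""

from __future__ import annotations

import numpy as np

from ..arena import ForagingEnv, _wrap_angle
from ..metabolism import ConsumptionEvent, NO_EVENT, step_metabolism

__all__ = ["GreedyForager"]

_EAT_RED = ConsumptionEvent(1, 0)
_EAT_BLUE = ConsumptionEvent(0, 1)


class GreedyForager:
    """One-step-lookahead drive minimizer (kinematic backend only)."""

    needs_observation = False

    def __call__(self, obs, env: ForagingEnv) -> np.ndarray:
        state = env.state
        d_none = env.drive_of(
            step_metabolism(state, env.rule, NO_EVENT, env.foods, frozen=env.frozen)
        )
        d_red = env.drive_of(
            step_metabolism(state, env.rule, _EAT_RED, env.foods, frozen=env.frozen)
        )
        d_blue = env.drive_of(
            step_metabolism(state, env.rule, _EAT_BLUE, env.foods, frozen=env.frozen)
        )

        dist_red, j_red = self._nearest(env.food_red, env.agent_xy)
        dist_blue, j_blue = self._nearest(env.food_blue, env.agent_xy)

        best = min(d_red, d_blue)
        if best >= d_none:
            return np.zeros(2)
        if d_red < d_blue:
            target = env.food_red[j_red]
        elif d_blue < d_red:
            target = env.food_blue[j_blue]
        else:
            # equal lookahead drives (e.g. identical test compositions):
            # nearest food wins; exact distance tie -> red (lower color index)
            target = env.food_red[j_red] if dist_red <= dist_blue else env.food_blue[j_blue]
        return self._steer(env, target)

    @staticmethod
    def _nearest(foods: np.ndarray, xy: np.ndarray) -> tuple[float, int]:
        d = np.hypot(*(foods - xy).T)
        j = int(np.argmin(d))  # argmin takes the lowest index on ties
        return float(d[j]), j

    @staticmethod
    def _steer(env: ForagingEnv, target: np.ndarray) -> np.ndarray:
        rel = target - env.agent_xy
        bearing_err = _wrap_angle(np.arctan2(rel[1], rel[0]) - env.heading)
        omega = np.clip(
            bearing_err / env.config.decision_dt,
            -env.config.omega_max,
            env.config.omega_max,
        )
        return np.array([env.config.v_max, omega])
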