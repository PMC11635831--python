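"""The 2D foraging arena.

A walled square arena contains ten red and ten blue food balls and one
embodied forager.  The default body is a kinematic point with a 2D action
``u = (forward-speed command, turn-rate command)``, integrated over the
decision interval and clipped at the walls.  Each decision tick the body
moves, contacts are resolved into consumption events, the metabolic rule
advances the internal state, and the homeostatic reward is computed from the
drive before and after the update.  An episode terminates (death) when either
internal nutrient leaves [-1, 1]; it truncates at the step cap.

The environment follows the familiar ``reset(seed)`` / ``step(action)``
contract: ``step`` returns ``(observation, reward, terminated, truncated,
info)``.  Observations concatenate a small proprioceptive block, a 2 x n_bins
egocentric rangefinder block (one sub-vector per food color), and the 2D
interoceptive state ``(s_blue, s_red)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .metabolism import (
    ConsumptionEvent,
    FoodComposition,
    MetabolicRule,
    NutritionalState,
    step_metabolism,
)
from .reward import (
    DriveWeights,
    PostureState,
    RewardConfig,
    cost as _cost,
    drive,
    weighted_drive,
)

__all__ = [
    "ArenaConfig",
    "Observation",
    "StepResult",
    "SessionResult",
    "ForagingEnv",
    "run_session",
]

TWO_PI = 2.0 * np.pi


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry, sensing and episode parameters of the foraging arena.

    Lengths are metres, times seconds.  The rangefinder covers +/-180 degrees
    in ``n_bins`` non-overlapping sectors per food color with maximum
    detection range ``d_max``.
    """

    half_width: float = 5.0
    n_food_per_type: int = 10
    consume_radius: float = 0.5
    d_max: float = 5.0
    n_bins: int = 20
    decision_dt: float = 0.05
    max_steps: int = 60_000
    init_range: float = 1.0 / 6.0
    v_max: float = 1.0
    omega_max: float = TWO_PI
    compute_extero: bool = True

    def __post_init__(self) -> None:
        if self.half_width <= 0 or self.consume_radius <= 0 or self.d_max <= 0:
            raise ValueError("lengths must be positive")
        if self.n_bins < 1 or self.max_steps < 1 or self.n_food_per_type < 1:
            raise ValueError("counts must be at least 1")
        # the arena must have room for all food plus a free agent start
        area_needed = (self.n_food_per_type * 2 + 1) * np.pi * self.consume_radius**2
        if area_needed > (2 * self.half_width) ** 2:
            raise ValueError("arena too small to place all food without overlap")


@dataclass(frozen=True)
class Observation:
    proprio: np.ndarray
    extero: np.ndarray  # concatenated (red bins, blue bins)
    intero: np.ndarray  # (s_blue, s_red)

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.proprio, self.extero, self.intero])


@dataclass(frozen=True)
class StepResult:
    observation: Optional[Observation]
    reward: float
    terminated: bool
    truncated: bool
    info: dict


@dataclass
class SessionResult:
    """Aggregate record of one rolled-out session."""

    intake_red: float = 0.0
    intake_blue: float = 0.0
    survived: bool = False
    steps_lived: int = 0
    total_reward: float = 0.0
    sum_sq_red: float = 0.0
    sum_sq_blue: float = 0.0
    consumptions: list = field(default_factory=list)  # (step, color, s_red, s_blue) pre-meal
    trajectory: Optional[list] = None

    @property
    def mean_sq_red(self) -> float:
        return self.sum_sq_red / max(self.steps_lived, 1)

    @property
    def mean_sq_blue(self) -> float:
        return self.sum_sq_blue / max(self.steps_lived, 1)


def _wrap_angle(a):
    """Wrap to [-pi, pi)."""
    return (a + np.pi) % TWO_PI - np.pi


def rangefinder(
    agent_xy: np.ndarray,
    heading: float,
    food_xy: np.ndarray,
    config: ArenaConfig,
) -> np.ndarray:
    """Egocentric binned range readings for one food color.

    Bin k spans [-180 + k*w, -180 + (k+1)*w) degrees of relative bearing
    (w = 360/n_bins); a food exactly on a boundary belongs to the lower-index
    bin.  The reading is 1 - min(d_k, d_max)/d_max for the nearest food of
    the color in the bin, 0 for empty bins.
    """
    out = np.zeros(config.n_bins)
    if len(food_xy) == 0:
        return out
    rel = food_xy - agent_xy
    d = np.hypot(rel[:, 0], rel[:, 1])
    bearing = _wrap_angle(np.arctan2(rel[:, 1], rel[:, 0]) - heading)
    width = TWO_PI / config.n_bins
    # ceil-minus-one assigns exact boundaries to the lower-index bin
    idx = np.ceil((bearing + np.pi) / width).astype(int) - 1
    np.clip(idx, 0, config.n_bins - 1, out=idx)
    nearest = np.full(config.n_bins, np.inf)
    np.minimum.at(nearest, idx, d)
    seen = nearest < config.d_max
    out[seen] = 1.0 - nearest[seen] / config.d_max
    return out


class ForagingEnv:
    """Two-nutrient foraging environment with interoception.

    Parameters
    ----------
    config
        Arena geometry and episode settings.
    rule
        Metabolic update rule (CD, NI or ED).
    foods
        Nutrient composition shared by all food of each color.
    weights
        Drive weights; the drive used for the reward.  ``None`` means the
        unweighted drive.
    reward_config
        Reward scale alpha and cost coefficients.
    frozen
        Which nutrient the NI rule freezes (ignored by CD/ED).
    """

    def __init__(
        self,
        config: ArenaConfig,
        rule: MetabolicRule,
        foods: FoodComposition,
        weights: Optional[DriveWeights] = None,
        reward_config: RewardConfig = RewardConfig(),
        frozen: str = "red",
    ):
        self.config = config
        self.rule = MetabolicRule(rule)
        self.foods = foods
        self.weights = weights
        self.reward_config = reward_config
        self.frozen = frozen
        self._rng: Optional[np.random.Generator] = None
        self._done = True

    # -- drive ------------------------------------------------------------
    def drive_of(self, state: NutritionalState) -> float:
        if self.weights is None:
            return drive(state)
        return weighted_drive(state, self.weights)

    # -- geometry helpers --------------------------------------------------
    def _sample_position(self) -> np.ndarray:
        h = self.config.half_width
        return self._rng.uniform(-h, h, size=2)

    def _sample_free_position(self, clear_of: np.ndarray) -> np.ndarray:
        """Uniform position at least one consume-radius from every given point."""
        for _ in range(1000):
            p = self._sample_position()
            if len(clear_of) == 0:
                return p
            d = np.hypot(*(clear_of - p).T)
            if np.all(d > self.config.consume_radius):
                return p
        raise RuntimeError("could not place object in arena; too crowded")

    # -- API ---------------------------------------------------------------
    def reset(self, seed: Optional[int] = None) -> Observation:
        if seed is not None:
            self._rng = np.random.default_rng(seed)
        elif self._rng is None:
            self._rng = np.random.default_rng()
        c = self.config
        r = c.init_range
        s = self._rng.uniform(-r, r, size=2)  # (red, blue)
        self.state = NutritionalState(float(s[0]), float(s[1]))
        n = c.n_food_per_type
        self.food_red = self._rng.uniform(-c.half_width, c.half_width, size=(n, 2))
        self.food_blue = self._rng.uniform(-c.half_width, c.half_width, size=(n, 2))
        all_food = np.vstack([self.food_red, self.food_blue])
        self.agent_xy = self._sample_free_position(all_food)
        self.heading = float(self._rng.uniform(-np.pi, np.pi))
        self.t = 0
        self._done = False
        return self.observe()

    def observe(self) -> Observation:
        c = self.config
        proprio = np.array(
            [
                self.agent_xy[0] / c.half_width,
                self.agent_xy[1] / c.half_width,
                np.cos(self.heading),
                np.sin(self.heading),
            ]
        )
        if c.compute_extero:
            extero = np.concatenate(
                [
                    rangefinder(self.agent_xy, self.heading, self.food_red, c),
                    rangefinder(self.agent_xy, self.heading, self.food_blue, c),
                ]
            )
        else:
            extero = np.zeros(2 * c.n_bins)
        intero = np.array([self.state.s_blue, self.state.s_red])
        return Observation(proprio=proprio, extero=extero, intero=intero)

    @property
    def observation_dim(self) -> int:
        return 4 + 2 * self.config.n_bins + 2

    @property
    def action_dim(self) -> int:
        return 2

    @property
    def action_low(self) -> np.ndarray:
        return np.array([-self.config.v_max, -self.config.omega_max])

    @property
    def action_high(self) -> np.ndarray:
        return np.array([self.config.v_max, self.config.omega_max])

    def _consume(self) -> ConsumptionEvent:
        """Resolve contacts; eat at most the nearest food of each color."""
        events = []
        for foods in (self.food_red, self.food_blue):
            d = np.hypot(*(foods - self.agent_xy).T)
            j = int(np.argmin(d))
            if d[j] <= self.config.consume_radius:
                events.append(1)
                # respawn keeps the per-type count constant; new spot is
                # clear of the agent so it is not auto-eaten next tick
                foods[j] = self._sample_free_position(self.agent_xy[None, :])
            else:
                events.append(0)
        return ConsumptionEvent(i_red=events[0], i_blue=events[1])

    def step(self, action, compute_obs: Optional[bool] = None) -> StepResult:
        if self._done:
            raise RuntimeError("step() called on a finished episode; call reset()")
        action = np.asarray(action, dtype=float)
        if action.shape != (2,):
            raise ValueError(f"action must have shape (2,), got {action.shape}")
        c = self.config
        v = float(np.clip(action[0], -c.v_max, c.v_max))
        omega = float(np.clip(action[1], -c.omega_max, c.omega_max))

        # 1. kinematic body update, clipped at the walls
        self.heading = float(_wrap_angle(self.heading + omega * c.decision_dt))
        self.agent_xy = np.clip(
            self.agent_xy
            + v * c.decision_dt * np.array([np.cos(self.heading), np.sin(self.heading)]),
            -c.half_width,
            c.half_width,
        )

        # 2. consumption, 3. metabolism
        event = self._consume()
        d_before = self.drive_of(self.state)
        self.state = step_metabolism(
            self.state, self.rule, event, self.foods, frozen=self.frozen
        )
        d_after = self.drive_of(self.state)

        # 4. reward (kinematic body has no posture: only the action cost)
        pose = PostureState(u_t=(v, omega))
        rh = self.reward_config.alpha * (d_before - d_after)
        cost_val = _cost(pose, self.reward_config)
        reward = rh - cost_val

        # 5. termination / truncation
        self.t += 1
        terminated = not self.state.is_alive()
        truncated = (not terminated) and self.t >= c.max_steps
        self._done = terminated or truncated

        info = {
            "i_red": event.i_red,
            "i_blue": event.i_blue,
            "drive": d_after,
            "rh": rh,
            "cost": cost_val,
            "event": event,
        }
        want_obs = c.compute_extero if compute_obs is None else compute_obs
        obs = self.observe() if want_obs else None
        return StepResult(obs, reward, terminated, truncated, info)


def run_session(
    policy,
    env: ForagingEnv,
    n_steps: int,
    seed: Optional[int] = None,
    record_trajectory: bool = False,
) -> SessionResult:
    """Roll a policy for ``n_steps`` ticks or until death.

    Accumulates cumulative nutrient intake per color (gain coefficients times
    event indicators, summed over ticks), per-step squared interoceptive
    errors, and the meal log.  ``survived`` is True iff the agent reached
    ``n_steps`` without dying.
    """
    if n_steps > env.config.max_steps:
        raise ValueError("n_steps exceeds the episode step cap")
    obs = env.reset(seed=seed)
    if hasattr(policy, "reset") and seed is not None:
        policy.reset(seed)
    needs_obs = getattr(policy, "needs_observation", True)
    comp = env.foods
    res = SessionResult(trajectory=[] if record_trajectory else None)
    for t in range(n_steps):
        action = policy(obs if needs_obs else None, env)
        pre = env.state
        sr = env.step(action, compute_obs=needs_obs)
        obs = sr.observation
        ev = sr.info["event"]
        if ev.i_red or ev.i_blue:
            res.intake_red += comp.a_red * ev.i_red + comp.b_red * ev.i_blue
            res.intake_blue += comp.a_blue * ev.i_red + comp.b_blue * ev.i_blue
            if ev.i_red:
                res.consumptions.append((t, "red", pre.s_red, pre.s_blue))
            if ev.i_blue:
                res.consumptions.append((t, "blue", pre.s_red, pre.s_blue))
        s = env.state
        res.total_reward += sr.reward
        res.sum_sq_red += s.s_red**2
        res.sum_sq_blue += s.s_blue**2
        res.steps_lived = t + 1
        if record_trajectory:
            res.trajectory.append(
                (
                    t,
                    s.s_red,
                    s.s_blue,
                    ev.i_red,
                    ev.i_blue,
                    sr.info["rh"],
                    sr.info["cost"],
                    sr.reward,
                    env.agent_xy[0],
                    env.agent_xy[1],
                )
            )
        if sr.terminated:
            res.survived = False
            return res
        if sr.truncated:
            break
    res.survived = res.steps_lived >= n_steps
    return res
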