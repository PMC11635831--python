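"""Homeostatic drive and reward.

The drive ``d`` is the (optionally weighted) squared Euclidean distance of
the internal nutritional state from the setpoint at the origin.  The reward
is the temporal difference of the drive, ``R_h = alpha * (d_t - d_{t+1})``,
minus a small posture/action cost ``C``.  Because ``R_h`` telescopes, the
cumulative homeostatic reward over an episode depends only on the initial
and final drive — the reward is a potential-based shaping of "get and stay
close to the setpoint".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metabolism import NutritionalState

__all__ = [
    "DriveWeights",
    "RewardConfig",
    "PostureState",
    "drive",
    "weighted_drive",
    "homeostatic_reward",
    "cost",
    "total_reward",
]


@dataclass(frozen=True)
class DriveWeights:
    """Motivational weights of the two nutrient drives.

    The weighted drive uses normalized coefficients
    ``c_x = 2 w_x / (w_red + w_blue)`` so the coefficients always sum to 2
    and their ratio equals ``w_blue / w_red``; equal weights recover the
    unweighted drive exactly.
    """

    w_red: float = 1.0
    w_blue: float = 1.0

    def __post_init__(self) -> None:
        if self.w_red <= 0 or self.w_blue <= 0:
            raise ValueError("drive weights must be strictly positive")

    def coefficients(self) -> tuple[float, float]:
        """Normalized (c_red, c_blue) multiplying the squared deviations."""
        total = self.w_red + self.w_blue
        return 2.0 * self.w_red / total, 2.0 * self.w_blue / total


@dataclass(frozen=True)
class RewardConfig:
    """Reward scale and cost coefficients (paper-standard defaults)."""

    alpha: float = 100.0
    k_p: float = 0.005
    k_u: float = 0.0005

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.k_p < 0 or self.k_u < 0:
            raise ValueError("cost coefficients must be non-negative")


@dataclass(frozen=True)
class PostureState:
    """Torso posture (roll, pitch) vs. target, plus the raw action vector.

    The kinematic point body has no articulated torso: its posture vectors
    are empty and only the action cost applies.
    """

    p_t: tuple[float, ...] = ()
    p_star: tuple[float, ...] = ()
    u_t: tuple[float, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if len(self.p_t) != len(self.p_star):
            raise ValueError("posture and target posture must share a dimension")


def drive(state: NutritionalState) -> float:
    """Unweighted drive: squared distance from the setpoint."""
    return state.s_red**2 + state.s_blue**2


def weighted_drive(state: NutritionalState, w: DriveWeights) -> float:
    """Weighted drive d = c_red*s_red^2 + c_blue*s_blue^2."""
    c_red, c_blue = w.coefficients()
    return c_red * state.s_red**2 + c_blue * state.s_blue**2


def homeostatic_reward(d_t: float, d_next: float, cfg: RewardConfig) -> float:
    """Temporal-difference reward alpha*(d_t - d_{t+1})."""
    return cfg.alpha * (d_t - d_next)


def cost(pose: PostureState, cfg: RewardConfig) -> float:
    """Posture-plus-action cost C = k_p*||p_t - p*||^2 + k_u*||u_t||^2."""
    p_err = sum((a - b) ** 2 for a, b in zip(pose.p_t, pose.p_star))
    u_sq = float(np.dot(pose.u_t, pose.u_t)) if len(pose.u_t) else 0.0
    return cfg.k_p * p_err + cfg.k_u * u_sq


def total_reward(
    d_t: float, d_next: float, pose: PostureState, cfg: RewardConfig
) -> float:
    """Full per-tick reward R = R_h - C."""
    return homeostatic_reward(d_t, d_next, cfg) - cost(pose, cfg)
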