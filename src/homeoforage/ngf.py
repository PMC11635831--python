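"""Nutritional-geometry analysis of long-term foraging.

In the nutritional geometry framework a session on a single food composition
moves cumulative intake along a *rail* — the ray from the origin of nutrient
space with direction proportional to the food's (red, blue) content.  The
*intake target* (IT) is the point reached when feeding ad libitum on
complementary foods.  Restricted to one imbalanced food, an animal must
compromise; the canonical rules of compromise predict where on the rail the
session ends:

* **CD** — the rail point closest to the IT (orthogonal projection).
* **ED** — the rail point whose absolute deviations from the IT are equal in
  the two nutrients, with one nutrient over- and the other under-consumed.
* **NI** — the rail point matching the IT in the regulated nutrient only.

Axis convention throughout: red intake on the x-axis, blue on the y-axis.
This module provides the closed-form expected points, along-rail statistics
of simulated sessions, the survivor filter, and the orchestration of the
full rail-sweep and drive-weighting experiments.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .arena import ArenaConfig, ForagingEnv, run_session
from .metabolism import (
    FoodComposition,
    MetabolicRule,
    make_test_foods,
    make_training_foods,
)
from .reward import DriveWeights, RewardConfig

__all__ = [
    "Rail",
    "IntakeRecord",
    "IntakeTarget",
    "RailSummary",
    "NGFResult",
    "DEFAULT_BETA_GRID",
    "rail_from_beta",
    "percent_error",
    "cd_expected_point",
    "ed_expected_point",
    "ni_expected_point",
    "expected_point",
    "summarize_along_rail",
    "survival_filter",
    "estimate_intake_target",
    "ngf_experiment",
    "weight_spectrum_experiment",
    "SpectrumResult",
]

#: Rail sweep from beta=0.2 to 0.8 in steps of 0.1.
DEFAULT_BETA_GRID = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8)


@dataclass(frozen=True)
class Rail:
    """A nutritional rail: the intake ray for the single-composition foods."""

    beta: float
    direction: np.ndarray  # unit vector, (red, blue)

    def project_scalar(self, point) -> float:
        """Signed coordinate of a point's projection onto the rail."""
        return float(np.dot(np.asarray(point, dtype=float), self.direction))


def rail_from_beta(beta: float) -> Rail:
    """Rail with direction proportional to (beta, 1-beta)."""
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie strictly in (0, 1), got {beta}")
    v = np.array([beta, 1.0 - beta])
    return Rail(beta=beta, direction=v / np.linalg.norm(v))


@dataclass(frozen=True)
class IntakeRecord:
    """Cumulative nutrient intake of one session on one rail."""

    total_red: float
    total_blue: float
    survived: bool
    beta: float
    seed: int

    @property
    def point(self) -> np.ndarray:
        return np.array([self.total_red, self.total_blue])


@dataclass(frozen=True)
class IntakeTarget:
    """Ad-libitum reference intake point with its dispersion."""

    point: np.ndarray  # (red, blue)
    n_sessions: int
    dispersion: np.ndarray  # per-axis SD


@dataclass
class RailSummary:
    beta: float
    n_survivors: int
    mean_point: Optional[np.ndarray] = None
    mean_scalar: float = np.nan
    sd_along_rail: float = np.nan
    expected_point: Optional[np.ndarray] = None
    percent_error_along_rail: float = np.nan


def percent_error(v: float, t: float) -> float:
    """(v - t)/t * 100; the signed relative error against a target."""
    if t == 0:
        raise ValueError("percent error undefined for a zero target")
    return (v - t) / t * 100.0


# ----------------------------------------------------------------------
# closed-form rule-of-compromise points
# ----------------------------------------------------------------------
def cd_expected_point(it_point, rail: Rail) -> np.ndarray:
    """Closest rail point to the IT: projection clipped to the nonnegative ray."""
    t = max(0.0, rail.project_scalar(it_point))
    return t * rail.direction


def ed_expected_point(it_point, rail: Rail) -> np.ndarray:
    """Rail point with equal absolute deviations of opposite sign from the IT.

    Solves t*u_r - IT_r = -(t*u_b - IT_b), i.e. t = (IT_r + IT_b)/(u_r + u_b);
    over-consumption of one nutrient balances under-consumption of the other.
    """
    it = np.asarray(it_point, dtype=float)
    denom = float(rail.direction.sum())
    if denom <= 0:
        raise ValueError("degenerate rail: direction components sum to zero")
    t = float(it.sum()) / denom
    return max(t, 0.0) * rail.direction


def ni_expected_point(it_point, rail: Rail, regulated: str = "blue") -> np.ndarray:
    """Rail point matching the IT in the regulated nutrient coordinate.

    The default regulated nutrient is blue, matching the NI metabolism that
    freezes red.
    """
    it = np.asarray(it_point, dtype=float)
    axis = {"red": 0, "blue": 1}[regulated]
    u = rail.direction[axis]
    if u <= 0:
        raise ValueError("rail has no component along the regulated nutrient")
    t = it[axis] / u
    return max(t, 0.0) * rail.direction


def expected_point(
    rule: MetabolicRule, it_point, rail: Rail, regulated: str = "blue"
) -> np.ndarray:
    rule = MetabolicRule(rule)
    if rule is MetabolicRule.CD:
        return cd_expected_point(it_point, rail)
    if rule is MetabolicRule.ED:
        return ed_expected_point(it_point, rail)
    return ni_expected_point(it_point, rail, regulated=regulated)


# ----------------------------------------------------------------------
# along-rail statistics
# ----------------------------------------------------------------------
def summarize_along_rail(records: Sequence[IntakeRecord], rail: Rail) -> RailSummary:
    """Project surviving sessions onto the rail and summarize.

    The mean point is the mean projected scalar times the rail direction;
    the SD is the sample (n-1) standard deviation of the scalars.
    """
    survivors = [r for r in records if r.survived]
    if not survivors:
        return RailSummary(beta=rail.beta, n_survivors=0)
    scalars = np.array([rail.project_scalar(r.point) for r in survivors])
    mean_scalar = float(scalars.mean())
    sd = float(scalars.std(ddof=1)) if len(scalars) > 1 else 0.0
    return RailSummary(
        beta=rail.beta,
        n_survivors=len(survivors),
        mean_point=mean_scalar * rail.direction,
        mean_scalar=mean_scalar,
        sd_along_rail=sd,
    )


def survival_filter(
    summaries: Sequence[RailSummary], min_n: int = 10
) -> list[RailSummary]:
    """Keep rails with at least ``min_n`` surviving sessions."""
    return [s for s in summaries if s.n_survivors >= min_n]


# ----------------------------------------------------------------------
# experiments
# ----------------------------------------------------------------------
def _make_env(
    arena: ArenaConfig,
    rule: MetabolicRule,
    foods: FoodComposition,
    weights: Optional[DriveWeights],
    reward_config: RewardConfig,
) -> ForagingEnv:
    return ForagingEnv(arena, rule, foods, weights=weights, reward_config=reward_config)


def estimate_intake_target(
    policy,
    rule: MetabolicRule,
    arena: ArenaConfig,
    n_sessions: int = 20,
    n_steps: int = 8_000,
    base_seed: int = 0,
    weights: Optional[DriveWeights] = None,
    reward_config: RewardConfig = RewardConfig(),
) -> IntakeTarget:
    """Ad-libitum IT: mean intake over surviving training-food sessions."""
    if n_sessions < 1:
        raise ValueError("n_sessions must be at least 1")
    foods = make_training_foods()
    points = []
    for k in range(n_sessions):
        env = _make_env(arena, rule, foods, weights, reward_config)
        res = run_session(policy, env, n_steps, seed=base_seed + k)
        if res.survived:
            points.append((res.intake_red, res.intake_blue))
    if not points:
        raise RuntimeError("no session survived; cannot estimate the intake target")
    pts = np.array(points)
    sd = pts.std(axis=0, ddof=1) if len(pts) > 1 else np.zeros(2)
    return IntakeTarget(point=pts.mean(axis=0), n_sessions=len(points), dispersion=sd)


@dataclass
class NGFResult:
    """Rail-sweep outcome: per-session records, per-rail summaries, IT."""

    rule: MetabolicRule
    intake_target: IntakeTarget
    summaries: list[RailSummary]
    records: list[IntakeRecord]
    regulated: str = "blue"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "rule": self.rule.value,
                    "beta": r.beta,
                    "seed": r.seed,
                    "survived": r.survived,
                    "total_red": r.total_red,
                    "total_blue": r.total_blue,
                }
                for r in self.records
            ]
        )

    def summary_dict(self) -> dict:
        return {
            "rule": self.rule.value,
            "intake_target": {
                "point": self.intake_target.point.tolist(),
                "n_sessions": self.intake_target.n_sessions,
                "dispersion": self.intake_target.dispersion.tolist(),
            },
            "rails": [
                {
                    "beta": s.beta,
                    "n_survivors": s.n_survivors,
                    "mean_point": None if s.mean_point is None else s.mean_point.tolist(),
                    "sd_along_rail": None if np.isnan(s.sd_along_rail) else s.sd_along_rail,
                    "expected_point": None
                    if s.expected_point is None
                    else s.expected_point.tolist(),
                    "percent_error_along_rail": None
                    if np.isnan(s.percent_error_along_rail)
                    else s.percent_error_along_rail,
                }
                for s in self.summaries
            ],
        }


def ngf_experiment(
    policy,
    rule: MetabolicRule,
    arena: ArenaConfig,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    n_sessions: int = 20,
    n_steps: int = 8_000,
    base_seed: int = 0,
    weights: Optional[DriveWeights] = None,
    reward_config: RewardConfig = RewardConfig(),
    regulated: str = "blue",
    intake_target: Optional[IntakeTarget] = None,
    min_survivors: int = 1,
) -> NGFResult:
    """Full rail sweep: test sessions per beta, along-rail statistics, and
    percent errors against the rule's expected curve from the estimated IT.

    Session seeds are ``base_seed + session_index`` within each rail; the IT
    estimation uses an offset seed block so its sessions are independent.
    """
    rule = MetabolicRule(rule)
    if intake_target is None:
        intake_target = estimate_intake_target(
            policy,
            rule,
            arena,
            n_sessions=n_sessions,
            n_steps=n_steps,
            base_seed=base_seed + 100_003,
            weights=weights,
            reward_config=reward_config,
        )
    records: list[IntakeRecord] = []
    summaries: list[RailSummary] = []
    for beta in beta_grid:
        rail = rail_from_beta(beta)
        foods = make_test_foods(beta)
        rail_records = []
        for k in range(n_sessions):
            env = _make_env(arena, rule, foods, weights, reward_config)
            res = run_session(policy, env, n_steps, seed=base_seed + k)
            rail_records.append(
                IntakeRecord(
                    total_red=res.intake_red,
                    total_blue=res.intake_blue,
                    survived=res.survived,
                    beta=beta,
                    seed=base_seed + k,
                )
            )
        records.extend(rail_records)
        summary = summarize_along_rail(rail_records, rail)
        exp = expected_point(rule, intake_target.point, rail, regulated=regulated)
        summary.expected_point = exp
        t_exp = rail.project_scalar(exp)
        if summary.n_survivors >= min_survivors and t_exp != 0:
            summary.percent_error_along_rail = percent_error(summary.mean_scalar, t_exp)
        summaries.append(summary)
    return NGFResult(
        rule=rule,
        intake_target=intake_target,
        summaries=summaries,
        records=records,
        regulated=regulated,
    )


@dataclass
class SpectrumResult:
    """Drive-weighting sweep: per-ratio interoceptive errors and NGF runs."""

    ratios: list[float]
    red_errors: list[float]  # time-averaged s_red^2, mean over sessions
    blue_errors: list[float]
    ngf_results: dict  # ratio -> NGFResult (only for ratios where run)


def weight_spectrum_experiment(
    policy_factory: Callable[[DriveWeights], object],
    arena: ArenaConfig,
    ratios: Sequence[float] = (1, 2, 4, 8, 16),
    rule: MetabolicRule = MetabolicRule.CD,
    error_steps: int = 10_000,
    error_sessions: int = 20,
    beta_grid: Sequence[float] = DEFAULT_BETA_GRID,
    ngf_sessions: int = 20,
    ngf_steps: int = 8_000,
    base_seed: int = 0,
    reward_config: RewardConfig = RewardConfig(),
    ngf_ratios: Optional[Sequence[float]] = None,
) -> SpectrumResult:
    """Sweep drive-weight ratios w_blue:w_red over the CD metabolism.

    For each ratio: evaluate time-averaged interoceptive errors (mean of
    s_red^2 and s_blue^2 over ``error_steps`` ticks in the training-food
    environment) and optionally run the full rail sweep.  ``ngf_ratios``
    restricts which ratios get the (costly) rail sweep; None means all.
    """
    from .policies import evaluate_policy  # local import avoids a cycle

    rule = MetabolicRule(rule)
    result = SpectrumResult(ratios=list(ratios), red_errors=[], blue_errors=[], ngf_results={})
    foods = make_training_foods()
    for ratio in ratios:
        weights = DriveWeights(w_red=1.0, w_blue=float(ratio))
        policy = policy_factory(weights)
        env_factory = lambda w=weights: _make_env(arena, rule, foods, w, reward_config)
        ev = evaluate_policy(
            policy, env_factory, error_steps, error_sessions, base_seed=base_seed
        )
        err_red, err_blue = ev.interoceptive_errors
        result.red_errors.append(err_red)
        result.blue_errors.append(err_blue)
        if ngf_ratios is None or ratio in ngf_ratios:
            result.ngf_results[ratio] = ngf_experiment(
                policy,
                rule,
                arena,
                beta_grid=beta_grid,
                n_sessions=ngf_sessions,
                n_steps=ngf_steps,
                base_seed=base_seed,
                weights=weights,
                reward_config=reward_config,
            )
    return result
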