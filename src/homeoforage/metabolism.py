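"""Metabolic update rules for the two-nutrient internal state.

A simulated forager carries a 2D nutritional state ``s = (s_red, s_blue)``
measured relative to the homeostatic setpoint at the origin.  Each time tick
the state drifts by a passive decay and jumps by fixed gains when food is
consumed.  Three update rules produce the three canonical long-term
"rules of compromise" of nutritional ecology:

* **CD** (closest distance) — both nutrients decay and both are replenished
  by the corresponding foods; the long-run intake lands nearest the intake
  target on the nutritional rail.
* **NI** (no interaction) — one nutrient (red by default) is frozen: its
  deviation from the setpoint is ignored and any ingested amount of it is
  instantly discarded.
* **ED** (equal distance) — CD followed by a substitution step in which a
  surplus in one nutrient compensates a deficit in the other, a stylized
  gluconeogenesis-like conversion.

All arithmetic is plain double precision with no clamping; the arena applies
the [-1, 1]^2 survival boundary after each update.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, replace

__all__ = [
    "NutritionalState",
    "ConsumptionEvent",
    "FoodComposition",
    "MetabolicRule",
    "cd_step",
    "ni_step",
    "ed_substitution",
    "ed_step",
    "step_metabolism",
    "make_training_foods",
    "make_test_foods",
    "TRAINING_GAIN",
    "DEFAULT_DECAY",
]

#: Nutrient gain per meal in the training preset (a_red = b_blue).
TRAINING_GAIN = 0.1
#: Passive per-tick decay rate shared by both nutrients.
DEFAULT_DECAY = 0.00015


@dataclass(frozen=True)
class NutritionalState:
    """Internal nutrient levels relative to the setpoint at the origin."""

    s_red: float
    s_blue: float

    def is_alive(self, bound: float = 1.0) -> bool:
        """True iff both components lie inside the closed survival box."""
        return (
            math.isfinite(self.s_red)
            and math.isfinite(self.s_blue)
            and abs(self.s_red) <= bound
            and abs(self.s_blue) <= bound
        )

    def as_tuple(self) -> tuple[float, float]:
        return (self.s_red, self.s_blue)


@dataclass(frozen=True)
class ConsumptionEvent:
    """Per-tick food-consumption indicators (1 = a food of that color eaten)."""

    i_red: int = 0
    i_blue: int = 0

    def __post_init__(self) -> None:
        if self.i_red not in (0, 1) or self.i_blue not in (0, 1):
            raise ValueError("consumption indicators must be 0 or 1")


NO_EVENT = ConsumptionEvent(0, 0)


@dataclass(frozen=True)
class FoodComposition:
    """Nutrient gains per food type plus the passive decay rate.

    ``a_*`` are the gains delivered by a red food, ``b_*`` by a blue food:
    eating a red food adds ``a_red`` to the red nutrient and ``a_blue`` to the
    blue nutrient.
    """

    a_red: float
    b_red: float
    a_blue: float
    b_blue: float
    delta_default: float = DEFAULT_DECAY

    def __post_init__(self) -> None:
        for name in ("a_red", "b_red", "a_blue", "b_blue", "delta_default"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")

    def gains(self, event: ConsumptionEvent) -> tuple[float, float]:
        """(red, blue) nutrient gain delivered by this tick's consumption."""
        return (
            self.a_red * event.i_red + self.b_red * event.i_blue,
            self.a_blue * event.i_red + self.b_blue * event.i_blue,
        )


class MetabolicRule(str, enum.Enum):
    CD = "cd"
    NI = "ni"
    ED = "ed"


def make_training_foods() -> FoodComposition:
    """Training preset: each food replenishes only its own nutrient."""
    return FoodComposition(
        a_red=TRAINING_GAIN,
        b_red=0.0,
        a_blue=0.0,
        b_blue=TRAINING_GAIN,
        delta_default=DEFAULT_DECAY,
    )


def make_test_foods(beta: float) -> FoodComposition:
    """Nutritional-rail test preset: every food shares one composition.

    ``beta`` in (0, 1) sets the red fraction: a_red = b_red = 0.1*beta and
    a_blue = b_blue = 0.1*(1-beta), so cumulative intake moves along the ray
    with direction (beta, 1-beta) regardless of which food is eaten.
    """
    if not 0.0 < beta < 1.0:
        raise ValueError(f"beta must lie strictly in (0, 1), got {beta}")
    return FoodComposition(
        a_red=TRAINING_GAIN * beta,
        b_red=TRAINING_GAIN * beta,
        a_blue=TRAINING_GAIN * (1.0 - beta),
        b_blue=TRAINING_GAIN * (1.0 - beta),
        delta_default=DEFAULT_DECAY,
    )


def cd_step(
    state: NutritionalState, event: ConsumptionEvent, comp: FoodComposition
) -> NutritionalState:
    """Closest-distance update: decay plus additive gains, no clamping."""
    g_red, g_blue = comp.gains(event)
    return NutritionalState(
        s_red=state.s_red - comp.delta_default + g_red,
        s_blue=state.s_blue - comp.delta_default + g_blue,
    )


def ni_step(
    state: NutritionalState,
    event: ConsumptionEvent,
    comp: FoodComposition,
    frozen: str = "red",
) -> NutritionalState:
    """No-interaction update: the frozen nutrient never changes.

    The frozen nutrient's deviation is ignored — ingested amounts of it are
    discarded — while the other nutrient follows the CD dynamics.
    """
    g_red, g_blue = comp.gains(event)
    if frozen == "red":
        return replace(state, s_blue=state.s_blue - comp.delta_default + g_blue)
    if frozen == "blue":
        return replace(state, s_red=state.s_red - comp.delta_default + g_red)
    raise ValueError(f"frozen nutrient must be 'red' or 'blue', got {frozen!r}")


def ed_substitution(s_tilde: NutritionalState) -> NutritionalState:
    """Surplus-for-deficit substitution of the equal-distance rule.

    If the two components have strictly opposite signs, transfer
    ``m = min(|s_red|, |s_blue|)`` from the surplus nutrient to the deficient
    one, zeroing the smaller-magnitude component.  If both are sufficient or
    both insufficient (or either is exactly zero) nothing changes.  The
    component sum is conserved exactly.
    """
    r, b = s_tilde.s_red, s_tilde.s_blue
    if r < 0.0 < b or b < 0.0 < r:
        m = min(abs(r), abs(b))
        if r < 0.0:
            return NutritionalState(r + m, b - m)
        return NutritionalState(r - m, b + m)
    return s_tilde


def ed_step(
    state: NutritionalState, event: ConsumptionEvent, comp: FoodComposition
) -> NutritionalState:
    """Equal-distance update: a CD step followed by the substitution step."""
    return ed_substitution(cd_step(state, event, comp))


def step_metabolism(
    state: NutritionalState,
    rule: MetabolicRule,
    event: ConsumptionEvent,
    comp: FoodComposition,
    frozen: str = "red",
) -> NutritionalState:
    """Advance the internal state one tick under the given metabolic rule."""
    rule = MetabolicRule(rule)
    if rule is MetabolicRule.CD:
        return cd_step(state, event, comp)
    if rule is MetabolicRule.NI:
        return ni_step(state, event, comp, frozen=frozen)
    return ed_step(state, event, comp)
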