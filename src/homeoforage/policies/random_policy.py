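"""Baseline policies: uniform-random and do-nothing."""

from __future__ import annotations

import numpy as np

__all__ = ["RandomPolicy", "StillPolicy"]


class RandomPolicy:
    """Uniform random action within the environment's bounds."""

    needs_observation = False

    def __init__(self, seed: int = 0):
        self._rng = np.random.default_rng(seed)

    def reset(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def __call__(self, obs, env) -> np.ndarray:
        return self._rng.uniform(env.action_low, env.action_high)


class StillPolicy:
    """Never moves; useful for decay-only closed-form checks."""

    needs_observation = False

    def __call__(self, obs, env) -> np.ndarray:
        return np.zeros(env.action_dim)
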