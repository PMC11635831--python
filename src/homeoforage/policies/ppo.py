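"""Proximal policy optimization for the foraging body, in plain numpy.

Actor-critic with two separate fully connected networks (hidden sizes
256-64, tanh activations).  The policy head outputs, per action dimension,
the two shape parameters of a Beta distribution (softplus + 1, so both
shapes are >= 1 and the density is unimodal); samples in (0, 1) are mapped
linearly onto the action interval, so every sampled action respects the
bounds by construction.  Training uses the clipped surrogate objective with
generalized advantage estimation and Adam.  Forward and backward passes are
written out explicitly; the Beta log-density and entropy gradients use the
digamma/trigamma functions from scipy.

The paper-scale schedule (500 iterations of 3e5 samples) is expressible via
:class:`TrainingConfig`; :meth:`TrainingConfig.scaled_profile` gives the
desk-scale profile exercised by the test suite.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Callable, Optional

import numpy as np
from scipy.special import betaln, digamma, polygamma

from ..arena import ForagingEnv, run_session

__all__ = [
    "TrainingConfig",
    "TrainedPolicy",
    "train_policy",
    "evaluate_policy",
    "EvaluationSummary",
]

_EPS = 1e-6


@dataclass
class TrainingConfig:
    """PPO schedule and network hyperparameters.

    Defaults follow the paper-scale setup where stated (iterations, sample
    and minibatch sizes, epochs, clipping, network shapes); the discount,
    GAE lambda, learning rate and entropy coefficient are unreported there
    and carry standard PPO defaults.
    """

    n_iterations: int = 500
    samples_per_iteration: int = 300_000
    minibatch: int = 50_000
    epochs_per_iteration: int = 30
    clip: float = 0.3
    gamma: float = 0.99
    gae_lambda: float = 0.95
    learning_rate: float = 3e-4
    entropy_coef: float = 0.01
    hidden: tuple[int, ...] = (256, 64)
    n_parallel_samplers: int = 10

    def __post_init__(self) -> None:
        if not 0 <= self.gamma < 1:
            raise ValueError("gamma must lie in [0, 1)")
        if self.clip <= 0:
            raise ValueError("clip must be positive")
        if self.minibatch > self.samples_per_iteration:
            raise ValueError("minibatch cannot exceed samples per iteration")

    @classmethod
    def scaled_profile(cls) -> "TrainingConfig":
        """Desk-scale profile: 20 iterations x 3e4 samples on one CPU."""
        return cls(
            n_iterations=20,
            samples_per_iteration=30_000,
            minibatch=3_000,
            epochs_per_iteration=10,
            n_parallel_samplers=1,
        )


# ----------------------------------------------------------------------
# dense network with manual backprop
# ----------------------------------------------------------------------
class _MLP:
    """Tanh MLP with linear output and cached-activation backprop."""

    def __init__(self, sizes: list[int], rng: np.random.Generator, out_scale=0.01):
        self.W, self.b = [], []
        for i, (n_in, n_out) in enumerate(zip(sizes[:-1], sizes[1:])):
            scale = out_scale if i == len(sizes) - 2 else 1.0
            w = rng.normal(size=(n_in, n_out)) * np.sqrt(1.0 / n_in) * scale
            self.W.append(w)
            self.b.append(np.zeros(n_out))

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._acts = [x]
        h = x
        for i, (w, b) in enumerate(zip(self.W, self.b)):
            h = h @ w + b
            if i < len(self.W) - 1:
                h = np.tanh(h)
            self._acts.append(h)
        return h

    def backward(self, dout: np.ndarray):
        """Gradients of a scalar loss given d(loss)/d(output)."""
        gW = [None] * len(self.W)
        gb = [None] * len(self.b)
        delta = dout
        for i in reversed(range(len(self.W))):
            a_in = self._acts[i]
            gW[i] = a_in.T @ delta
            gb[i] = delta.sum(axis=0)
            if i > 0:
                delta = (delta @ self.W[i].T) * (1.0 - self._acts[i] ** 2)
        return gW, gb

    def params(self):
        return self.W + self.b

    def set_params(self, flat: list[np.ndarray]) -> None:
        n = len(flat) // 2
        self.W = [np.asarray(p) for p in flat[:n]]
        self.b = [np.asarray(p) for p in flat[n:]]


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.lr = lr
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, params, grads, beta1=0.9, beta2=0.999, eps=1e-8):
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - beta2**self.t) / (1 - beta1**self.t)
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= beta1
            m += (1 - beta1) * g
            v *= beta2
            v += (1 - beta2) * g * g
            p -= lr_t * m / (np.sqrt(v) + eps)


# ----------------------------------------------------------------------
# Beta policy head
# ----------------------------------------------------------------------
def _softplus(x):
    return np.logaddexp(0.0, x)


def _shapes_from_logits(logits: np.ndarray):
    """Split head output into Beta shapes a, b >= 1 (softplus + 1)."""
    n = logits.shape[-1] // 2
    a = _softplus(logits[..., :n]) + 1.0
    b = _softplus(logits[..., n:]) + 1.0
    return a, b


def _beta_logpdf(u, a, b):
    return (a - 1) * np.log(u) + (b - 1) * np.log1p(-u) - betaln(a, b)


def _beta_entropy(a, b):
    s = a + b
    return betaln(a, b) - (a - 1) * digamma(a) - (b - 1) * digamma(b) + (s - 2) * digamma(s)


class TrainedPolicy:
    """A (possibly stochastic) policy backed by the trained Beta actor."""

    needs_observation = True

    def __init__(
        self,
        net: _MLP,
        action_low: np.ndarray,
        action_high: np.ndarray,
        stochastic: bool = False,
        seed: int = 0,
        config: Optional[TrainingConfig] = None,
    ):
        self.net = net
        self.low = np.asarray(action_low, dtype=float)
        self.high = np.asarray(action_high, dtype=float)
        self.stochastic = stochastic
        self.config = config
        self._rng = np.random.default_rng(seed)

    def reset(self, seed: int) -> None:
        self._rng = np.random.default_rng(seed)

    def _shapes(self, obs_vec: np.ndarray):
        logits = self.net.forward(obs_vec[None, :])
        return _shapes_from_logits(logits)

    def __call__(self, obs, env) -> np.ndarray:
        a, b = self._shapes(obs.as_vector())
        if self.stochastic:
            u = self._rng.beta(a, b)[0]
        else:
            u = (a / (a + b))[0]  # Beta mean
        return self.low + (self.high - self.low) * u

    # -- persistence -----------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.net.params())}
        meta = {
            "low": self.low.tolist(),
            "high": self.high.tolist(),
            "config": asdict(self.config) if self.config else None,
        }
        np.savez(path, meta=json.dumps(meta), **arrays)

    @classmethod
    def load(cls, path) -> "TrainedPolicy":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            flat = [z[f"p{i}"] for i in range(len(z.files) - 1)]
        net = _MLP.__new__(_MLP)
        net.set_params(flat)
        cfg = TrainingConfig(**meta["config"]) if meta["config"] else None
        return cls(net, meta["low"], meta["high"], config=cfg)


# ----------------------------------------------------------------------
# rollout + GAE
# ----------------------------------------------------------------------
def _collect_rollout(env, pi, vf, low, span, n_samples, rng, cfg):
    d_obs = env.observation_dim
    n_act = env.action_dim
    obs_buf = np.empty((n_samples, d_obs))
    u_buf = np.empty((n_samples, n_act))
    logp_buf = np.empty(n_samples)
    rew_buf = np.empty(n_samples)
    done_buf = np.zeros(n_samples, dtype=bool)  # true terminal (death)
    stop_buf = np.zeros(n_samples, dtype=bool)  # terminal or truncation
    ep_returns, ep_lens = [], []
    ep_ret = ep_len = 0.0

    obs = env.reset(seed=int(rng.integers(2**31 - 1))).as_vector()
    for t in range(n_samples):
        logits = pi.forward(obs[None, :])
        a, b = _shapes_from_logits(logits)
        u = np.clip(rng.beta(a, b)[0], _EPS, 1 - _EPS)
        logp = float(_beta_logpdf(u, a[0], b[0]).sum())
        action = low + span * u
        sr = env.step(action, compute_obs=True)

        obs_buf[t] = obs
        u_buf[t] = u
        logp_buf[t] = logp
        rew_buf[t] = sr.reward
        ep_ret += sr.reward
        ep_len += 1
        if sr.terminated or sr.truncated:
            done_buf[t] = sr.terminated
            stop_buf[t] = True
            ep_returns.append(ep_ret)
            ep_lens.append(ep_len)
            ep_ret = ep_len = 0.0
            obs = env.reset(seed=int(rng.integers(2**31 - 1))).as_vector()
        else:
            obs = sr.observation.as_vector()

    # values in one batched pass; bootstrap value for the trailing state
    values = vf.forward(obs_buf)[:, 0]
    v_last = float(vf.forward(obs[None, :])[0, 0])

    # GAE over episode segments
    adv = np.empty(n_samples)
    gl = cfg.gamma * cfg.gae_lambda
    last_gae = 0.0
    for t in range(n_samples - 1, -1, -1):
        if stop_buf[t]:
            v_next = 0.0 if done_buf[t] else _bootstrap(vf, env, obs_buf, t, n_samples, v_last)
            last_gae = 0.0
        else:
            v_next = values[t + 1] if t + 1 < n_samples else v_last
        delta = rew_buf[t] + cfg.gamma * v_next - values[t]
        last_gae = delta + gl * last_gae
        adv[t] = last_gae
    returns = adv + values
    if ep_returns:
        mean_ret, mean_len = float(np.mean(ep_returns)), float(np.mean(ep_lens))
    else:  # no episode finished within the batch
        mean_ret, mean_len = float(ep_ret), float(ep_len)
    return obs_buf, u_buf, logp_buf, adv, returns, mean_ret, mean_len, len(ep_returns)


def _bootstrap(vf, env, obs_buf, t, n, v_last):
    # truncation mid-batch: the successor observation was replaced by a
    # reset, so approximate the cut-off state's value by its own value
    # (the drive changes little in one tick).  The trailing cut uses the
    # true successor.
    if t == n - 1:
        return v_last
    return float(vf.forward(obs_buf[t][None, :])[0, 0])


# ----------------------------------------------------------------------
# PPO update
# ----------------------------------------------------------------------
def _policy_loss(pi, obs, u, logp_old, adv, cfg) -> float:
    """Clipped-surrogate + entropy loss (no gradients); used for checking."""
    logits = pi.forward(obs)
    a, b = _shapes_from_logits(logits)
    logp = _beta_logpdf(u, a, b).sum(axis=1)
    ratio = np.exp(logp - logp_old)
    surr1 = ratio * adv
    surr2 = np.clip(ratio, 1 - cfg.clip, 1 + cfg.clip) * adv
    return float(
        -np.minimum(surr1, surr2).mean()
        - cfg.entropy_coef * _beta_entropy(a, b).sum(axis=1).mean()
    )


def _policy_grads(pi, obs, u, logp_old, adv, cfg):
    """Loss and analytic parameter gradients of the clipped objective."""
    logits = pi.forward(obs)
    a, b = _shapes_from_logits(logits)
    logp = _beta_logpdf(u, a, b).sum(axis=1)
    ratio = np.exp(logp - logp_old)
    surr1 = ratio * adv
    surr2 = np.clip(ratio, 1 - cfg.clip, 1 + cfg.clip) * adv
    loss = (
        -np.minimum(surr1, surr2).mean()
        - cfg.entropy_coef * _beta_entropy(a, b).sum(axis=1).mean()
    )
    if not np.isfinite(loss):
        raise RuntimeError("PPO diverged: non-finite policy loss")

    n = obs.shape[0]
    grad_active = (surr1 <= surr2).astype(float)
    dlogp = -(adv * ratio * grad_active) / n  # d(loss)/d(logp_i)

    s = a + b
    dig_s = digamma(s)
    # d logp / d a, d b  (per dimension)
    dl_da = np.log(u) - digamma(a) + dig_s
    dl_db = np.log1p(-u) - digamma(b) + dig_s
    # entropy gradients
    tri_s = polygamma(1, s)
    dH_da = -(a - 1) * polygamma(1, a) + (s - 2) * tri_s
    dH_db = -(b - 1) * polygamma(1, b) + (s - 2) * tri_s

    da = dlogp[:, None] * dl_da - (cfg.entropy_coef / n) * dH_da
    db = dlogp[:, None] * dl_db - (cfg.entropy_coef / n) * dH_db
    # chain through softplus(+1)
    n_act = a.shape[1]
    dlogits = np.empty_like(logits)
    dlogits[:, :n_act] = da / (1.0 + np.exp(-logits[:, :n_act]))
    dlogits[:, n_act:] = db / (1.0 + np.exp(-logits[:, n_act:]))
    gW, gb = pi.backward(dlogits)
    return float(loss), gW + gb


def _policy_minibatch_update(pi, opt_pi, obs, u, logp_old, adv, cfg):
    loss, grads = _policy_grads(pi, obs, u, logp_old, adv, cfg)
    opt_pi.step(pi.params(), grads)
    return loss


def _value_grads(vf, obs, returns):
    v = vf.forward(obs)[:, 0]
    err = v - returns
    loss = 0.5 * float(np.mean(err**2))
    if not np.isfinite(loss):
        raise RuntimeError("PPO diverged: non-finite value loss")
    gW, gb = vf.backward((err / len(err))[:, None])
    return loss, gW + gb


def _value_minibatch_update(vf, opt_vf, obs, returns):
    loss, grads = _value_grads(vf, obs, returns)
    opt_vf.step(vf.params(), grads)
    return loss


def train_policy(
    env_factory: Callable[[], ForagingEnv],
    cfg: TrainingConfig,
    seed: int = 0,
    log_callback: Optional[Callable[[dict], None]] = None,
) -> tuple[TrainedPolicy, list[dict]]:
    """Run the PPO schedule and return the trained policy plus the log.

    The log has one entry per iteration with the mean episodic return, mean
    episode length and final losses — the training curve.
    """
    env = env_factory()
    rng = np.random.default_rng(seed)
    d_obs, n_act = env.observation_dim, env.action_dim
    pi = _MLP([d_obs, *cfg.hidden, 2 * n_act], rng)
    vf = _MLP([d_obs, *cfg.hidden, 1], rng, out_scale=1.0)
    opt_pi = _Adam(pi.params(), cfg.learning_rate)
    opt_vf = _Adam(vf.params(), cfg.learning_rate)
    low, span = env.action_low, env.action_high - env.action_low

    log: list[dict] = []
    for it in range(cfg.n_iterations):
        obs, u, logp_old, adv, rets, mean_ret, mean_len, n_eps = _collect_rollout(
            env, pi, vf, low, span, cfg.samples_per_iteration, rng, cfg
        )
        adv = (adv - adv.mean()) / (adv.std() + 1e-8)
        n = len(obs)
        p_loss = v_loss = np.nan
        for _ in range(cfg.epochs_per_iteration):
            order = rng.permutation(n)
            for start in range(0, n, cfg.minibatch):
                mb = order[start : start + cfg.minibatch]
                p_loss = _policy_minibatch_update(
                    pi, opt_pi, obs[mb], u[mb], logp_old[mb], adv[mb], cfg
                )
                v_loss = _value_minibatch_update(vf, opt_vf, obs[mb], rets[mb])
        entry = {
            "iteration": it,
            "mean_return": mean_ret,
            "mean_episode_length": mean_len,
            "n_episodes": n_eps,
            "policy_loss": p_loss,
            "value_loss": v_loss,
        }
        log.append(entry)
        if log_callback:
            log_callback(entry)

    policy = TrainedPolicy(pi, env.action_low, env.action_high, config=cfg, seed=seed)
    return policy, log


# ----------------------------------------------------------------------
# evaluation
# ----------------------------------------------------------------------
@dataclass
class EvaluationSummary:
    """Per-session and aggregate statistics of a policy evaluation."""

    returns: list[float]
    survived: list[bool]
    intake_red: list[float]
    intake_blue: list[float]
    mean_sq_red: list[float]
    mean_sq_blue: list[float]
    consumptions: list = field(default_factory=list)

    @property
    def mean_return(self) -> float:
        return float(np.mean(self.returns))

    @property
    def survival_rate(self) -> float:
        return float(np.mean(self.survived))

    @property
    def mean_intake(self) -> tuple[float, float]:
        return float(np.mean(self.intake_red)), float(np.mean(self.intake_blue))

    @property
    def interoceptive_errors(self) -> tuple[float, float]:
        """Time-averaged (s_red^2, s_blue^2), averaged over sessions."""
        return float(np.mean(self.mean_sq_red)), float(np.mean(self.mean_sq_blue))


def evaluate_policy(
    policy,
    env_factory: Callable[[], ForagingEnv],
    n_steps: int,
    n_sessions: int,
    base_seed: int = 0,
) -> EvaluationSummary:
    """Run independent sessions (seed = base_seed + index) and summarize."""
    out = EvaluationSummary([], [], [], [], [], [])
    for k in range(n_sessions):
        env = env_factory()
        res = run_session(policy, env, n_steps, seed=base_seed + k)
        out.returns.append(res.total_reward)
        out.survived.append(res.survived)
        out.intake_red.append(res.intake_red)
        out.intake_blue.append(res.intake_blue)
        out.mean_sq_red.append(res.mean_sq_red)
        out.mean_sq_blue.append(res.mean_sq_blue)
        out.consumptions.extend((k, *c) for c in res.consumptions)
    return out
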