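"""Offline dueling double-DQN trained on fixed EMR trajectories.

The Q-network is a fully connected net (input 49, hidden 64 and 32, batch
normalization and leaky-ReLU after each hidden layer) whose last hidden layer
splits into a state-value stream V(s) and an advantage stream A(s, a),
recombined as Q(s, a) = V(s) + A(s, a) − mean_a A(s, a).  Training uses
double-DQN targets (the evaluation network chooses the argmax action, the
slowly tracking target network values it), prioritized experience replay with
importance-weight correction, an additive penalty on Q-values whose magnitude
exceeds the maximum attainable reward, Adam updates, and a Polyak soft target
update every iteration.

The whole stack is plain NumPy with hand-written gradients, which keeps
training bit-deterministic for a given seed.
"""

from __future__ import annotations

import copy
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from .replay import PrioritizedReplay

LEAKY_SLOPE = 0.01
BN_EPS = 1e-5


class DQNError(RuntimeError):
    pass


@dataclass(frozen=True)
class TrainConfig:
    """Hyperparameters of the offline Q-learning loop (defaults as used for
    the registry-scale models; tests and demos shrink ``n_iterations``)."""

    gamma: float = 0.9          # discount factor
    tau: float = 0.01           # Polyak soft-update rate
    lr: float = 0.001           # Adam learning rate
    lr_final: float | None = None  # linear decay target (None: constant lr)
    batch_size: int = 256
    n_iterations: int = 100_000
    r_reg: float = 4.0          # Q-magnitude threshold of the penalty
    lam: float = 0.5            # penalty weight
    alpha: float = 0.6          # replay priority exponent
    beta: float = 0.4           # importance-weight exponent
    priority_floor: float = 1e-3
    grad_clip: float = 10.0     # global-norm gradient clip
    target_clip: float = 14.0   # bootstrapped targets clipped to +/- this
    conservative_weight: float = 0.5  # CQL-style penalty on out-of-data actions
    bn_momentum: float = 0.99
    seed: int = 0
    log_every: int = 1000

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")
        if not 0.0 < self.tau <= 1.0:
            raise ValueError("tau must lie in (0, 1]")
        for name in ("lr", "batch_size", "n_iterations", "lam", "priority_floor"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")


class QNetwork:
    """Dueling MLP with manual forward/backward passes."""

    def __init__(
        self,
        n_in: int,
        n_actions: int,
        hidden: tuple[int, int] = (64, 32),
        dueling: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.n_in, self.n_actions, self.hidden, self.dueling = (
            n_in, n_actions, tuple(hidden), dueling,
        )
        h1, h2 = hidden

        def he(n_a, n_b):
            return rng.normal(0.0, np.sqrt(2.0 / n_a), size=(n_a, n_b))

        self.params = {
            "W1": he(n_in, h1), "b1": np.zeros(h1),
            "g1": np.ones(h1), "be1": np.zeros(h1),
            "W2": he(h1, h2), "b2": np.zeros(h2),
            "g2": np.ones(h2), "be2": np.zeros(h2),
        }
        if dueling:
            self.params.update(
                {"Wv": he(h2, 1), "bv": np.zeros(1),
                 "Wa": he(h2, n_actions), "ba": np.zeros(n_actions)}
            )
        else:
            self.params.update({"Wo": he(h2, n_actions), "bo": np.zeros(n_actions)})
        # batch-norm running statistics (not gradient-trained)
        self.stats = {
            "m1": np.zeros(h1), "v1": np.ones(h1),
            "m2": np.zeros(h2), "v2": np.ones(h2),
        }

    # -- forward ----------------------------------------------------------
    def _bn_forward(self, z, layer, train, momentum):
        g, be = self.params[f"g{layer}"], self.params[f"be{layer}"]
        if train:
            mu, var = z.mean(axis=0), z.var(axis=0)
            self.stats[f"m{layer}"] = (
                momentum * self.stats[f"m{layer}"] + (1 - momentum) * mu
            )
            self.stats[f"v{layer}"] = (
                momentum * self.stats[f"v{layer}"] + (1 - momentum) * var
            )
        else:
            mu, var = self.stats[f"m{layer}"], self.stats[f"v{layer}"]
        std = np.sqrt(var + BN_EPS)
        zhat = (z - mu) / std
        return g * zhat + be, (zhat, std)

    def forward(self, X, train: bool = False, momentum: float = 0.99):
        X = np.asarray(X, float)
        if X.ndim == 1:
            X = X[None, :]
        if X.shape[1] != self.n_in:
            raise DQNError(f"state width {X.shape[1]} != network input {self.n_in}")
        p = self.params
        z1 = X @ p["W1"] + p["b1"]
        bn1, bn1c = self._bn_forward(z1, 1, train, momentum)
        h1 = np.where(bn1 > 0, bn1, LEAKY_SLOPE * bn1)
        z2 = h1 @ p["W2"] + p["b2"]
        bn2, bn2c = self._bn_forward(z2, 2, train, momentum)
        h2 = np.where(bn2 > 0, bn2, LEAKY_SLOPE * bn2)
        if self.dueling:
            v = h2 @ p["Wv"] + p["bv"]                    # (N, 1)
            a = h2 @ p["Wa"] + p["ba"]                    # (N, A)
            q = v + a - a.mean(axis=1, keepdims=True)
        else:
            q = h2 @ p["Wo"] + p["bo"]
        cache = (X, bn1, bn1c, h1, bn2, bn2c, h2)
        return q, cache

    def q_values(self, X) -> np.ndarray:
        """Deterministic evaluation-mode Q-values (frozen batch-norm stats)."""
        return self.forward(X, train=False)[0]

    # -- backward ---------------------------------------------------------
    @staticmethod
    def _bn_backward(dout, g, zhat, std):
        n = dout.shape[0]
        dg = (dout * zhat).sum(axis=0)
        dbe = dout.sum(axis=0)
        dzh = dout * g
        dz = (dzh * n - dzh.sum(axis=0) - zhat * (dzh * zhat).sum(axis=0)) / (n * std)
        return dz, dg, dbe

    def backward(self, dq, cache) -> dict:
        X, bn1, bn1c, h1, bn2, bn2c, h2 = cache
        p, grads = self.params, {}
        if self.dueling:
            dv = dq.sum(axis=1, keepdims=True)
            da = dq - dq.mean(axis=1, keepdims=True)
            grads["Wv"], grads["bv"] = h2.T @ dv, dv.sum(axis=0)
            grads["Wa"], grads["ba"] = h2.T @ da, da.sum(axis=0)
            dh2 = dv @ p["Wv"].T + da @ p["Wa"].T
        else:
            grads["Wo"], grads["bo"] = h2.T @ dq, dq.sum(axis=0)
            dh2 = dq @ p["Wo"].T
        dbn2 = dh2 * np.where(bn2 > 0, 1.0, LEAKY_SLOPE)
        dz2, grads["g2"], grads["be2"] = self._bn_backward(dbn2, p["g2"], *bn2c)
        grads["W2"], grads["b2"] = h1.T @ dz2, dz2.sum(axis=0)
        dh1 = dz2 @ p["W2"].T
        dbn1 = dh1 * np.where(bn1 > 0, 1.0, LEAKY_SLOPE)
        dz1, grads["g1"], grads["be1"] = self._bn_backward(dbn1, p["g1"], *bn1c)
        grads["W1"], grads["b1"] = X.T @ dz1, dz1.sum(axis=0)
        return grads

    def copy(self) -> "QNetwork":
        return copy.deepcopy(self)


def soft_update(target: QNetwork, source: QNetwork, tau: float) -> None:
    """Polyak update: target <- tau * source + (1 - tau) * target."""
    for k in target.params:
        if target.params[k].shape != source.params[k].shape:
            raise DQNError(f"parameter shape mismatch for {k}")
        target.params[k] = tau * source.params[k] + (1 - tau) * target.params[k]
    for k in target.stats:
        target.stats[k] = tau * source.stats[k] + (1 - tau) * target.stats[k]


def td_target(
    rewards: np.ndarray,
    next_states: np.ndarray,
    terminal: np.ndarray,
    qnet: QNetwork,
    target_net: QNetwork,
    gamma: float,
) -> np.ndarray:
    """Double-DQN targets: r + gamma * Q_target(s', argmax_a Q_eval(s', a));
    terminal samples reduce to r."""
    out = np.asarray(rewards, float).copy()
    alive = ~np.asarray(terminal, bool)
    if alive.any():
        ns = np.asarray(next_states, float)[alive]
        a_star = np.argmax(qnet.q_values(ns), axis=1)
        q_next = target_net.q_values(ns)[np.arange(len(a_star)), a_star]
        out[alive] += gamma * q_next
    return out


def loss_fn(
    q_pred: np.ndarray,
    targets: np.ndarray,
    weights: np.ndarray,
    lam: float,
    r_reg: float,
):
    """Weighted mean of squared TD error plus the over-magnitude penalty
    lam * max(|Q| - r_reg, 0).  Returns (loss, td_errors, dloss_dq)."""
    q_pred, targets = np.asarray(q_pred, float), np.asarray(targets, float)
    w = np.asarray(weights, float)
    if not (np.all(np.isfinite(q_pred)) and np.all(np.isfinite(targets))):
        raise DQNError("non-finite inputs to the loss")
    td = targets - q_pred
    penalty = np.maximum(np.abs(q_pred) - r_reg, 0.0)
    loss = float(np.mean(w * (td**2 + lam * penalty)))
    dq = w * (-2.0 * td + lam * np.sign(q_pred) * (penalty > 0)) / len(q_pred)
    return loss, td, dq


class Adam:
    def __init__(self, params: dict, lr: float, b1=0.9, b2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, b1, b2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0

    def step(self, params: dict, grads: dict) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g**2
            mhat = self.m[k] / (1 - self.b1**self.t)
            vhat = self.v[k] / (1 - self.b2**self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def _clip_gradients(grads: dict, max_norm: float) -> None:
    total = np.sqrt(sum(float((g**2).sum()) for g in grads.values()))
    if total > max_norm:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale


@dataclass
class QModel:
    """A trained Q-model: evaluation net, its target copy and provenance."""

    net: QNetwork
    target: QNetwork
    treatment_type: str
    config: TrainConfig
    scheme_fingerprint: str = ""
    loss_history: np.ndarray = field(default_factory=lambda: np.empty(0))

    def q_values(self, states) -> np.ndarray:
        return self.net.q_values(states)

    def greedy_action(self, state) -> int:
        return int(np.argmax(self.q_values(state)[0]))

    # -- checkpointing (plain JSON: text-only, human-inspectable) ----------
    def save(self, path) -> None:
        doc = {
            "treatment_type": self.treatment_type,
            "config": asdict(self.config),
            "scheme_fingerprint": self.scheme_fingerprint,
            "spec": {
                "n_in": self.net.n_in,
                "n_actions": self.net.n_actions,
                "hidden": list(self.net.hidden),
                "dueling": self.net.dueling,
            },
            "params": {k: v.tolist() for k, v in self.net.params.items()},
            "stats": {k: v.tolist() for k, v in self.net.stats.items()},
            "target_params": {k: v.tolist() for k, v in self.target.params.items()},
            "target_stats": {k: v.tolist() for k, v in self.target.stats.items()},
        }
        with open(path, "w") as fh:
            json.dump(doc, fh)

    @classmethod
    def load(cls, path) -> "QModel":
        with open(path) as fh:
            doc = json.load(fh)
        spec = doc["spec"]
        net = QNetwork(spec["n_in"], spec["n_actions"], tuple(spec["hidden"]),
                       spec["dueling"])
        net.params = {k: np.asarray(v) for k, v in doc["params"].items()}
        net.stats = {k: np.asarray(v) for k, v in doc["stats"].items()}
        tgt = net.copy()
        tgt.params = {k: np.asarray(v) for k, v in doc["target_params"].items()}
        tgt.stats = {k: np.asarray(v) for k, v in doc["target_stats"].items()}
        return cls(net, tgt, doc["treatment_type"], TrainConfig(**doc["config"]),
                   doc["scheme_fingerprint"])


def train(
    states: np.ndarray,
    actions: np.ndarray,
    rewards: np.ndarray,
    next_states: np.ndarray,
    terminal: np.ndarray,
    n_actions: int,
    config: TrainConfig = TrainConfig(),
    treatment_type: str = "antiglycemic",
    scheme_fingerprint: str = "",
    hidden: tuple[int, int] = (64, 32),
    dueling: bool = True,
    progress: bool = False,
) -> QModel:
    """Run the offline training loop on a fixed transition set.

    Each iteration: prioritized batch sample -> double-DQN targets ->
    weighted regularized loss -> Adam step on the evaluation network ->
    priority refresh with the new |TD errors| -> Polyak soft target update.
    Deterministic given ``config.seed``.
    """
    states = np.asarray(states, float)
    actions = np.asarray(actions, int)
    if len(states) == 0:
        raise DQNError("no transitions to train on")
    if actions.max() >= n_actions or actions.min() < 0:
        raise DQNError("action index out of range for the action space")

    rng = np.random.default_rng(config.seed)
    net = QNetwork(states.shape[1], n_actions, hidden, dueling, rng)
    tgt = net.copy()
    opt = Adam(net.params, config.lr)
    buffer = PrioritizedReplay(
        len(states), config.alpha, config.beta, config.priority_floor
    )
    history = np.empty(config.n_iterations)

    for it in range(config.n_iterations):
        idx, w = buffer.sample(config.batch_size, rng)
        targets = td_target(
            rewards[idx], next_states[idx], terminal[idx], net, tgt, config.gamma
        )
        if config.target_clip:
            # offline data never grounds rarely-taken actions; bounding the
            # bootstrapped target to the plausible return range blocks the
            # extrapolation-error feedback loop
            targets = np.clip(targets, -config.target_clip, config.target_clip)
        q_all, cache = net.forward(states[idx], train=True, momentum=config.bn_momentum)
        rows = np.arange(len(idx))
        q_sa = q_all[rows, actions[idx]]
        loss, td, dq_sa = loss_fn(q_sa, targets, w, config.lam, config.r_reg)
        if not np.isfinite(loss):
            raise DQNError(f"training diverged at iteration {it}: loss={loss}")
        dq = np.zeros_like(q_all)
        dq[rows, actions[idx]] = dq_sa
        if config.conservative_weight:
            # conservative value penalty: push down the soft-maximum over all
            # actions and up the logged action, so actions without behavioral
            # support cannot win the argmax through extrapolation alone
            z = q_all - q_all.max(axis=1, keepdims=True)
            softmax = np.exp(z)
            softmax /= softmax.sum(axis=1, keepdims=True)
            cw = config.conservative_weight * w[:, None] / len(idx)
            dq += cw * softmax
            dq[rows, actions[idx]] -= cw[:, 0]
        grads = net.backward(dq, cache)
        _clip_gradients(grads, config.grad_clip)
        if config.lr_final is not None:
            frac = it / max(config.n_iterations - 1, 1)
            opt.lr = config.lr + frac * (config.lr_final - config.lr)
        opt.step(net.params, grads)
        buffer.update(idx, td)
        soft_update(tgt, net, config.tau)
        history[it] = loss
        if progress and config.log_every and (it + 1) % config.log_every == 0:
            print(f"iter {it + 1}: loss={np.mean(history[max(0, it - 99): it + 1]):.4f}")

    return QModel(net, tgt, treatment_type, config, scheme_fingerprint, history)
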