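"""Prioritized experience replay over a fixed offline transition set.

The buffer is built once from the retrospective trajectories (offline RL: no
environment interaction) and holds one priority per transition, maintained as
|TD error| + floor.  Batches are drawn with probability proportional to
priority^alpha and paired with importance weights (N * P(i))^(-beta),
normalized by their maximum.
"""

from __future__ import annotations

import numpy as np


class ReplayError(ValueError):
    pass


class PrioritizedReplay:
    def __init__(
        self,
        n_items: int,
        alpha: float = 0.6,
        beta: float = 0.4,
        priority_floor: float = 1e-3,
    ) -> None:
        if n_items <= 0:
            raise ReplayError("empty replay buffer")
        self.alpha = float(alpha)
        self.beta = float(beta)
        self.priority_floor = float(priority_floor)
        # new items start at maximal priority so every transition is seen
        self.priorities = np.ones(n_items)

    def __len__(self) -> int:
        return len(self.priorities)

    def probabilities(self) -> np.ndarray:
        scaled = self.priorities**self.alpha
        return scaled / scaled.sum()

    def sample(self, batch_size: int, rng: np.random.Generator):
        """Draw a batch (with replacement); returns (indices, weights)."""
        p = self.probabilities()
        idx = rng.choice(len(p), size=batch_size, replace=True, p=p)
        w = (len(p) * p[idx]) ** (-self.beta)
        return idx, w / w.max()

    def update(self, idx: np.ndarray, td_errors: np.ndarray) -> None:
        pri = np.abs(td_errors) + self.priority_floor
        if not np.all(np.isfinite(pri)):
            raise ReplayError("non-finite TD errors in priority update")
        self.priorities[idx] = pri
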