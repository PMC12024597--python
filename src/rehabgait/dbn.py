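"""Dynamic (time-sliced) belief updating with a sliding evidence window.

The network is replicated over training cycles: one slice per cycle (20 min
by default).  Per node, a state-transition matrix is re-estimated from the
recent window of discretized observations with additive smoothing, the
current belief is propagated through it, and new evidence conditions the
result.  The window advances FIFO, so old cycles stop influencing the
transition estimate — the belief tracks the patient's current dynamics
rather than their whole history.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .errors import ConfigError, DegenerateEstimateError

__all__ = [
    "DbnConfig",
    "estimate_transition",
    "dbn_step",
    "NodeBeliefTracker",
]


@dataclass(frozen=True)
class DbnConfig:
    """Time-slice configuration.

    slice_duration_min: minutes per slice (one training cycle; default 20).
    window_length: number of past slices retained for transition estimation.
    transition_pseudocount: additive smoothing weight (counts per cell).
    """

    slice_duration_min: float = 20.0
    window_length: int = 5
    transition_pseudocount: float = 1.0

    def __post_init__(self):
        if self.slice_duration_min <= 0:
            raise ConfigError("slice_duration_min must be positive")
        if self.window_length < 1:
            raise ConfigError("window_length must be at least 1")
        if self.transition_pseudocount < 0:
            raise ConfigError("transition_pseudocount must be nonnegative")


def estimate_transition(window: Sequence[int], n_states: int,
                        pseudocount: float) -> np.ndarray:
    """Row-stochastic transition matrix from consecutive pairs in ``window``.

    ``T[i, j] = (c_ij + alpha) / (c_i. + n alpha)``.  An empty window with
    zero pseudocount has no defined estimate.
    """
    counts = np.zeros((n_states, n_states))
    for a, b in zip(window, list(window)[1:]):
        counts[int(a), int(b)] += 1.0
    if counts.sum() == 0 and pseudocount == 0:
        raise DegenerateEstimateError(
            "empty evidence window and zero pseudocount: transition matrix "
            "is undefined")
    smoothed = counts + pseudocount
    rows = smoothed.sum(axis=1, keepdims=True)
    # A row can still be all-zero when pseudocount is 0 but other rows have
    # counts; fall back to uniform for that unvisited state.
    zero = rows[:, 0] == 0
    smoothed[zero] = 1.0
    rows = smoothed.sum(axis=1, keepdims=True)
    return smoothed / rows


def dbn_step(beliefs: np.ndarray, new_evidence: int | None, cfg: DbnConfig,
             window: Sequence[int] = (),
             transition: np.ndarray | None = None
             ) -> tuple[np.ndarray, list[int]]:
    """Advance one node's belief by one slice.

    The transition matrix is re-estimated from ``window`` (unless given
    explicitly), the belief is propagated (``T' b``), and hard evidence for
    the new slice collapses the result.  Returns the new belief and the
    FIFO-advanced window.
    """
    b = np.asarray(beliefs, dtype=float)
    if b.ndim != 1 or abs(b.sum() - 1.0) > 1e-9 or np.any(b < 0):
        raise ConfigError("beliefs must be a normalized probability vector")
    k = b.shape[0]
    if transition is None:
        transition = estimate_transition(window, k,
                                         cfg.transition_pseudocount)
    T = np.asarray(transition, dtype=float)
    predicted = T.T @ b
    predicted = predicted / predicted.sum()
    if new_evidence is not None:
        if not 0 <= int(new_evidence) < k:
            raise ConfigError(f"evidence state {new_evidence} out of range")
        post = np.zeros(k)
        post[int(new_evidence)] = 1.0
    else:
        post = predicted
    new_window = deque(window, maxlen=cfg.window_length)
    if new_evidence is not None:
        new_window.append(int(new_evidence))
    return post, list(new_window)


@dataclass
class NodeBeliefTracker:
    """Stateful wrapper: sliding window + current belief for one node."""

    n_states: int
    cfg: DbnConfig = field(default_factory=DbnConfig)
    beliefs: np.ndarray | None = None
    window: list[int] = field(default_factory=list)

    def __post_init__(self):
        if self.beliefs is None:
            self.beliefs = np.full(self.n_states, 1.0 / self.n_states)

    def step(self, new_evidence: int | None = None) -> np.ndarray:
        self.beliefs, self.window = dbn_step(
            self.beliefs, new_evidence, self.cfg, self.window)
        return self.beliefs

    def transition(self) -> np.ndarray:
        return estimate_transition(self.window, self.n_states,
                                   self.cfg.transition_pseudocount)
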