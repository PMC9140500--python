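"""Exact discrete-time Bayesian baseline for two-state Markov environments.

Sufficient statistics are a matrix of directed transition counts; each
switch probability gets an independent Beta posterior under a uniform
Beta(1, 1) prior.  The point estimate used throughout is the posterior
median.  ``normalize_and_sample`` is the reference (sequential,
cumulative-sum) version of the operation that the circuit realizes
molecularly via competitive integrator binding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import betaincinv

from .environment import STATES, EnvTrace

__all__ = [
    "TransitionCounts",
    "BetaPosterior",
    "transition_update",
    "counts_from_trace",
    "posterior",
    "posterior_median",
    "normalize_and_sample",
    "predictive",
    "analytic_posterior_timecourse",
]


@dataclass(frozen=True)
class TransitionCounts:
    """n x n matrix of directed transition counts (row = from-state)."""

    counts: tuple[tuple[int, ...], ...] = ((0, 0), (0, 0))
    labels: tuple[str, ...] = STATES

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts)
        if arr.shape != (len(self.labels), len(self.labels)):
            raise ValueError("counts must be square and match labels")
        if (arr < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(
            self, "counts", tuple(tuple(int(v) for v in row) for row in arr)
        )

    @property
    def n_states(self) -> int:
        return len(self.labels)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=np.int64)

    def total(self) -> int:
        return int(self.as_array().sum())

    def index(self, state: str) -> int:
        try:
            return self.labels.index(state)
        except ValueError:
            raise KeyError(f"unknown state label {state!r}") from None

    def row(self, state: str) -> tuple[int, ...]:
        return self.counts[self.index(state)]


def transition_update(
    T: TransitionCounts, from_state: str, to_state: str
) -> TransitionCounts:
    """Increment the (from, to) counter by one; pure (returns a new matrix)."""
    i, j = T.index(from_state), T.index(to_state)
    arr = T.as_array()
    arr[i, j] += 1
    return TransitionCounts(tuple(map(tuple, arr)), T.labels)


def counts_from_trace(trace: EnvTrace | str) -> TransitionCounts:
    """Fold ``transition_update`` over adjacent state pairs of a trace."""
    states = trace.states if isinstance(trace, EnvTrace) else tuple(trace)
    if len(states) < 2:
        raise ValueError("need at least two states to count transitions")
    T = TransitionCounts()
    for a, b in zip(states, states[1:]):
        T = transition_update(T, a, b)
    return T


@dataclass(frozen=True)
class BetaPosterior:
    """Beta(alpha, beta) posterior over one switch probability."""

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("Beta parameters must be positive")

    @property
    def mean(self) -> float:
        return self.alpha / (self.alpha + self.beta)

    @property
    def std(self) -> float:
        a, b = self.alpha, self.beta
        return float(np.sqrt(a * b / ((a + b) ** 2 * (a + b + 1))))

    @property
    def median(self) -> float:
        return posterior_median(self)


def posterior(T: TransitionCounts, row: str) -> BetaPosterior:
    """Beta posterior over the switch probability of ``row``.

    With a uniform Beta(1, 1) prior: alpha = 1 + n_switch (off-diagonal
    count of the row), beta = 1 + n_stay (diagonal count).
    """
    i = T.index(row)
    counts = T.as_array()[i]
    n_stay = int(counts[i])
    n_switch = int(counts.sum() - counts[i])
    return BetaPosterior(alpha=1.0 + n_switch, beta=1.0 + n_stay)


def posterior_median(p: BetaPosterior) -> float:
    """0.5 quantile of Beta(alpha, beta), via regularized-incomplete-beta
    inversion (accurate well below 1e-9 absolute)."""
    return float(betaincinv(p.alpha, p.beta, 0.5))


def normalize_and_sample(row, rng: np.random.Generator) -> int:
    """Normalize a row of counts and sample an index in proportion.

    Reference sequential algorithm: compute cumulative sums, draw one
    uniform w in [0, 1), and return the first index whose cumulative
    normalized mass exceeds w.
    """
    row = np.asarray(row, dtype=float)
    if (row < 0).any():
        raise ValueError("row entries must be non-negative")
    total = row.sum()
    if total <= 0:
        raise ValueError("cannot sample from an all-zero row")
    w = rng.random()
    cumulative = 0.0
    for i, value in enumerate(row):
        cumulative += value / total
        if cumulative > w:
            return i
    return int(len(row) - 1)  # guard against float round-off


def predictive(
    current_state: str, pi_ab_hat: float, pi_ba_hat: float
) -> dict[str, float]:
    """P(X_{t+1} | X_t, estimated switch probabilities).

    P(next = A) is 1 - pi_ab_hat if currently in A, else pi_ba_hat.
    """
    for name, v in (("pi_ab_hat", pi_ab_hat), ("pi_ba_hat", pi_ba_hat)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must lie in [0, 1]")
    if current_state == "A":
        p_a = 1.0 - pi_ab_hat
    elif current_state == "B":
        p_a = pi_ba_hat
    else:
        raise ValueError(f"unknown state {current_state!r}")
    return {"A": p_a, "B": 1.0 - p_a}


def analytic_posterior_timecourse(
    trace: EnvTrace, grid_interval: float | None = None
) -> pd.DataFrame:
    """Per-grid-point posterior medians of both switch probabilities.

    At each grid time t the posteriors use all transitions among
    observations with timestamps <= t.  The default grid is the trace's
    own pulse grid, which observes the full discretized sequence
    (self-transitions included — these carry the duration information).
    """
    if grid_interval is not None and grid_interval <= 0:
        raise ValueError("grid_interval must be > 0")
    times = np.asarray(trace.times)
    if grid_interval is None:
        grid = times
    else:
        grid = np.arange(times[0], trace.horizon + 1e-9, grid_interval)

    arr = np.zeros((2, 2), dtype=np.int64)
    idx = {s: k for k, s in enumerate(STATES)}
    rows = []
    obs = 0  # observations consumed so far
    for t in grid:
        while obs < len(times) and times[obs] <= t + 1e-9:
            if obs > 0:
                arr[idx[trace.states[obs - 1]], idx[trace.states[obs]]] += 1
            obs += 1
        pab = posterior_median(
            BetaPosterior(1.0 + arr[0, 1], 1.0 + arr[0, 0])
        )
        pba = posterior_median(
            BetaPosterior(1.0 + arr[1, 0], 1.0 + arr[1, 1])
        )
        rows.append((float(t), pab, pba))
    return pd.DataFrame(rows, columns=["time", "pi_ab_median", "pi_ba_median"])
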