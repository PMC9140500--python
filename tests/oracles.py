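"""Independent oracles used by the test suite.

The master-equation oracle enumerates the reachable state space of a
small reaction network by breadth-first search and integrates the
chemical master equation with a dense matrix exponential — a route
entirely independent of the event-driven simulator it validates.
"""

from __future__ import annotations

import numpy as np
from scipy.linalg import expm

from polyinfer.circuit import N_SPECIES, RuleSet


def reachable_states(rules: RuleSet, x0: np.ndarray, cap: int = 400):
    """BFS enumeration of states reachable from x0 (error if > cap)."""
    start = tuple(int(v) for v in x0)
    seen = {start: 0}
    order = [start]
    frontier = [start]
    stoich = rules._stoich.astype(np.int64)
    while frontier:
        nxt = []
        for state in frontier:
            x = np.asarray(state, dtype=np.float64)
            a = rules.propensities(x)
            for j in np.nonzero(a > 0)[0]:
                target = tuple(
                    int(v) for v in (x + stoich[j])
                )
                if target not in seen:
                    if len(seen) >= cap:
                        raise RuntimeError("state space exceeds cap")
                    seen[target] = len(order)
                    order.append(target)
                    nxt.append(target)
        frontier = nxt
    return order, seen


def master_equation_distribution(
    rules: RuleSet, x0: np.ndarray, times
) -> tuple[list[tuple], np.ndarray]:
    """Exact P(state, t) for each requested time.

    Returns (states, dists) where dists[k, i] is the probability of
    ``states[i]`` at ``times[k]``.
    """
    order, index = reachable_states(rules, x0)
    n = len(order)
    Q = np.zeros((n, n))
    for i, state in enumerate(order):
        x = np.asarray(state, dtype=np.float64)
        a = rules.propensities(x)
        stoich = rules._stoich.astype(np.int64)
        for j in np.nonzero(a > 0)[0]:
            target = tuple(int(v) for v in (x + stoich[j]))
            k = index[target]
            Q[i, k] += a[j]
            Q[i, i] -= a[j]
    p0 = np.zeros(n)
    p0[index[tuple(int(v) for v in x0)]] = 1.0
    dists = np.vstack([p0 @ expm(Q * t) for t in times])
    return order, dists


def total_variation(p: np.ndarray, q: np.ndarray) -> float:
    return 0.5 * float(np.abs(p - q).sum())
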