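"""Exact stochastic simulation of the circuit rule set.

The direct-method SSA runs between the deterministic timed perturbations
of the environment schedule; scheduled events are hard interrupts (the
pending step is discarded, which is exact because exponential waiting
times are memoryless).  Species counts are sampled on a fixed
observation grid decoupled from reaction event times.

Which polymer extends never affects the kinetics (propensities depend
only on terminal-kind counts), so polymer sequences are reconstructed
after the fact by replaying the recorded seed/extension firings and
assigning each to a uniformly chosen eligible polymer from a dedicated
random substream.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .circuit import (
    INTEGRATOR_POOLS,
    N_SPECIES,
    SPECIES,
    CircuitConfig,
    CircuitState,
    Polymer,
    RateConstants,
    RuleSet,
    S,
    build_ruleset,
)
from .environment import PULSE, REMOVAL, EnvTrace, PerturbationEvent

__all__ = [
    "Trajectory",
    "simulate",
    "integrator_fraction",
    "run_environment",
    "mass_balance_residuals",
]

try:  # optional JIT of the inner SSA loop; the fallback is equivalent
    from numba import njit as _njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

#: random numbers drawn per block; chunk boundaries never affect results
_BLOCK = 1 << 14


def _ssa_chunk_py(xe, k, ri1, ri2, stoich, a, t, t_stop, exps, us, fired):
    """Advance until t_stop or until a random-number block is exhausted.

    Consumes one exponential per step and one uniform per fired
    reaction, in that order, so any implementation of this routine
    produces identical trajectories from identical blocks.

    Returns (t, n_fired, i_exp, i_uni, done).
    """
    n_r = k.shape[0]
    n_s = xe.shape[0] - 1
    i_exp = 0
    i_uni = 0
    n_fired = 0
    while True:
        a_tot = 0.0
        for j in range(n_r):
            a[j] = k[j] * xe[ri1[j]] * xe[ri2[j]]
            a_tot += a[j]
        if a_tot <= 0.0 or a_tot != a_tot or a_tot == np.inf:
            return t, n_fired, i_exp, i_uni, (1 if a_tot <= 0.0 else -1)
        if i_exp >= exps.shape[0] or i_uni >= us.shape[0]:
            return t, n_fired, i_exp, i_uni, 0
        t += exps[i_exp] / a_tot
        i_exp += 1
        if t >= t_stop:
            return t_stop, n_fired, i_exp, i_uni, 1
        u = us[i_uni] * a_tot
        i_uni += 1
        acc = 0.0
        j = n_r - 1
        for jj in range(n_r):
            acc += a[jj]
            if u < acc:
                j = jj
                break
        for sp in range(n_s):
            xe[sp] += stoich[j, sp]
        fired[n_fired] = j
        n_fired += 1


if _HAVE_NUMBA:
    _ssa_chunk_jit = _njit(cache=True, fastmath=False)(_ssa_chunk_py)
else:  # pragma: no cover
    _ssa_chunk_jit = _ssa_chunk_py

_EPS = 1e-9

#: channels whose firings are replayed to reconstruct polymer sequences
_POLYMER_CHANNELS = ("seed_A", "seed_B", "ext_AA", "ext_AB", "ext_BA", "ext_BB")


@dataclass
class Trajectory:
    """Grid-sampled copy numbers plus the applied perturbation log."""

    times: np.ndarray
    counts: np.ndarray  # (n_grid, n_species), int64
    species: tuple[str, ...]
    event_log: pd.DataFrame  # time, kind, species, amount (as applied)
    seed: int
    firing_totals: np.ndarray  # total firings per reaction channel
    reaction_names: tuple[str, ...]
    final_state: CircuitState | None = None
    config: CircuitConfig | None = None

    def series(self, name: str) -> np.ndarray:
        """Copy-number time series of one species by registry name."""
        return self.counts[:, getattr(S, name)]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=list(self.species))
        df.insert(0, "time", self.times)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _validate_schedule(
    schedule: Sequence[PerturbationEvent], horizon: float
) -> list[PerturbationEvent]:
    events = list(schedule)
    times = [e.time for e in events]
    if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
        raise ValueError("schedule must be ordered by time")
    if events and (times[0] < 0 or times[-1] > horizon + _EPS):
        raise ValueError("schedule times must lie within [0, horizon]")
    return events


def simulate(
    state0: CircuitState,
    rules: RuleSet,
    schedule: Sequence[PerturbationEvent],
    horizon: float,
    seed: int,
    sample_every: float = 1.0,
    track_polymers: bool = False,
) -> Trajectory:
    """Gillespie direct method interleaved with the perturbation schedule.

    Returns the grid-sampled trajectory; the final :class:`CircuitState`
    (with polymer sequences when ``track_polymers``) is attached as
    ``trajectory.final_state``.
    """
    if sample_every <= 0:
        raise ValueError("sample_every must be > 0")
    events = _validate_schedule(schedule, horizon)

    root = np.random.SeedSequence(seed)
    ss_ssa, ss_poly = root.spawn(2)
    rng = np.random.default_rng(ss_ssa)

    x = state0.x.astype(np.float64).copy()
    grid = np.arange(0.0, horizon + sample_every * 0.5, sample_every)
    out = np.empty((len(grid), N_SPECIES), dtype=np.float64)

    k = rules._k
    ri1 = rules._ri1
    ri2 = rules._ri2
    stoich = rules._stoich
    n_r = len(k)
    xe = np.empty(N_SPECIES + 1, dtype=np.float64)
    xe[:N_SPECIES] = x
    xe[N_SPECIES] = 1.0
    x = xe[:N_SPECIES]  # view
    a = np.empty(max(n_r, 1), dtype=np.float64)

    tracked_mask = np.zeros(max(n_r, 1), dtype=bool)
    firings: list[int] = []
    if track_polymers:
        for j, name in enumerate(rules.names()):
            tracked_mask[j] = name in _POLYMER_CHANNELS

    firing_totals = np.zeros(n_r, dtype=np.int64)
    applied: list[tuple[float, str, str, int]] = []

    chunk = _ssa_chunk_jit
    exps = rng.standard_exponential(_BLOCK)
    us = rng.random(_BLOCK)
    fired = np.empty(_BLOCK, dtype=np.int64)
    pos = [0, 0]  # consumed exponentials / uniforms in the current blocks

    def advance(t: float, t_stop: float) -> float:
        if n_r == 0:
            return t_stop
        nonlocal exps, us
        while True:
            t, n_f, i_e, i_u, done = chunk(
                xe, k, ri1, ri2, stoich, a, t, t_stop,
                exps[pos[0]:], us[pos[1]:], fired,
            )
            if n_f:
                firing_totals[:] += np.bincount(fired[:n_f], minlength=n_r)
                if track_polymers:
                    hits = fired[:n_f]
                    firings.extend(hits[tracked_mask[hits]].tolist())
            pos[0] += i_e
            pos[1] += i_u
            if done == 1:
                return t_stop
            if done == -1:
                raise OverflowError("propensity overflow")
            # random-number blocks exhausted: refill both (deterministic
            # policy shared by the jitted and pure-Python kernels)
            exps = rng.standard_exponential(_BLOCK)
            us = rng.random(_BLOCK)
            pos[0] = pos[1] = 0

    breakpoints = np.union1d(grid, [e.time for e in events])
    t = 0.0
    ev_i = 0
    grid_i = 0
    for t_bp in breakpoints:
        if t_bp > t:
            t = advance(t, float(t_bp))
        # scheduled events at this breakpoint; removal precedes pulse by
        # schedule construction
        while ev_i < len(events) and events[ev_i].time <= t_bp + _EPS:
            e = events[ev_i]
            if e.kind == REMOVAL:
                for sp, ctr, label in (
                    (S.free_A, S.removed_A, "A"),
                    (S.free_B, S.removed_B, "B"),
                ):
                    n = x[sp]
                    x[ctr] += n
                    x[sp] = 0.0
                    applied.append((e.time, REMOVAL, label, int(n)))
            elif e.kind == PULSE:
                sp = S.free_A if e.species == "A" else S.free_B
                ctr = S.pulsed_A if e.species == "A" else S.pulsed_B
                x[sp] += e.amount
                x[ctr] += e.amount
                applied.append((e.time, PULSE, e.species, e.amount))
            else:
                raise ValueError(f"unknown event kind {e.kind!r}")
            ev_i += 1
        while grid_i < len(grid) and grid[grid_i] <= t_bp + _EPS:
            out[grid_i] = x
            grid_i += 1

    if (x < -_EPS).any():
        raise RuntimeError("internal consistency failure: negative copies")

    polymers: list[Polymer] = []
    if track_polymers:
        polymers = _replay_polymers(
            firings, rules, np.random.default_rng(ss_poly)
        )
    final = CircuitState(x=x.copy(), polymers=polymers)

    return Trajectory(
        times=grid,
        counts=out.astype(np.int64),
        species=SPECIES,
        event_log=pd.DataFrame(
            applied, columns=["time", "kind", "species", "amount"]
        ),
        seed=seed,
        firing_totals=firing_totals,
        reaction_names=tuple(rules.names()),
        final_state=final,
        config=rules.config,
    )


def _replay_polymers(
    firings: list[int], rules: RuleSet, rng: np.random.Generator
) -> list[Polymer]:
    names = rules.names()
    polymers: list[Polymer] = []
    by_end: dict[str, list[Polymer]] = {"A": [], "B": []}
    for j in firings:
        name = names[j]
        if name.startswith("seed_"):
            kind = name[-1]
            p = Polymer(["T", kind])
            polymers.append(p)
            by_end[kind].append(p)
        else:  # ext_XY
            x_kind, y_kind = name[-2], name[-1]
            group = by_end[x_kind]
            i = int(rng.integers(len(group)))
            p = group[i]
            p.extend(y_kind)
            if x_kind != y_kind:
                group[i] = group[-1]
                group.pop()
                by_end[y_kind].append(p)
    return polymers


def integrator_fraction(traj: Trajectory, pool: str = "A-To-B") -> np.ndarray:
    """Active fraction of an integrator pool at each grid time.

    Active means bound by the pool's transition-encoding memory molecule;
    program-mode complexes formed on an active integrator still hold that
    molecule and count as active.
    """
    if pool not in INTEGRATOR_POOLS:
        raise KeyError(f"unknown integrator pool {pool!r}")
    idx = INTEGRATOR_POOLS[pool]
    c = traj.counts
    active = c[:, idx["act"]] + c[:, idx["cplx_prod"]]
    total = (
        c[:, idx["empty"]]
        + c[:, idx["act"]]
        + c[:, idx["rep"]]
        + c[:, idx["cplx_prod"]]
        + c[:, idx["cplx_deg"]]
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(total > 0, active / np.maximum(total, 1), 0.0)
    return frac


def run_environment(
    trace: EnvTrace,
    rates: RateConstants | None = None,
    config: CircuitConfig | None = None,
    seed: int = 0,
    sample_every: float = 1.0,
    track_polymers: bool = False,
) -> Trajectory:
    """Convenience wrapper: run the circuit against an environment trace."""
    rates = rates or RateConstants()
    if config is None:
        config = CircuitConfig(
            pulse_hint=trace.pulse_amount, interval_hint=trace.interval
        )
    rules = build_ruleset(rates, config)
    state0 = CircuitState.initial(config)
    return simulate(
        state0,
        rules,
        trace.events,
        horizon=trace.horizon,
        seed=seed,
        sample_every=sample_every,
        track_polymers=track_polymers,
    )


# --- invariants ------------------------------------------------------------

def mass_balance_residuals(
    counts: np.ndarray, config: CircuitConfig
) -> dict[str, np.ndarray]:
    """Residuals of the circuit's conservation laws (all should be 0).

    ``counts`` is either one state vector or a (n_grid, n_species) array.
    Covered: A/B mass balance (free + polymerized + complexed + degraded
    + removed = pulsed), T conservation, and fixed integrator totals.
    """
    c = np.atleast_2d(np.asarray(counts, dtype=np.int64))
    res = {
        "mass_A": (
            c[:, S.free_A]
            + c[:, S.seeded_A]
            + c[:, S.cum_AA]
            + c[:, S.cum_BA]
            + c[:, S.degraded_A]
            + c[:, S.removed_A]
            + c[:, S.cplx_AB_prod]
            + c[:, S.cplx_AB_deg]
            - c[:, S.pulsed_A]
        ),
        "mass_B": (
            c[:, S.free_B]
            + c[:, S.seeded_B]
            + c[:, S.cum_AB]
            + c[:, S.cum_BB]
            + c[:, S.degraded_B]
            + c[:, S.removed_B]
            + c[:, S.cplx_BA_prod]
            + c[:, S.cplx_BA_deg]
            - c[:, S.pulsed_B]
        ),
        "T_total": (
            c[:, S.T_free]
            + c[:, S.poly_end_A]
            + c[:, S.poly_end_B]
            - config.n_t
        ),
        "int_AB_total": (
            c[:, S.int_AB_empty]
            + c[:, S.int_AB_act]
            + c[:, S.int_AB_rep]
            + c[:, S.cplx_AB_prod]
            + c[:, S.cplx_AB_deg]
            - config.integrator_copies
        ),
        "int_BA_total": (
            c[:, S.int_BA_empty]
            + c[:, S.int_BA_act]
            + c[:, S.int_BA_rep]
            + c[:, S.cplx_BA_prod]
            + c[:, S.cplx_BA_deg]
            - config.integrator_copies
        ),
    }
    return res
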