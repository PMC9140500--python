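"""Markov chemical environments.

A two-state (A/B) discrete-time Markov chain drives a bioreactor schedule:
at fixed time intervals a state is sampled, and on every state change all
free A and B in the reactor are removed and a fixed pulse of the new
state's species is added.  The resulting timed event list is the only
input the stochastic circuit simulator consumes, so the generator here
doubles as the fixture generator for every experiment.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence, Union

import numpy as np
import pandas as pd

STATE_A = "A"
STATE_B = "B"
STATES = (STATE_A, STATE_B)

PULSE = "pulse"
REMOVAL = "removal"

__all__ = [
    "MarkovEnvSpec",
    "PiecewiseEnvSpec",
    "PerturbationEvent",
    "EnvTrace",
    "sample_state_sequence",
    "trace_to_perturbation_schedule",
]


def _check_prob(name: str, p: float) -> None:
    if not (0.0 <= p <= 1.0):
        raise ValueError(f"{name} must lie in [0, 1], got {p!r}")


@dataclass(frozen=True)
class MarkovEnvSpec:
    """Two-state Markov environment parameters.

    Self-transition probabilities are derived, never stored:
    ``pi_aa = 1 - pi_ab`` and ``pi_bb = 1 - pi_ba``.
    """

    pi_ab: float
    pi_ba: float
    interval: float = 50.0
    pulse_amount: int = 5000
    n_perturbations: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        _check_prob("pi_ab", self.pi_ab)
        _check_prob("pi_ba", self.pi_ba)
        if self.interval <= 0:
            raise ValueError("interval must be > 0")
        if self.pulse_amount <= 0:
            raise ValueError("pulse_amount must be a positive integer")
        if self.n_perturbations <= 0:
            raise ValueError("n_perturbations must be a positive integer")

    @property
    def pi_aa(self) -> float:
        return 1.0 - self.pi_ab

    @property
    def pi_bb(self) -> float:
        return 1.0 - self.pi_ba

    def transition_row(self, state: str) -> tuple[float, float]:
        """Return (P(next=A), P(next=B)) given the current state."""
        if state == STATE_A:
            return (self.pi_aa, self.pi_ab)
        if state == STATE_B:
            return (self.pi_ba, self.pi_bb)
        raise ValueError(f"unknown state {state!r}")


@dataclass(frozen=True)
class PiecewiseEnvSpec:
    """Concatenation of Markov segments sharing one seed stream.

    The first state of a later segment is sampled conditioned on the last
    state of the previous segment (the chain is continuous across the
    boundary; there is no re-initialization).
    """

    segments: tuple[MarkovEnvSpec, ...]
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("piecewise spec needs at least one segment")
        object.__setattr__(self, "segments", tuple(self.segments))

    @property
    def n_perturbations(self) -> int:
        return sum(s.n_perturbations for s in self.segments)


@dataclass(frozen=True)
class PerturbationEvent:
    """One timed reactor perturbation.

    ``kind == "removal"`` removes *all* free A and B (species is the
    literal "AB" and amount is 0 by convention); ``kind == "pulse"`` adds
    ``amount`` copies of ``species``.
    """

    time: float
    kind: str
    species: str
    amount: int


@dataclass(frozen=True)
class EnvTrace:
    """A sampled environment: state sequence, pulse times and event list."""

    states: tuple[str, ...]
    times: tuple[float, ...]
    events: tuple[PerturbationEvent, ...]
    interval: float
    pulse_amount: int
    seed: int
    segment_boundaries: tuple[float, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.states)

    def state_string(self) -> str:
        return "".join(self.states)

    @property
    def horizon(self) -> float:
        """End of the final epoch (one interval past the last pulse)."""
        return self.times[-1] + self.interval

    def n_switches(self) -> int:
        return sum(a != b for a, b in zip(self.states, self.states[1:]))

    def events_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(e.time, e.kind, e.species, e.amount) for e in self.events],
            columns=["time", "kind", "species", "amount"],
        )

    def to_tsv(self, path) -> None:
        self.events_table().to_csv(path, sep="\t", index=False)


def _sample_segment(
    rng: np.random.Generator,
    spec: MarkovEnvSpec,
    n: int,
    previous: str | None,
) -> list[str]:
    states: list[str] = []
    state = previous
    for _ in range(n):
        if state is None:
            # uniform initial distribution over {A, B}
            state = STATE_A if rng.random() < 0.5 else STATE_B
        else:
            p_a, _ = spec.transition_row(state)
            state = STATE_A if rng.random() < p_a else STATE_B
        states.append(state)
    return states


def sample_state_sequence(
    spec: Union[MarkovEnvSpec, PiecewiseEnvSpec],
) -> EnvTrace:
    """Sample a state sequence and build its perturbation schedule.

    The initial state is drawn uniformly from {A, B}; every subsequent
    state is drawn from the transition row of its predecessor.  Pulse
    timestamps are uniformly spaced at the (per-segment) interval.
    """
    if isinstance(spec, MarkovEnvSpec):
        segments = (spec,)
        seed = spec.seed
    else:
        segments = spec.segments
        seed = spec.seed
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    states: list[str] = []
    times: list[float] = []
    boundaries: list[float] = []
    t = 0.0
    previous: str | None = None
    for seg in segments:
        if states:
            boundaries.append(t)
        seg_states = _sample_segment(rng, seg, seg.n_perturbations, previous)
        for s in seg_states:
            states.append(s)
            times.append(t)
            t += seg.interval
        previous = states[-1]

    # Per-segment pulse amounts: build the schedule segment by segment.
    events: list[PerturbationEvent] = []
    idx = 0
    for seg in segments:
        seg_slice = slice(idx, idx + seg.n_perturbations)
        prev_state = states[idx - 1] if idx > 0 else None
        events.extend(
            _schedule(
                states[seg_slice],
                times[seg_slice],
                seg.pulse_amount,
                previous_state=prev_state,
            )
        )
        idx += seg.n_perturbations

    first = segments[0]
    return EnvTrace(
        states=tuple(states),
        times=tuple(times),
        events=tuple(events),
        interval=first.interval,
        pulse_amount=first.pulse_amount,
        seed=seed,
        segment_boundaries=tuple(boundaries),
    )


def _schedule(
    states: Sequence[str],
    times: Sequence[float],
    pulse_amount: int,
    previous_state: str | None = None,
) -> list[PerturbationEvent]:
    events: list[PerturbationEvent] = []
    prev = previous_state
    for state, t in zip(states, times):
        if prev is None:
            events.append(PerturbationEvent(t, PULSE, state, pulse_amount))
        elif state != prev:
            # removal strictly precedes the pulse at the same timestamp
            events.append(PerturbationEvent(t, REMOVAL, "AB", 0))
            events.append(PerturbationEvent(t, PULSE, state, pulse_amount))
        prev = state
    return events


def trace_to_perturbation_schedule(
    trace: EnvTrace, pulse_amount: int | None = None
) -> tuple[PerturbationEvent, ...]:
    """Deterministic timed event list consumed by the simulator.

    On a state change, all free A and B are removed and then the new
    state's species is pulsed; self-transitions produce no event.
    """
    amount = trace.pulse_amount if pulse_amount is None else pulse_amount
    return tuple(_schedule(trace.states, trace.times, amount))


def dwell_epochs(trace: EnvTrace) -> list[tuple[str, float, float]]:
    """Contiguous same-state epochs as (state, t_start, t_end) triples.

    ``t_end`` of the final epoch is the trace horizon.
    """
    epochs: list[tuple[str, float, float]] = []
    start = trace.times[0]
    state = trace.states[0]
    for s, t in zip(trace.states[1:], trace.times[1:]):
        if s != state:
            epochs.append((state, start, t))
            state, start = s, t
    epochs.append((state, start, trace.horizon))
    return epochs
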