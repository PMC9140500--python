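"""Anticipatory B-Program regulation and rate-constant calibration.

The regulation circuit couples free A/B to occupied integrators:
complexes on activator-bound integrators produce (A side) or degrade
(B side) the B-Program, so expression ramps up during A dwells and is
cleared after each B onset.  Rate constants are fitted against a
deterministic "sawtooth" target profile — peaks exactly at B onsets with
saturating, non-decreasing amplitudes — by derivative-free search in
log-rate space with common random numbers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, fields, replace

import numpy as np
from scipy.optimize import minimize

from .circuit import (
    CircuitConfig,
    CircuitState,
    RateConstants,
    RuleSet,
    build_ruleset,
)
from .environment import EnvTrace
from .simulator import Trajectory, simulate

__all__ = [
    "ProgramRules",
    "TargetProfile",
    "CalibrationResult",
    "program_ruleset",
    "sawtooth_target",
    "simulate_program",
    "mean_program_profile",
    "optimize_rates",
    "DEFAULT_FREE_PARAMS",
]

#: rate names searched by default during calibration
DEFAULT_FREE_PARAMS = (
    "k_a_on_int",
    "k_prod",
    "k_prog_deg",
    "k_prog_deg_b",
    "k_prog_basal",
)


@dataclass(frozen=True)
class ProgramRules:
    """Rates of the B-Program regulation reactions."""

    k_a_on_int: float = 1e-4
    k_a_off_int: float = 0.02
    k_prod: float = 0.5
    k_prog_deg: float = 0.005
    k_prod_b: float = 0.0
    k_prog_deg_b: float = 0.005
    k_prog_basal: float = 0.002

    def __post_init__(self) -> None:
        for f in fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"rate {f.name} must be >= 0")

    def merge_into(self, rates: RateConstants) -> RateConstants:
        return replace(
            rates, **{f.name: getattr(self, f.name) for f in fields(self)}
        )

    @classmethod
    def from_rates(cls, rates: RateConstants) -> "ProgramRules":
        return cls(
            **{f.name: getattr(rates, f.name) for f in fields(cls)}
        )


def program_ruleset(
    prog: ProgramRules,
    base_rates: RateConstants | None = None,
    config: CircuitConfig | None = None,
) -> RuleSet:
    """Full rule set with the regulation reactions appended."""
    base_rates = base_rates or RateConstants()
    config = config or CircuitConfig(n_t=100)
    if config.integrator_copies <= 0:
        raise ValueError("program circuit requires integrator pools")
    merged = prog.merge_into(base_rates)
    return build_ruleset(merged, replace(config, program_mode=True))


@dataclass(frozen=True)
class TargetProfile:
    """Deterministic sawtooth target for B-Program expression."""

    times: np.ndarray
    values: np.ndarray
    onsets: tuple[float, ...]
    amplitudes: tuple[float, ...]

    def __post_init__(self) -> None:
        amps = np.asarray(self.amplitudes)
        if len(amps) and (np.diff(amps) < -1e-12).any():
            raise ValueError("peak amplitudes must be non-decreasing")


def b_onset_times(trace: EnvTrace) -> list[float]:
    """Times at which the environment switches from A into B."""
    return [
        t
        for prev, cur, t in zip(trace.states, trace.states[1:], trace.times[1:])
        if prev == "A" and cur == "B"
    ]


def sawtooth_target(
    trace: EnvTrace,
    grid_times: np.ndarray,
    peak_scale: float = 100.0,
    peak_halfsat: float = 2.0,
    decay_tau: float | None = None,
    rise_span: float | None = None,
) -> TargetProfile:
    """Build the target profile on an observation grid.

    Expression ramps linearly over ``rise_span`` before each B onset,
    peaks exactly at the onset with amplitude
    ``peak_scale * k / (k + peak_halfsat)`` for the k-th onset
    (saturating, non-decreasing), and decays exponentially afterwards.
    An empty schedule (no B onset) yields a flat zero profile.
    """
    onsets = b_onset_times(trace)
    decay_tau = trace.interval / 2.0 if decay_tau is None else decay_tau
    rise_span = trace.interval if rise_span is None else rise_span
    grid = np.asarray(grid_times, dtype=float)

    amps = [
        peak_scale * (k + 1) / (k + 1 + peak_halfsat)
        for k in range(len(onsets))
    ]

    def decayed(t: float) -> float:
        # value of the most recent peak's decaying tail at time t
        v = 0.0
        for t_k, a_k in zip(onsets, amps):
            if t_k <= t:
                v = a_k * math.exp(-(t - t_k) / decay_tau)
        return v

    values = np.empty_like(grid)
    for i, t in enumerate(grid):
        v = decayed(t)
        for t_k, a_k in zip(onsets, amps):
            if t < t_k <= t + rise_span:
                start = t_k - rise_span
                v0 = decayed(start)
                frac = (t - start) / rise_span
                v = max(v, v0 + (a_k - v0) * frac)
                break
        values[i] = v
    return TargetProfile(
        times=grid,
        values=values,
        onsets=tuple(onsets),
        amplitudes=tuple(amps),
    )


def simulate_program(
    prog: ProgramRules,
    trace: EnvTrace,
    base_rates: RateConstants | None = None,
    config: CircuitConfig | None = None,
    seed: int = 0,
    sample_every: float = 1.0,
    track_polymers: bool = False,
) -> Trajectory:
    base_rates = base_rates or RateConstants()
    if config is None:
        config = CircuitConfig(
            n_t=100,
            pulse_hint=trace.pulse_amount,
            interval_hint=trace.interval,
        )
    rules = program_ruleset(prog, base_rates, config)
    state0 = CircuitState.initial(rules.config)
    return simulate(
        state0,
        rules,
        trace.events,
        horizon=trace.horizon,
        seed=seed,
        sample_every=sample_every,
        track_polymers=track_polymers,
    )


def mean_program_profile(
    prog: ProgramRules,
    trace: EnvTrace,
    seeds,
    base_rates: RateConstants | None = None,
    config: CircuitConfig | None = None,
    sample_every: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Seed-averaged B-Program series: (times, mean, std over seeds)."""
    series = []
    times = None
    for s in seeds:
        traj = simulate_program(
            prog, trace, base_rates, config, seed=int(s),
            sample_every=sample_every,
        )
        series.append(traj.series("b_program").astype(float))
        times = traj.times
    arr = np.vstack(series)
    return times, arr.mean(axis=0), arr.std(axis=0)


@dataclass
class CalibrationResult:
    rates: ProgramRules
    loss: float
    initial_loss: float
    loss_history: list[float]
    seeds: tuple[int, ...]
    n_evaluations: int
    best_profile: np.ndarray | None = None

    def report(self) -> str:
        lines = [f"loss = {self.loss:.6g} (initial {self.initial_loss:.6g})"]
        lines.append(f"evaluations = {self.n_evaluations}")
        lines.append(f"seeds = {list(self.seeds)}")
        for f in fields(ProgramRules):
            lines.append(f"{f.name} = {getattr(self.rates, f.name):.6g}")
        return "\n".join(lines)


def optimize_rates(
    initial: ProgramRules,
    target: TargetProfile,
    trace: EnvTrace,
    base_rates: RateConstants | None = None,
    config: CircuitConfig | None = None,
    n_eval_seeds: int = 5,
    budget: int = 200,
    seed: int = 0,
    free_params: tuple[str, ...] = DEFAULT_FREE_PARAMS,
    sample_every: float = 1.0,
) -> CalibrationResult:
    """Derivative-free MSE fit of the program rates against the target.

    Nelder-Mead in log10-rate space with a fixed set of evaluation seeds
    (common random numbers); a failed simulation penalizes the candidate
    rather than aborting.  The returned loss never exceeds the loss at
    the initial point because the initial simplex vertex is evaluated
    first and the best point seen is kept.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    base_rates = base_rates or RateConstants()
    eval_seeds = tuple(
        int(s.generate_state(1)[0])
        for s in np.random.SeedSequence(seed).spawn(n_eval_seeds)
    )

    x0 = np.array(
        [math.log10(max(getattr(initial, p), 1e-8)) for p in free_params]
    )
    history: list[float] = []
    best: dict = {"loss": np.inf, "rates": initial, "profile": None}

    def make_rates(x: np.ndarray) -> ProgramRules:
        # snap to the exact initial value where a coordinate is untouched
        # (avoids log10/exp round-off at the starting point)
        updates = {
            p: getattr(initial, p) if v == x0[i] else float(10.0 ** v)
            for i, (p, v) in enumerate(zip(free_params, x))
        }
        return replace(initial, **updates)

    def loss_fn(x: np.ndarray) -> float:
        rates = make_rates(x)
        try:
            _, mean, _ = mean_program_profile(
                rates, trace, eval_seeds, base_rates, config,
                sample_every=sample_every,
            )
            value = float(np.mean((mean - target.values) ** 2))
        except (OverflowError, RuntimeError, ValueError):
            value, mean = 1e12, None
        history.append(value)
        if value < best["loss"]:
            best.update(loss=value, rates=rates, profile=mean)
        return value

    initial_loss = loss_fn(x0)
    if budget > 1:
        minimize(
            loss_fn,
            x0,
            method="Nelder-Mead",
            options={
                "maxfev": budget - 1,
                "xatol": 0.01,
                "fatol": 1e-8,
                "adaptive": True,
            },
        )

    return CalibrationResult(
        rates=best["rates"],
        loss=best["loss"],
        initial_loss=initial_loss,
        loss_history=history,
        seeds=eval_seeds,
        n_evaluations=len(history),
        best_profile=best["profile"],
    )
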