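"""Comparisons between the circuit readout and the analytic baseline.

Per replicate, the analytic summary is the median over time of per-time
posterior medians; the circuit summary is the end-state (or median over
time) active-integrator fraction.  Because the two quantities are not on
the same scale, the comparison uses the ratio of the two analytic
medians against the ratio of the two active fractions, pooled over a
grid of transition-probability settings and scored by Spearman rank
correlation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .circuit import CircuitConfig, RateConstants
from .environment import MarkovEnvSpec, sample_state_sequence
from .inference import analytic_posterior_timecourse
from .simulator import Trajectory, integrator_fraction, run_environment

__all__ = [
    "ComparisonSummary",
    "SweepResult",
    "summarize_analytic",
    "summarize_circuit",
    "sweep_and_correlate",
    "tracking_correlation",
    "DEFAULT_SETTINGS",
]

#: default 3x3 sweep grid over (pi_ab, pi_ba)
DEFAULT_SETTINGS: tuple[tuple[float, float], ...] = tuple(
    (a, b) for a in (0.05, 0.5, 0.95) for b in (0.05, 0.5, 0.95)
)


@dataclass(frozen=True)
class ComparisonSummary:
    """One replicate's scalar summaries and ratios."""

    pi_ab: float
    pi_ba: float
    replicate: int
    seed: int
    pi_hat_ab: float
    pi_hat_ba: float
    i_hat_ab: float
    i_hat_ba: float

    @property
    def ratio_posterior(self) -> float:
        return self.pi_hat_ab / self.pi_hat_ba

    @property
    def ratio_integrator(self) -> float | None:
        if self.i_hat_ba <= 0:
            return None
        return self.i_hat_ab / self.i_hat_ba


def summarize_analytic(timecourse: pd.DataFrame) -> tuple[float, float]:
    """Median over time of the per-time posterior medians."""
    if len(timecourse) == 0:
        raise ValueError("empty timecourse")
    return (
        float(timecourse["pi_ab_median"].median()),
        float(timecourse["pi_ba_median"].median()),
    )


def summarize_circuit(
    traj: Trajectory, mode: str = "endpoint"
) -> tuple[float, float]:
    """Scalar active-integrator fractions for both pools.

    ``endpoint`` takes the final grid time; ``median_over_time`` the
    median over the full grid.
    """
    f_ab = integrator_fraction(traj, "A-To-B")
    f_ba = integrator_fraction(traj, "B-To-A")
    if mode == "endpoint":
        return float(f_ab[-1]), float(f_ba[-1])
    if mode == "median_over_time":
        return float(np.median(f_ab)), float(np.median(f_ba))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class SweepResult:
    table: pd.DataFrame
    rho: float | None
    n_excluded: int
    per_setting_rho: pd.DataFrame

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def report(self) -> str:
        rho = "undefined" if self.rho is None else f"{self.rho:.4f}"
        return (
            f"pooled Spearman rho = {rho}\n"
            f"points = {len(self.table)} (excluded {self.n_excluded})\n"
        )


def sweep_and_correlate(
    settings=DEFAULT_SETTINGS,
    n_replicates: int = 20,
    interval: float = 50.0,
    n_perturbations: int = 50,
    pulse_amount: int = 5000,
    rates: RateConstants | None = None,
    config: CircuitConfig | None = None,
    seed: int = 0,
    mode: str = "median_over_time",
    sample_every: float = 5.0,
) -> SweepResult:
    """Run the setting-by-replicate sweep and pool the rank correlation.

    Every setting x replicate draws a fresh environment and a fresh
    circuit run from deterministic substreams of ``seed``.  Replicates
    whose integrator ratio is undefined (zero denominator) are excluded
    from the correlation and counted.
    """
    settings = list(settings)
    if len(settings) < 2:
        raise ValueError("need at least two settings")
    rates = rates or RateConstants()
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(settings) * n_replicates)

    rows = []
    n_excluded = 0
    it = iter(children)
    for pi_ab, pi_ba in settings:
        for rep in range(n_replicates):
            child = next(it)
            env_seed, circ_seed = (
                int(s.generate_state(1)[0]) for s in child.spawn(2)
            )
            spec = MarkovEnvSpec(
                pi_ab=pi_ab,
                pi_ba=pi_ba,
                interval=interval,
                pulse_amount=pulse_amount,
                n_perturbations=n_perturbations,
                seed=env_seed,
            )
            trace = sample_state_sequence(spec)
            cfg = config or CircuitConfig(
                pulse_hint=pulse_amount, interval_hint=interval
            )
            traj = run_environment(
                trace, rates, cfg, seed=circ_seed, sample_every=sample_every
            )
            pi_hat_ab, pi_hat_ba = summarize_analytic(
                analytic_posterior_timecourse(trace)
            )
            i_hat_ab, i_hat_ba = summarize_circuit(traj, mode=mode)
            summary = ComparisonSummary(
                pi_ab, pi_ba, rep, circ_seed,
                pi_hat_ab, pi_hat_ba, i_hat_ab, i_hat_ba,
            )
            ratio_i = summary.ratio_integrator
            if ratio_i is None:
                n_excluded += 1
            rows.append(
                {
                    "pi_ab": pi_ab,
                    "pi_ba": pi_ba,
                    "replicate": rep,
                    "seed": circ_seed,
                    "pi_hat_ab": pi_hat_ab,
                    "pi_hat_ba": pi_hat_ba,
                    "i_hat_ab": i_hat_ab,
                    "i_hat_ba": i_hat_ba,
                    "ratio_posterior": summary.ratio_posterior,
                    "ratio_integrator": np.nan if ratio_i is None else ratio_i,
                }
            )

    table = pd.DataFrame(rows)
    ok = table.dropna(subset=["ratio_integrator"])
    rho = _spearman(ok["ratio_posterior"], ok["ratio_integrator"])

    per_setting = []
    for (pi_ab, pi_ba), grp in ok.groupby(["pi_ab", "pi_ba"]):
        per_setting.append(
            {
                "pi_ab": pi_ab,
                "pi_ba": pi_ba,
                "rho": _spearman(grp["ratio_posterior"], grp["ratio_integrator"]),
                "n": len(grp),
            }
        )
    return SweepResult(
        table=table,
        rho=rho,
        n_excluded=n_excluded,
        per_setting_rho=pd.DataFrame(per_setting),
    )


def _spearman(x, y) -> float | None:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return None
    rho = spearmanr(x, y).statistic
    return None if np.isnan(rho) else float(rho)


def tracking_correlation(
    fraction: np.ndarray,
    fraction_times: np.ndarray,
    timecourse: pd.DataFrame,
    which: str = "pi_ab",
    burn_in_fraction: float = 0.2,
) -> float:
    """Spearman correlation between an (ensemble-mean) active-integrator
    fraction series and the analytic posterior-median series.

    The analytic series is stepped onto the trajectory grid.  An initial
    burn-in window is discarded: the circuit starts with empty pools
    while the analytic model starts from the prior, so the two are not
    comparable until memory has accumulated.
    """
    col = "pi_ab_median" if which == "pi_ab" else "pi_ba_median"
    t_grid = np.asarray(fraction_times, dtype=float)
    idx = np.searchsorted(
        np.asarray(timecourse["time"], dtype=float), t_grid, side="right"
    ) - 1
    idx = np.clip(idx, 0, len(timecourse) - 1)
    analytic = np.asarray(timecourse[col], dtype=float)[idx]
    start = int(len(t_grid) * burn_in_fraction)
    rho = _spearman(fraction[start:], analytic[start:])
    return float("nan") if rho is None else rho
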