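import numpy as np
import pytest

from polyinfer.circuit import (
    CircuitConfig,
    CircuitState,
    RateConstants,
    Reaction,
    RuleSet,
    S,
    build_ruleset,
)
from polyinfer.environment import (
    MarkovEnvSpec,
    PerturbationEvent,
    sample_state_sequence,
)
from polyinfer.simulator import (
    integrator_fraction,
    mass_balance_residuals,
    run_environment,
    simulate,
)

from tests.oracles import master_equation_distribution, total_variation


def toy_ruleset(reactions):
    return RuleSet(reactions, RateConstants(), CircuitConfig())


def empty_state():
    return CircuitState(x=np.zeros(len(RuleSet([], RateConstants(), CircuitConfig()).species)))


class TestScheduleHandling:
    def test_empty_rules_constant_after_pulse(self):
        rules = toy_ruleset([])
        state = CircuitState.initial(CircuitConfig(n_t=0, integrator_copies=0))
        schedule = [PerturbationEvent(0.0, "pulse", "A", 100)]
        traj = simulate(state, rules, schedule, horizon=10.0, seed=1)
        assert (traj.series("free_A") == 100).all()

    def test_removal_zeroes_free_species(self):
        rules = toy_ruleset([])
        state = CircuitState.initial(CircuitConfig(n_t=0, integrator_copies=0))
        schedule = [
            PerturbationEvent(0.0, "pulse", "A", 50),
            PerturbationEvent(5.0, "removal", "AB", 0),
            PerturbationEvent(5.0, "pulse", "B", 70),
        ]
        traj = simulate(state, rules, schedule, horizon=10.0, seed=1)
        i5 = np.searchsorted(traj.times, 5.0)
        assert traj.series("free_A")[i5] == 0
        assert traj.series("free_B")[i5] == 70
        removed = traj.event_log.query("kind == 'removal' and species == 'A'")
        assert removed["amount"].iloc[0] == 50

    def test_unordered_schedule_rejected(self):
        rules = toy_ruleset([])
        state = empty_state()
        schedule = [
            PerturbationEvent(5.0, "pulse", "A", 1),
            PerturbationEvent(1.0, "pulse", "B", 1),
        ]
        with pytest.raises(ValueError):
            simulate(state, rules, schedule, horizon=10.0, seed=1)

    def test_schedule_outside_horizon_rejected(self):
        rules = toy_ruleset([])
        with pytest.raises(ValueError):
            simulate(
                empty_state(),
                rules,
                [PerturbationEvent(99.0, "pulse", "A", 1)],
                horizon=10.0,
                seed=1,
            )


class TestDeathProcessOracle:
    def test_mean_decay_matches_closed_form(self):
        # linear death process: E[N(t)] = n0 * exp(-d t)
        d, n0, t_end = 0.05, 200, 10.0
        rules = toy_ruleset(
            [
                Reaction(
                    "death", d, (S.free_A,),
                    ((S.free_A, -1), (S.degraded_A, 1)),
                )
            ]
        )
        finals = []
        for seed in range(300):
            state = empty_state()
            state.x[S.free_A] = n0
            traj = simulate(state, rules, [], horizon=t_end, seed=seed,
                            sample_every=t_end)
            finals.append(traj.series("free_A")[-1])
        expected = n0 * np.exp(-d * t_end)
        var = n0 * np.exp(-d * t_end) * (1 - np.exp(-d * t_end))
        se = np.sqrt(var / len(finals))
        assert abs(np.mean(finals) - expected) <= 3 * se


@pytest.fixture(scope="module")
def toy():
    # A+B -> C, C -> A+B, C+B -> D on a small closed state space
    reactions = [
        Reaction("bind", 0.05, (S.free_A, S.free_B),
                 ((S.free_A, -1), (S.free_B, -1), (S.mem_AA, 1))),
        Reaction("unbind", 0.2, (S.mem_AA,),
                 ((S.mem_AA, -1), (S.free_A, 1), (S.free_B, 1))),
        Reaction("convert", 0.02, (S.mem_AA, S.free_B),
                 ((S.mem_AA, -1), (S.free_B, -1), (S.mem_AB, 1))),
    ]
    rules = toy_ruleset(reactions)
    x0 = np.zeros(len(rules.species))
    x0[S.free_A] = 4
    x0[S.free_B] = 6
    return rules, x0


class TestMasterEquationOracle:

    def test_state_space_is_small(self, toy):
        from tests.oracles import reachable_states

        rules, x0 = toy
        order, _ = reachable_states(rules, x0)
        assert 2 < len(order) <= 200

    def test_empirical_distribution_matches_master_equation(self, toy):
        rules, x0 = toy
        checkpoints = [1.0, 4.0, 12.0]
        order, dists = master_equation_distribution(rules, x0, checkpoints)
        index = {s: i for i, s in enumerate(order)}

        n_runs = 10_000
        counts = np.zeros((len(checkpoints), len(order)))
        for seed in range(n_runs):
            state = CircuitState(x=x0.copy())
            traj = simulate(
                state, rules, [], horizon=checkpoints[-1], seed=seed,
                sample_every=1.0,
            )
            for k, t in enumerate(checkpoints):
                row = traj.counts[np.searchsorted(traj.times, t)]
                counts[k, index[tuple(int(v) for v in row)]] += 1
        for k in range(len(checkpoints)):
            tv = total_variation(counts[k] / n_runs, dists[k])
            assert tv < 0.05, f"checkpoint {checkpoints[k]}: TV={tv:.4f}"


class TestDeterminism:
    def test_identical_seed_identical_trajectory(self):
        spec = MarkovEnvSpec(pi_ab=0.9, pi_ba=0.9, n_perturbations=8, seed=4)
        trace = sample_state_sequence(spec)
        t1 = run_environment(trace, seed=99, track_polymers=True)
        t2 = run_environment(trace, seed=99, track_polymers=True)
        assert (t1.counts == t2.counts).all()
        assert [str(p) for p in t1.final_state.polymers] == [
            str(p) for p in t2.final_state.polymers
        ]

    def test_python_kernel_matches_jit_kernel(self, monkeypatch):
        # both kernels consume the identical random stream
        import polyinfer.simulator as sim

        spec = MarkovEnvSpec(pi_ab=0.9, pi_ba=0.9, n_perturbations=6, seed=4)
        trace = sample_state_sequence(spec)
        fast = run_environment(trace, seed=31)
        monkeypatch.setattr(sim, "_ssa_chunk_jit", sim._ssa_chunk_py)
        slow = run_environment(trace, seed=31)
        assert (fast.counts == slow.counts).all()

    def test_different_seed_differs(self):
        spec = MarkovEnvSpec(pi_ab=0.9, pi_ba=0.9, n_perturbations=8, seed=4)
        trace = sample_state_sequence(spec)
        t1 = run_environment(trace, seed=1)
        t2 = run_environment(trace, seed=2)
        assert (t1.counts != t2.counts).any()


class TestIntegratorFraction:
    def test_empty_pool_zero(self):
        rules = toy_ruleset([])
        traj = simulate(
            CircuitState.initial(CircuitConfig(n_t=0)), rules, [],
            horizon=5.0, seed=0,
        )
        assert (integrator_fraction(traj, "A-To-B") == 0).all()
        with pytest.raises(KeyError):
            integrator_fraction(traj, "nope")

    def test_symmetric_clamped_pools_half_active(self):
        rates = RateConstants(
            k_poly=0, k_mem_deg=0, k_ab_deg=0, k_on_act=1.0, k_off=0.05
        )
        cfg = CircuitConfig(
            n_t=0, integrator_copies=200, clamp_memory=True, bias_factor=1.0
        )
        rules = build_ruleset(rates, cfg)
        state = CircuitState.initial(cfg)
        state.x[S.mem_AB] = 50
        state.x[S.mem_AA] = 50
        traj = simulate(state, rules, [], horizon=2000.0, seed=5)
        frac = integrator_fraction(traj, "A-To-B")
        mean = frac[200:].mean()
        assert abs(mean - 0.5 * (1 - 1e-3)) < 0.02  # empty ~ koff/(a+r)

    def test_clamped_three_to_one_equilibrium(self):
        # normalization: long-run active fraction ~ c1/(c1+c2) = 0.75
        rates = RateConstants(
            k_poly=0, k_mem_deg=0, k_ab_deg=0, k_on_act=1.0, k_off=0.01
        )
        cfg = CircuitConfig(
            n_t=0, integrator_copies=400, clamp_memory=True, bias_factor=1.0
        )
        rules = build_ruleset(rates, cfg)
        state = CircuitState.initial(cfg)
        state.x[S.mem_AB] = 300
        state.x[S.mem_AA] = 100
        traj = simulate(state, rules, [], horizon=10_100.0, seed=8)
        frac = integrator_fraction(traj, "A-To-B")[100:]
        # ~1e4 grid samples; correlation time ~ 1/k_off = 100 units
        n_eff = len(frac) / 200
        se = np.sqrt(0.75 * 0.25 / 400) / np.sqrt(n_eff)
        assert abs(frac.mean() - 0.75) <= 3 * se + 1e-3


@pytest.fixture(scope="module")
def traj():
    spec = MarkovEnvSpec(pi_ab=0.95, pi_ba=0.95, n_perturbations=15, seed=3)
    trace = sample_state_sequence(spec)
    return run_environment(trace, seed=21)


class TestCircuitRunInvariants:

    def test_counts_non_negative(self, traj):
        assert (traj.counts >= 0).all()

    def test_mass_balance_at_every_sample(self, traj):
        for name, res in mass_balance_residuals(
            traj.counts, traj.config
        ).items():
            assert (res == 0).all(), name

    def test_cumulative_counters_monotone(self, traj):
        for name in ("cum_AA", "cum_AB", "cum_BA", "cum_BB",
                     "seeded_A", "seeded_B"):
            assert (np.diff(traj.series(name)) >= 0).all(), name

    def test_removal_then_pulse_ordering(self, traj):
        log = traj.event_log
        for t, grp in log.groupby("time"):
            kinds = list(grp["kind"])
            if "removal" in kinds:
                assert kinds.index("removal") < max(
                    i for i, k in enumerate(kinds) if k == "pulse"
                )

    def test_exports(self, traj, tmp_path):
        traj.to_tsv(tmp_path / "traj.tsv")
        import pandas as pd

        df = pd.read_csv(tmp_path / "traj.tsv", sep="\t")
        assert df.shape[0] == len(traj.times)
        assert "free_A" in df.columns
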