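"""Domain model of the polymerizing circuit.

Linear polymers are seeded by T monomers and grow irreversibly at the
tail; every extension emits one memory molecule ex nihilo whose identity
encodes the (previous terminal -> added monomer) pair.  Transition-
encoding memory molecules (A-To-B, B-To-A) act as activators and
duration-encoding ones (A-To-A, B-To-B) as repressors on fixed pools of
integrators, bound mutually exclusively; the activator-bound fraction
realizes normalization-sampling.

Propensities depend only on pooled counts (free monomers, polymers
grouped by terminal kind, free memory, integrator occupancy), so the
reaction network compiles to a count-vector mass-action system; the
individual polymer sequences are tracked separately and do not feed back
on the kinetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

__all__ = [
    "SPECIES",
    "S",
    "Monomer",
    "Polymer",
    "RateConstants",
    "CircuitConfig",
    "Reaction",
    "RuleSet",
    "CircuitState",
    "build_ruleset",
    "enumerate_propensities",
    "polymer_report",
    "PolymerReport",
    "MEMORY_KINDS",
    "INTEGRATOR_POOLS",
]

# --- species registry ------------------------------------------------------

SPECIES: tuple[str, ...] = (
    "free_A",
    "free_B",
    "T_free",
    "poly_end_A",
    "poly_end_B",
    "mem_AA",
    "mem_AB",
    "mem_BA",
    "mem_BB",
    "int_AB_empty",
    "int_AB_act",
    "int_AB_rep",
    "int_BA_empty",
    "int_BA_act",
    "int_BA_rep",
    "b_program",
    "cplx_AB_prod",
    "cplx_AB_deg",
    "cplx_BA_prod",
    "cplx_BA_deg",
    # cumulative counters (pseudo-species; only ever incremented)
    "seeded_A",
    "seeded_B",
    "cum_AA",
    "cum_AB",
    "cum_BA",
    "cum_BB",
    "degraded_A",
    "degraded_B",
    "removed_A",
    "removed_B",
    "pulsed_A",
    "pulsed_B",
)


class S:
    """Integer index for every species (``S.free_A`` etc.)."""


for _i, _name in enumerate(SPECIES):
    setattr(S, _name, _i)

N_SPECIES = len(SPECIES)

#: memory-molecule display names -> (free-pool species, cumulative counter)
MEMORY_KINDS = {
    "A-To-A": (S.mem_AA, S.cum_AA),
    "A-To-B": (S.mem_AB, S.cum_AB),
    "B-To-A": (S.mem_BA, S.cum_BA),
    "B-To-B": (S.mem_BB, S.cum_BB),
}

#: integrator pool name -> dict of occupancy species
INTEGRATOR_POOLS = {
    "A-To-B": {
        "empty": S.int_AB_empty,
        "act": S.int_AB_act,
        "rep": S.int_AB_rep,
        "cplx_prod": S.cplx_AB_prod,
        "cplx_deg": S.cplx_AB_deg,
    },
    "B-To-A": {
        "empty": S.int_BA_empty,
        "act": S.int_BA_act,
        "rep": S.int_BA_rep,
        "cplx_prod": S.cplx_BA_prod,
        "cplx_deg": S.cplx_BA_deg,
    },
}


# --- structural types ------------------------------------------------------


@dataclass(frozen=True)
class Monomer:
    """A monomer with polar head/tail bond sites.

    ``head``/``tail`` are either ``None`` (free site) or the index of the
    bonded neighbour within a polymer.  T monomers only ever occupy the
    head end of a polymer.
    """

    kind: str  # "T", "A" or "B"
    head: int | None = None
    tail: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("T", "A", "B"):
            raise ValueError(f"unknown monomer kind {self.kind!r}")


class Polymer:
    """Ordered monomer kinds from the head (always T) to the tail end.

    Growth happens only at the tail and is irreversible.
    """

    __slots__ = ("sequence",)

    def __init__(self, sequence: Iterable[str]):
        seq = list(sequence)
        if not seq or seq[0] != "T":
            raise ValueError("a polymer starts with a T monomer")
        if any(m not in ("A", "B") for m in seq[1:]):
            raise ValueError("non-head monomers must be A or B")
        self.sequence = seq

    def extend(self, kind: str) -> None:
        if kind not in ("A", "B"):
            raise ValueError("polymers extend only with A or B")
        self.sequence.append(kind)

    @property
    def terminal(self) -> str:
        return self.sequence[-1]

    def __len__(self) -> int:
        return len(self.sequence)

    def __str__(self) -> str:
        return "".join(self.sequence)


# --- parameters ------------------------------------------------------------


@dataclass(frozen=True)
class RateConstants:
    """All rate constants of the rule set (per-pair propensity units).

    ``k_poly`` is the only value fixed by the source system description;
    the remaining defaults are chosen so that memory half-life spans
    several environment epochs and integrator occupancy equilibrates
    within roughly one epoch.
    """

    k_poly: float = 1e-4        # polymerization (seed + extend)
    k_mem_deg: float = 0.001    # free memory-molecule degradation
    k_ab_deg: float = 0.001     # free A/B degradation
    k_on_act: float = 0.005     # activator (transition memory) binding
    k_off: float = 0.01         # memory unbinding from integrators
    # program (regulation) rates
    k_a_on_int: float = 1e-4    # A/B binding an occupied integrator
    k_a_off_int: float = 0.02
    k_prod: float = 0.5         # B-Program production per producing complex
    k_prog_deg: float = 0.005   # B-Program removal per degrading complex
    k_prod_b: float = 0.0       # B-side producing complex (default off)
    k_prog_deg_b: float = 0.005
    k_prog_basal: float = 0.002  # basal B-Program turnover

    def __post_init__(self) -> None:
        for name, value in self.__dict__.items():
            if value < 0:
                raise ValueError(f"rate {name} must be >= 0, got {value}")


@dataclass(frozen=True)
class CircuitConfig:
    """Copy numbers and structural flags of one circuit instance."""

    n_t: int = 20
    integrator_copies: int = 400
    # repressor on-rate / activator on-rate; None derives the abundance
    # heuristic from pulse/interval hints instead of the tuned default
    bias_factor: float | None = 0.3
    program_mode: bool = False
    clamp_memory: bool = False  # binding does not deplete free memory pools
    pulse_hint: int = 5000      # used only for the default bias factor
    interval_hint: float = 50.0

    def __post_init__(self) -> None:
        if self.n_t < 0 or self.integrator_copies < 0:
            raise ValueError("copy numbers must be non-negative")
        if self.bias_factor is not None and not (0 < self.bias_factor <= 1):
            raise ValueError("bias_factor must lie in (0, 1]")

    def resolved_bias(self, rates: RateConstants) -> float:
        """Repressor/activator on-rate ratio.

        Default compensates the abundance bias of duration-encoding
        memory: roughly one transition-encoding molecule is produced per
        polymer per epoch versus ``k_poly * pulse * interval``
        duration-encoding extensions, so the repressor on-rate is scaled
        down by the expected number of extensions per polymer per epoch.
        """
        if self.bias_factor is not None:
            return self.bias_factor
        expected = rates.k_poly * self.pulse_hint * self.interval_hint
        return float(min(1.0, 1.0 / max(expected, 1.0)))


# --- reactions -------------------------------------------------------------


@dataclass(frozen=True)
class Reaction:
    """One mass-action channel: propensity = rate * prod(x[reactants])."""

    name: str
    rate: float
    reactants: tuple[int, ...]  # 0, 1 or 2 species indices
    stoich: tuple[tuple[int, int], ...]  # (species, delta)

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError(f"reaction {self.name} has negative rate")
        if len(self.reactants) > 2:
            raise ValueError("at most bimolecular reactions are supported")


class RuleSet:
    """Compiled reaction set over the fixed species registry."""

    def __init__(
        self,
        reactions: Iterable[Reaction],
        rates: RateConstants,
        config: CircuitConfig,
    ):
        self.reactions: tuple[Reaction, ...] = tuple(reactions)
        self.rates = rates
        self.config = config
        self.species = SPECIES
        n_r = len(self.reactions)
        # reactant index arrays into the extended state (last slot == 1)
        self._ri1 = np.full(n_r, N_SPECIES, dtype=np.intp)
        self._ri2 = np.full(n_r, N_SPECIES, dtype=np.intp)
        self._k = np.empty(n_r, dtype=np.float64)
        self._stoich = np.zeros((n_r, N_SPECIES), dtype=np.float64)
        for j, r in enumerate(self.reactions):
            self._k[j] = r.rate
            if len(r.reactants) >= 1:
                self._ri1[j] = r.reactants[0]
            if len(r.reactants) == 2:
                self._ri2[j] = r.reactants[1]
            for sp, delta in r.stoich:
                self._stoich[j, sp] += delta

    def __len__(self) -> int:
        return len(self.reactions)

    def names(self) -> list[str]:
        return [r.name for r in self.reactions]

    def index(self, name: str) -> int:
        for j, r in enumerate(self.reactions):
            if r.name == name:
                return j
        raise KeyError(name)

    def propensities(self, x: np.ndarray) -> np.ndarray:
        """Mass-action propensity of every channel at state ``x``."""
        xe = np.append(np.asarray(x, dtype=np.float64), 1.0)
        return self._k * xe[self._ri1] * xe[self._ri2]

    def rule_table(self) -> str:
        """Human-readable audit table (reactants -> products, rate)."""
        lines = []
        for r in self.reactions:
            lhs = " + ".join(SPECIES[i] for i in r.reactants) or "(void)"
            consumed = {sp: -d for sp, d in r.stoich if d < 0}
            produced = {sp: d for sp, d in r.stoich if d > 0}
            rhs = " + ".join(
                (f"{n}*" if n > 1 else "") + SPECIES[sp]
                for sp, n in produced.items()
            ) or "(void)"
            lines.append(f"{r.name:18s} {lhs:28s} -> {rhs:40s} rate={r.rate:g}")
        return "\n".join(lines)


def build_ruleset(rates: RateConstants, config: CircuitConfig) -> RuleSet:
    """Build the full reaction set of the polymerizing circuit.

    Seed rules (2): a free-tailed T binds the head of a free A or B,
    forming a dimer.  Extension rules (4): a polymer with free-tailed
    terminal X binds the head of a free Y and emits one X-To-Y memory
    molecule.  Degradation rules act on free memory and free A/B.
    Integrator rules bind/unbind activator and repressor memory mutually
    exclusively; with ``program_mode``, the regulation reactions of the
    B-Program circuit are appended.
    """
    k_on_rep = config.resolved_bias(rates) * rates.k_on_act
    clamp = config.clamp_memory

    def mem(sp: int, delta: int) -> tuple[tuple[int, int], ...]:
        # with clamped pools, binding/unbinding leaves free memory fixed
        return () if clamp else ((sp, delta),)

    rxns: list[Reaction] = [
        Reaction(
            "seed_A", rates.k_poly, (S.T_free, S.free_A),
            ((S.T_free, -1), (S.free_A, -1), (S.poly_end_A, 1), (S.seeded_A, 1)),
        ),
        Reaction(
            "seed_B", rates.k_poly, (S.T_free, S.free_B),
            ((S.T_free, -1), (S.free_B, -1), (S.poly_end_B, 1), (S.seeded_B, 1)),
        ),
        Reaction(
            "ext_AA", rates.k_poly, (S.poly_end_A, S.free_A),
            ((S.free_A, -1), (S.mem_AA, 1), (S.cum_AA, 1)),
        ),
        Reaction(
            "ext_AB", rates.k_poly, (S.poly_end_A, S.free_B),
            ((S.free_B, -1), (S.poly_end_A, -1), (S.poly_end_B, 1),
             (S.mem_AB, 1), (S.cum_AB, 1)),
        ),
        Reaction(
            "ext_BA", rates.k_poly, (S.poly_end_B, S.free_A),
            ((S.free_A, -1), (S.poly_end_B, -1), (S.poly_end_A, 1),
             (S.mem_BA, 1), (S.cum_BA, 1)),
        ),
        Reaction(
            "ext_BB", rates.k_poly, (S.poly_end_B, S.free_B),
            ((S.free_B, -1), (S.mem_BB, 1), (S.cum_BB, 1)),
        ),
        Reaction("deg_mem_AA", rates.k_mem_deg, (S.mem_AA,), ((S.mem_AA, -1),)),
        Reaction("deg_mem_AB", rates.k_mem_deg, (S.mem_AB,), ((S.mem_AB, -1),)),
        Reaction("deg_mem_BA", rates.k_mem_deg, (S.mem_BA,), ((S.mem_BA, -1),)),
        Reaction("deg_mem_BB", rates.k_mem_deg, (S.mem_BB,), ((S.mem_BB, -1),)),
        Reaction(
            "deg_free_A", rates.k_ab_deg, (S.free_A,),
            ((S.free_A, -1), (S.degraded_A, 1)),
        ),
        Reaction(
            "deg_free_B", rates.k_ab_deg, (S.free_B,),
            ((S.free_B, -1), (S.degraded_B, 1)),
        ),
        # A-To-B integrator: activator = A-To-B, repressor = A-To-A
        Reaction(
            "bind_AB_act", rates.k_on_act, (S.mem_AB, S.int_AB_empty),
            mem(S.mem_AB, -1) + ((S.int_AB_empty, -1), (S.int_AB_act, 1)),
        ),
        Reaction(
            "bind_AB_rep", k_on_rep, (S.mem_AA, S.int_AB_empty),
            mem(S.mem_AA, -1) + ((S.int_AB_empty, -1), (S.int_AB_rep, 1)),
        ),
        Reaction(
            "unbind_AB_act", rates.k_off, (S.int_AB_act,),
            mem(S.mem_AB, 1) + ((S.int_AB_act, -1), (S.int_AB_empty, 1)),
        ),
        Reaction(
            "unbind_AB_rep", rates.k_off, (S.int_AB_rep,),
            mem(S.mem_AA, 1) + ((S.int_AB_rep, -1), (S.int_AB_empty, 1)),
        ),
        # B-To-A integrator: activator = B-To-A, repressor = B-To-B
        Reaction(
            "bind_BA_act", rates.k_on_act, (S.mem_BA, S.int_BA_empty),
            mem(S.mem_BA, -1) + ((S.int_BA_empty, -1), (S.int_BA_act, 1)),
        ),
        Reaction(
            "bind_BA_rep", k_on_rep, (S.mem_BB, S.int_BA_empty),
            mem(S.mem_BB, -1) + ((S.int_BA_empty, -1), (S.int_BA_rep, 1)),
        ),
        Reaction(
            "unbind_BA_act", rates.k_off, (S.int_BA_act,),
            mem(S.mem_BA, 1) + ((S.int_BA_act, -1), (S.int_BA_empty, 1)),
        ),
        Reaction(
            "unbind_BA_rep", rates.k_off, (S.int_BA_rep,),
            mem(S.mem_BB, 1) + ((S.int_BA_rep, -1), (S.int_BA_empty, 1)),
        ),
    ]

    if config.program_mode:
        rxns += _program_reactions(rates)

    return RuleSet(rxns, rates, config)


def _program_reactions(rates: RateConstants) -> list[Reaction]:
    """B-Program regulation reactions.

    Free A binds an active (A-To-B-bound) A-To-B integrator to form a
    producing complex, and a repressed (A-To-A-bound) one to form a
    degrading complex; production/degradation of B-Program is catalytic.
    The B side uses the B-To-A integrator with the anticipatory logic
    mirrored: active (switch-to-A evidence) complexes degrade B-Program,
    repressed (stay-in-B evidence) complexes produce it.
    """
    return [
        Reaction(
            "a_bind_act", rates.k_a_on_int, (S.free_A, S.int_AB_act),
            ((S.free_A, -1), (S.int_AB_act, -1), (S.cplx_AB_prod, 1)),
        ),
        Reaction(
            "a_unbind_act", rates.k_a_off_int, (S.cplx_AB_prod,),
            ((S.cplx_AB_prod, -1), (S.free_A, 1), (S.int_AB_act, 1)),
        ),
        Reaction(
            "a_bind_rep", rates.k_a_on_int, (S.free_A, S.int_AB_rep),
            ((S.free_A, -1), (S.int_AB_rep, -1), (S.cplx_AB_deg, 1)),
        ),
        Reaction(
            "a_unbind_rep", rates.k_a_off_int, (S.cplx_AB_deg,),
            ((S.cplx_AB_deg, -1), (S.free_A, 1), (S.int_AB_rep, 1)),
        ),
        Reaction(
            "prod_bprog", rates.k_prod, (S.cplx_AB_prod,),
            ((S.b_program, 1),),
        ),
        Reaction(
            "deg_bprog", rates.k_prog_deg, (S.cplx_AB_deg, S.b_program),
            ((S.b_program, -1),),
        ),
        Reaction(
            "b_bind_act", rates.k_a_on_int, (S.free_B, S.int_BA_act),
            ((S.free_B, -1), (S.int_BA_act, -1), (S.cplx_BA_deg, 1)),
        ),
        Reaction(
            "b_unbind_act", rates.k_a_off_int, (S.cplx_BA_deg,),
            ((S.cplx_BA_deg, -1), (S.free_B, 1), (S.int_BA_act, 1)),
        ),
        Reaction(
            "b_bind_rep", rates.k_a_on_int, (S.free_B, S.int_BA_rep),
            ((S.free_B, -1), (S.int_BA_rep, -1), (S.cplx_BA_prod, 1)),
        ),
        Reaction(
            "b_unbind_rep", rates.k_a_off_int, (S.cplx_BA_prod,),
            ((S.cplx_BA_prod, -1), (S.free_B, 1), (S.int_BA_rep, 1)),
        ),
        Reaction(
            "prod_bprog_b", rates.k_prod_b, (S.cplx_BA_prod,),
            ((S.b_program, 1),),
        ),
        Reaction(
            "deg_bprog_b", rates.k_prog_deg_b, (S.cplx_BA_deg, S.b_program),
            ((S.b_program, -1),),
        ),
        Reaction(
            "basal_deg_bprog", rates.k_prog_basal, (S.b_program,),
            ((S.b_program, -1),),
        ),
    ]


# --- state -----------------------------------------------------------------


@dataclass
class CircuitState:
    """Full mutable circuit state: count vector plus polymer sequences."""

    x: np.ndarray
    polymers: list[Polymer] = field(default_factory=list)

    @classmethod
    def initial(cls, config: CircuitConfig) -> "CircuitState":
        x = np.zeros(N_SPECIES, dtype=np.float64)
        x[S.T_free] = config.n_t
        x[S.int_AB_empty] = config.integrator_copies
        x[S.int_BA_empty] = config.integrator_copies
        return cls(x=x)

    def count(self, name: str) -> int:
        return int(self.x[getattr(S, name)])

    def counts(self) -> dict[str, int]:
        return {name: int(v) for name, v in zip(SPECIES, self.x)}


def enumerate_propensities(
    state: CircuitState, rules: RuleSet
) -> list[tuple[Reaction, float]]:
    """Per-channel mass-action propensities at the current state."""
    x = state.x
    if (x[: len(SPECIES)] < 0).any():
        raise ValueError("inconsistent state: negative copy number")
    a = rules.propensities(x)
    return list(zip(rules.reactions, (float(v) for v in a)))


# --- polymer reporting -----------------------------------------------------


def run_length_encode(seq: str) -> list[tuple[str, int]]:
    out: list[tuple[str, int]] = []
    for ch in seq:
        if out and out[-1][0] == ch:
            out[-1] = (ch, out[-1][1] + 1)
        else:
            out.append((ch, 1))
    return out


@dataclass(frozen=True)
class PolymerReport:
    """Head-to-tail polymer strings in stable (length, lexicographic) order."""

    strings: tuple[str, ...]

    @property
    def lengths(self) -> tuple[int, ...]:
        return tuple(len(s) for s in self.strings)

    def run_lengths(self) -> list[list[tuple[str, int]]]:
        return [run_length_encode(s) for s in self.strings]

    def to_text(self) -> str:
        return "\n".join(self.strings)

    def to_fasta(self) -> str:
        return "\n".join(
            f">polymer_{i} length={len(s)}\n{s}"
            for i, s in enumerate(self.strings)
        )


def polymer_report(state: CircuitState) -> PolymerReport:
    strings = sorted((str(p) for p in state.polymers), key=lambda s: (len(s), s))
    return PolymerReport(strings=tuple(strings))
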