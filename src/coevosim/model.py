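"""Domain types and rate laws of the cancer-immune interaction network.

This module holds the in-memory state of a realisation (cancer cells with
their mutation sets, the registry of antigen types with their specialised
effector populations) plus the mutation/inheritance/escape model and the
per-channel reaction rates.  It contains no simulation loop; the engine
drives these pieces.

Reaction network (per antigenic mutation ``i`` with carriers ``C_i`` and
effectors ``E_i``; ``C`` the total cancer population)::

    cancer birth        b * C        (mother replaced by two daughters)
    cancer death        d * C
    passive recruit     B            (while C_i >= 1)
    effector death      D * E_i
    active recruit      alpha_i * C_i * E_i
    killing             beta_i  * C_i * E_i
    inhibition          gamma_i * C_i * E_i

with ``alpha_i = alpha0*I_i/(1 + alpha0*h_alpha*C_i*I_i)`` (type-II
saturation), ``beta_i = beta0*A_i`` and ``gamma_i = gamma0``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from ._indexed import IndexedSet
from .params import ModelParams, ParameterError

__all__ = [
    "CancerCell",
    "AntigenType",
    "SystemState",
    "ConsistencyError",
    "draw_new_mutations",
    "make_daughter",
    "recruitment_rate",
    "killing_rate",
    "inhibition_rate",
    "antigen_channel_rates",
    "channel_propensities",
]


class ConsistencyError(RuntimeError):
    """Stored bookkeeping disagrees with a brute-force recount."""


@dataclass
class CancerCell:
    """One tumour cell: its antigenic and neutral mutation-identifier sets."""

    cell_id: int
    antigenic: set
    neutral: set

    @property
    def mutations(self) -> set:
        """All mutations carried by the cell (antigenic plus neutral)."""
        return self.antigenic | self.neutral


class AntigenType:
    """Registry entry for antigenic mutation ``i``.

    Carries the immutable traits (antigenicity ``A_i`` and immunogenicity
    ``I_i``, each drawn Exp(mean 1) at creation), the set of living carrier
    cells and the size of the specialised effector population.
    """

    __slots__ = ("mutation_id", "antigenicity", "immunogenicity",
                 "carriers", "effectors")

    def __init__(self, mutation_id: int, antigenicity: float,
                 immunogenicity: float):
        self.mutation_id = mutation_id
        self.antigenicity = float(antigenicity)
        self.immunogenicity = float(immunogenicity)
        self.carriers = IndexedSet()   # O(1) uniform victim choice on kills
        self.effectors: int = 0

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return (f"AntigenType(id={self.mutation_id}, A={self.antigenicity:.3g}, "
                f"I={self.immunogenicity:.3g}, C={self.n_carriers}, "
                f"E={self.effectors})")


class SystemState:
    """Complete simulation state at a point in time.

    Mutation identifiers are allocated from a monotone counter and never
    reused (infinite-sites assumption: every mutation is unique).  Antigen
    types whose carrier and effector counts both hit zero are pruned from
    the active registry and archived; they can never be revived.
    """

    def __init__(self, rng: np.random.Generator):
        self.time: float = 0.0
        self.rng = rng
        self.cells: dict = {}
        self.antigens: dict = {}          # active: C_i > 0 or E_i > 0
        self.archived: dict = {}          # mutation_id -> (A_i, I_i)
        self.next_mutation_id: int = 0
        self.next_cell_id: int = 0
        # Incrementally maintained aggregates.
        self.total_effectors: int = 0     # E = sum_i E_i
        self.sum_AE: float = 0.0          # sum_i A_i * E_i
        self.sum_IE: float = 0.0          # sum_i I_i * E_i
        self.U_antigenic: int = 0         # total antigenic occurrences
        self.U_neutral: int = 0

    # -- construction -----------------------------------------------------

    @classmethod
    def founder(cls, rng: np.random.Generator) -> "SystemState":
        """Initial condition: a single mutation-free cancer cell at t=0."""
        state = cls(rng)
        cell = CancerCell(state.next_cell_id, set(), set())
        state.next_cell_id += 1
        state.cells[cell.cell_id] = cell
        return state

    # -- aggregates -------------------------------------------------------

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def effector_counts(self) -> dict:
        return {i: ag.effectors for i, ag in self.antigens.items()
                if ag.effectors > 0}

    # -- structural edits -------------------------------------------------

    def register_antigen(self, mutation_id: int) -> AntigenType:
        a = float(self.rng.standard_exponential())
        i = float(self.rng.standard_exponential())
        ag = AntigenType(mutation_id, a, i)
        self.antigens[mutation_id] = ag
        return ag

    def insert_cell(self, cell: CancerCell) -> None:
        """Add a cell and enrol it in the carrier sets of its antigens."""
        self.cells[cell.cell_id] = cell
        cid = cell.cell_id
        antigens = self.antigens
        for mid in cell.antigenic:
            antigens[mid].carriers.add(cid)
        self.U_antigenic += len(cell.antigenic)
        self.U_neutral += len(cell.neutral)

    def remove_cell(self, cell_id: int) -> CancerCell:
        """Remove a cell and withdraw it from its antigens' carrier sets."""
        cell = self.cells.pop(cell_id)
        antigens = self.antigens
        for mid in cell.antigenic:
            antigens[mid].carriers.discard(cell_id)
        self.U_antigenic -= len(cell.antigenic)
        self.U_neutral -= len(cell.neutral)
        return cell

    def prune_antigen(self, mutation_id: int) -> None:
        """Archive an antigen type with no carriers and no effectors."""
        ag = self.antigens.pop(mutation_id)
        self.archived[mutation_id] = (ag.antigenicity, ag.immunogenicity)

    # -- oracles ----------------------------------------------------------

    def recount_carriers(self) -> dict:
        """Brute-force carrier counts over all living cells."""
        counts: dict = {}
        for cell in self.cells.values():
            for mid in cell.antigenic:
                counts[mid] = counts.get(mid, 0) + 1
        return counts

    def check_consistency(self) -> None:
        """Verify stored carrier sets against a brute-force recount."""
        recount = self.recount_carriers()
        for mid, ag in self.antigens.items():
            if ag.n_carriers != recount.get(mid, 0):
                raise ConsistencyError(
                    f"antigen {mid}: stored carriers {ag.n_carriers} != "
                    f"recount {recount.get(mid, 0)}")
        stray = set(recount) - set(self.antigens)
        if stray:
            raise ConsistencyError(f"carried antigens missing from registry: {sorted(stray)[:5]}")
        u_a = sum(len(c.antigenic) for c in self.cells.values())
        if u_a != self.U_antigenic:
            raise ConsistencyError(f"U mismatch: {self.U_antigenic} != {u_a}")


# -- mutation model -------------------------------------------------------

def draw_new_mutations(state: SystemState, lambda_: float, p_a: float):
    """Draw a daughter cell's new mutations.

    The antigenic and neutral counts are independent Poisson draws with
    means ``p_a*lambda_`` and ``(1-p_a)*lambda_``.  Every new antigenic
    identifier is registered as an :class:`AntigenType` with fresh Exp(1)
    antigenicity and immunogenicity.  Identifiers come from the state's
    monotone counter and are never reused.

    Returns ``(antigenic_ids, neutral_ids)`` as lists.
    """
    if lambda_ < 0:
        raise ParameterError(f"lambda_ must be >= 0, got {lambda_!r}")
    if not 0.0 <= p_a <= 1.0:
        raise ParameterError(f"p_a must lie in [0, 1], got {p_a!r}")
    rng = state.rng
    n_a = int(rng.poisson(p_a * lambda_)) if p_a > 0 and lambda_ > 0 else 0
    n_n = int(rng.poisson((1.0 - p_a) * lambda_)) if lambda_ > 0 else 0
    nid = state.next_mutation_id
    antigenic_ids = list(range(nid, nid + n_a))
    neutral_ids = list(range(nid + n_a, nid + n_a + n_n))
    state.next_mutation_id = nid + n_a + n_n
    for mid in antigenic_ids:
        state.register_antigen(mid)
    return antigenic_ids, neutral_ids


def make_daughter(state: SystemState, mother: CancerCell,
                  params: ModelParams) -> CancerCell:
    """Create, insert and return one daughter cell of ``mother``.

    The daughter inherits the mother's full antigenic and neutral sets and
    acquires new mutations via :func:`draw_new_mutations`.  With probability
    ``p_e`` the daughter undergoes immune escape: its entire antigenic set
    (inherited and newly acquired) is moved into the neutral set, leaving
    the antigenic set empty.  Escape is lineage-local: other carriers of the
    same mutations keep them antigenic.  Carrier bookkeeping for every
    affected antigen type is updated by the insertion.
    """
    antigenic = set(mother.antigenic)
    neutral = set(mother.neutral)
    new_a, new_n = draw_new_mutations(state, params.lambda_, params.p_a)
    antigenic.update(new_a)
    neutral.update(new_n)
    if antigenic and params.p_e > 0 and state.rng.random() < params.p_e:
        neutral.update(antigenic)
        antigenic = set()
    daughter = CancerCell(state.next_cell_id, antigenic, neutral)
    state.next_cell_id += 1
    state.insert_cell(daughter)
    return daughter


# -- rate laws ------------------------------------------------------------

def recruitment_rate(alpha0: float, h_alpha: float, immunogenicity: float,
                     n_carriers: float) -> float:
    """Per-pair active recruitment rate, type-II saturating in ``C_i``.

    ``alpha_i = alpha0*I_i / (1 + alpha0*h_alpha*C_i*I_i)``; non-increasing
    in the carrier count, reducing to ``alpha0*I_i`` when ``h_alpha == 0``.
    """
    return alpha0 * immunogenicity / (
        1.0 + alpha0 * h_alpha * n_carriers * immunogenicity)


def killing_rate(beta0: float, antigenicity: float) -> float:
    """Per-pair killing rate ``beta_i = beta0 * A_i``."""
    return beta0 * antigenicity


def inhibition_rate(gamma0: float) -> float:
    """Per-pair inhibition/exhaustion rate ``gamma_i = gamma0`` (type-I)."""
    return gamma0


def antigen_channel_rates(params: ModelParams, ag: AntigenType):
    """The five reaction propensities attached to one antigen type.

    Returns ``(passive, effector_death, active_recruit, kill, inhibit)`` in
    canonical order.  Passive recruitment is gated on the mutation having at
    least one living carrier; pairwise channels are mass-action in
    ``C_i * E_i``.  The engine and the brute-force oracle both call this
    function, so their per-channel values agree bitwise.
    """
    c = ag.n_carriers
    e = ag.effectors
    passive = params.B if c > 0 else 0.0
    e_death = params.D * e
    if c > 0 and e > 0:
        pairs = c * e
        recruit = recruitment_rate(params.alpha0, params.h_alpha,
                                   ag.immunogenicity, c) * pairs
        kill = killing_rate(params.beta0, ag.antigenicity) * pairs
        inhibit = inhibition_rate(params.gamma0) * pairs
    else:
        recruit = kill = inhibit = 0.0
    return passive, e_death, recruit, kill, inhibit


def channel_propensities(state: SystemState, params: ModelParams,
                         check: bool = True) -> dict:
    """Brute-force propensity vector for every reaction channel.

    Keys are ``("birth",)``, ``("death",)`` and per-antigen tuples
    ``("passive"|"effector_death"|"recruit"|"kill"|"inhibit", mutation_id)``.
    Antigens with carriers get all five channels; eradicated antigens
    (``C_i == 0`` with surviving effectors) retain only effector death.
    With ``check=True`` the stored carrier counts are first verified against
    a brute-force recount (raising :class:`ConsistencyError` on mismatch).
    """
    if check:
        state.check_consistency()
    c_total = state.n_cells
    props: dict = {
        ("birth",): params.b * c_total,
        ("death",): params.d * c_total,
    }
    for mid, ag in state.antigens.items():
        passive, e_death, recruit, kill, inhibit = antigen_channel_rates(params, ag)
        if ag.n_carriers > 0:
            props[("passive", mid)] = passive
            props[("effector_death", mid)] = e_death
            props[("recruit", mid)] = recruit
            props[("kill", mid)] = kill
            props[("inhibit", mid)] = inhibit
        elif ag.effectors > 0:
            props[("effector_death", mid)] = e_death
    return props
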