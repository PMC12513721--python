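"""Exact stochastic simulation of the cancer-immune reaction network.

The standard Gillespie algorithm recomputes every propensity after every
event, which scales with the number of antigen types.  Here a dynamic
dependency structure keeps the cost per event proportional to the affected
cell's antigenic burden: the five channels attached to an antigen type are
refreshed only when one of their inputs (carrier count, effector count)
changes, and the per-antigen total weights live in a binary sum tree giving
O(log n) weighted selection and update.  A naive full recomputation of the
same propensity vector is available through
:func:`coevosim.model.channel_propensities` and is used as the exactness
oracle in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._indexed import IndexedSet
from .model import (SystemState, antigen_channel_rates, make_daughter)
from .params import ModelParams

__all__ = ["Simulation", "SimResult", "OutcomeRecord", "Trajectory", "run"]

_CHANNEL_NAMES = ("passive", "effector_death", "recruit", "kill", "inhibit")


class _SumTree:
    """Fixed-capacity binary sum tree over non-negative weights.

    Supports O(log n) point assignment and O(log n) sampling of the leaf
    containing a given prefix mass.  Internal sums are refreshed from the
    leaves periodically to keep float drift bounded.
    """

    __slots__ = ("cap", "t", "_sets")

    def __init__(self, capacity: int = 1024):
        cap = 1
        while cap < capacity:
            cap <<= 1
        self.cap = cap
        self.t = [0.0] * (2 * cap)
        self._sets = 0

    @property
    def total(self) -> float:
        return self.t[1]

    def set(self, leaf: int, value: float) -> None:
        t = self.t
        j = leaf + self.cap
        delta = value - t[j]
        if delta == 0.0:
            return
        while j:
            t[j] += delta
            j >>= 1
        self._sets += 1
        if self._sets >= 65536:
            self.rebuild()

    def get(self, leaf: int) -> float:
        return self.t[leaf + self.cap]

    def rebuild(self) -> None:
        t = self.t
        for j in range(self.cap - 1, 0, -1):
            jj = 2 * j
            t[j] = t[jj] + t[jj + 1]
        self._sets = 0

    def grow(self) -> None:
        old_leaves = self.t[self.cap:]
        self.cap *= 2
        self.t = [0.0] * (2 * self.cap)
        self.t[self.cap:self.cap + len(old_leaves)] = old_leaves
        self.rebuild()

    def find(self, u: float):
        """Leaf index holding prefix mass ``u`` and the residual within it."""
        t = self.t
        cap = self.cap
        j = 1
        while j < cap:
            j <<= 1
            left = t[j]
            if u > left:
                u -= left
                j += 1
        return j - cap, u


@dataclass(frozen=True)
class OutcomeRecord:
    """Terminal classification of a realisation.

    ``no_suppression``: the cancer population reached ``K`` before
    ``T_end``.  ``extinct``: it hit zero.  ``slow_growing``: it was still
    strictly between 0 and ``K`` at ``T_end``.  The latter two jointly count
    as suppression.
    """

    outcome: str
    end_time: float
    final_C: int
    final_E: int

    @property
    def suppressed(self) -> bool:
        return self.outcome in ("extinct", "slow_growing")


@dataclass
class Trajectory:
    """Regularly sampled time series of a realisation.

    Samples carry the last pre-sample state forward across event-free
    intervals; the final row is the terminal state at ``end_time``.
    ``mean_A``/``mean_I`` are the effector-weighted averages (NaN while no
    effector exists); ``mean_burden`` is the mean antigenic burden ``U/C``.
    """

    times: np.ndarray
    C: np.ndarray
    E: np.ndarray
    mean_A: np.ndarray
    mean_I: np.ndarray
    mean_burden: np.ndarray
    dominant_type: Optional[np.ndarray] = None   # mutation id of largest E_i
    dominant_E: Optional[np.ndarray] = None

    def to_frame(self):
        import pandas as pd

        data = {"time": self.times, "C": self.C, "E": self.E,
                "mean_A": self.mean_A, "mean_I": self.mean_I,
                "mean_burden": self.mean_burden}
        if self.dominant_E is not None:
            data["dominant_type"] = self.dominant_type
            data["dominant_E"] = self.dominant_E
        return pd.DataFrame(data)


@dataclass
class SimResult:
    params: ModelParams
    seed: Optional[int]
    trajectory: Trajectory
    outcome: OutcomeRecord
    state: SystemState
    event_counts: dict = field(default_factory=dict)


class Simulation:
    """One realisation of the cancer-immune model.

    Parameters
    ----------
    params : ModelParams
    seed : int, optional
        Seed of the realisation's random stream; defaults to
        ``params.seed``.
    sample_dt : float
        Spacing of the trajectory sampling grid (time units).
    track_dominant : bool
        Record, at each sample, the effector type with the largest
        population (O(#antigen types) per sample; off by default).
    """

    def __init__(self, params: ModelParams, seed: Optional[int] = None,
                 rng: Optional[np.random.Generator] = None,
                 sample_dt: float = 0.01, track_dominant: bool = False,
                 state: Optional[SystemState] = None):
        self.params = params
        self.seed = params.seed if seed is None else seed
        if rng is None:
            rng = np.random.default_rng(self.seed)
        self.state = state if state is not None else SystemState.founder(rng)
        self.state.rng = rng
        self.rng = rng
        self.sample_dt = float(sample_dt)
        self.track_dominant = track_dominant
        self.event_counts: dict = {}

        self._cells = IndexedSet(self.state.cells)
        self._tree = _SumTree(1024)
        self._slot: dict = {}      # mutation_id -> leaf index
        self._owner: dict = {}     # leaf index -> mutation_id
        self._free: list = []
        self._channels: dict = {}  # mutation_id -> 5-tuple of rates
        self._next_slot = 0
        for mid in list(self.state.antigens):
            self._refresh_antigen(mid)

    # -- dependency-tracked propensity updates ---------------------------

    def _alloc_slot(self, mid: int) -> int:
        if self._free:
            slot = self._free.pop()
        else:
            if self._next_slot >= self._tree.cap:
                self._tree.grow()
            slot = self._next_slot
            self._next_slot += 1
        self._slot[mid] = slot
        self._owner[slot] = mid
        return slot

    def _refresh_antigen(self, mid: int) -> None:
        """Recompute the five channels of antigen ``mid`` after a change.

        Prunes the type (archiving its traits) once both its carrier and
        effector counts are zero; pruned types can never be revived.
        """
        ag = self.state.antigens.get(mid)
        if ag is None:
            return
        if ag.effectors == 0 and len(ag.carriers) == 0:
            slot = self._slot.pop(mid, None)
            if slot is not None:
                self._tree.set(slot, 0.0)
                del self._owner[slot]
                self._free.append(slot)
            self._channels.pop(mid, None)
            self.state.prune_antigen(mid)
            return
        rates = antigen_channel_rates(self.params, ag)
        self._channels[mid] = rates
        slot = self._slot.get(mid)
        if slot is None:
            slot = self._alloc_slot(mid)
        self._tree.set(slot, rates[0] + rates[1] + rates[2] + rates[3] + rates[4])

    def propensity_snapshot(self) -> dict:
        """The engine's maintained propensity vector, keyed like the naive
        :func:`coevosim.model.channel_propensities` oracle."""
        params = self.params
        n = len(self._cells)
        props = {("birth",): params.b * n, ("death",): params.d * n}
        for mid, rates in self._channels.items():
            ag = self.state.antigens[mid]
            if len(ag.carriers) > 0:
                for name, value in zip(_CHANNEL_NAMES, rates):
                    props[(name, mid)] = value
            else:
                props[("effector_death", mid)] = rates[1]
        return props

    # -- event mechanics --------------------------------------------------

    def _select(self, u: float):
        """Map a mass coordinate ``u`` in [0, total) to a channel key."""
        params = self.params
        n = len(self._cells)
        a_birth = params.b * n
        if u < a_birth:
            return ("birth",)
        u -= a_birth
        a_death = params.d * n
        if u < a_death:
            return ("death",)
        u -= a_death
        slot, rem = self._tree.find(u)
        mid = self._owner.get(slot)
        if mid is None:
            # Float drift pushed the search past the live mass; resync.
            self._tree.rebuild()
            slot, rem = self._tree.find(min(u, self._tree.total * (1 - 1e-12)))
            mid = self._owner[slot]
        rates = self._channels[mid]
        for k in range(4):
            if rem < rates[k]:
                return (_CHANNEL_NAMES[k], mid)
            rem -= rates[k]
        return (_CHANNEL_NAMES[4], mid)

    def total_propensity(self) -> float:
        n = len(self._cells)
        return (self.params.b + self.params.d) * n + self._tree.total

    def _apply(self, event) -> None:
        state = self.state
        kind = event[0]
        if kind == "birth":
            mother_id = self._cells.choose(self.rng)
            mother = state.remove_cell(mother_id)
            self._cells.discard(mother_id)
            first_new = state.next_mutation_id
            d1 = make_daughter(state, mother, self.params)
            d2 = make_daughter(state, mother, self.params)
            self._cells.add(d1.cell_id)
            self._cells.add(d2.cell_id)
            affected = set(mother.antigenic)
            affected.update(d1.antigenic)
            affected.update(d2.antigenic)
            # New ids that escaped immediately still need pruning.
            for mid in range(first_new, state.next_mutation_id):
                if mid in state.antigens:
                    affected.add(mid)
            for mid in affected:
                self._refresh_antigen(mid)
        elif kind == "death":
            victim_id = self._cells.choose(self.rng)
            cell = state.remove_cell(victim_id)
            self._cells.discard(victim_id)
            for mid in cell.antigenic:
                self._refresh_antigen(mid)
        elif kind == "kill":
            mid = event[1]
            victim_id = state.antigens[mid].carriers.choose(self.rng)
            cell = state.remove_cell(victim_id)
            self._cells.discard(victim_id)
            for m in cell.antigenic:
                self._refresh_antigen(m)
        elif kind in ("passive", "recruit"):
            mid = event[1]
            ag = state.antigens[mid]
            ag.effectors += 1
            state.total_effectors += 1
            state.sum_AE += ag.antigenicity
            state.sum_IE += ag.immunogenicity
            self._refresh_antigen(mid)
        else:  # effector_death, inhibit
            mid = event[1]
            ag = state.antigens[mid]
            ag.effectors -= 1
            state.total_effectors -= 1
            state.sum_AE -= ag.antigenicity
            state.sum_IE -= ag.immunogenicity
            self._refresh_antigen(mid)
        self.event_counts[kind] = self.event_counts.get(kind, 0) + 1

    def step(self):
        """Advance one reaction: exponential waiting time, propensity-
        weighted channel choice, state update.

        Returns ``(tau, event_key)`` or ``None`` when no channel is active
        (only possible when every rate is structurally zero).
        """
        total = self.total_propensity()
        if total <= 0.0:
            return None
        rng = self.rng
        tau = rng.standard_exponential() / total
        event = self._select(rng.random() * total)
        self.state.time += tau
        self._apply(event)
        return tau, event

    # -- sampled observables ----------------------------------------------

    def _observe(self):
        state = self.state
        n = state.n_cells
        e = state.total_effectors
        mean_a = state.sum_AE / e if e > 0 else np.nan
        mean_i = state.sum_IE / e if e > 0 else np.nan
        burden = state.U_antigenic / n if n > 0 else np.nan
        row = (n, e, mean_a, mean_i, burden)
        if not self.track_dominant:
            return row
        dom_mid, dom_e = -1, 0
        for mid, ag in state.antigens.items():
            if ag.effectors > dom_e:
                dom_mid, dom_e = mid, ag.effectors
        return row + (dom_mid, dom_e)

    def run(self) -> SimResult:
        """Iterate to termination: ``C = 0``, ``C >= K`` or ``t >= T_end``.

        Effector decay after cancer extinction is not simulated (it cannot
        change the outcome).
        """
        params = self.params
        K, T_end = params.K, params.T_end
        dt = self.sample_dt
        samples = []
        sample_times = []
        next_sample = 0.0

        end_time = None
        outcome = None
        while True:
            total = self.total_propensity()
            if total <= 0.0:
                t_next = T_end
            else:
                t_next = self.state.time + self.rng.standard_exponential() / total
            while next_sample < t_next and next_sample <= T_end:
                sample_times.append(next_sample)
                samples.append(self._observe())
                next_sample += dt
            if t_next >= T_end:
                self.state.time = T_end
                end_time = T_end
                outcome = "slow_growing" if 0 < self.state.n_cells < K else (
                    "extinct" if self.state.n_cells == 0 else "no_suppression")
                break
            self.state.time = t_next
            event = self._select(self.rng.random() * total)
            self._apply(event)
            n = self.state.n_cells
            if n == 0:
                end_time = t_next
                outcome = "extinct"
                break
            if n >= K:
                end_time = t_next
                outcome = "no_suppression"
                break

        if not sample_times or sample_times[-1] != end_time:
            sample_times.append(end_time)
            samples.append(self._observe())
        arr = np.asarray(samples, dtype=float)
        traj = Trajectory(
            times=np.asarray(sample_times),
            C=arr[:, 0], E=arr[:, 1], mean_A=arr[:, 2], mean_I=arr[:, 3],
            mean_burden=arr[:, 4],
            dominant_type=arr[:, 5].astype(int) if self.track_dominant else None,
            dominant_E=arr[:, 6] if self.track_dominant else None,
        )
        record = OutcomeRecord(outcome=outcome, end_time=end_time,
                               final_C=self.state.n_cells,
                               final_E=self.state.total_effectors)
        return SimResult(params=self.params, seed=self.seed, trajectory=traj,
                         outcome=record, state=self.state,
                         event_counts=dict(self.event_counts))


def run(params: ModelParams, seed: Optional[int] = None,
        sample_dt: float = 0.01, track_dominant: bool = False) -> SimResult:
    """Convenience wrapper: build a :class:`Simulation` and run it."""
    sim = Simulation(params, seed=seed, sample_dt=sample_dt,
                     track_dominant=track_dominant)
    return sim.run()
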