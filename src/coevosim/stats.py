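"""Genetic summary statistics and neutral-theory baselines.

Two histograms summarise the mutational state of a tumour snapshot: the
site frequency spectrum ``S_j`` (number of mutations of a class present in
exactly ``j`` cells) and the single-cell mutational burden distribution
``B_k`` (number of cells carrying exactly ``k`` mutations of that class).
They share the total occurrence count ``U = sum_j j*S_j = sum_k k*B_k``,
and the MBD mean is ``U/C``.

The neutral baseline (no immune response) is generated by a bundled
Monte-Carlo oracle: an ensemble of simulations with every immune channel
disabled, grown to a matched population size.  The expected mean burden
under neutrality grows linearly as ``2*nu*b*t`` where ``nu`` is the
per-daughter mutation mean of the class considered.

Distances between burden distributions use the 1-Wasserstein metric on the
burden axis rescaled to [0, 1] with each histogram normalised to unit mass,
so the distance itself lies in [0, 1].
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy.stats import wasserstein_distance

from .params import ModelParams, ParameterError

__all__ = [
    "Histogram",
    "NeutralExpectation",
    "compute_sfs",
    "compute_mbd",
    "total_occurrences",
    "effector_averages",
    "neutral_mean_burden",
    "neutral_expectations",
    "wasserstein_mbd",
    "mean_histogram",
]


@dataclass
class Histogram:
    """Integer-indexed counts; counts may be fractional for ensemble means."""

    index: np.ndarray
    counts: np.ndarray

    def __post_init__(self):
        self.index = np.asarray(self.index, dtype=int)
        self.counts = np.asarray(self.counts, dtype=float)
        if self.index.shape != self.counts.shape:
            raise ValueError("index and counts must have equal length")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @classmethod
    def from_counter(cls, counter: dict) -> "Histogram":
        if not counter:
            return cls(np.empty(0, dtype=int), np.empty(0))
        idx = np.array(sorted(counter))
        return cls(idx, np.array([counter[i] for i in idx], dtype=float))

    @property
    def total(self) -> float:
        """Total mass (for an MBD: the number of cells C)."""
        return float(self.counts.sum())

    @property
    def occurrences(self) -> float:
        """``sum_i i * count_i`` (the quantity U for either histogram)."""
        return float((self.index * self.counts).sum())

    @property
    def mean(self) -> float:
        """Mass-weighted mean index (for an MBD: ``U/C``)."""
        total = self.total
        if total == 0:
            return np.nan
        return self.occurrences / total

    def dense(self, kmax: Optional[int] = None) -> np.ndarray:
        """Counts on the contiguous index range ``0..kmax``."""
        if kmax is None:
            kmax = int(self.index.max()) if self.index.size else 0
        out = np.zeros(kmax + 1)
        keep = self.index <= kmax
        out[self.index[keep]] = self.counts[keep]
        return out

    def to_frame(self, index_name: str = "index", counts_name: str = "count"):
        import pandas as pd

        return pd.DataFrame({index_name: self.index, counts_name: self.counts})


def _class_sets(cells: Iterable, mutation_class: str):
    if mutation_class == "antigenic":
        return [cell.antigenic for cell in cells]
    if mutation_class == "neutral":
        return [cell.neutral for cell in cells]
    raise ValueError(f"mutation_class must be 'antigenic' or 'neutral', got {mutation_class!r}")


def compute_sfs(cells, mutation_class: str = "antigenic") -> Histogram:
    """Site frequency spectrum of the given mutation class.

    ``S_j`` counts mutations carried by exactly ``j`` living cells, with
    per-cell classification: a mutation that escaped in one lineage but is
    still antigenic in another contributes to both class spectra at the
    respective occupancy.  An empty population yields an empty histogram.
    """
    occurrence: Counter = Counter()
    for s in _class_sets(cells, mutation_class):
        occurrence.update(s)
    return Histogram.from_counter(Counter(occurrence.values()))


def compute_mbd(cells, mutation_class: str = "antigenic") -> Histogram:
    """Single-cell mutational burden distribution of the given class.

    ``B_k`` counts cells carrying exactly ``k`` mutations of the class; the
    ``k = 0`` bin is included, so ``sum_k B_k`` equals the population size.
    """
    burdens = Counter(len(s) for s in _class_sets(cells, mutation_class))
    return Histogram.from_counter(burdens)


def total_occurrences(cells, mutation_class: str = "antigenic") -> int:
    """``U``: the total number of mutational occurrences of the class."""
    return sum(len(s) for s in _class_sets(cells, mutation_class))


def effector_averages(antigens) -> tuple:
    """Effector-weighted average antigenicity and immunogenicity.

    ``<A> = sum_i A_i E_i / sum_i E_i`` and likewise for ``<I>``, summed
    over every currently existing effector population (including types
    whose target mutation is already eradicated).  With no effectors the
    averages are undefined and ``(nan, nan)`` is returned.
    """
    if isinstance(antigens, dict):
        antigens = antigens.values()
    e_tot = 0
    sum_ae = 0.0
    sum_ie = 0.0
    for ag in antigens:
        e = ag.effectors
        if e:
            e_tot += e
            sum_ae += ag.antigenicity * e
            sum_ie += ag.immunogenicity * e
    if e_tot == 0:
        return (np.nan, np.nan)
    return (sum_ae / e_tot, sum_ie / e_tot)


def neutral_mean_burden(t, b: float, nu: float) -> np.ndarray:
    """Expected mean burden under neutral growth: ``2*nu*b*t``.

    Each division replaces one cell by two daughters carrying on average
    ``nu`` new mutations of the class each, so the population mean burden
    gains ``2*nu*b`` per unit time regardless of the death rate.
    """
    out = 2.0 * nu * b * np.asarray(t, dtype=float)
    return float(out) if out.ndim == 0 else out


@dataclass
class NeutralExpectation:
    """Monte-Carlo neutral (no-immune) reference at matched tumour size.

    ``sfs`` and ``mbd`` are per-bin ensemble means over realisations grown
    to the target population size with every immune channel disabled.
    """

    mutation_class: str
    nu: float
    b: float
    target_C: int
    n_replicates: int
    sfs: Histogram
    mbd: Histogram
    mean_end_time: float

    def mean_burden(self, t) -> np.ndarray:
        return neutral_mean_burden(t, self.b, self.nu)


def mean_histogram(histograms) -> Histogram:
    """Per-bin mean of histograms (missing bins count as zero)."""
    histograms = list(histograms)
    if not histograms:
        raise ValueError("no histograms to average")
    kmax = max((int(h.index.max()) if h.index.size else 0) for h in histograms)
    acc = np.zeros(kmax + 1)
    for h in histograms:
        acc += h.dense(kmax)
    acc /= len(histograms)
    return Histogram(np.arange(kmax + 1), acc)


def neutral_expectations(params: ModelParams, target_C: int,
                         mutation_class: str = "antigenic",
                         n_replicates: int = 50,
                         seed: Optional[int] = None,
                         sample_dt: float = 1.0) -> NeutralExpectation:
    """Neutral SFS/MBD expectation curves from the no-immune oracle.

    Simulates ``n_replicates`` realisations of the branching process with
    every immune channel disabled (mutations of both classes still accrue)
    until the population reaches ``target_C``; realisations that go extinct
    are discarded and replaced.  Requires supercritical growth ``b > d``.
    """
    from .engine import Simulation  # local import to avoid a cycle

    if not params.b > params.d:
        raise ParameterError("neutral expectations need supercritical growth (b > d)")
    nu = params.p_a * params.lambda_ if mutation_class == "antigenic" \
        else (1.0 - params.p_a) * params.lambda_
    base = params.no_immune().replace(K=int(target_C), T_end=1e9)
    seed_base = int(np.random.SeedSequence(
        seed if seed is not None else 0).generate_state(1, np.uint32)[0])
    sfs_list, mbd_list, end_times = [], [], []
    attempts = 0
    max_attempts = 20 * n_replicates
    while len(mbd_list) < n_replicates:
        if attempts >= max_attempts:
            raise RuntimeError("neutral oracle: too many extinct replicates")
        child = (seed_base + attempts) % (2**31)
        attempts += 1
        res = Simulation(base, seed=child, sample_dt=sample_dt).run()
        if res.outcome.outcome != "no_suppression":
            continue
        cells = res.state.cells.values()
        sfs_list.append(compute_sfs(cells, mutation_class))
        mbd_list.append(compute_mbd(cells, mutation_class))
        end_times.append(res.outcome.end_time)
    return NeutralExpectation(
        mutation_class=mutation_class, nu=nu, b=params.b,
        target_C=int(target_C), n_replicates=n_replicates,
        sfs=mean_histogram(sfs_list), mbd=mean_histogram(mbd_list),
        mean_end_time=float(np.mean(end_times)))


def wasserstein_mbd(sim: Histogram, ref: Histogram) -> float:
    """Rescaled 1-Wasserstein distance between two burden distributions.

    The burden axis is rescaled by the largest support value across both
    inputs to the interval [0, 1] and each histogram is normalised to a
    probability density, so the distance is symmetric and lies in [0, 1].
    """
    if sim.total == 0 or ref.total == 0:
        raise ValueError("wasserstein_mbd needs non-empty histograms")
    kmax = max(int(sim.index.max()) if sim.index.size else 0,
               int(ref.index.max()) if ref.index.size else 0)
    if kmax == 0:
        return 0.0  # both distributions are a point mass at zero burden
    return float(wasserstein_distance(
        sim.index / kmax, ref.index / kmax,
        u_weights=sim.counts, v_weights=ref.counts))
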