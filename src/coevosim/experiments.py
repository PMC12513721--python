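"""Ensemble execution over interaction-parameter grids.

Sweeps a (log-spaced) grid of the active-recruitment and killing constants
``(alpha0, beta0)``, runs independent replicates at each point, and
tabulates outcome proportions (suppressed = extinct + slow-growing) with
Wilson confidence intervals, the ensemble-averaged burden distributions of
tumours that grew to the ending size, and their rescaled Wasserstein
distance to a matched neutral (no-immune) reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .engine import Simulation
from .params import ModelParams
from .stats import (Histogram, compute_mbd, mean_histogram,
                    neutral_expectations, wasserstein_mbd)

__all__ = ["SweepSpec", "PointResult", "SweepResult", "run_ensemble",
           "run_replicates"]

_OUTCOMES = ("extinct", "slow_growing", "no_suppression")


@dataclass(frozen=True)
class SweepSpec:
    """Grid sweep specification.

    ``alpha0_grid`` and ``beta0_grid`` are crossed into a full grid.
    Replicate ``r`` (numbered consecutively across the whole sweep) runs
    with seed ``base_seed + r``, so the table is reproducible and
    independent of execution order.  ``overrides`` replaces any other
    :class:`ModelParams` field (e.g. the desk-scale ``K``).
    """

    alpha0_grid: tuple
    beta0_grid: tuple
    lambda_: float = 1.0
    n_replicates: int = 50
    base_seed: int = 0
    overrides: dict = field(default_factory=dict)
    neutral_replicates: int = 30
    sample_dt: float = 0.05

    def __post_init__(self):
        object.__setattr__(self, "alpha0_grid", tuple(self.alpha0_grid))
        object.__setattr__(self, "beta0_grid", tuple(self.beta0_grid))
        if not self.alpha0_grid or not self.beta0_grid:
            raise ValueError("parameter grid must be non-empty")
        if self.n_replicates < 1:
            raise ValueError("need at least one replicate per grid point")

    def params_at(self, alpha0: float, beta0: float) -> ModelParams:
        return ModelParams(lambda_=self.lambda_, **self.overrides).replace(
            alpha0=alpha0, beta0=beta0)

    @staticmethod
    def log_grid(lo: float, hi: float, n: int) -> tuple:
        """Log-uniform grid matching the decade structure of the heat maps."""
        return tuple(np.geomspace(lo, hi, n))


@dataclass
class PointResult:
    alpha0: float
    beta0: float
    outcomes: list
    end_times: list
    mbd_antigenic: Optional[Histogram]   # mean over no-suppression runs
    mbd_neutral: Optional[Histogram]
    n_failed: int = 0


@dataclass
class SweepResult:
    spec: SweepSpec
    table: pd.DataFrame
    points: list
    neutral_ref_antigenic: Optional[object] = None
    neutral_ref_neutral: Optional[object] = None


def run_replicates(params: ModelParams, n_replicates: int, base_seed: int,
                   first_replicate: int = 0, sample_dt: float = 0.05,
                   keep_trajectories: bool = False):
    """Run independent replicates; returns (results, n_failed).

    Each result keeps the outcome record, end time and the final burden
    histograms; trajectories are optionally retained.  Per-replicate
    failures are counted and excluded, never silently dropped.
    """
    out = []
    n_failed = 0
    for r in range(first_replicate, first_replicate + n_replicates):
        try:
            sim = Simulation(params, seed=base_seed + r, sample_dt=sample_dt)
            res = sim.run()
            entry = {
                "seed": base_seed + r,
                "outcome": res.outcome,
                "mbd_antigenic": compute_mbd(res.state.cells.values(), "antigenic"),
                "mbd_neutral": compute_mbd(res.state.cells.values(), "neutral"),
            }
            if keep_trajectories:
                entry["trajectory"] = res.trajectory
            out.append(entry)
        except Exception:  # pragma: no cover - defensive accounting
            n_failed += 1
    return out, n_failed


def run_ensemble(spec: SweepSpec, with_neutral_reference: bool = True,
                 progress: bool = False) -> SweepResult:
    """Execute the sweep and build the outcome table.

    Columns follow the tool's tidy-output contract: one row per grid point
    with outcome proportions (and Wilson 95% intervals on the suppression
    proportion), mean end time, and the Wasserstein distances of the
    ensemble-mean burden distributions of grown tumours against the
    matched neutral reference (NaN where no tumour reached ``K``).
    """
    base = ModelParams(lambda_=spec.lambda_, **spec.overrides)
    ref_a = ref_n = None
    if with_neutral_reference:
        ref_a = neutral_expectations(base, target_C=base.K, mutation_class="antigenic",
                                     n_replicates=spec.neutral_replicates,
                                     seed=spec.base_seed + 999_983)
        ref_n = neutral_expectations(base, target_C=base.K, mutation_class="neutral",
                                     n_replicates=spec.neutral_replicates,
                                     seed=spec.base_seed + 999_979)

    rows = []
    points = []
    rep_counter = 0
    grid = [(a, b) for b in spec.beta0_grid for a in spec.alpha0_grid]
    for alpha0, beta0 in grid:
        params = spec.params_at(alpha0, beta0)
        reps, n_failed = run_replicates(params, spec.n_replicates,
                                        spec.base_seed,
                                        first_replicate=rep_counter,
                                        sample_dt=spec.sample_dt)
        rep_counter += spec.n_replicates
        outcomes = [r["outcome"] for r in reps]
        n = len(outcomes)
        counts = {o: sum(1 for rec in outcomes if rec.outcome == o)
                  for o in _OUTCOMES}
        n_sup = counts["extinct"] + counts["slow_growing"]
        lo, hi = proportion_confint(n_sup, n, alpha=0.05, method="wilson") \
            if n else (np.nan, np.nan)
        grown_a = [r["mbd_antigenic"] for r, rec in zip(reps, outcomes)
                   if rec.outcome == "no_suppression"]
        grown_n = [r["mbd_neutral"] for r, rec in zip(reps, outcomes)
                   if rec.outcome == "no_suppression"]
        mbd_a = mean_histogram(grown_a) if grown_a else None
        mbd_n = mean_histogram(grown_n) if grown_n else None
        w1_a = wasserstein_mbd(mbd_a, ref_a.mbd) if (mbd_a and ref_a) else np.nan
        w1_n = wasserstein_mbd(mbd_n, ref_n.mbd) if (mbd_n and ref_n) else np.nan
        rows.append({
            "alpha0": alpha0, "beta0": beta0, "lambda": spec.lambda_,
            "K": params.K, "n_reps": n, "n_failed": n_failed,
            "p_extinct": counts["extinct"] / n if n else np.nan,
            "p_slow": counts["slow_growing"] / n if n else np.nan,
            "p_suppressed": n_sup / n if n else np.nan,
            "p_no_suppression": counts["no_suppression"] / n if n else np.nan,
            "p_suppressed_lo": lo, "p_suppressed_hi": hi,
            "mean_end_time": float(np.mean([rec.end_time for rec in outcomes]))
            if n else np.nan,
            "W1_antigenic": w1_a, "W1_neutral": w1_n,
        })
        points.append(PointResult(
            alpha0=alpha0, beta0=beta0, outcomes=outcomes,
            end_times=[rec.end_time for rec in outcomes],
            mbd_antigenic=mbd_a, mbd_neutral=mbd_n, n_failed=n_failed))
        if progress:  # pragma: no cover - cosmetic
            print(f"alpha0={alpha0:g} beta0={beta0:g}: "
                  f"p_suppressed={rows[-1]['p_suppressed']:.2f}")
    table = pd.DataFrame(rows)
    return SweepResult(spec=spec, table=table, points=points,
                       neutral_ref_antigenic=ref_a, neutral_ref_neutral=ref_n)
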