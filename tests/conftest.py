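"""Shared fixtures: desk-scale simulation ensembles reused across tests.

The heavy ensembles are session-scoped so the outcome-classification,
selection-signature and cycle-ordering tests share the same realisations.
All seeds are fixed constants; every ensemble is generated at run time.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import coevosim as cs

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")

# Desk-scale ending population for ensemble tests (the baseline 3e4 is used
# for single illustrative runs only).
DESK_K = 10_000

POINT_A = dict(alpha0=0.002, beta0=0.001)   # low immune effectiveness
POINT_B = dict(alpha0=0.03, beta0=0.3)      # high immune effectiveness
POINT_C = dict(alpha0=0.005, beta0=0.01)    # lambda=10, low effectiveness
HIGH_KILL_ALPHA0 = (0.001, 0.005, 0.02)     # killing-threshold row beta0=0.3


@pytest.fixture(scope="session")
def lam10_point_c_ensemble():
    """50 realisations at lambda=10, point c, desk-scale K.

    Keeps outcomes and trajectories (shared by the outcome-proportion and
    cycle-counting tests).
    """
    params = cs.ModelParams(lambda_=10.0, K=DESK_K, **POINT_C)
    runs = []
    for r in range(50):
        res = cs.run(params, seed=1000 + r)
        runs.append({"outcome": res.outcome, "trajectory": res.trajectory})
    return runs


@pytest.fixture(scope="session")
def lam10_high_kill_row():
    """50 outcomes per alpha0 along the high-killing row beta0=0.3."""
    row = {}
    for j, a0 in enumerate(HIGH_KILL_ALPHA0):
        params = cs.ModelParams(lambda_=10.0, alpha0=a0, beta0=0.3, K=DESK_K)
        row[a0] = [cs.run(params, seed=4000 + 100 * j + r, sample_dt=0.05).outcome
                   for r in range(50)]
    return row


def _lam1_ensemble(point: dict, base_seed: int, n_grown: int = 50,
                   max_reps: int = 150):
    params = cs.ModelParams(lambda_=1.0, K=DESK_K, **point)
    runs = []
    grown = 0
    r = 0
    while grown < n_grown and r < max_reps:
        res = cs.run(params, seed=base_seed + r)
        entry = {"outcome": res.outcome, "trajectory": res.trajectory}
        if res.outcome.outcome == "no_suppression":
            entry["mbd_antigenic"] = cs.compute_mbd(
                res.state.cells.values(), "antigenic")
            entry["mbd_neutral"] = cs.compute_mbd(
                res.state.cells.values(), "neutral")
            grown += 1
        runs.append(entry)
        r += 1
    return runs


@pytest.fixture(scope="session")
def lam1_point_a_ensemble():
    """lambda=1 realisations at point a until 50 tumours reached K."""
    return _lam1_ensemble(POINT_A, base_seed=2000)


@pytest.fixture(scope="session")
def lam1_point_b_ensemble():
    """lambda=1 realisations at point b until 50 tumours reached K."""
    return _lam1_ensemble(POINT_B, base_seed=3000)


@pytest.fixture(scope="session")
def neutral_reference_lam1():
    """No-immune oracle ensembles at lambda=1 matched to desk-scale K."""
    base = cs.ModelParams(lambda_=1.0, K=DESK_K)
    return {
        "antigenic": cs.neutral_expectations(
            base, target_C=DESK_K, mutation_class="antigenic",
            n_replicates=50, seed=7001),
        "neutral": cs.neutral_expectations(
            base, target_C=DESK_K, mutation_class="neutral",
            n_replicates=50, seed=7002),
    }


@pytest.fixture()
def small_mixed_state():
    """A small evolved state with active antigens, for oracle checks."""
    params = cs.ModelParams(lambda_=5.0, p_a=0.5, alpha0=0.02, beta0=0.005,
                            K=400, T_end=30.0)
    sim = cs.Simulation(params, seed=11)
    while sim.state.n_cells and sim.state.n_cells < 200:
        sim.step()
    assert sim.state.n_cells >= 200
    return sim
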