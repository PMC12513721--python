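"""Model parameters for the cancer-immune coevolution simulator.

The baseline values are the ones used throughout the simulation study:
a branching cancer population (birth rate ``b``, death rate ``d``) accrues
mutations at mean rate ``lambda_`` per daughter per division, a fraction
``p_a`` of which are antigenic and recruit a specialised effector-cell
population.  Effector types are passively recruited at zeroth-order rate
``B`` and die at per-capita rate ``D``; pairwise cancer-effector encounters
actively recruit (``alpha0``, saturating with constant ``h_alpha``), kill
(``beta0``) or inhibit (``gamma0``) at mass-action rates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


class ParameterError(ValueError):
    """Raised for out-of-domain model parameters."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter set of the stochastic cancer-immune model.

    Attributes
    ----------
    b, d : float
        Cancer per-capita birth and death rates (1/time).
    lambda_ : float
        Mean number of new (exomic) mutations per daughter cell per division.
    p_a : float
        Probability that a new mutation is antigenic (else neutral).
    p_e : float
        Probability per daughter per division of immune escape: all of the
        daughter's mutations (inherited and new) become neutral.
    B, D : float
        Passive effector recruitment rate (cells/time, zeroth order, active
        while the target mutation has at least one carrier) and effector
        per-capita death rate (1/time).
    alpha0, beta0, gamma0 : float
        Active-recruitment, killing and inhibition constants of the pairwise
        cancer-effector interaction rates.
    h_alpha : float
        Saturation (handling) constant of the type-II active-recruitment
        response ``alpha_i = alpha0*I_i / (1 + alpha0*h_alpha*C_i*I_i)``.
        Its value is not anchored by the baseline table; the default 0.1
        caps the per-effector amplification rate at ``I_i/h_alpha`` =
        10*I_i, fast enough for high-immunogenicity types to mount the
        burst-like specialised responses characteristic of the model while
        keeping weak-interaction tumours able to escape (see the methods
        note for the calibration reasoning).
    K : int
        Ending cancer population size; reaching it terminates a realisation
        as "no suppression".
    T_end : float
        Maximum simulated time; reaching it with ``0 < C < K`` terminates a
        realisation as "slow-growing".
    seed : int | None
        Seed of the realisation's random stream.
    """

    b: float = 1.0
    d: float = 0.1
    lambda_: float = 1.0
    p_a: float = 0.075
    p_e: float = 1e-6
    B: float = 0.2
    D: float = 0.1
    alpha0: float = 0.03
    beta0: float = 0.3
    gamma0: float = 1e-3
    h_alpha: float = 0.1
    K: int = 30_000
    T_end: float = 16.0
    seed: int | None = None

    def __post_init__(self) -> None:
        for name in ("b", "d", "lambda_", "B", "D", "alpha0", "beta0",
                     "gamma0", "h_alpha"):
            value = getattr(self, name)
            if not value >= 0:
                raise ParameterError(f"{name} must be >= 0, got {value!r}")
        for name in ("p_a", "p_e"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1], got {value!r}")
        if not self.K >= 1:
            raise ParameterError(f"K must be >= 1, got {self.K!r}")
        if not self.T_end > 0:
            raise ParameterError(f"T_end must be > 0, got {self.T_end!r}")

    def replace(self, **changes) -> "ModelParams":
        """Return a copy with the given fields replaced (re-validated)."""
        return dataclasses.replace(self, **changes)

    def no_immune(self) -> "ModelParams":
        """Copy with every immune channel disabled (pure branching process).

        Antigenic mutations are still drawn and recorded, but no effector is
        ever recruited, so they evolve neutrally.  This is the neutral
        reference used by the theory baselines.
        """
        return self.replace(B=0.0, alpha0=0.0, beta0=0.0, gamma0=0.0)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(
                f"unknown parameter keys: {sorted(unknown)}; known keys are {sorted(known)}"
            )
        return cls(**data)
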