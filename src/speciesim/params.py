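"""Model parameters and run options.

All quantities are dimensionless model units: genetic similarity q lies in
[-1, 1] (q = 2x - 1 for a fraction x of identical sites), geographic
distances are direct pairwise draws (no embedding in a plane), and time is
counted in birth-death steps, with one generation = N steps.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

__all__ = ["ModelParams", "StopRule", "ConfigError", "MODES", "MATE_GATES"]

MODES = ("sexual", "asexual")

#: How mate eligibility is restricted beyond geography.
#: "equilibrium"  - pairwise similarity must reach q_min_eq (default; the
#:                  deep cut-off is the biological incompatibility threshold)
#: "phase"        - gate at the currently active richness cut-off
#: "none"         - any neighbour within d_c may be chosen
MATE_GATES = ("equilibrium", "phase", "none")


class ConfigError(ValueError):
    """A configuration value is missing, unknown, or out of range."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigError(msg)


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the zero-sum birth-death speciation model.

    Parameters
    ----------
    mu : float
        Mutation rate per nucleotide per birth-death cycle (>= 0).
    mode : str
        Reproductive mode, ``"sexual"`` or ``"asexual"``.
    n : int
        Community (census) size: number of occupied sites, constant in time.
    q_min_transient : float
        Similarity cut-off used to delimit species during the diverging
        transient phase (fine cut-off; incipient clusters).
    q_min_eq : float
        Similarity cut-off used to delimit species at the
        speciation-extinction steady state, and (by default) to gate mating.
        Must not exceed ``q_min_transient``.
    d_c : float
        Maximum geographic distance for finding a mate and for dispersal.
    dist_mean, dist_sd : float
        Mean and standard deviation of the normal distribution from which
        pairwise distances are sampled (negative draws are rejected).
    genome_length : int
        Number of two-state sites, used only by the explicit-genome oracle
        backend; the expectation backend stores no genomes.
    generations : int
        Default run length / cap in generations (one generation = n steps).
    replicates : int
        Number of independent replicates for multi-replicate runs.
    seed : int
        Base seed; replicate r uses seed + r.
    mate_gate : str
        One of :data:`MATE_GATES`.
    victim_includes_mother : bool
        Whether the mother herself may be the randomly killed individual
        whose site the offspring takes (keeps d_c = 0 well defined).
    """

    mu: float
    mode: str
    n: int = 1000
    q_min_transient: float = 0.97
    q_min_eq: float = 0.90
    d_c: float = 1.0
    dist_mean: float = 0.5
    dist_sd: float = 0.35
    genome_length: int = 100_000
    generations: int = 500
    replicates: int = 50
    seed: int = 0
    mate_gate: str = "equilibrium"
    victim_includes_mother: bool = True

    def __post_init__(self) -> None:
        _check(self.mode in MODES, f"mode must be one of {MODES}, got {self.mode!r}")
        _check(self.mu >= 0, f"mu must be >= 0, got {self.mu}")
        _check(self.n >= 2, f"n must be >= 2, got {self.n}")
        for name in ("q_min_transient", "q_min_eq"):
            v = getattr(self, name)
            _check(0 < v < 1, f"{name} must lie in (0, 1), got {v}")
        _check(
            self.q_min_eq <= self.q_min_transient,
            "q_min_eq must not exceed q_min_transient "
            f"({self.q_min_eq} > {self.q_min_transient})",
        )
        _check(self.d_c >= 0, f"d_c must be >= 0, got {self.d_c}")
        _check(self.dist_sd > 0, f"dist_sd must be > 0, got {self.dist_sd}")
        _check(self.genome_length >= 1, "genome_length must be >= 1")
        _check(self.generations >= 1, "generations must be >= 1")
        _check(self.replicates >= 1, "replicates must be >= 1")
        _check(
            self.mate_gate in MATE_GATES,
            f"mate_gate must be one of {MATE_GATES}, got {self.mate_gate!r}",
        )

    def replace(self, **kwargs) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def mate_cutoff(self, phase: str = "equilibrium") -> float | None:
        """Similarity a pair must reach to mate, or None if ungated."""
        if self.mate_gate == "none":
            return None
        if self.mate_gate == "phase":
            return self.q_min_transient if phase == "transient" else self.q_min_eq
        return self.q_min_eq


@dataclass(frozen=True)
class StopRule:
    """When a replicate ends.

    kind:
      ``fixed_generations``      run exactly ``max_generations``.
      ``transient_qbar_target``  stop the first generation the community mean
                                 similarity drops to ``qbar_target`` or below
                                 (the divergence-phase protocol); a replicate
                                 that never reaches the target within
                                 ``max_generations`` is flagged unconverged.
      ``steady_state``           stop once the mean similarity has ranged less
                                 than ``tol`` over the trailing ``window``
                                 generations, whatever its initial value.
    """

    kind: str = "fixed_generations"
    max_generations: int = 500
    qbar_target: float = 0.97
    window: int = 100
    tol: float = 0.03

    KINDS = ("fixed_generations", "transient_qbar_target", "steady_state")

    def __post_init__(self) -> None:
        _check(self.kind in self.KINDS, f"stop rule kind must be one of {self.KINDS}")
        _check(self.max_generations >= 1, "max_generations must be >= 1")
        _check(0 < self.qbar_target < 1, "qbar_target must lie in (0, 1)")
        _check(self.window >= 2, "window must be >= 2")
        _check(self.tol > 0, "tol must be > 0")
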