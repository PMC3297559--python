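"""Stochastic zero-sum birth-death metacommunity simulator.

The community holds exactly N individuals, one per site, with a fixed
symmetric matrix D of pairwise geographic distances (direct draws from a
truncated normal; no planar embedding, and the triangle inequality is not
assumed). The default backend evolves the expected pairwise similarity
matrix Q directly: a birth-death step picks a mother uniformly, a mate
among compatible neighbours within d_c (sexual mode; clonal fallback when
none), kills a uniformly chosen victim within d_c of the mother, and
replaces the victim's row/column of Q with the offspring's expected
similarities. One generation is N such steps; genomes themselves are never
stored. An explicit-genome backend (see :mod:`speciesim.genome`) is
available for cross-checks at small N.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import founder_population, genome_similarity, mutate, recombine
from .params import ModelParams, StopRule
from .species import ExtinctionEvent, LineageTracker, SpeciationEvent, species_partition

__all__ = [
    "CommunityState",
    "StepOutcome",
    "Trajectory",
    "sample_distance_matrix",
    "initial_state",
    "neighbors_within",
    "select_mate",
    "birth_death_step",
    "run_generation",
    "run_replicate",
    "run_many",
]


def sample_distance_matrix(
    n: int, mean: float, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Symmetric nonnegative distance matrix with zero diagonal.

    Each unordered pair's distance is drawn from Normal(mean, sd), redrawn
    until nonnegative (truncation by rejection, not clipping).
    """
    if n < 2:
        raise ValueError(f"need at least 2 sites, got {n}")
    if sd <= 0:
        raise ValueError(f"sd must be > 0, got {sd}")
    iu = np.triu_indices(n, k=1)
    m = iu[0].size
    vals = np.empty(m)
    todo = np.arange(m)
    while todo.size:
        draw = rng.normal(mean, sd, todo.size)
        ok = draw >= 0
        vals[todo[ok]] = draw[ok]
        todo = todo[~ok]
    d = np.zeros((n, n))
    d[iu] = vals
    d += d.T
    return d


@dataclass
class CommunityState:
    """Mutable simulator state: Q, D, per-site species labels, clocks."""

    q: np.ndarray
    d: np.ndarray
    rng: np.random.Generator
    t_steps: int = 0
    labels: np.ndarray | None = None
    genomes: np.ndarray | None = None  # (n, S) int8, genome backend only

    @property
    def n(self) -> int:
        return self.q.shape[0]

    @property
    def generation(self) -> int:
        return self.t_steps // self.n

    def mean_similarity(self) -> float:
        n = self.n
        return float((self.q.sum() - n) / (n * (n - 1)))


def initial_state(
    params: ModelParams,
    seed: int | None = None,
    backend: str = "expectation",
) -> CommunityState:
    """Founded community: all similarities 1, distances freshly sampled."""
    rng = np.random.default_rng(params.seed if seed is None else seed)
    d = sample_distance_matrix(params.n, params.dist_mean, params.dist_sd, rng)
    q = np.ones((params.n, params.n))
    genomes = None
    if backend == "genome":
        genomes = founder_population(params.n, params.genome_length)
    elif backend != "expectation":
        raise ValueError(f"unknown backend {backend!r}")
    state = CommunityState(q=q, d=d, rng=rng, genomes=genomes)
    state.labels = species_partition(q, params.q_min_transient)
    return state


def neighbors_within(state: CommunityState, site: int, d_c: float) -> np.ndarray:
    """Sites j != site with d(site, j) <= d_c, in index order."""
    row = state.d[site]
    mask = row <= d_c
    mask[site] = False
    return np.flatnonzero(mask)


def _neighbor_cache(d: np.ndarray, d_c: float, include_self: bool):
    n = d.shape[0]
    within = d <= d_c
    if not include_self:
        np.fill_diagonal(within, False)
    else:
        np.fill_diagonal(within, True)  # d_ii = 0 <= d_c always
    return [np.flatnonzero(within[i]) for i in range(n)]


def select_mate(
    state: CommunityState,
    mother: int,
    d_c: float,
    q_min: float | None,
    rng: np.random.Generator | None = None,
    neighbors: np.ndarray | None = None,
) -> int | None:
    """Uniform choice among compatible neighbours; None means no potential
    mate exists and the mother reproduces clonally instead.

    ``q_min=None`` drops the similarity gate (geography only).
    """
    rng = state.rng if rng is None else rng
    cand = neighbors_within(state, mother, d_c) if neighbors is None else neighbors
    if q_min is not None:
        cand = cand[state.q[mother, cand] >= q_min]
    if cand.size == 0:
        return None
    return int(cand[rng.integers(cand.size)])


@dataclass(frozen=True)
class StepOutcome:
    mother_site: int
    mate_site: int | None
    victim_site: int
    clonal_fallback: bool


def birth_death_step(
    state: CommunityState,
    params: ModelParams,
    phase: str = "equilibrium",
    _neighbors=None,
    _victims=None,
) -> StepOutcome:
    """One zero-sum birth-death event; mutates ``state`` in place.

    The offspring occupies the victim's site (inheriting that site's row of
    D) and its row/column of Q holds the expected similarity to every
    survivor; its own diagonal entry is 1. The victim pool is the mother's
    d_c-neighbourhood, including the mother herself unless configured
    otherwise, and never the mate.
    """
    rng = state.rng
    n = state.n
    mother = int(rng.integers(n))

    nbrs = (
        neighbors_within(state, mother, params.d_c)
        if _neighbors is None
        else _neighbors[mother]
    )
    mate: int | None = None
    clonal = True
    if params.mode == "sexual":
        mate = select_mate(
            state, mother, params.d_c, params.mate_cutoff(phase), rng, neighbors=nbrs
        )
        clonal = mate is None

    if _victims is None:
        victims = nbrs
        if params.victim_includes_mother:
            victims = np.append(victims, mother)
    else:
        victims = _victims[mother]
    if mate is not None:
        victims = victims[victims != mate]
    if victims.size == 0:
        victim = mother  # isolated site with self-death disabled: fall back
    else:
        victim = int(victims[rng.integers(victims.size)])

    q = state.q
    decay = np.exp(-2.0 * params.mu)
    if state.genomes is None:
        if mate is None:
            row = decay * q[mother]
        else:
            row = decay * 0.5 * (q[mother] + q[mate])
    else:
        child = state.genomes[mother] if mate is None else recombine(
            state.genomes[mother], state.genomes[mate], rng
        )
        child = mutate(child, params.mu, rng)
        state.genomes[victim] = child
        row = state.genomes.astype(np.int32) @ child.astype(np.int32)
        row = row / params.genome_length
    q[victim, :] = row
    q[:, victim] = row
    q[victim, victim] = 1.0

    state.t_steps += 1
    return StepOutcome(
        mother_site=mother, mate_site=mate, victim_site=victim, clonal_fallback=clonal
    )


def run_generation(
    state: CommunityState,
    params: ModelParams,
    phase: str = "equilibrium",
    _neighbors=None,
    _victims=None,
) -> CommunityState:
    """Apply exactly N birth-death steps (one generation)."""
    for _ in range(state.n):
        birth_death_step(state, params, phase, _neighbors, _victims)
    return state


@dataclass
class Trajectory:
    """Per-generation record of one replicate.

    Events are logged at both cut-offs: the fine transient cut-off resolves
    incipient clusters, the deep equilibrium cut-off counts well-diverged
    species. ``converged`` reports whether the stop rule was satisfied
    within its generation cap; unconverged replicates still carry their
    partial series.
    """

    params: ModelParams
    stop_rule: StopRule
    seed: int
    generations: int = 0
    converged: bool = False
    q_bar: np.ndarray = field(default_factory=lambda: np.empty(0))
    richness_transient: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    richness_eq: np.ndarray = field(default_factory=lambda: np.empty(0, int))
    speciations_transient: list[SpeciationEvent] = field(default_factory=list)
    extinctions_transient: list[ExtinctionEvent] = field(default_factory=list)
    speciations_eq: list[SpeciationEvent] = field(default_factory=list)
    extinctions_eq: list[ExtinctionEvent] = field(default_factory=list)
    final_state: CommunityState | None = None


def run_replicate(
    params: ModelParams,
    stop_rule: StopRule | None = None,
    seed: int | None = None,
    phase: str | None = None,
    track_events: bool = True,
    backend: str = "expectation",
) -> Trajectory:
    """Run one replicate under a stop rule, recording per-generation series.

    The species partition is recomputed once per generation (event
    timestamps are in generations). ``phase`` controls which cut-off gates
    mating when ``params.mate_gate == "phase"``; it defaults to "transient"
    for the transient stop rule and "equilibrium" otherwise.
    """
    stop_rule = StopRule() if stop_rule is None else stop_rule
    seed = params.seed if seed is None else seed
    if phase is None:
        phase = (
            "transient" if stop_rule.kind == "transient_qbar_target" else "equilibrium"
        )

    state = initial_state(params, seed=seed, backend=backend)
    nbrs = _neighbor_cache(state.d, params.d_c, include_self=False)
    victims = _neighbor_cache(state.d, params.d_c, include_self=params.victim_includes_mother)

    tracker_t = tracker_e = None
    if track_events:
        tracker_t = LineageTracker(species_partition(state.q, params.q_min_transient))
        tracker_e = LineageTracker(species_partition(state.q, params.q_min_eq))

    max_gen = stop_rule.max_generations
    q_bar = np.empty(max_gen)
    rich_t = np.empty(max_gen, dtype=int)
    rich_e = np.empty(max_gen, dtype=int)
    converged = False
    g = 0
    for g in range(1, max_gen + 1):
        run_generation(state, params, phase, nbrs, victims)
        q_bar[g - 1] = state.mean_similarity()
        part_t = species_partition(state.q, params.q_min_transient)
        part_e = species_partition(state.q, params.q_min_eq)
        rich_t[g - 1] = np.unique(part_t).size
        rich_e[g - 1] = np.unique(part_e).size
        if track_events:
            tracker_t.update(part_t, g)
            tracker_e.update(part_e, g)
            state.labels = (
                tracker_t.labels if phase == "transient" else tracker_e.labels
            )
        else:
            state.labels = part_t if phase == "transient" else part_e

        if stop_rule.kind == "transient_qbar_target":
            if q_bar[g - 1] <= stop_rule.qbar_target:
                converged = True
                break
        elif stop_rule.kind == "steady_state":
            if g >= stop_rule.window:
                win = q_bar[g - stop_rule.window : g]
                if win.max() - win.min() < stop_rule.tol:
                    converged = True
                    break
        else:  # fixed_generations
            if g == max_gen:
                converged = True

    traj = Trajectory(
        params=params,
        stop_rule=stop_rule,
        seed=seed,
        generations=g,
        converged=converged,
        q_bar=q_bar[:g].copy(),
        richness_transient=rich_t[:g].copy(),
        richness_eq=rich_e[:g].copy(),
        final_state=state,
    )
    if track_events:
        traj.speciations_transient = tracker_t.speciations
        traj.extinctions_transient = tracker_t.extinctions
        traj.speciations_eq = tracker_e.speciations
        traj.extinctions_eq = tracker_e.extinctions
    return traj


def run_many(
    params: ModelParams,
    stop_rule: StopRule | None = None,
    replicates: int | None = None,
    **kwargs,
) -> list[Trajectory]:
    """Independent replicates; replicate r runs with seed params.seed + r."""
    reps = params.replicates if replicates is None else replicates
    return [
        run_replicate(params, stop_rule, seed=params.seed + r, **kwargs)
        for r in range(reps)
    ]
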