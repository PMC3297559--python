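"""Canned studies: the package's headline computations at fixed conditions.

Each function runs a complete mini-study from scratch — generating its own
inputs, running the method, and measuring the result — and returns a plain
dict of numbers. The paired sexual-vs-asexual comparisons use a community
of N = 200 sites with distances drawn from the truncated Normal(0.5, 0.35),
a mating/dispersal radius d_c = 1 and mutation rate mu = 5e-4 per
nucleotide per birth-death cycle, conditions under which the speciation
condition holds at both species cut-offs (mutation-drift equilibrium
similarity 1/(1 + 2 N mu) ~= 0.83 < 0.90 < 0.97). Problem sizes are scaled
for a single CPU; see docs/methods.md.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import binomtest

from . import genome, similarity
from .engine import birth_death_step, initial_state, run_replicate
from .params import ModelParams, StopRule
from .species import species_partition
from .stats import ks_two_sample, singleton_fraction

__all__ = [
    "clonal_decay_study",
    "recombination_offspring_study",
    "critical_step_grid",
    "equilibrium_recovery_study",
    "mode_comparison_transient",
    "mode_comparison_equilibrium",
    "mutation_induced_study",
    "analytic_summary",
]


def _sub_seed(seed: int, k: int) -> int:
    """Deterministic sub-stream seed below 2**31."""
    return (seed * 100_003 + k) % (2**31 - 1)


def clonal_decay_study(
    seed: int,
    genome_length: int = 100_000,
    mu: float = 1e-3,
    n_steps: int = 50,
    replicates: int = 200,
) -> dict:
    """Clonal-chain oracle: finite-genome decay vs e^(-2 mu n) at every step."""
    rng = np.random.default_rng(_sub_seed(seed, 1))
    report = genome.validate_decay(genome_length, mu, n_steps, replicates, rng)
    return {
        "max_abs_z": float(np.abs(report.z_scores).max()),
        "n_flagged": int(report.flagged.sum()),
        "final_empirical": float(report.empirical_mean[-1]),
        "final_analytic": float(report.analytic[-1]),
        "n_steps": n_steps,
        "replicates": replicates,
    }


def recombination_offspring_study(
    seed: int,
    genome_length: int = 100_000,
    mu: float = 5e-3,
    q_mother_father: float = 0.8,
    replicates: int = 500,
) -> dict:
    """Sexual oracle: offspring-mother similarity vs e^(-2 mu)(1 + q_mf)/2.

    The father is built to differ from the mother at exactly
    S (1 - q_mf)/2 sites; each replicate recombines and mutates once.
    """
    rng = np.random.default_rng(_sub_seed(seed, 2))
    mother = genome.founder_genome(genome_length)
    k = round(genome_length * (1.0 - q_mother_father) / 2.0)
    father = mother.copy()
    father[:k] = -father[:k]
    q_mf = genome.genome_similarity(mother, father).q
    expected = similarity.sexual_offspring_similarity(1.0, q_mf, mu)
    qs = np.empty(replicates)
    for r in range(replicates):
        child = genome.mutate(genome.recombine(mother, father, rng), mu, rng)
        qs[r] = genome.genome_similarity(child, mother).q
    se = qs.std(ddof=1) / np.sqrt(replicates)
    return {
        "empirical": float(qs.mean()),
        "expected": float(expected),
        "z": float((qs.mean() - expected) / se),
        "replicates": replicates,
    }


def critical_step_grid(
    mus: np.ndarray | None = None,
    q_mins: tuple = (0.9, 0.95, 0.97, 0.99),
    q_bars: tuple = (0.0, 0.5, 0.9, 0.99),
) -> dict:
    """Dominance of the sexual critical step over the full parameter grid."""
    mus = np.logspace(-5, -2, 13) if mus is None else np.asarray(mus)
    n_cells = 0
    violations = 0
    equality_failures = 0
    for mu in mus:
        for q_min in q_mins:
            n_asex = similarity.n_star_asex(mu, q_min)
            if similarity.n_star_sex(mu, q_min, 1.0) != n_asex:
                equality_failures += 1
            for q_bar in q_bars:
                n_cells += 1
                if similarity.n_star_sex(mu, q_min, q_bar) > n_asex:
                    violations += 1
    return {
        "n_cells": n_cells,
        "dominance_violations": violations,
        "equality_failures_at_qbar_1": equality_failures,
    }


def equilibrium_recovery_study(
    seed: int,
    n_effective: int = 100,
    mu: float = 2.5e-4,
    burn_in: int = 500,
    horizon: int = 2500,
    replicates: int = 2,
) -> dict:
    """Panmictic asexual run recovering q_hat = 1/(1 + 4 N_e mu).

    The community census is twice the requested effective size because
    overlapping-generations (Moran) dynamics halve the effective size; the
    measured value is the time average of the matrix mean similarity after
    burn-in, pooled over replicates.
    """
    census = int(round(2 * n_effective))
    predicted = similarity.equilibrium_similarity(n_effective, mu)
    params = ModelParams(
        mu=mu, mode="asexual", n=census, d_c=np.inf, seed=_sub_seed(seed, 3)
    )
    rule = StopRule(kind="fixed_generations", max_generations=horizon)
    tails = []
    for r in range(replicates):
        traj = run_replicate(params, rule, seed=params.seed + r, track_events=False)
        tails.append(traj.q_bar[burn_in:])
    measured = float(np.concatenate(tails).mean())
    return {
        "measured_qbar": measured,
        "predicted_qhat": float(predicted),
        "abs_error": float(abs(measured - predicted)),
        "n_effective": n_effective,
        "census": census,
        "generations_averaged": (horizon - burn_in) * replicates,
    }


def _paired_params(n, mu, d_c, seed):
    base = dict(mu=mu, n=n, d_c=d_c)
    return (
        ModelParams(mode="sexual", seed=seed, **base),
        ModelParams(mode="asexual", seed=seed, **base),
    )


def mode_comparison_transient(
    seed: int,
    n: int = 200,
    mu: float = 5e-4,
    d_c: float = 1.0,
    replicates: int = 20,
    window: int = 500,
) -> dict:
    """Paired radiation race: cumulative incipient-species events, sexual vs
    asexual, over a fixed early window after founding.

    Events are counted at the fine (transient) cut-off. Each pair of runs
    shares a seed, hence a distance matrix (common random numbers). Returns
    per-replicate event counts, a one-sided sign test for "sexual produces
    more events", pooled incipient abundances, their singleton fractions
    and a one-sided KS comparison (sexual stochastically smaller).
    """
    rule = StopRule(kind="fixed_generations", max_generations=window)
    ev_sex, ev_asex = [], []
    sizes_sex, sizes_asex = [], []
    for r in range(replicates):
        rep_seed = _sub_seed(seed, 10_000 + r)
        p_sex, p_asex = _paired_params(n, mu, d_c, rep_seed)
        t_sex = run_replicate(p_sex, rule)
        t_asex = run_replicate(p_asex, rule)
        ev_sex.append(len(t_sex.speciations_transient))
        ev_asex.append(len(t_asex.speciations_transient))
        sizes_sex.extend(e.incipient_abundance for e in t_sex.speciations_transient)
        sizes_asex.extend(e.incipient_abundance for e in t_asex.speciations_transient)
    ev_sex = np.array(ev_sex)
    ev_asex = np.array(ev_asex)
    wins = int((ev_sex > ev_asex).sum())
    ties = int((ev_sex == ev_asex).sum())
    informative = replicates - ties
    sign_p = (
        binomtest(wins, informative, 0.5, alternative="greater").pvalue
        if informative
        else 1.0
    )
    # one-sided: sexual incipient sizes stochastically smaller, i.e. their
    # ECDF lies above the asexual one (scipy's "greater" alternative)
    ks_stat, ks_p = ks_two_sample(sizes_sex, sizes_asex, alternative="greater")
    return {
        "events_sexual": ev_sex,
        "events_asexual": ev_asex,
        "median_events_sexual": float(np.median(ev_sex)),
        "median_events_asexual": float(np.median(ev_asex)),
        "sign_test_p": float(sign_p),
        "sexual_wins": wins,
        "singleton_fraction_sexual": singleton_fraction(sizes_sex),
        "singleton_fraction_asexual": singleton_fraction(sizes_asex),
        "mean_incipient_sexual": float(np.mean(sizes_sex)),
        "mean_incipient_asexual": float(np.mean(sizes_asex)),
        "ks_statistic": float(ks_stat),
        "ks_p": float(ks_p),
        "replicates": replicates,
        "window": window,
    }


def mode_comparison_equilibrium(
    seed: int,
    n: int = 200,
    mu: float = 5e-4,
    d_c: float = 1.0,
    replicates: int = 20,
    generations: int = 1500,
    tail: int = 400,
) -> dict:
    """Paired steady-state richness: species counted at the deep
    (equilibrium) cut-off, medians over the trailing window per replicate."""
    rule = StopRule(kind="fixed_generations", max_generations=generations)
    rich_sex, rich_asex = [], []
    qbar_sex, qbar_asex = [], []
    for r in range(replicates):
        rep_seed = _sub_seed(seed, 20_000 + r)
        p_sex, p_asex = _paired_params(n, mu, d_c, rep_seed)
        t_sex = run_replicate(p_sex, rule, track_events=False)
        t_asex = run_replicate(p_asex, rule, track_events=False)
        rich_sex.append(np.median(t_sex.richness_eq[-tail:]))
        rich_asex.append(np.median(t_asex.richness_eq[-tail:]))
        qbar_sex.append(t_sex.q_bar[-tail:].mean())
        qbar_asex.append(t_asex.q_bar[-tail:].mean())
    rich_sex = np.array(rich_sex)
    rich_asex = np.array(rich_asex)
    return {
        "richness_sexual": rich_sex,
        "richness_asexual": rich_asex,
        "median_richness_sexual": float(np.median(rich_sex)),
        "median_richness_asexual": float(np.median(rich_asex)),
        "mean_qbar_sexual": float(np.mean(qbar_sex)),
        "mean_qbar_asexual": float(np.mean(qbar_asex)),
        "predicted_qhat": similarity.equilibrium_similarity(
            similarity.moran_effective_size(n), mu
        ),
        "replicates": replicates,
        "generations": generations,
    }


def mutation_induced_study(
    seed: int,
    n: int = 50,
    q_min: float = 0.97,
    generations: int = 2,
    margin: float = 1.3,
) -> dict:
    """Hopeful-monster regime: with mu strictly above -ln(q_min)/2, every
    clonal birth must found a new single-member cluster at the moment of
    birth (checked exactly after every step)."""
    mu = margin * similarity.mutation_induced_threshold(q_min)
    params = ModelParams(
        mu=mu,
        mode="asexual",
        n=n,
        q_min_transient=q_min,
        q_min_eq=q_min,
        seed=_sub_seed(seed, 4),
    )
    state = initial_state(params)
    births = 0
    singleton_births = 0
    for _ in range(generations * n):
        outcome = birth_death_step(state, params)
        births += 1
        part = species_partition(state.q, q_min)
        if (part == part[outcome.victim_site]).sum() == 1:
            singleton_births += 1
    return {
        "mu": mu,
        "threshold": similarity.mutation_induced_threshold(q_min),
        "births": births,
        "singleton_births": singleton_births,
        "all_singletons": singleton_births == births,
    }


def analytic_summary(
    mu: float, q_min: float, q_bar: float, n_effective: float
) -> dict:
    """The analytic kernel in one view, as emitted by the CLI."""
    try:
        n_asex = similarity.n_star_asex(mu, q_min)
        n_sex = similarity.n_star_sex(mu, q_min, q_bar)
    except ValueError:
        n_asex = n_sex = None
    return {
        "n_star_asex": n_asex,
        "n_star_sex": n_sex,
        "q_hat": similarity.equilibrium_similarity(n_effective, mu),
        "mu_hopeful": similarity.mutation_induced_threshold(q_min),
        "speciation_ok": similarity.speciation_condition(n_effective, mu, q_min),
    }
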