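"""Spatial birth-death engine: distance sampling, neighbourhoods, mate
choice, step/generation updates, stop rules, backends and determinism."""

import warnings

import numpy as np
import pytest
from scipy import stats as sps

from speciesim import engine as eng
from speciesim.params import ModelParams, StopRule
from speciesim.species import species_partition


def make_params(**kw):
    defaults = dict(mu=1e-3, mode="asexual", n=40, seed=7)
    defaults.update(kw)
    return ModelParams(**defaults)


class TestDistanceMatrix:
    def test_shape_symmetry_and_support(self, rng):
        d = eng.sample_distance_matrix(30, 0.5, 0.35, rng)
        assert d.shape == (30, 30)
        assert np.array_equal(d, d.T)
        assert np.all(np.diag(d) == 0)
        off = d[np.triu_indices(30, 1)]
        assert np.all(off >= 0)

    def test_tiny_sd_concentrates_at_mean(self, rng):
        d = eng.sample_distance_matrix(10, 0.5, 1e-9, rng)
        off = d[np.triu_indices(10, 1)]
        assert np.allclose(off, 0.5, atol=1e-6)

    def test_mean_matches_truncated_normal(self, rng):
        mean, sd = 0.5, 0.35
        d = eng.sample_distance_matrix(120, mean, sd, rng)
        off = d[np.triu_indices(120, 1)]
        expected = sps.truncnorm.mean((0 - mean) / sd, np.inf, loc=mean, scale=sd)
        se = off.std(ddof=1) / np.sqrt(off.size)
        assert abs(off.mean() - expected) < 3 * se


class TestNeighbourhoods:
    def test_matches_brute_force_scan(self):
        params = make_params(n=25)
        state = eng.initial_state(params)
        for site in range(25):
            got = eng.neighbors_within(state, site, 0.6)
            want = [
                j for j in range(25) if j != site and state.d[site, j] <= 0.6
            ]
            assert got.tolist() == want

    def test_radius_extremes(self):
        state = eng.initial_state(make_params(n=15))
        assert eng.neighbors_within(state, 3, np.inf).size == 14
        assert eng.neighbors_within(state, 3, 0.0).size == 0


class TestSelectMate:
    def _state_with_q(self, q, seed=5):
        params = make_params(n=q.shape[0], mode="sexual", seed=seed)
        state = eng.initial_state(params)
        state.q = q
        return state, params

    def test_no_compatible_neighbour_means_clonal_fallback(self):
        q = np.full((6, 6), 0.5)
        np.fill_diagonal(q, 1.0)
        state, _ = self._state_with_q(q)
        assert eng.select_mate(state, 0, np.inf, 0.97) is None

    def test_single_eligible_is_chosen(self):
        q = np.full((6, 6), 0.5)
        np.fill_diagonal(q, 1.0)
        q[0, 3] = q[3, 0] = 0.99
        state, _ = self._state_with_q(q)
        for _ in range(10):
            assert eng.select_mate(state, 0, np.inf, 0.97) == 3

    def test_uniform_over_eligible_set(self):
        n = 8
        q = np.ones((n, n))
        state, _ = self._state_with_q(q, seed=11)
        eligible = list(range(1, 6))
        state.q = np.full((n, n), 0.5)
        np.fill_diagonal(state.q, 1.0)
        for j in eligible:
            state.q[0, j] = state.q[j, 0] = 0.99
        draws = [eng.select_mate(state, 0, np.inf, 0.97) for _ in range(4000)]
        counts = np.array([draws.count(j) for j in eligible])
        chi2, p = sps.chisquare(counts)
        assert p > 1e-3
        assert set(draws) == set(eligible)

    def test_ungated_uses_geography_only(self):
        q = np.full((6, 6), -0.5)
        np.fill_diagonal(q, 1.0)
        state, _ = self._state_with_q(q)
        assert eng.select_mate(state, 0, np.inf, None) is not None


class TestBirthDeathStep:
    def test_no_mutation_clone_duplicates_mother_row(self):
        params = make_params(mu=0.0, n=20, seed=3)
        state = eng.initial_state(params)
        state.q = np.round(np.clip(state.d / state.d.max(), 0, 1), 3)  # arbitrary
        state.q = (state.q + state.q.T) / 2
        np.fill_diagonal(state.q, 1.0)
        out = eng.birth_death_step(state, params)
        m, v = out.mother_site, out.victim_site
        if v != m:
            assert state.q[v, m] == 1.0  # clone of the mother, no mutation
            others = [j for j in range(20) if j != v]
            assert np.allclose(state.q[v, others], state.q[m, others])
        assert state.q[v, v] == 1.0

    def test_zero_sum_and_matrix_invariants_over_generations(self):
        params = make_params(mode="sexual", mu=2e-3, n=30, seed=9)
        state = eng.initial_state(params)
        for _ in range(5):
            eng.run_generation(state, params)
            assert state.q.shape == (30, 30)
            assert np.array_equal(state.q, state.q.T)
            assert np.all(np.diag(state.q) == 1.0)
            assert np.all(state.q <= 1.0) and np.all(state.q >= -1.0)
        assert state.t_steps == 5 * 30
        assert state.generation == 5

    def test_victim_in_mother_neighbourhood_and_mate_protected(self):
        params = make_params(mode="sexual", n=25, d_c=0.5, mu=1e-3, seed=21)
        state = eng.initial_state(params)
        for _ in range(200):
            out = eng.birth_death_step(state, params)
            m, v = out.mother_site, out.victim_site
            assert v == m or state.d[m, v] <= params.d_c
            if out.mate_site is not None:
                assert out.victim_site != out.mate_site
                assert state.d[m, out.mate_site] <= params.d_c

    def test_offspring_mother_similarity_is_mutation_decay(self):
        params = make_params(mu=3e-3, n=30, seed=13)
        state = eng.initial_state(params)
        f = np.exp(-2 * params.mu)
        seen = 0
        for _ in range(300):
            out = eng.birth_death_step(state, params)
            if out.victim_site != out.mother_site:
                assert state.q[out.victim_site, out.mother_site] == pytest.approx(
                    f, rel=1e-12
                )
                seen += 1
        assert seen > 100

    def test_no_mutation_single_genotype_stays_uniform(self):
        params = make_params(mu=0.0, n=20)
        state = eng.initial_state(params)
        eng.run_generation(state, params)
        assert np.all(state.q == 1.0)


def meanfield_qbar(n, mu, generations):
    """Independent oracle: deterministic per-event expectation recursion for
    the panmictic asexual mean similarity."""
    f = np.exp(-2 * mu)
    qb = 1.0
    out = []
    for step in range(generations * n):
        delta = ((n - 1) / n) * 2 * (f * (1 + (n - 2) * qb) - (n - 1) * qb) + (
            1 / n
        ) * 2 * (f - 1) * (n - 1) * qb
        qb += delta / (n * (n - 1))
        if (step + 1) % n == 0:
            out.append(qb)
    return np.array(out)


class TestTrajectories:
    def test_panmictic_decay_tracks_meanfield_recursion(self):
        n, mu, gens = 150, 1e-3, 50
        params = make_params(n=n, mu=mu, d_c=np.inf, seed=31)
        rule = StopRule(kind="fixed_generations", max_generations=gens)
        sims = np.array(
            [
                eng.run_replicate(params, rule, seed=100 + r, track_events=False).q_bar
                for r in range(3)
            ]
        )
        theory = meanfield_qbar(n, mu, gens)
        assert np.abs(sims.mean(axis=0) - theory).max() < 0.02

    def test_transient_rule_stops_at_first_crossing(self):
        params = make_params(n=60, mu=2e-3, d_c=np.inf, seed=17)
        rule = StopRule(
            kind="transient_qbar_target", qbar_target=0.97, max_generations=200
        )
        traj = eng.run_replicate(params, rule, track_events=False)
        assert traj.converged
        assert traj.q_bar[-1] <= 0.97
        assert np.all(traj.q_bar[:-1] > 0.97)

    def test_transient_rule_flags_when_target_unreachable(self):
        params = make_params(n=30, mu=0.0, seed=2)
        rule = StopRule(
            kind="transient_qbar_target", qbar_target=0.97, max_generations=10
        )
        traj = eng.run_replicate(params, rule, track_events=False)
        assert not traj.converged
        assert traj.generations == 10

    def test_steady_state_rule_accepts_constant_series(self):
        params = make_params(n=30, mu=0.0, seed=2)  # q_bar pinned at 1
        rule = StopRule(kind="steady_state", window=10, tol=0.01, max_generations=50)
        traj = eng.run_replicate(params, rule, track_events=False)
        assert traj.converged
        assert traj.generations == 10

    def test_steady_state_rule_rejects_drifting_series(self):
        params = make_params(n=100, mu=5e-3, d_c=np.inf, seed=4)
        rule = StopRule(kind="steady_state", window=30, tol=1e-6, max_generations=40)
        traj = eng.run_replicate(params, rule, track_events=False)
        assert not traj.converged

    def test_identical_seed_gives_bit_identical_trajectories(self):
        params = make_params(mode="sexual", n=50, mu=1e-3, seed=42, generations=30)
        rule = StopRule(kind="fixed_generations", max_generations=30)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = eng.run_replicate(params, rule)
            b = eng.run_replicate(params, rule)
        assert np.array_equal(a.q_bar, b.q_bar)
        assert np.array_equal(a.final_state.q, b.final_state.q)
        assert a.speciations_transient == b.speciations_transient
        assert a.extinctions_eq == b.extinctions_eq

    def test_distances_irrelevant_when_radius_unbounded(self):
        # with d_c = inf the neighbourhood is everyone, so permuting the
        # distance matrix cannot change the dynamics (site exchangeability)
        params = make_params(n=40, mu=1e-3, d_c=np.inf, seed=8)
        state_a = eng.initial_state(params)
        state_b = eng.initial_state(params)  # same seed: same D, same rng
        perm = np.random.default_rng(0).permutation(40)
        state_b.d = state_b.d[np.ix_(perm, perm)]
        for _ in range(5):
            eng.run_generation(state_a, params)
            eng.run_generation(state_b, params)
        assert np.array_equal(state_a.q, state_b.q)

    def test_separated_clusters_keep_diverging(self):
        # once two components are mutually below the mating cut-off, the
        # maximum similarity between them can only decay: every offspring
        # row is a shrunk average of rows from its own side
        n = 40
        params = make_params(mode="asexual", n=n, mu=2e-3, d_c=np.inf, seed=19)
        state = eng.initial_state(params)
        q = np.full((n, n), 0.99)
        half = n // 2
        q[:half, half:] = 0.6  # two cohesive clusters, cross-pairs diverged
        q[half:, :half] = 0.6
        np.fill_diagonal(q, 1.0)
        state.q = q
        part = species_partition(state.q, params.q_min_eq)
        assert np.unique(part).size == 2
        # lineage side: offspring belong to their mother's cluster even when
        # they take over a site on the other side
        side = np.array([0] * half + [1] * half)
        prev = state.q[np.ix_(side == 0, side == 1)].max()
        for _ in range(10 * n):
            out = eng.birth_death_step(state, params)
            side[out.victim_site] = side[out.mother_site]
            if (side == 0).any() and (side == 1).any():
                cur = state.q[np.ix_(side == 0, side == 1)].max()
                assert cur <= prev + 1e-12
                prev = cur


class TestGenomeBackend:
    def test_matrix_matches_explicit_genomes(self):
        params = make_params(
            mode="sexual", n=20, mu=5e-3, genome_length=400, seed=23, d_c=np.inf
        )
        rule = StopRule(kind="fixed_generations", max_generations=5)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            traj = eng.run_replicate(params, rule, backend="genome")
        state = traj.final_state
        g = state.genomes.astype(np.int32)
        q_direct = (g @ g.T) / params.genome_length
        assert np.allclose(state.q, q_direct)
        assert np.all(np.abs(state.q) <= 1.0)

    def test_backend_names_validated(self):
        with pytest.raises(ValueError):
            eng.initial_state(make_params(), backend="quantum")
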