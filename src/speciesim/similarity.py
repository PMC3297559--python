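"""Analytic kernel for genetic-similarity dynamics.

Genomes are long sequences of two-state sites; the similarity of two
individuals is q = (1/S) sum_a s_i^a s_j^a in [-1, 1]. Mutations hit each
site as a Poisson process with rate ``mu`` per birth, and each hit flips the
site, so only the parity of the hit count matters. Everything here follows
from that parity marginal:

* a site differs from its parental copy with probability (1 - e^(-2 mu))/2;
* an offspring's expected similarity to any standing individual j is
  e^(-2 mu) q_parent,j (clonal) or e^(-2 mu)(q_mother,j + q_father,j)/2
  (sexual, free recombination);
* along a chain of inheritance similarity decays geometrically, which gives
  the critical chain length n* at which a descendant first drops below the
  species cut-off q_min.

Sexual reproduction adds the mate's divergence to every step: the per-step
decay factor becomes e^(-2 mu)(1 + q_bar)/2 for a typical mate similarity
q_bar, so n*_sex <= n*_asex, with equality only at q_bar = 1.
"""

from __future__ import annotations

import math

__all__ = [
    "flip_probability",
    "stay_probability",
    "asexual_offspring_similarity",
    "sexual_offspring_similarity",
    "similarity_after_n_steps",
    "n_star_asex",
    "n_star_sex",
    "equilibrium_similarity",
    "moran_effective_size",
    "speciation_condition",
    "mutation_induced_threshold",
]


def _check_mu(mu: float) -> None:
    if mu < 0:
        raise ValueError(f"mutation rate must be >= 0, got {mu}")


def _check_q(q: float, name: str = "q") -> None:
    if not -1.0 <= q <= 1.0:
        raise ValueError(f"{name} must lie in [-1, 1], got {q}")


def _check_q_min(q_min: float) -> None:
    if not 0.0 < q_min < 1.0:
        raise ValueError(f"q_min must lie in (0, 1), got {q_min}")


def flip_probability(mu: float) -> float:
    """Probability that a site ends up flipped after one birth.

    The number of mutations at a site is Poisson(mu) and each mutation
    toggles the site, so the site differs from the parental copy iff the
    count is odd: P(odd) = (1 - e^(-2 mu))/2. Increases from 0 at mu = 0 to
    the parity-randomised limit 1/2.
    """
    _check_mu(mu)
    return (1.0 - math.exp(-2.0 * mu)) / 2.0


def stay_probability(mu: float) -> float:
    """Complement of :func:`flip_probability`: P(even number of hits)."""
    _check_mu(mu)
    return (1.0 + math.exp(-2.0 * mu)) / 2.0


def asexual_offspring_similarity(q_parent_j: float, mu: float) -> float:
    """Expected similarity of a clonal offspring to a standing individual j.

    Each site is copied from the single parent and independently flipped
    with the parity probability, shrinking every site correlation by
    e^(-2 mu): E[q_offspring,j] = e^(-2 mu) q_parent,j. Offspring-self
    similarity is of course 1 and is not produced by this function.
    """
    _check_mu(mu)
    _check_q(q_parent_j, "q_parent_j")
    return math.exp(-2.0 * mu) * q_parent_j


def sexual_offspring_similarity(q_mother_j: float, q_father_j: float, mu: float) -> float:
    """Expected similarity of a sexual offspring to a standing individual j.

    With free recombination each site comes from either parent with equal
    probability, then mutates; hence
    E[q_offspring,j] = e^(-2 mu) (q_mother,j + q_father,j)/2.
    Setting j = mother gives e^(-2 mu)(1 + q_mother,father)/2: mates
    contribute divergence from the mother beyond mutation itself.
    """
    _check_mu(mu)
    _check_q(q_mother_j, "q_mother_j")
    _check_q(q_father_j, "q_father_j")
    return math.exp(-2.0 * mu) * 0.5 * (q_mother_j + q_father_j)


def similarity_after_n_steps(q0: float, mu: float, n: int) -> float:
    """Expected similarity between an ancestor and its n-th clonal descendant.

    Iterating the clonal recursion n times from q0 gives q0 e^(-2 mu n).
    """
    _check_mu(mu)
    _check_q(q0, "q0")
    if n < 0:
        raise ValueError(f"n must be >= 0, got {n}")
    return q0 * math.exp(-2.0 * mu * n)


def _smallest_crossing(log_qmin: float, log_factor: float) -> int:
    """Smallest integer n with factor^n < q_min, factor in (0, 1)."""
    ratio = log_qmin / log_factor  # both negative -> positive
    n = math.floor(ratio) + 1  # strict inequality: exact integers bump up
    # guard against floating error putting us one step off either way
    while n > 1 and (n - 1) * log_factor < log_qmin:
        n -= 1
    while n * log_factor >= log_qmin:
        n += 1
    return n


def n_star_asex(mu: float, q_min: float) -> int:
    """Critical chain length without sex.

    The smallest number of direct inheritance links n for which the expected
    ancestor-descendant similarity e^(-2 mu n) falls strictly below q_min,
    i.e. the ceiling of -ln(q_min)/(2 mu) with exact integers bumped up one.

    Raises
    ------
    ValueError
        If mu = 0 (similarity never decays: no finite critical step).
    """
    _check_q_min(q_min)
    _check_mu(mu)
    if mu == 0:
        raise ValueError("mu = 0: similarity never decays, no finite critical step")
    return _smallest_crossing(math.log(q_min), -2.0 * mu)


def n_star_sex(mu: float, q_min: float, q_bar: float) -> int:
    """Critical chain length with sex, for mean mate similarity q_bar.

    Each step multiplies the expected ancestor similarity by
    e^(-2 mu)(1 + q_bar)/2: mutation plus the mate's divergence. The
    per-step log-decay gains the extra term ln(2/(1 + q_bar)) over the
    clonal case, so n*_sex <= n*_asex, with equality at q_bar = 1.
    """
    _check_q_min(q_min)
    _check_mu(mu)
    if not 0.0 <= q_bar <= 1.0:
        raise ValueError(f"q_bar must lie in [0, 1], got {q_bar}")
    log_factor = -2.0 * mu + math.log((1.0 + q_bar) / 2.0)
    if mu == 0 and q_bar == 1.0:
        raise ValueError("no decay: mu = 0 and identical mates")
    return _smallest_crossing(math.log(q_min), log_factor)


def moran_effective_size(n_census: int) -> float:
    """Effective population size of the overlapping-generations community.

    One generation is N birth-death steps, during which a given pair of
    lineages coalesces with probability ~2/N (each member is replaced about
    once, and the new parent is any of N individuals), twice the
    non-overlapping-generations rate. Pairwise-coalescence clocks therefore
    run at effective size N/2.
    """
    if n_census < 2:
        raise ValueError(f"census size must be >= 2, got {n_census}")
    return n_census / 2.0


def equilibrium_similarity(n_effective: float, mu: float) -> float:
    """Mean pairwise similarity at mutation-drift balance, q_hat.

    For a panmictic community, similarity is lost at rate 4 mu per pair per
    generation (both members mutate) and regained by coalescence at rate
    1/N_e, giving q_hat = 1/(1 + 4 N_e mu), valid for small mu. Pass the
    *effective* size; for the overlapping-generations simulator use
    :func:`moran_effective_size` (half the census size).
    """
    if n_effective < 1:
        raise ValueError(f"n_effective must be >= 1, got {n_effective}")
    _check_mu(mu)
    return 1.0 / (1.0 + 4.0 * n_effective * mu)


def speciation_condition(n_effective: float, mu: float, q_min: float) -> bool:
    """Whether divergence can outrun cohesion: q_hat strictly below q_min.

    If the mutation-drift equilibrium similarity stays at or above the
    species cut-off the community remains a single connected cluster and
    speciation never starts; the boundary case counts as no speciation.
    """
    _check_q_min(q_min)
    return equilibrium_similarity(n_effective, mu) < q_min


def mutation_induced_threshold(q_min: float) -> float:
    """Mutation rate above which every clonal offspring founds a new cluster.

    Solving e^(-2 mu) < q_min for one step gives mu > -ln(q_min)/2: the
    offspring is born incompatible with its own parent (a "hopeful
    monster"), so n*_asex = 1 and species are mutation-induced rather than
    fission-induced.
    """
    _check_q_min(q_min)
    return -math.log(q_min) / 2.0
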