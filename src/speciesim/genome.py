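"""Explicit finite-genome engine (two-state sites).

Serves as the brute-force oracle behind every expectation in
:mod:`speciesim.similarity` and as an alternative simulation backend at
small community sizes. Genomes are int8 arrays over {-1, +1}; founders are
all +1 so every founder pair has similarity exactly 1.

Mutation is applied as the exact parity marginal of the per-site Poisson
process: a site is flipped with probability (1 - e^(-2 mu))/2, which is
distributionally identical to sampling a Poisson count per site and taking
its parity, because the observable is only the final state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .similarity import flip_probability, similarity_after_n_steps

__all__ = [
    "founder_genome",
    "founder_population",
    "mutate",
    "recombine",
    "genome_similarity",
    "SimilarityEstimate",
    "DecayReport",
    "validate_decay",
    "write_fasta",
]


@dataclass(frozen=True)
class SimilarityEstimate:
    """Empirical similarity of two genomes.

    ``q`` is the mean site product in [-1, 1]; ``x_frac`` the fraction of
    identical sites; the two satisfy q = 2 x - 1 exactly.
    """

    q: float
    x_frac: float


def founder_genome(length: int) -> np.ndarray:
    """All-(+1) genome of the given length (the common ancestor state)."""
    if length < 1:
        raise ValueError(f"genome length must be >= 1, got {length}")
    return np.ones(length, dtype=np.int8)


def founder_population(n: int, length: int) -> np.ndarray:
    """(n, length) array of identical founder genomes."""
    if n < 1:
        raise ValueError(f"population size must be >= 1, got {n}")
    return np.ones((n, length), dtype=np.int8)


def mutate(genome: np.ndarray, mu: float, rng: np.random.Generator) -> np.ndarray:
    """Return a mutated copy: each site independently flipped with the
    Poisson parity probability (1 - e^(-2 mu))/2.

    Works on a single genome or a 2-D population array (sites on the last
    axis); the input is not modified.
    """
    p = flip_probability(mu)
    out = genome.copy()
    if p > 0:
        mask = rng.random(genome.shape) < p
        out[mask] = -out[mask]
    return out


def recombine(mother: np.ndarray, father: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Free recombination: each site copied from either parent with
    probability 1/2, independently (no linkage)."""
    if mother.shape != father.shape:
        raise ValueError(
            f"parent genomes differ in shape: {mother.shape} vs {father.shape}"
        )
    take_mother = rng.random(mother.shape) < 0.5
    return np.where(take_mother, mother, father).astype(np.int8)


def genome_similarity(g1: np.ndarray, g2: np.ndarray) -> SimilarityEstimate:
    """Similarity q = (1/S) sum_a s1^a s2^a, with the identical-site fraction."""
    if g1.shape != g2.shape:
        raise ValueError(f"genomes differ in shape: {g1.shape} vs {g2.shape}")
    q = float(np.multiply(g1, g2, dtype=np.float64).mean())
    return SimilarityEstimate(q=q, x_frac=(1.0 + q) / 2.0)


@dataclass(frozen=True)
class DecayReport:
    """Per-step comparison of empirical clonal-chain similarity to theory."""

    steps: np.ndarray        # 1..n_steps
    empirical_mean: np.ndarray
    empirical_se: np.ndarray
    analytic: np.ndarray     # e^(-2 mu n)
    z_scores: np.ndarray
    flagged: np.ndarray      # |z| > 3

    @property
    def any_flagged(self) -> bool:
        return bool(self.flagged.any())


def validate_decay(
    genome_length: int,
    mu: float,
    n_steps: int,
    replicates: int,
    rng: np.random.Generator,
) -> DecayReport:
    """Run ``replicates`` independent clonal chains and compare the mean
    descendant-founder similarity at every step against e^(-2 mu n).

    Each replicate starts from the founder genome and mutates it once per
    step; the similarity to the founder is the mean site value, tracked for
    all replicates at once. Steps where |z| > 3 are flagged.
    """
    if min(genome_length, n_steps, replicates) < 1:
        raise ValueError("genome_length, n_steps and replicates must all be >= 1")
    pop = founder_population(replicates, genome_length)
    means = np.empty(n_steps)
    ses = np.empty(n_steps)
    for step in range(n_steps):
        pop = mutate(pop, mu, rng)
        qs = pop.mean(axis=1, dtype=np.float64)  # founder is all +1
        means[step] = qs.mean()
        ses[step] = qs.std(ddof=1) / np.sqrt(replicates) if replicates > 1 else np.nan
    steps = np.arange(1, n_steps + 1)
    analytic = np.array([similarity_after_n_steps(1.0, mu, int(n)) for n in steps])
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(ses > 0, (means - analytic) / ses, 0.0)
    return DecayReport(
        steps=steps,
        empirical_mean=means,
        empirical_se=ses,
        analytic=analytic,
        z_scores=z,
        flagged=np.abs(z) > 3,
    )


def write_fasta(genomes: np.ndarray, path, prefix: str = "ind") -> None:
    """Debug export of genomes as two-letter (A = -1, T = +1) FASTA records."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    arr = np.atleast_2d(genomes)
    lut = np.array(["A", "T"])
    records = [
        SeqRecord(
            Seq("".join(lut[(row > 0).astype(int)])),
            id=f"{prefix}{i}",
            description="",
        )
        for i, row in enumerate(arr)
    ]
    seqio_write(records, str(path), "fasta")
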