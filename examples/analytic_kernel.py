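"""How many generations of descent until a lineage leaves its species?

Computes the critical chain lengths n* for clonal and sexual reproduction,
the mutation-drift equilibrium similarity, and the regime boundaries, for a
typical parameter set.
"""

from speciesim import (
    equilibrium_similarity,
    moran_effective_size,
    mutation_induced_threshold,
    n_star_asex,
    n_star_sex,
    speciation_condition,
)

mu = 1e-3          # mutations per nucleotide per birth
q_min = 0.97       # similarity below which a pair is incompatible
q_bar = 0.98       # typical similarity of mated pairs
census = 200       # community size (one individual per site)

print(f"mu = {mu}, q_min = {q_min}, community census = {census}")
print(f"clonal critical chain length  n*_asex = {n_star_asex(mu, q_min)}")
print(f"sexual critical chain length  n*_sex  = {n_star_sex(mu, q_min, q_bar)}"
      f"  (mates at q_bar = {q_bar} add divergence each step)")

n_eff = moran_effective_size(census)
q_hat = equilibrium_similarity(n_eff, mu)
print(f"effective size N_e = {n_eff:.0f}, equilibrium similarity "
      f"q_hat = {q_hat:.4f}")
print(f"speciation condition q_hat < q_min: "
      f"{speciation_condition(n_eff, mu, q_min)}")
print(f"hopeful-monster threshold (every clonal birth a new species): "
      f"mu > {mutation_induced_threshold(q_min):.5f}")

# Interpretation: with sex a descendant needs only n*_sex steps to diverge
# past the cut-off from its ancestor, versus n*_asex without sex, so chains
# of dead intermediates (fission events) split sexual clusters far sooner.
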