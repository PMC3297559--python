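# Methods

## Model definition

The metacommunity is a zero-sum Moran-type process: *N* haploid
individuals, one per site, with overlapping generations. One birth–death
step = choose a mother uniformly; (sexual mode) choose a mate uniformly
among compatible neighbours within distance *d_c*, falling back to clonal
reproduction when none exists (this keeps *d_c* = 0 well defined); choose a
victim uniformly among sites within *d_c* of the mother — the mother
herself included, the mate excluded; the offspring takes the victim's site
and thereby the victim site's row of the fixed distance matrix **D**. A
generation is *N* steps. Species labels, richness and the event log are
updated once per generation (event timestamps are in generations; per-step
partitioning would multiply cost ~*N*-fold without changing any reported
statistic).

**Distances.** Entries of **D** are direct pairwise draws from
Normal(mean 0.5, sd 0.35), redrawn until nonnegative (rejection, not
clipping, so the shape of the positive part is preserved); **D** is
symmetric with zero diagonal and no triangle inequality is imposed. There
is no planar embedding: "space" is only the mating/dispersal graph induced
by *d_c*.

**Genetics.** Each site of a two-state genome mutates as a Poisson(μ)
process per birth; a site differs from the parental copy with the parity
probability (1−e^(−2μ))/2. Consequently the expected similarity of a
newborn to each survivor is e^(−2μ)·q(mother, j) (clonal) or
e^(−2μ)·(q(mother, j)+q(father, j))/2 (free recombination). The default
backend evolves the similarity matrix **Q** on these expectations directly
— the infinite-genome limit, in which similarity decays are deterministic
given the pedigree. An explicit-genome backend (finite S, default 10^5,
sampling noise O(1/√S)) implements the same process literally and is used
as the brute-force oracle; the per-site parity-marginal Bernoulli flip is
distributionally exact for the two-state alphabet, so no per-site Poisson
counts are ever sampled.

**Species.** A species is a connected component of the compatibility graph
(edges: q_ij ≥ q_min; strict `q < q_min` means incompatible, so a pair
exactly at the cut-off is compatible). Components are found with sparse
graph routines; a brute-force transitive-closure oracle backs this in the
tests. Lineage identity is carried across generations by majority overlap:
each component inherits the previous label it shares most members with
(ties broken by the lowest site index), fragments left without a label are
speciation events carrying their incipient abundance, labels inherited by
no component are extinctions, and a label whose surviving members were
absorbed by another component is a merger — counted and warned about, since
mergers should be vanishingly rare once clusters are deeply diverged. An
alternative rule ("all fragments but the largest are new") is available.

## Two cut-offs, and what gates mating

The model uses two species cut-offs with distinct roles:

* **q_min_transient = 0.97** — a fine divergence criterion used while the
  founded community relaxes toward mutation–drift balance; it resolves
  incipient clusters long before they are deeply isolated.
* **q_min_eq = 0.90** — the deep criterion used at the
  speciation–extinction steady state, and the *biological incompatibility
  threshold*: by default a pair can mate only if q ≥ q_min_eq
  (`mate_gate="equilibrium"`; `"phase"` and `"none"` are available).

Gating mates at the deep threshold rather than the fine one is a
deliberate design choice: reproductive incompatibility is a property of
the organisms, not of the bookkeeping cut-off used to count clusters. It
is also what makes the sexual mode's characteristic behaviour possible at
all. An offspring of two mates with similarity q_mf sits at
e^(−2μ)(1+q_mf)/2 from each parent; if mating required q ≥ 0.97, every
newborn would sit at ≥ 0.985·e^(−2μ) > 0.97 from its mother and could
never found a new fine-cut-off cluster at birth. With the gate at 0.90, a
mating between equilibrium-compatible but transient-divergent partners
(q_mf < 2·0.97·e^(2μ) − 1 ≈ 0.94) produces an offspring that is below the
fine cut-off with *everyone* simultaneously — a singleton incipient
species. This is the engine of the sexual mode's fast radiation and of the
smallness of its new species.

The admissible window for q_min_eq follows from the kernel itself: it must
exceed the equilibrium similarity q̂(μ) (otherwise the speciation condition
fails and the steady state is a single species) and lie below ≈0.94
(otherwise the outcrossing mechanism above is impossible). 0.90 is the
round value in that window at the study conditions below.

## Effective population size

The simulator has overlapping generations: per generation each lineage is
replaced about once, but a given *pair* experiences ~2 replacement events,
so pairwise coalescence runs at rate 2/N per generation — twice the
non-overlapping rate. The mutation–drift equilibrium of the panmictic
asexual community is therefore

    q̂ = 1/(1 + 4 N_e μ),  N_e = N/2,

equivalently 1/(1 + 2Nμ) in census size (small-μ approximation). This was
verified by direct simulation: census N = 200 at μ = 2.5·10⁻⁴ time-averages
to q̄ ≈ 0.904 against the prediction 1/1.1 ≈ 0.909, while census 100 gives
≈ 0.954 = 1/(1+2·100·μ). `equilibrium_similarity` therefore takes the
*effective* size, with `moran_effective_size` for the conversion.

## Study conditions

The paired mode comparisons (`speciesim.experiments`) fix, once:

| quantity | value | why |
|---|---|---|
| census N | 200 | large enough for multi-species steady states, small enough for 1-CPU replication |
| μ | 5·10⁻⁴ | satisfies the speciation condition at both cut-offs: q̂ = 0.833 < 0.90 < 0.97 |
| d_c | 1.0 | near-panmictic mating/dispersal on the Normal(0.5, 0.35) distance scale |
| replicates | 20 per mode, paired by shared seed (common distance matrix) |
| radiation window | 500 generations after founding, events at the fine cut-off |
| steady state | 1500 generations (≈16 relaxation times 1/(4μ+2/N)), richness at the deep cut-off, medians over the trailing 400 |

The transient stop rule (stop when q̄ first reaches a target, default 0.97)
is implemented and tested, but the radiation comparison uses a fixed
window: with N = 200 the relaxation rate of q̄ is floored by the
coalescence term 2/N = 0.01 per generation, so q̄ crosses 0.97 within
~10–150 generations — before fission has produced events in either mode —
and an event count taken at that instant is uninformatively zero for both.
The fixed window measures the same contrast (cumulative events while the
community radiates from the founder) at a resolvable scale.

The equilibrium-recovery study uses effective size 100 (census 200),
μ = 2.5·10⁻⁴, 2 replicates × 2500 generations with a 500-generation
burn-in. Oracle studies use S = 10⁵ (clonal chains: 50 steps × 200
replicates; recombination: 500 one-step replicates), flagging any step
beyond 3 standard errors.

## What the generator emulates — and what it does not

The simulator generates all of its own inputs; there is no empirical data.
It emulates neutral, well-mixed-within-radius communities with: equal
birth/death chances for every individual (no selection, no ecological
differentiation), a single fixed mutation rate across sites and lineages,
free recombination (no linkage), haploidy, strict asexuality (no horizontal
transfer), and a static geography. Passing tests therefore demonstrate the
internal logic of neutral speciation–extinction dynamics — not that real
sexual or asexual taxa behave this way; in real systems selection,
ecological opportunity, linkage and mate choice all act on the quantities
held fixed here. Two further idealisations matter when interpreting output:
expectation dynamics remove genome-sampling noise (similarities are exact
conditional expectations, so near-threshold cluster boundaries flicker more
smoothly than finite genomes would), and label tracking at generation
granularity can count a split–remerge–split sequence as two events.

## Numerical choices

* Critical steps are integers: n* is the smallest n with decay^n strictly
  below q_min; an exactly-attained cut-off does not cross (so at
  μ = −ln(q_min)/2 the clonal n* is 2, and strictly above it, 1). The
  implementation floors the log-ratio then corrects for floating error by
  direct inequality checks.
* Q stays exactly symmetric with unit diagonal by construction (row and
  column written together, diagonal reset); invariants are asserted in
  tests, not at runtime.
* Steady-state detection: q̄ range < tol (default 0.03) over a trailing
  window (default 100 generations); replicates that never satisfy their
  stop rule are returned flagged (`converged=False`) with partial series.
* Determinism: one `numpy` Generator per replicate, seeded as
  base_seed + replicate index; identical seed + parameters reproduce every
  output byte for byte. Derived sub-study seeds stay below 2³¹.
* Mate and victim draws use index-uniform choice over precomputed
  neighbour lists (D and d_c are fixed, so neighbourhoods are cached once
  per replicate).

## Known limitations

* The expectation backend's similarity values are conditional expectations,
  not realisations; variance-sensitive statistics near the cut-off (e.g.
  flicker rates) differ from finite-genome runs, which is why the genome
  backend exists for cross-checks at small N.
* q̂ = 1/(1+4N_eμ) is a small-μ approximation; at μ ≳ 10⁻² the neglected
  O(μ²) terms become visible.
* The label-inheritance rule is a convention; any rule that names fragments
  changes which fragment is "new" in rare balanced splits (the
  `all_but_largest` option quantifies this sensitivity).
* At very high μ (approaching the hopeful-monster threshold) the sexual
  community at the fine cut-off dissolves into transient singletons and
  "richness" ceases to describe persistent units; the deep cut-off is the
  meaningful one there.
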