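"""Species delimitation on the compatibility graph.

A species is a connected component of the undirected graph whose vertices
are the N individuals and whose edges join pairs with similarity
q_ij >= q_min. Path-connectivity suffices: two members of a species may
themselves be incompatible as long as a chain of compatible intermediates
links them (a ring species).

:class:`LineageTracker` carries species identities through time. When the
partition changes, each component inherits the previous label it shares the
most members with (majority rule, deterministic tie-break); fragments left
without a label are new species (speciation events, with their incipient
abundance recorded), and labels that no component inherits are extinctions.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "species_partition",
    "richness",
    "abundances",
    "SpeciationEvent",
    "ExtinctionEvent",
    "LineageTracker",
]


def species_partition(q: np.ndarray, q_min: float) -> np.ndarray:
    """Label each individual with its connected component under the cut-off.

    Parameters
    ----------
    q : (N, N) array
        Symmetric similarity matrix with unit diagonal.
    q_min : float
        Minimum similarity for a pair to be compatible; pairs strictly
        below q_min carry no edge.

    Returns
    -------
    (N,) int array of component ids (0..k-1, arbitrary but deterministic).
    """
    adj = csr_matrix(q >= q_min)
    _, labels = connected_components(adj, directed=False)
    return labels


def richness(labeling: np.ndarray) -> int:
    """Number of distinct species labels."""
    return int(np.unique(np.asarray(labeling)).size)


def abundances(labeling: np.ndarray) -> np.ndarray:
    """Sorted (descending) abundance of each species; sums to N."""
    _, counts = np.unique(np.asarray(labeling), return_counts=True)
    return np.sort(counts)[::-1]


@dataclass(frozen=True)
class SpeciationEvent:
    generation: int
    parent_label: int
    new_label: int
    incipient_abundance: int


@dataclass(frozen=True)
class ExtinctionEvent:
    generation: int
    label: int
    lifespan_generations: int


class LineageTracker:
    """Persistent species labels with speciation/extinction event logging.

    Label inheritance is by majority overlap: every (component, previous
    label) pair is ranked by shared member count, ties broken by the lowest
    site index among the component's members, and labels are assigned
    greedily so that when a species splits, the larger fragment keeps the
    name and the smaller fragment is the new species. With
    ``new_rule="all_but_largest"`` every fragment except the largest is
    marked new instead. Components inheriting no label raise a
    :class:`SpeciationEvent`; labels inherited by no component raise an
    :class:`ExtinctionEvent`. A label that disappears while its members
    survive was absorbed by another species; such merges are logged as
    warnings because deep divergence makes them near-impossible in the
    model's intended regime.
    """

    def __init__(self, initial_partition: np.ndarray, generation: int = 0,
                 new_rule: str = "majority"):
        if new_rule not in ("majority", "all_but_largest"):
            raise ValueError(f"unknown new_rule {new_rule!r}")
        self.new_rule = new_rule
        comp = np.asarray(initial_partition)
        self.labels = comp.astype(np.int64).copy()
        self.next_label = int(self.labels.max()) + 1
        self.birth_generation: dict[int, int] = {
            int(lab): generation for lab in np.unique(self.labels)
        }
        self.speciations: list[SpeciationEvent] = []
        self.extinctions: list[ExtinctionEvent] = []
        self.merge_count = 0

    # -- internals ---------------------------------------------------------

    def _rank_overlaps(self, partition: np.ndarray):
        """(count, -min_member, component, prev_label) sorted best-first."""
        ranked = []
        for comp_id in np.unique(partition):
            members = np.flatnonzero(partition == comp_id)
            counts = Counter(self.labels[members].tolist())
            low = -int(members.min())
            for lab, k in counts.items():
                ranked.append((k, low, int(comp_id), int(lab)))
        ranked.sort(key=lambda t: (-t[0], -t[1], t[2], t[3]))
        return ranked

    # -- API ---------------------------------------------------------------

    def update(self, partition: np.ndarray, generation: int):
        """Advance labels to a new partition; returns (speciations, extinctions)
        recorded at this generation."""
        partition = np.asarray(partition)
        ranked = self._rank_overlaps(partition)

        majority: dict[int, int] = {}
        inherited: dict[int, int] = {}
        used: set[int] = set()
        for k, _low, comp_id, lab in ranked:
            majority.setdefault(comp_id, lab)
            if comp_id in inherited or lab in used:
                continue
            inherited[comp_id] = lab
            used.add(lab)

        if self.new_rule == "all_but_largest":
            # only the largest fragment of each parent keeps the name
            sizes = {c: int((partition == c).sum()) for c in majority}
            keep: dict[int, int] = {}
            for comp_id, lab in inherited.items():
                cur = keep.get(lab)
                if cur is None or sizes[comp_id] > sizes[cur] or (
                    sizes[comp_id] == sizes[cur] and comp_id < cur
                ):
                    keep[lab] = comp_id
            inherited = {c: lab for lab, c in keep.items()}
            used = set(inherited.values())

        new_events: list[SpeciationEvent] = []
        new_labels = np.empty_like(self.labels)
        for comp_id in np.unique(partition):
            comp_id = int(comp_id)
            mask = partition == comp_id
            if comp_id in inherited:
                lab = inherited[comp_id]
            else:
                lab = self.next_label
                self.next_label += 1
                self.birth_generation[lab] = generation
                new_events.append(
                    SpeciationEvent(
                        generation=generation,
                        parent_label=majority[comp_id],
                        new_label=lab,
                        incipient_abundance=int(mask.sum()),
                    )
                )
            new_labels[mask] = lab

        survivors = set(int(x) for x in np.unique(new_labels))
        lost = sorted(set(int(x) for x in np.unique(self.labels)) - survivors)
        # a lost label whose members (2 or more) sit together inside some
        # surviving component was absorbed rather than dying out
        max_overlap: dict[int, int] = {}
        for k, _low, _comp, lab in ranked:
            if k > max_overlap.get(lab, 0):
                max_overlap[lab] = k
        extinct_events = []
        merged = 0
        for lab in lost:
            if max_overlap.get(lab, 0) >= 2:
                merged += 1
            extinct_events.append(
                ExtinctionEvent(
                    generation=generation,
                    label=lab,
                    lifespan_generations=generation - self.birth_generation[lab],
                )
            )
        if merged:
            if self.merge_count == 0:
                warnings.warn(
                    f"species absorbed by merger at generation {generation}; "
                    "mergers are expected to be vanishingly rare once clusters are "
                    "deeply diverged (subsequent mergers are counted silently in "
                    "merge_count)",
                    stacklevel=2,
                )
            self.merge_count += merged

        self.speciations.extend(new_events)
        self.extinctions.extend(extinct_events)
        self.labels = new_labels
        return new_events, extinct_events
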