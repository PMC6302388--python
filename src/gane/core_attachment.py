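"""Complex detection: clique cores ranked by density, plus attachments.

Following the core-attachment picture of complex organisation, detection
runs in two phases on the cosine-weighted PPI graph:

1. *Cores.*  All maximal cliques with >= 3 members are enumerated
   (Tomita-pivot Bron--Kerbosch) as candidate cores.  Candidates are
   repeatedly re-sorted by density score (sum of internal edge weights);
   the top clique becomes a seed core, its members are subtracted from
   every overlapping candidate, and candidates that shrink below the
   minimum size are dropped.  Seed cores are therefore pairwise disjoint
   and remain cliques (subsets of cliques are cliques).

2. *Attachments.*  For each seed core, every graph-neighbor p of the core
   with mean weight to the core members strictly above the threshold
   theta is attached.  A protein may attach to several cores, so reported
   complexes can overlap; exact-duplicate complexes are collapsed.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import networkx as nx

from .embedding import WeightedGraph
from .io_formats import Complex, ComplexSet, PPINetwork


@dataclass
class DetectionConfig:
    """Detection knobs: attachment threshold theta (default 0.3) and the
    minimum clique/core size (default 3)."""

    theta: float = 0.3
    min_clique_size: int = 3

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError("theta must be in [0, 1]")
        if self.min_clique_size < 1:
            raise ValueError("min_clique_size must be >= 1")


def enumerate_maximal_cliques(
    network: PPINetwork, min_size: int = 3
) -> list[tuple[str, ...]]:
    """All maximal cliques with at least *min_size* members.

    Output is normalised: each clique as a lexicographically sorted tuple,
    cliques sorted lexicographically.
    """
    cliques = [
        tuple(sorted(c))
        for c in nx.find_cliques(network.to_networkx())
        if len(c) >= min_size
    ]
    return sorted(cliques)


def density_score(members, weights: WeightedGraph) -> float:
    """Sum of edge weights over the unordered distinct member pairs."""
    return sum(weights.weight(u, v) for u, v in combinations(sorted(members), 2))


def _sort_key(members: frozenset[str], score: float):
    # descending score, then larger cliques, then smallest member list
    return (-score, -len(members), tuple(sorted(members)))


def select_seed_cores(
    cliques, weights: WeightedGraph, min_size: int = 3
) -> list[frozenset[str]]:
    """Greedy subtract-and-prune selection of disjoint seed cores.

    Each round re-sorts the surviving candidates by (recomputed) density
    score, promotes the top one, subtracts its members from every
    overlapping candidate and drops candidates now below *min_size*.
    Duplicate candidate sets created by subtraction collapse to one.
    """
    candidates: set[frozenset[str]] = {frozenset(c) for c in cliques}
    candidates = {c for c in candidates if len(c) >= min_size}
    seeds: list[frozenset[str]] = []
    while candidates:
        winner = min(candidates, key=lambda c: _sort_key(c, density_score(c, weights)))
        seeds.append(winner)
        updated: set[frozenset[str]] = set()
        for c in candidates:
            if c == winner:
                continue
            rest = c - winner
            if len(rest) >= min_size:
                updated.add(rest)
        candidates = updated
    return seeds


def correlation_score(protein: str, clique, weights: WeightedGraph) -> float:
    """Mean edge weight from *protein* to the clique members."""
    members = frozenset(clique)
    if protein in members:
        raise ValueError(f"{protein!r} is a member of the clique")
    return sum(weights.weight(protein, k) for k in members) / len(members)


def attach_and_assemble(
    seed_cores,
    network: PPINetwork,
    weights: WeightedGraph,
    theta: float = 0.3,
) -> ComplexSet:
    """Attach high-correlation neighbors to each seed core.

    Candidates are proteins outside the core adjacent (in the unweighted
    graph) to at least one core member; those with correlation score
    strictly above *theta* attach.  Complexes with identical member sets
    deduplicate keeping the first.
    """
    out: list[Complex] = []
    seen: set[frozenset[str]] = set()
    for core in seed_cores:
        core = frozenset(core)
        neighborhood = sorted(
            set().union(*(network.neighbors(p) for p in core)) - core
        )
        attachments = frozenset(
            p for p in neighborhood if correlation_score(p, core, weights) > theta
        )
        members = core | attachments
        if members in seen:
            continue
        seen.add(members)
        out.append(
            Complex(
                members=members,
                core=core,
                attachments=attachments,
                density=density_score(core, weights),
            )
        )
    return ComplexSet(out)


def detect_cores_and_attachments(
    network: PPINetwork,
    weights: WeightedGraph,
    config: DetectionConfig | None = None,
) -> ComplexSet:
    """Full detection pass: cliques -> seed cores -> attached complexes."""
    if config is None:
        config = DetectionConfig()
    cliques = enumerate_maximal_cliques(network, config.min_clique_size)
    seeds = select_seed_cores(cliques, weights, config.min_clique_size)
    return attach_and_assemble(seeds, network, weights, config.theta)
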