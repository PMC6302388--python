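"""Shared fixtures and independent brute-force oracles.

The oracle functions here deliberately use the most literal possible
formulation (nested loops, all-subsets enumeration) so they stay
independent of the library code paths they cross-check.
"""

from itertools import combinations

import pytest

from gane import PPINetwork, WeightedGraph


# ---------------------------------------------------------------------------
# oracles
# ---------------------------------------------------------------------------

def brute_force_maximal_cliques(proteins, edges, min_size):
    """All-subsets maximality check (exponential; tiny graphs only)."""
    edges = {frozenset(e) for e in edges}

    def is_clique(sub):
        return all(frozenset((u, v)) in edges for u, v in combinations(sub, 2))

    nodes = list(proteins)
    cliques = []
    for r in range(min_size, len(nodes) + 1):
        for sub in combinations(nodes, r):
            if not is_clique(sub):
                continue
            maximal = True
            for extra in nodes:
                if extra in sub:
                    continue
                if is_clique(sub + (extra,)):
                    maximal = False
                    break
            if maximal:
                cliques.append(tuple(sorted(sub)))
    return sorted(cliques)


def brute_force_loss(Phi, a, S, lam):
    """Literal double loop over ordered pairs i != j."""
    n = Phi.shape[0]
    total = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = Phi[i] - Phi[j]
            total += a[i, j] * float(d @ d)
            total += lam * (S[i, j] - float(Phi[i] @ Phi[j])) ** 2
    return total


def brute_force_metrics(P, B, omega):
    """Nested-loop NA matching and clustering-wise metrics.

    P and B are lists of frozensets.  Returns a dict with n_cp, n_cb,
    precision, recall, f, sn, ppv, acc.
    """
    def na(p, b):
        inter = len(p & b)
        return inter * inter / (len(p) * len(b))

    n_cp = 0
    for p in P:
        for b in B:
            if na(p, b) >= omega:
                n_cp += 1
                break
    n_cb = 0
    for b in B:
        for p in P:
            if na(p, b) >= omega:
                n_cb += 1
                break
    precision = n_cp / len(P) if P else 0.0
    recall = n_cb / len(B)
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0

    sn_num = sn_den = 0
    for b in B:
        best = 0
        for p in P:
            best = max(best, len(b & p))
        sn_num += best
        sn_den += len(b)
    ppv_num = ppv_den = 0
    for p in P:
        best = 0
        for b in B:
            overlap = len(b & p)
            best = max(best, overlap)
            ppv_den += overlap
        ppv_num += best
    sn = sn_num / sn_den
    ppv = ppv_num / ppv_den if ppv_den else 0.0
    acc = (sn * ppv) ** 0.5
    return dict(n_cp=n_cp, n_cb=n_cb, precision=precision, recall=recall,
                f=f, sn=sn, ppv=ppv, acc=acc)


def random_complex_sets(rng, max_complexes=20, max_proteins=200):
    """One random (P, B) instance over a shared protein universe."""
    universe = [f"Y{i:03d}" for i in range(int(rng.integers(10, max_proteins + 1)))]

    def draw():
        sets = []
        for _ in range(int(rng.integers(1, max_complexes + 1))):
            size = int(rng.integers(1, min(12, len(universe)) + 1))
            sets.append(frozenset(rng.choice(universe, size, replace=False)))
        return sets

    return draw(), draw()


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def uniform_weights(network: PPINetwork, w: float = 1.0) -> WeightedGraph:
    return WeightedGraph(
        network.proteins, {tuple(sorted(e)): w for e in network.edges}
    )


@pytest.fixture
def triangle_with_pendant() -> PPINetwork:
    return PPINetwork([("a", "b"), ("a", "c"), ("b", "c"), ("c", "d")])


@pytest.fixture
def two_shared_triangles() -> PPINetwork:
    """Triangles a-b-c and b-c-d sharing the edge b-c."""
    return PPINetwork([("a", "b"), ("a", "c"), ("b", "c"), ("b", "d"), ("c", "d")])


def random_gnp(rng, n, p):
    nodes = [f"n{i:02d}" for i in range(n)]
    edges = [
        (nodes[i], nodes[j])
        for i in range(n)
        for j in range(i + 1, n)
        if rng.random() < p
    ]
    return PPINetwork(edges, proteins=nodes)
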