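"""Joint topology + attribute embedding and the cosine-weighted adjacency.

Each protein i gets a vector phi_i in R^d minimising

    L = sum_{i != j} a_ij ||phi_i - phi_j||^2
        + lambda * sum_{i != j} (s_ij - phi_i . phi_j)^2

where A is the binary adjacency of the PPI network and S the attribute
affinity matrix.  The first term pulls interacting proteins together; the
second pushes the Gram matrix of the embedding toward the attribute
affinities.  Both sums run over ordered pairs with the diagonal excluded
(a_ii = 0 after self-loop removal, and the diagonal attribute term would
make the per-row subproblem quartic instead of quadratic).

The loss is bi-convex: with every other row fixed, row i's subproblem is
an unconstrained convex quadratic.  Setting the gradient

    sum_j a_ij (phi_i - phi_j) + lambda * sum_{j != i} (phi_i . phi_j - s_ij) phi_j

to zero gives the d×d linear system

    [deg_i I + lambda * Phi_{-i}^T Phi_{-i}] phi_i
        = sum_j a_ij phi_j + lambda * sum_{j != i} s_ij phi_j,

solved exactly for one row at a time in a serial sweep over vertices, so
the loss trace is monotonically non-increasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .attributes import AttributeData
from .io_formats import PPINetwork

logger = logging.getLogger(__name__)


@dataclass
class EmbeddingConfig:
    """Hyperparameters of the joint embedding.

    dim
        Embedding dimension d (default 128).
    lam
        Trade-off lambda between topology and attribute terms (default 0.1).
    max_sweeps
        Upper bound on full coordinate-descent sweeps.
    tol
        Stop when the relative loss change between sweeps falls below this.
    seed
        Seed for the initial embedding draw; fixes the run bit-for-bit.
    """

    dim: int = 128
    lam: float = 0.1
    max_sweeps: int = 50
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.dim < 1:
            raise ValueError("dim must be >= 1")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")


@dataclass
class Embedding:
    proteins: tuple[str, ...]
    vectors: np.ndarray  # n×d
    loss_trace: tuple[float, ...]
    config: EmbeddingConfig

    @property
    def loss(self) -> float:
        return self.loss_trace[-1]

    def vector(self, protein: str) -> np.ndarray:
        return self.vectors[self.proteins.index(protein)]


class WeightedGraph:
    """Cosine edge weights on the PPI vertex set.

    w_ij = cos(phi_i, phi_j) where a_ij = 1, else 0; the cosine with a
    zero vector is defined as 0.  Weights may be negative (cosines are not
    clamped by default).
    """

    def __init__(self, proteins: tuple[str, ...], weights: dict[tuple[str, str], float]):
        self.proteins = proteins
        self._w = weights  # keys are sorted pairs

    def weight(self, u: str, v: str) -> float:
        if u == v:
            return 0.0
        key = (u, v) if u <= v else (v, u)
        return self._w.get(key, 0.0)

    def items(self):
        return self._w.items()

    def __len__(self) -> int:
        return len(self._w)


def _affinity_offdiag(attrs: AttributeData, n: int) -> np.ndarray:
    """Dense S with zeroed diagonal (the loss excludes i = j)."""
    S = attrs.affinity_dense().copy()
    np.fill_diagonal(S, 0.0)
    return S


def loss(
    vectors: np.ndarray,
    network: PPINetwork,
    attrs: AttributeData,
    lam: float,
) -> float:
    """Evaluate the joint loss at *vectors* (ordered pairs, diagonal excluded)."""
    Phi = np.asarray(vectors, dtype=float)
    if Phi.shape[0] != network.n:
        raise ValueError(
            f"embedding has {Phi.shape[0]} rows for a network of {network.n} proteins"
        )
    idx = network.index
    l1 = 0.0
    for u, v in network.edges:
        d = Phi[idx[u]] - Phi[idx[v]]
        l1 += 2.0 * float(d @ d)  # (i,j) and (j,i)
    S = _affinity_offdiag(attrs, network.n)
    G = Phi @ Phi.T
    np.fill_diagonal(G, 0.0)
    R = S - G
    l2 = float((R * R).sum())
    return l1 + lam * l2


def fit_embedding(
    network: PPINetwork,
    attrs: AttributeData,
    config: EmbeddingConfig | None = None,
) -> Embedding:
    """Minimise the joint loss by exact block-coordinate descent.

    Rows are visited in lexicographic protein order; each visit solves the
    row's d×d quadratic subproblem exactly, so the per-sweep loss trace is
    non-increasing.  Deterministic for a fixed seed.
    """
    if config is None:
        config = EmbeddingConfig()
    n, d, lam = network.n, config.dim, config.lam
    rng = np.random.default_rng(config.seed)
    Phi = rng.uniform(-0.5 / d, 0.5 / d, size=(n, d))
    if n == 0:
        return Embedding(network.proteins, Phi, (0.0,), config)

    S = _affinity_offdiag(attrs, n)
    nbr_idx = [
        np.fromiter(
            (network.index[q] for q in sorted(network.neighbors(p))), dtype=int
        )
        for p in network.proteins
    ]
    eye = np.eye(d)
    G = Phi.T @ Phi  # running Gram of all rows

    trace = [loss(Phi, network, attrs, lam)]
    for _sweep in range(config.max_sweeps):
        for i in range(n):
            phi_old = Phi[i].copy()
            nb = nbr_idx[i]
            deg = len(nb)
            M = deg * eye + lam * (G - np.outer(phi_old, phi_old))
            rhs = (Phi[nb].sum(axis=0) if deg else np.zeros(d)) + lam * (S[i] @ Phi)
            try:
                phi_new = np.linalg.solve(M, rhs)
            except np.linalg.LinAlgError:
                jitter = 1e-10 * (np.trace(M) / d + 1.0)
                logger.warning(
                    "singular row subproblem at vertex %d; ridge-jittered lstsq", i
                )
                phi_new = np.linalg.lstsq(M + jitter * eye, rhs, rcond=None)[0]
            Phi[i] = phi_new
            G += np.outer(phi_new, phi_new) - np.outer(phi_old, phi_old)
        cur = loss(Phi, network, attrs, lam)
        prev = trace[-1]
        trace.append(cur)
        if abs(prev - cur) < config.tol * max(abs(prev), 1e-30):
            break
    return Embedding(network.proteins, Phi, tuple(trace), config)


def cosine(u: np.ndarray, v: np.ndarray) -> float:
    """Cosine similarity; 0 when either vector is zero."""
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        return 0.0
    return float(u @ v) / (nu * nv)


def build_weighted_adjacency(
    embedding: Embedding,
    network: PPINetwork,
    clamp_negative: bool = False,
) -> WeightedGraph:
    """Weight every PPI edge by the cosine of its endpoint embeddings.

    Non-edges have weight 0.  With *clamp_negative* negative cosines are
    floored at 0 (off by default; downstream scores tolerate negatives).
    """
    if embedding.proteins != network.proteins:
        raise ValueError("embedding and network protein orders differ")
    idx = network.index
    Phi = embedding.vectors
    weights: dict[tuple[str, str], float] = {}
    for u, v in network.edges:
        w = cosine(Phi[idx[u]], Phi[idx[v]])
        if clamp_negative and w < 0:
            w = 0.0
        weights[(u, v) if u <= v else (v, u)] = w
    return WeightedGraph(network.proteins, weights)
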