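"""Binary GO-slim attribute matrix O and protein affinity matrix S.

Each protein is described by the set of GO-slim terms annotated to it
(biological-process and molecular-function aspects by default).  The
affinity between two proteins is the cosine similarity of their binary
term-indicator vectors:

    s_ij = sum_k o_ik o_jk / (sqrt(sum_k o_ik^2) * sqrt(sum_k o_jk^2))

A protein with no annotation has an all-zero row; its affinity to every
protein (itself included) is defined as 0, the no-evidence value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .io_formats import AnnotationTable, PPINetwork

#: above this protein count the affinity matrix is kept sparse
DENSE_AFFINITY_LIMIT = 2000


@dataclass
class AttributeData:
    """Attribute matrix O (n×m, binary) and affinity matrix S (n×n).

    Rows follow the network's lexicographic protein order; columns follow
    lexicographic term order.  ``affinity`` is ``None`` until
    :func:`build_affinity` fills it, and may be dense or CSR sparse.
    """

    proteins: tuple[str, ...]
    terms: tuple[str, ...]
    matrix: np.ndarray  # n×m, dtype float64 with {0,1} entries
    affinity: np.ndarray | sp.csr_matrix | None = None

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    def affinity_dense(self) -> np.ndarray:
        if self.affinity is None:
            raise ValueError("affinity not built; call build_affinity first")
        if sp.issparse(self.affinity):
            return np.asarray(self.affinity.todense())
        return self.affinity


def build_attribute_matrix(network: PPINetwork, table: AnnotationTable) -> AttributeData:
    """Construct O with o_ij = 1 iff protein i carries term j.

    The network defines the protein universe: annotations for proteins not
    in the network are ignored, and network proteins without annotations
    get all-zero rows.
    """
    terms = table.terms()
    term_idx = {t: j for j, t in enumerate(terms)}
    O = np.zeros((network.n, len(terms)), dtype=float)
    by_protein = table.terms_by_protein()
    for p, ts in by_protein.items():
        i = network.index.get(p)
        if i is None:
            continue
        for t in ts:
            O[i, term_idx[t]] = 1.0
    return AttributeData(proteins=network.proteins, terms=terms, matrix=O)


def build_affinity(
    data: AttributeData, dense_limit: int = DENSE_AFFINITY_LIMIT
) -> AttributeData:
    """Fill ``data.affinity`` with the binary-cosine matrix S.

    S is symmetric with entries in [0, 1]; the diagonal is 1 for annotated
    proteins and 0 for unannotated ones.  Dense below *dense_limit*
    proteins, CSR sparse above.
    """
    O = data.matrix
    n = O.shape[0]
    norms = np.sqrt((O * O).sum(axis=1))
    inv = np.zeros_like(norms)
    nz = norms > 0
    inv[nz] = 1.0 / norms[nz]
    if n <= dense_limit:
        U = O * inv[:, None]
        S = U @ U.T
        np.clip(S, 0.0, 1.0, out=S)
        S[np.diag_indices(n)] = nz.astype(float)
    else:
        U = sp.csr_matrix(O * inv[:, None])
        S = (U @ U.T).tocsr()
        S.data = np.clip(S.data, 0.0, 1.0)
        S.setdiag(nz.astype(float))
        S.eliminate_zeros()
    data.affinity = S
    return data


def write_affinity_tsv(data: AttributeData, path) -> None:
    """Tab-separated dump of S for inspection (protein IDs as header/rows)."""
    S = data.affinity_dense()
    with open(path, "w") as fh:
        fh.write("protein\t" + "\t".join(data.proteins) + "\n")
        for p, row in zip(data.proteins, S):
            fh.write(p + "\t" + "\t".join(f"{x:.6g}" for x in row) + "\n")
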