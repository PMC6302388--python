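"""Plain-text readers/writers and the validated domain containers.

Three input formats feed the pipeline:

* a PPI edge list — one interaction per line, two whitespace- or
  tab-separated protein IDs, ``#`` comments allowed;
* a GO-slim annotation table in the ``go_slim_mapping.tab`` dialect
  (tab-separated; systematic name in column 1, single-letter ontology
  aspect in column 4, GO term identifier in column 6);
* a complex catalogue — one complex per line, whitespace-separated
  protein IDs, with an optional annotated dialect where a ``|`` separates
  core members from attachments.

All containers order proteins lexicographically so that every derived
matrix (attribute, affinity, adjacency, weights) has a reproducible row
order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

logger = logging.getLogger(__name__)

#: single-letter aspect codes used by the go_slim_mapping dialect
ASPECT_CODES = {"P": "Bp", "F": "Mf", "C": "Cc"}
VALID_ASPECTS = frozenset({"Bp", "Mf", "Cc"})
DEFAULT_ASPECTS = frozenset({"Bp", "Mf"})


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


def _norm_edge(u: str, v: str) -> tuple[str, str]:
    return (u, v) if u <= v else (v, u)


class PPINetwork:
    """Undirected simple graph over protein identifiers.

    Self-loops and duplicate/reversed edges are normalised away at
    construction time; protein order is lexicographic.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str]] = (),
        proteins: Iterable[str] = (),
    ) -> None:
        edge_set: set[tuple[str, str]] = set()
        node_set: set[str] = set(proteins)
        n_loops = 0
        for u, v in edges:
            node_set.add(u)
            node_set.add(v)
            if u == v:
                n_loops += 1
                continue
            edge_set.add(_norm_edge(u, v))
        if n_loops:
            logger.info("dropped %d self-loop(s)", n_loops)
        self.proteins: tuple[str, ...] = tuple(sorted(node_set))
        self.edges: frozenset[tuple[str, str]] = frozenset(edge_set)
        self.index: dict[str, int] = {p: i for i, p in enumerate(self.proteins)}
        nbrs: dict[str, set[str]] = {p: set() for p in self.proteins}
        for u, v in edge_set:
            nbrs[u].add(v)
            nbrs[v].add(u)
        self._neighbors = {p: frozenset(s) for p, s in nbrs.items()}

    # -- queries -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.proteins)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def has_edge(self, u: str, v: str) -> bool:
        return u != v and _norm_edge(u, v) in self.edges

    def neighbors(self, p: str) -> frozenset[str]:
        return self._neighbors[p]

    def degree(self, p: str) -> int:
        return len(self._neighbors[p])

    def adjacency_matrix(self):
        """Binary adjacency in lexicographic protein order (CSR)."""
        import scipy.sparse as sp

        rows, cols = [], []
        for u, v in self.edges:
            i, j = self.index[u], self.index[v]
            rows += [i, j]
            cols += [j, i]
        data = [1.0] * len(rows)
        return sp.csr_matrix((data, (rows, cols)), shape=(self.n, self.n))

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.proteins)
        g.add_edges_from(self.edges)
        return g

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PPINetwork):
            return NotImplemented
        return self.proteins == other.proteins and self.edges == other.edges

    def __repr__(self) -> str:
        return f"PPINetwork(n={self.n}, edges={self.n_edges})"


@dataclass(frozen=True, order=True)
class AnnotationRecord:
    protein: str
    term: str
    aspect: str  # one of Bp / Mf / Cc


class AnnotationTable:
    """Deduplicated (protein, GO-slim term, aspect) records."""

    def __init__(self, records: Iterable[AnnotationRecord | tuple[str, str, str]]):
        seen: set[AnnotationRecord] = set()
        for r in records:
            if not isinstance(r, AnnotationRecord):
                r = AnnotationRecord(*r)
            if r.aspect not in VALID_ASPECTS:
                raise ValueError(f"invalid GO aspect {r.aspect!r}")
            seen.add(r)
        self.records: tuple[AnnotationRecord, ...] = tuple(sorted(seen))

    def filter_aspects(self, keep: Iterable[str]) -> "AnnotationTable":
        keep = frozenset(keep)
        return AnnotationTable(r for r in self.records if r.aspect in keep)

    def terms_by_protein(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for r in self.records:
            out.setdefault(r.protein, set()).add(r.term)
        return out

    def terms(self) -> tuple[str, ...]:
        """Distinct term IDs, lexicographic."""
        return tuple(sorted({r.term for r in self.records}))

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[AnnotationRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationTable):
            return NotImplemented
        return self.records == other.records


@dataclass(frozen=True)
class Complex:
    """One protein complex, optionally split into core and attachments."""

    members: frozenset[str]
    core: frozenset[str] | None = None
    attachments: frozenset[str] | None = None
    density: float | None = None

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a complex needs at least one member")
        if self.core is not None:
            att = self.attachments if self.attachments is not None else frozenset()
            if self.core | att != self.members:
                raise ValueError("core/attachment split must partition members")

    @property
    def size(self) -> int:
        return len(self.members)


class ComplexSet:
    """Ordered collection of complexes (predicted or reference)."""

    def __init__(self, complexes: Iterable[Complex | Iterable[str]]):
        out: list[Complex] = []
        for c in complexes:
            if not isinstance(c, Complex):
                c = Complex(members=frozenset(c))
            out.append(c)
        self.complexes: list[Complex] = out

    def member_sets(self) -> list[frozenset[str]]:
        return [c.members for c in self.complexes]

    def filter_min_size(self, k: int) -> "ComplexSet":
        if k < 1:
            raise ValueError("minimum size must be >= 1")
        return ComplexSet(c for c in self.complexes if c.size >= k)

    def __len__(self) -> int:
        return len(self.complexes)

    def __iter__(self) -> Iterator[Complex]:
        return iter(self.complexes)

    def __getitem__(self, i: int) -> Complex:
        return self.complexes[i]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ComplexSet):
            return NotImplemented
        return self.member_sets() == other.member_sets()


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

def read_edge_list(path: str | Path, comment_prefix: str = "#") -> PPINetwork:
    """Read a two-column PPI edge list into a normalised :class:`PPINetwork`.

    Lines starting with *comment_prefix* and blank lines are skipped; the
    first two whitespace-separated tokens of every other line are taken as
    protein IDs.  Self-loops are dropped (logged) and duplicate edges in
    either orientation collapse to one.
    """
    path = Path(path)
    edges: list[tuple[str, str]] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(comment_prefix):
                continue
            toks = line.split()
            if len(toks) < 2:
                raise ParseError(
                    f"{path}:{lineno}: expected at least two protein IDs, got {line!r}"
                )
            edges.append((toks[0], toks[1]))
    return PPINetwork(edges)


def read_go_slim(
    path: str | Path,
    keep_aspects: Iterable[str] = DEFAULT_ASPECTS,
) -> AnnotationTable:
    """Read a ``go_slim_mapping.tab``-dialect annotation file.

    Columns (tab-separated): systematic name, standard name, SGDID, aspect
    code (P/F/C), term name, GO ID, feature type.  Only the systematic
    name, aspect and GO ID columns are used.  Rows whose aspect is not in
    *keep_aspects* are excluded; by default the cellular-component (Cc)
    aspect is dropped because its slim terms leak complex-membership
    information into the attributes.
    """
    keep = frozenset(keep_aspects)
    if not keep <= VALID_ASPECTS:
        raise ValueError(f"keep_aspects must be a subset of {sorted(VALID_ASPECTS)}")
    path = Path(path)
    records: list[AnnotationRecord] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("!") or line.startswith("#"):
                continue
            cols = line.rstrip("\n").split("\t")
            if len(cols) < 4:
                raise ParseError(
                    f"{path}:{lineno}: missing aspect column "
                    f"(need >= 4 tab-separated columns, got {len(cols)})"
                )
            protein = cols[0].strip()
            code = cols[3].strip()
            aspect = ASPECT_CODES.get(code, code if code in VALID_ASPECTS else None)
            if aspect is None:
                logger.warning("%s:%d: unknown aspect code %r, row skipped", path, lineno, code)
                continue
            term = cols[5].strip() if len(cols) > 5 and cols[5].strip() else cols[4].strip()
            if not term:
                logger.warning("%s:%d: empty term, row skipped", path, lineno)
                continue
            if aspect in keep:
                records.append(AnnotationRecord(protein, term, aspect))
    return AnnotationTable(records)


def read_complexes(path: str | Path) -> ComplexSet:
    """Read one complex per line; a ``|`` marks a core/attachment split."""
    path = Path(path)
    out: list[Complex] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if line.startswith("#"):
                continue
            if not line:
                logger.warning("%s:%d: empty line skipped", path, lineno)
                continue
            if "|" in line:
                core_part, _, att_part = line.partition("|")
                core = frozenset(core_part.split())
                att = frozenset(att_part.split())
                out.append(Complex(members=core | att, core=core, attachments=att))
            else:
                out.append(Complex(members=frozenset(line.split())))
    return ComplexSet(out)


def write_complexes(complexes: ComplexSet, path: str | Path) -> None:
    """Write complexes one per line (annotated ``core | attachments``
    dialect whenever the split is known).  Members are written sorted so
    write→read round-trips exactly."""
    path = Path(path)
    with path.open("w") as fh:
        for c in complexes:
            if c.core is not None:
                att = sorted(c.attachments or ())
                fh.write(" ".join(sorted(c.core)))
                if att:
                    fh.write(" | " + " ".join(att))
                fh.write("\n")
            else:
                fh.write(" ".join(sorted(c.members)) + "\n")


def filter_min_size(complexes: ComplexSet, k: int) -> ComplexSet:
    """Keep exactly the complexes with at least *k* members (order kept)."""
    return complexes.filter_min_size(k)


# -- embedding matrix export (tab-separated, protein-ID first column) -------

def write_embedding_tsv(proteins: Sequence[str], vectors, path: str | Path) -> None:
    import numpy as np

    vectors = np.asarray(vectors)
    path = Path(path)
    with path.open("w") as fh:
        fh.write("protein\t" + "\t".join(str(i) for i in range(vectors.shape[1])) + "\n")
        for p, row in zip(proteins, vectors):
            fh.write(p + "\t" + "\t".join(repr(float(x)) for x in row) + "\n")


def read_embedding_tsv(path: str | Path):
    """Return (proteins tuple, n×d float array) from :func:`write_embedding_tsv` output."""
    import numpy as np

    path = Path(path)
    proteins: list[str] = []
    rows: list[list[float]] = []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("protein"):
            raise ParseError(f"{path}: missing embedding header row")
        for line in fh:
            toks = line.rstrip("\n").split("\t")
            proteins.append(toks[0])
            rows.append([float(x) for x in toks[1:]])
    return tuple(proteins), np.asarray(rows, dtype=float)
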