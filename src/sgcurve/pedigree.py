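"""Pedigree handling and additive (numerator) relationship matrices.

The numerator relationship matrix (NRM) ``A`` holds expected additive genetic
relationships between animals: ``a_ij`` is twice the kinship coefficient and the
diagonal is ``1 + F_i`` with ``F_i`` the inbreeding coefficient.  It supplies the
covariance structure ``Σ_u ⊗ A`` of the genetic effects in the growth models and
the covariance of maternal effects.

Construction uses the tabular method: process animals with parents before
offspring and fill each row from the parental rows,

    a_ij = (a_{s(i),j} + a_{d(i),j}) / 2          (j processed before i)
    a_ii = 1 + a_{s(i),d(i)} / 2

with unknown parents contributing zero (founders are taken as unrelated and
non-inbred).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import scipy.sparse as sp

__all__ = [
    "PedigreeTable",
    "RelationshipMatrix",
    "build_nrm",
    "truncate_pedigree",
    "nrm_inverse",
]

#: sentinel for an unknown parent
UNKNOWN = None


def _norm_id(x) -> str | None:
    """Normalize an id token; ``0``, ``"0"``, ``""`` and None mean unknown."""
    if x is None:
        return None
    s = str(x).strip()
    if s in ("", "0", ".", "NA"):
        return None
    return s


@dataclass
class PedigreeTable:
    """Animal/sire/dam triples.

    Parents referenced but never listed as animals are augmented as founder
    records, so after construction every non-unknown parent id appears as an
    animal id.  The pedigree must be acyclic (no animal is its own ancestor).
    """

    records: list[tuple[str, str | None, str | None]]
    _graph: nx.DiGraph = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        norm = [(_norm_id(a), _norm_id(s), _norm_id(d)) for a, s, d in self.records]
        if any(a is None for a, _, _ in norm):
            raise ValueError("animal id may not be unknown/empty")
        ids = [a for a, _, _ in norm]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate animal ids: {dupes[:5]}")
        known = set(ids)
        founders = []
        for _, s, d in norm:
            for p in (s, d):
                if p is not None and p not in known:
                    known.add(p)
                    founders.append((p, None, None))
        self.records = founders + norm
        g = nx.DiGraph()
        g.add_nodes_from(a for a, _, _ in self.records)
        for a, s, d in self.records:
            for p in (s, d):
                if p is not None:
                    g.add_edge(p, a)  # parent -> offspring
        if not nx.is_directed_acyclic_graph(g):
            cyc = nx.find_cycle(g)
            raise ValueError(f"pedigree contains a cycle: {cyc}")
        self._graph = g

    # -- basic queries ----------------------------------------------------
    def __len__(self) -> int:
        return len(self.records)

    @property
    def ids(self) -> list[str]:
        return [a for a, _, _ in self.records]

    def parents(self, animal: str) -> tuple[str | None, str | None]:
        for a, s, d in self.records:
            if a == animal:
                return s, d
        raise KeyError(animal)

    @property
    def generation_depth(self) -> int:
        """Longest ancestor chain length (founder generation = depth 0)."""
        return int(nx.dag_longest_path_length(self._graph)) if len(self) else 0

    def topological_ids(self) -> list[str]:
        """Parents-before-offspring ordering, ties broken by id string."""
        return list(nx.lexicographical_topological_sort(self._graph, key=str))


@dataclass
class RelationshipMatrix:
    """Ordered ids plus the symmetric additive-relationship matrix."""

    ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("ids/values shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("relationship matrix must be symmetric")

    def index(self, ids) -> np.ndarray:
        pos = {a: k for k, a in enumerate(self.ids)}
        return np.array([pos[a] for a in ids], dtype=int)

    def submatrix(self, ids) -> "RelationshipMatrix":
        """Marginal relationship matrix over a subset of animals."""
        idx = self.index(ids)
        return RelationshipMatrix(list(ids), self.values[np.ix_(idx, idx)])

    def inbreeding(self) -> np.ndarray:
        return np.diag(self.values) - 1.0


def build_nrm(pedigree: PedigreeTable) -> RelationshipMatrix:
    """Numerator relationship matrix by the tabular method.

    Animals are ordered topologically (parents first; ties by id string).
    Unknown parents are treated as unrelated non-inbred founders, and
    inbreeding enters through the parental relationship ``a_sd``.
    """
    order = pedigree.topological_ids()
    pos = {a: k for k, a in enumerate(order)}
    par = {a: (s, d) for a, s, d in pedigree.records}
    n = len(order)
    a = np.zeros((n, n))
    for i, animal in enumerate(order):
        s, d = par[animal]
        si = pos[s] if s is not None else -1
        di = pos[d] if d is not None else -1
        row = np.zeros(i)
        if si >= 0:
            row += 0.5 * a[si, :i]
        if di >= 0:
            row += 0.5 * a[di, :i]
        a[i, :i] = row
        a[:i, i] = row
        a[i, i] = 1.0 + (0.5 * a[si, di] if (si >= 0 and di >= 0) else 0.0)
    return RelationshipMatrix(order, a)


def truncate_pedigree(
    pedigree: PedigreeTable, phenotyped_ids, generations: int
) -> PedigreeTable:
    """Retain phenotyped animals plus ancestors up to ``generations`` back.

    Parents falling outside the retained set become unknown, i.e. ancestors
    beyond the cut are treated as founders.
    """
    if generations < 0:
        raise ValueError("generations must be >= 0")
    phen = [_norm_id(a) for a in phenotyped_ids]
    if not phen:
        raise ValueError("phenotyped id set is empty")
    known = set(pedigree.ids)
    missing = [a for a in phen if a not in known]
    if missing:
        raise ValueError(f"phenotyped ids absent from pedigree: {missing[:5]}")
    par = {a: (s, d) for a, s, d in pedigree.records}
    keep: set[str] = set(phen)
    frontier = set(phen)
    for _ in range(generations):
        nxt = set()
        for a in frontier:
            for p in par[a]:
                if p is not None and p not in keep:
                    nxt.add(p)
        keep |= nxt
        frontier = nxt
        if not frontier:
            break
    recs = []
    for a, s, d in pedigree.records:
        if a in keep:
            recs.append(
                (a, s if s in keep else None, d if d in keep else None)
            )
    return PedigreeTable(recs)


def nrm_inverse(matrix: RelationshipMatrix, zero_tol: float = 1e-10) -> sp.csr_matrix:
    """Sparse symmetric inverse of an NRM.

    Dense inversion followed by symmetrization; the exact inverse of an NRM is
    sparse (non-zeros connect animals to their parents and mates), so entries
    below ``zero_tol`` are numerical fill and are dropped.
    """
    vals = matrix.values
    # positive definiteness check doubles as the factorization
    try:
        c = np.linalg.cholesky(vals)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "relationship matrix is singular / not positive definite"
        ) from exc
    inv = np.linalg.inv(c.T) @ np.linalg.inv(c)
    inv = 0.5 * (inv + inv.T)
    inv[np.abs(inv) < zero_tol] = 0.0
    return sp.csr_matrix(inv)
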