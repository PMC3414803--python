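"""All-vs-all local protein alignment and the -log10(E) similarity graph.

Every sequence is compared against every other with an exact affine-gap
Smith-Waterman alignment (no heuristic seeding; full dynamic programming,
appropriate at desk scale).  E-values follow the Karlin-Altschul bit-score
formula with fixed gapped-BLOSUM62(11,1) constants; only the rank order and
cutoff behaviour of E matter downstream, so the empirical shuffling
statistics of dedicated search tools are deliberately not reproduced.
Hits passing the E-value cutoff become edges of a sparse symmetric graph
weighted by capped -log10(E), the input expected by Markov clustering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from tbssr.records import AA_ALPHABET_X, ProteinRecord

_N_AA = len(AA_ALPHABET_X)  # 21, X last
_AA_INDEX = {c: i for i, c in enumerate(AA_ALPHABET_X)}


def _load_blosum62() -> np.ndarray:
    """BLOSUM62 as a 21x21 int matrix in AA_ALPHABET_X order; X scores 0."""
    from Bio.Align import substitution_matrices

    bl = substitution_matrices.load("BLOSUM62")
    mat = np.zeros((_N_AA, _N_AA), dtype=np.int32)
    for i, a in enumerate(AA_ALPHABET_X[:-1]):
        for j, b in enumerate(AA_ALPHABET_X[:-1]):
            mat[i, j] = int(bl[a, b])
    # X is treated as fully ambiguous: neutral against everything.
    mat[_N_AA - 1, :] = 0
    mat[:, _N_AA - 1] = 0
    return mat


_BLOSUM62 = _load_blosum62()
_MATRICES = {"BLOSUM62": _BLOSUM62}


@dataclass
class ScoringScheme:
    """Scoring parameters for local alignment and E-value statistics.

    ``gap_open``/``gap_extend`` follow the BLAST convention: a gap of
    length *k* costs ``gap_open + k * gap_extend``.  ``lam`` (nats) and
    ``K`` are the Karlin-Altschul constants for gapped BLOSUM62(11,1).
    """

    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    lam: float = 0.267
    K: float = 0.041

    def __post_init__(self) -> None:
        if self.gap_open < self.gap_extend or self.gap_extend < 1:
            raise ValueError("require gap_open >= gap_extend >= 1")
        if self.lam <= 0 or self.K <= 0:
            raise ValueError("lambda and K must be positive")
        if self.matrix_name not in _MATRICES:
            raise ValueError(f"unknown matrix {self.matrix_name!r}")

    @property
    def matrix(self) -> np.ndarray:
        return _MATRICES[self.matrix_name]


@dataclass
class SimilarityHit:
    """A directed query->subject local alignment passing the E cutoff.

    ``aligned_ranges`` are 0-based half-open ``((qstart, qend),
    (sstart, send))`` on the ungapped sequences.
    """

    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity: float
    aligned_ranges: tuple[tuple[int, int], tuple[int, int]]

    def __post_init__(self) -> None:
        if self.e_value <= 0:
            raise ValueError("E-value must be positive")
        if self.raw_score < 0:
            raise ValueError("raw score must be non-negative")


def encode(seq: str) -> np.ndarray:
    """Encode an amino-acid string as int8 indices into AA_ALPHABET_X."""
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.int8)
    except KeyError as exc:  # pragma: no cover - guarded by ProteinRecord
        raise ValueError(f"invalid residue {exc.args[0]!r}") from exc


@njit(cache=True)
def _sw_kernel(a, b, sub, go, ge):
    """Smith-Waterman with affine gaps; returns score, end cell, matrices.

    Gap of length k costs go + k*ge.  The best cell is the first maximum
    in row-major order, which together with the diagonal > up > left
    traceback preference makes the alignment deterministic.
    """
    n = a.shape[0]
    m = b.shape[0]
    NEG = np.int32(-(10 ** 9))
    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    E = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    F = np.full((n + 1, m + 1), NEG, dtype=np.int32)
    best = np.int32(0)
    bi = 0
    bj = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            e = H[i, j - 1] - (go + ge)
            if E[i, j - 1] - ge > e:
                e = E[i, j - 1] - ge
            E[i, j] = e
            f = H[i - 1, j] - (go + ge)
            if F[i - 1, j] - ge > f:
                f = F[i - 1, j] - ge
            F[i, j] = f
            h = H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]
            v = np.int32(0)
            if h > v:
                v = h
            if f > v:
                v = f
            if e > v:
                v = e
            H[i, j] = v
            if v > best:
                best = v
                bi = i
                bj = j
    return H, E, F, best, bi, bj


@njit(cache=True)
def _sw_traceback(a, b, sub, go, ge, H, E, F, bi, bj):
    """Deterministic traceback (diagonal, then up, then left)."""
    i = bi
    j = bj
    matches = 0
    aln_len = 0
    state = 0  # 0 = H, 1 = F (gap in b, consume a), 2 = E (gap in a)
    while True:
        if state == 0:
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[a[i - 1], b[j - 1]]:
                aln_len += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                i -= 1
                j -= 1
            elif H[i, j] == F[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            if F[i, j] == H[i - 1, j] - (go + ge):
                i -= 1
                state = 0
            else:
                i -= 1
        else:
            aln_len += 1
            if E[i, j] == H[i, j - 1] - (go + ge):
                j -= 1
                state = 0
            else:
                j -= 1
    return i, j, matches, aln_len


def sw_align(
    a: str, b: str, scoring: ScoringScheme | None = None
) -> tuple[int, float, tuple[tuple[int, int], tuple[int, int]]]:
    """Optimal local alignment of two protein sequences.

    Returns ``(raw_score, identity, ((qstart, qend), (sstart, send)))``
    with 0-based half-open ranges.  Identity is exact matches over
    alignment columns (BLAST ``pident`` convention); a zero score yields
    an empty alignment with identity 0 and empty ranges.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scoring = scoring or ScoringScheme()
    ea, eb = encode(a), encode(b)
    H, E, F, best, bi, bj = _sw_kernel(
        ea, eb, scoring.matrix, scoring.gap_open, scoring.gap_extend
    )
    if best == 0:
        return 0, 0.0, ((0, 0), (0, 0))
    i0, j0, matches, aln_len = _sw_traceback(
        ea, eb, scoring.matrix, scoring.gap_open, scoring.gap_extend,
        H, E, F, bi, bj,
    )
    identity = matches / aln_len if aln_len else 0.0
    return int(best), identity, ((i0, bi), (j0, bj))


#: Numerical floor applied to E-values to keep -log10(E) finite.
E_VALUE_FLOOR = 1e-200


def evalue(
    raw_score: int,
    query_len: int,
    database_size: int,
    scoring: ScoringScheme | None = None,
) -> float:
    """Karlin-Altschul E-value for a raw local alignment score.

    bit = (lambda * S - ln K) / ln 2 and E = m * n * 2**(-bit), floored
    at 1e-200.  Strictly decreasing in the raw score.
    """
    if raw_score < 0:
        raise ValueError("raw score must be non-negative")
    if query_len <= 0 or database_size <= 0:
        raise ValueError("lengths must be positive")
    scoring = scoring or ScoringScheme()
    bit = (scoring.lam * raw_score - math.log(scoring.K)) / math.log(2.0)
    e = float(query_len) * float(database_size) * math.pow(2.0, -bit)
    return max(e, E_VALUE_FLOOR)


def bit_score(raw_score: int, scoring: ScoringScheme | None = None) -> float:
    scoring = scoring or ScoringScheme()
    return (scoring.lam * raw_score - math.log(scoring.K)) / math.log(2.0)


def all_vs_all(
    proteins: list[ProteinRecord],
    scoring: ScoringScheme | None = None,
    e_cutoff: float = 0.01,
) -> list[SimilarityHit]:
    """Every sequence queried against the whole set (self-hits excluded).

    The alignment is computed once per unordered pair (the raw score is
    symmetric); the two directed hits differ only through the query
    length entering the E-value.  ``database_size`` is the total residue
    count of the set.
    """
    scoring = scoring or ScoringScheme()
    ids = [p.id for p in proteins]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate protein ids in input")
    db = sum(p.length for p in proteins)
    hits: list[SimilarityHit] = []
    for i in range(len(proteins)):
        for j in range(i + 1, len(proteins)):
            p, q = proteins[i], proteins[j]
            score, ident, (ra, rb) = sw_align(p.sequence, q.sequence, scoring)
            if score == 0:
                continue
            bits = bit_score(score, scoring)
            for qrec, srec, qr, sr in ((p, q, ra, rb), (q, p, rb, ra)):
                e = evalue(score, qrec.length, db, scoring)
                if e <= e_cutoff:
                    hits.append(
                        SimilarityHit(
                            query_id=qrec.id,
                            subject_id=srec.id,
                            raw_score=score,
                            bit_score=bits,
                            e_value=e,
                            identity=ident,
                            aligned_ranges=(qr, sr),
                        )
                    )
    return hits


class SimilarityGraph:
    """Sparse symmetric graph weighted by capped -log10(E-value).

    Edges are stored once with ``i < j`` (index order); isolated nodes
    are retained so every input protein survives to the partition.
    """

    def __init__(
        self,
        node_ids: list[str],
        weight_cap: float = 200.0,
        e_cutoff: float = 0.01,
        database_size: int = 0,
    ) -> None:
        if len(set(node_ids)) != len(node_ids):
            raise ValueError("duplicate node ids")
        self.node_ids = list(node_ids)
        self.index = {n: i for i, n in enumerate(self.node_ids)}
        self.edges: dict[tuple[int, int], float] = {}
        self.weight_cap = float(weight_cap)
        self.e_cutoff = float(e_cutoff)
        self.database_size = int(database_size)

    def __len__(self) -> int:
        return len(self.node_ids)

    def add_edge(self, u: str, v: str, weight: float) -> None:
        """Insert or max-merge an undirected edge; self-edges are ignored."""
        if weight <= 0:
            raise ValueError("edge weight must be positive")
        i, j = self.index[u], self.index[v]
        if i == j:
            return
        if i > j:
            i, j = j, i
        w = min(weight, self.weight_cap)
        prev = self.edges.get((i, j))
        if prev is None or w > prev:
            self.edges[(i, j)] = w

    def weight(self, u: str, v: str) -> float:
        i, j = self.index[u], self.index[v]
        if i > j:
            i, j = j, i
        return self.edges.get((i, j), 0.0)

    def to_dense(self) -> np.ndarray:
        n = len(self.node_ids)
        a = np.zeros((n, n), dtype=float)
        for (i, j), w in self.edges.items():
            a[i, j] = w
            a[j, i] = w
        return a

    def to_sparse(self):
        from scipy import sparse

        n = len(self.node_ids)
        if not self.edges:
            return sparse.csr_matrix((n, n))
        rows, cols, vals = [], [], []
        for (i, j), w in sorted(self.edges.items()):
            rows += [i, j]
            cols += [j, i]
            vals += [w, w]
        return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))

    def subgraph(self, ids: list[str]) -> "SimilarityGraph":
        sub = SimilarityGraph(
            ids, self.weight_cap, self.e_cutoff, self.database_size
        )
        keep = set(ids)
        for (i, j), w in self.edges.items():
            u, v = self.node_ids[i], self.node_ids[j]
            if u in keep and v in keep:
                sub.add_edge(u, v, w)
        return sub

    def degree(self, u: str) -> int:
        i = self.index[u]
        return sum(1 for (a, b) in self.edges if a == i or b == i)


def build_graph(
    hits: list[SimilarityHit],
    weight_cap: float = 200.0,
    node_ids: list[str] | None = None,
    e_cutoff: float = 0.01,
    database_size: int = 0,
) -> SimilarityGraph:
    """Collect directed hits into the undirected -log10(E) graph.

    The two directions of a pair are merged by taking the maximum weight
    (either direction can report the pair).  ``node_ids`` lists all
    proteins so that isolated ones are kept as nodes; when omitted, the
    node set is the ids seen in the hits.
    """
    if node_ids is None:
        seen: list[str] = []
        seen_set: set[str] = set()
        for h in hits:
            for x in (h.query_id, h.subject_id):
                if x not in seen_set:
                    seen.append(x)
                    seen_set.add(x)
        node_ids = seen
    g = SimilarityGraph(node_ids, weight_cap, e_cutoff, database_size)
    for h in hits:
        if h.e_value <= 0:
            raise ValueError("non-positive E-value")
        g.add_edge(h.query_id, h.subject_id, -math.log10(h.e_value))
    return g
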