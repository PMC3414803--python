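"""Per-family multiple alignment and catalytic-motif detection.

Tyrosine recombinases cleave DNA with a C-terminal catalytic tyrosine
activated by a conserved arginine roughly 30 residues upstream.  The
motif scan below formalises what is traditionally read off a family
alignment by eye: a highly conserved Y column in the C-terminal part of
the alignment with a conserved R column whose per-row ungapped spacing
to the Y has a median around 30.

Alignments are built progressively along a UPGMA guide tree with
profile-profile affine-gap alignment; an external command-line aligner
can be substituted through a simple FASTA-in / aligned-FASTA-out
adapter.
"""

from __future__ import annotations

import statistics
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from numba import njit
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from tbssr.records import AA_ALPHABET_X, ProteinRecord
from tbssr.similarity import ScoringScheme, SimilarityGraph, encode

_N_AA = len(AA_ALPHABET_X)


@dataclass
class Msa:
    """A family alignment: equal-length gapped rows keyed by protein id."""

    family_index: int
    rows: dict[str, str]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows.values()}
        if len(lengths) > 1:
            raise ValueError("alignment rows have unequal lengths")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)


@dataclass
class ConservationProfile:
    """Per-column consensus residue, consensus fraction and gap fraction.

    The consensus fraction is computed over non-gap rows only; an
    all-gap column has consensus fraction 0 and gap fraction 1.
    """

    consensus: list[str]
    consensus_fraction: np.ndarray
    gap_fraction: np.ndarray


@dataclass
class MotifOptions:
    conservation_min: float = 0.9
    gap_max: float = 0.2
    spacing_range: tuple[int, int] = (20, 40)
    c_terminal_window: float = 0.35
    min_rows: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.conservation_min <= 1:
            raise ValueError("conservation_min must be in (0, 1]")
        if self.spacing_range[0] > self.spacing_range[1]:
            raise ValueError("spacing_range must be ordered")


@dataclass
class MotifCall:
    """Outcome of the catalytic-motif scan on one family alignment."""

    found: bool
    y_column: int | None = None
    r_column: int | None = None
    median_spacing: int | None = None
    label: str = "no obvious one"
    y_conservation: float = 0.0
    r_conservation: float = 0.0
    reason: str = ""


def guide_tree(
    members: list[ProteinRecord], graph: SimilarityGraph
) -> tuple[list[str], np.ndarray]:
    """UPGMA guide tree from similarity-graph weights.

    Distances are d(i, j) = 1 - w(i, j) / w_max within the family, with
    missing edges at distance 1.  Members are sorted by id before
    linkage so ties resolve by id order.  Returns the leaf id order and
    a scipy linkage matrix (empty for a single member).
    """
    if not members:
        raise ValueError("no members")
    ids = sorted(p.id for p in members)
    n = len(ids)
    if n == 1:
        return ids, np.empty((0, 4))
    wmax = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            wmax = max(wmax, graph.weight(ids[i], ids[j]))
    if wmax == 0:
        wmax = 1.0
    d = np.ones((n, n))
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(i + 1, n):
            w = graph.weight(ids[i], ids[j])
            d[i, j] = d[j, i] = 1.0 - w / wmax
    z = linkage(squareform(d, checks=False), method="average")
    return ids, z


@njit(cache=True)
def _global_affine_ops(S, go, ge):
    """Global affine-gap alignment over a precomputed column-score matrix.

    Returns the operation sequence (0 diagonal, 1 up / consume first
    profile, 2 left) with the diagonal > up > left tie preference.
    """
    n, m = S.shape
    NEG = -1e17
    H = np.full((n + 1, m + 1), NEG)
    E = np.full((n + 1, m + 1), NEG)
    F = np.full((n + 1, m + 1), NEG)
    ptrH = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 F, 2 E
    ptrE = np.zeros((n + 1, m + 1), dtype=np.int8)  # 1 = opened from H
    ptrF = np.zeros((n + 1, m + 1), dtype=np.int8)
    H[0, 0] = 0.0
    for j in range(1, m + 1):
        E[0, j] = -(go + ge) - (j - 1) * ge
        H[0, j] = E[0, j]
        ptrH[0, j] = 2
        ptrE[0, j] = 1 if j == 1 else 0
    for i in range(1, n + 1):
        F[i, 0] = -(go + ge) - (i - 1) * ge
        H[i, 0] = F[i, 0]
        ptrH[i, 0] = 1
        ptrF[i, 0] = 1 if i == 1 else 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eo = H[i, j - 1] - (go + ge)
            ee = E[i, j - 1] - ge
            if eo >= ee:
                E[i, j] = eo
                ptrE[i, j] = 1
            else:
                E[i, j] = ee
                ptrE[i, j] = 0
            fo = H[i - 1, j] - (go + ge)
            fe = F[i - 1, j] - ge
            if fo >= fe:
                F[i, j] = fo
                ptrF[i, j] = 1
            else:
                F[i, j] = fe
                ptrF[i, j] = 0
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            best = diag
            ptr = 0
            if F[i, j] > best:
                best = F[i, j]
                ptr = 1
            if E[i, j] > best:
                best = E[i, j]
                ptr = 2
            H[i, j] = best
            ptrH[i, j] = ptr
    ops = np.empty(n + m, dtype=np.int8)
    k = 0
    i, j = n, m
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = ptrH[i, j]
            if i == 0:
                p = 2
            elif j == 0:
                p = 1
            if p == 0:
                ops[k] = 0
                k += 1
                i -= 1
                j -= 1
            elif p == 1:
                state = 1
            else:
                state = 2
        elif state == 1:
            ops[k] = 1
            k += 1
            if ptrF[i, j] == 1:
                state = 0
            i -= 1
        else:
            ops[k] = 2
            k += 1
            if ptrE[i, j] == 1:
                state = 0
            j -= 1
    return ops[:k][::-1].copy()


def _profile_counts(rows: list[str]) -> np.ndarray:
    """Residue count matrix (columns x 21); gaps are not counted."""
    ncol = len(rows[0])
    counts = np.zeros((ncol, _N_AA), dtype=np.float64)
    for r in rows:
        for c, ch in enumerate(r):
            if ch != "-":
                counts[c, AA_ALPHABET_X.index(ch)] += 1
    return counts


def _merge_profiles(
    rows_a: list[str],
    rows_b: list[str],
    scoring: ScoringScheme,
) -> tuple[list[str], list[str]]:
    ca = _profile_counts(rows_a)
    cb = _profile_counts(rows_b)
    sub = scoring.matrix.astype(np.float64)
    # average sum-of-pairs column score over non-gap residue pairs
    s = ca @ sub @ cb.T
    denom = np.outer(ca.sum(axis=1), cb.sum(axis=1))
    denom[denom == 0] = 1.0
    s = s / denom
    ops = _global_affine_ops(s, float(scoring.gap_open), float(scoring.gap_extend))
    out_a = ["" for _ in rows_a]
    out_b = ["" for _ in rows_b]
    ia = ib = 0
    for op in ops:
        if op == 0:
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ia += 1
            ib += 1
        elif op == 1:
            for k, r in enumerate(rows_a):
                out_a[k] += r[ia]
            for k in range(len(rows_b)):
                out_b[k] += "-"
            ia += 1
        else:
            for k in range(len(rows_a)):
                out_a[k] += "-"
            for k, r in enumerate(rows_b):
                out_b[k] += r[ib]
            ib += 1
    return out_a, out_b


def progressive_msa(
    members: list[ProteinRecord],
    tree: tuple[list[str], np.ndarray],
    scoring: ScoringScheme | None = None,
    family_index: int = -1,
) -> Msa:
    """Merge sequences bottom-up along the guide tree.

    Each internal node aligns the two child profiles globally with
    average sum-of-pairs substitution scores and affine gaps.  Gap
    removal from any output row reproduces the input sequence exactly.
    """
    scoring = scoring or ScoringScheme()
    by_id = {p.id: p for p in members}
    ids, z = tree
    if set(ids) != set(by_id):
        raise ValueError("tree leaves do not match member ids")
    for p in members:
        bad = set(p.sequence) - set(AA_ALPHABET_X)
        if bad:
            raise ValueError(f"invalid residues in {p.id}: {sorted(bad)}")
    clusters: dict[int, tuple[list[str], list[str]]] = {
        i: ([pid], [by_id[pid].sequence]) for i, pid in enumerate(ids)
    }
    nxt = len(ids)
    for row in z:
        a, b = int(row[0]), int(row[1])
        ids_a, rows_a = clusters.pop(a)
        ids_b, rows_b = clusters.pop(b)
        new_a, new_b = _merge_profiles(rows_a, rows_b, scoring)
        clusters[nxt] = (ids_a + ids_b, new_a + new_b)
        nxt += 1
    (final_ids, final_rows), = clusters.values()
    return Msa(family_index=family_index, rows=dict(zip(final_ids, final_rows)))


def align_family(
    members: list[ProteinRecord],
    scoring: ScoringScheme | None = None,
    family_index: int = -1,
) -> Msa:
    """Convenience: build the within-family similarity graph, guide tree
    and progressive alignment in one call."""
    from tbssr.similarity import all_vs_all, build_graph

    if len(members) == 1:
        return Msa(family_index=family_index,
                   rows={members[0].id: members[0].sequence})
    scoring = scoring or ScoringScheme()
    hits = all_vs_all(members, scoring)
    graph = build_graph(
        hits,
        node_ids=[p.id for p in members],
        database_size=sum(p.length for p in members),
    )
    return progressive_msa(
        members, guide_tree(members, graph), scoring, family_index=family_index
    )


def align_with_external(
    members: list[ProteinRecord],
    command: list[str],
    family_index: int = -1,
) -> Msa:
    """Adapter for an external aligner (e.g. ``["mafft", "--auto"]``).

    The command receives a FASTA path as its last argument and must
    print aligned FASTA on stdout.
    """
    from Bio import SeqIO

    with tempfile.TemporaryDirectory() as td:
        fin = Path(td) / "in.fasta"
        fin.write_text(
            "".join(f">{p.id}\n{p.sequence}\n" for p in members)
        )
        res = subprocess.run(
            command + [str(fin)], capture_output=True, text=True, check=True
        )
        out = Path(td) / "out.fasta"
        out.write_text(res.stdout)
        rows = {
            rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(out), "fasta")
        }
    return Msa(family_index=family_index, rows=rows)


def column_conservation(msa: Msa) -> ConservationProfile:
    """Consensus residue and fraction per column, over non-gap rows."""
    if not msa.rows:
        raise ValueError("empty alignment")
    rows = list(msa.rows.values())
    nrow = len(rows)
    ncol = msa.n_columns
    consensus: list[str] = []
    cons_frac = np.zeros(ncol)
    gap_frac = np.zeros(ncol)
    for c in range(ncol):
        col = [r[c] for r in rows]
        gaps = col.count("-")
        gap_frac[c] = gaps / nrow
        residues = [x for x in col if x != "-"]
        if not residues:
            consensus.append("-")
            continue
        best = max(sorted(set(residues)), key=residues.count)
        consensus.append(best)
        cons_frac[c] = residues.count(best) / len(residues)
    return ConservationProfile(consensus, cons_frac, gap_frac)


def _ungapped_positions(row: str) -> np.ndarray:
    """Map alignment column -> 0-based ungapped index (-1 on gaps)."""
    out = np.full(len(row), -1, dtype=np.int64)
    k = 0
    for c, ch in enumerate(row):
        if ch != "-":
            out[c] = k
            k += 1
    return out


def find_catalytic_motif(msa: Msa, opts: MotifOptions | None = None) -> MotifCall:
    """Scan a family alignment for the catalytic R...Y motif.

    Conserved Y columns inside the C-terminal window are visited from
    the right; for each, upstream conserved R columns are tested
    (nearest first) and the first pair whose per-row ungapped spacing
    has a median inside ``spacing_range`` wins.  The label is "R", the
    consensus residues of the consecutive conserved columns immediately
    following the R column (at most 4), then "-Y"; families with no
    qualifying pair are labelled "no obvious one".
    """
    opts = opts or MotifOptions()
    if msa.n_rows < opts.min_rows:
        return MotifCall(found=False, reason="too few rows")
    prof = column_conservation(msa)
    ncol = msa.n_columns
    rows = list(msa.rows.values())
    ungapped = [_ungapped_positions(r) for r in rows]

    def conserved(c: int, residue: str) -> bool:
        return (
            prof.consensus[c] == residue
            and prof.consensus_fraction[c] >= opts.conservation_min
            and prof.gap_fraction[c] <= opts.gap_max
        )

    window_start = int(np.ceil(ncol * (1.0 - opts.c_terminal_window)))
    lo, hi = opts.spacing_range
    for y in range(ncol - 1, window_start - 1, -1):
        if not conserved(y, "Y"):
            continue
        for r in range(y - 1, -1, -1):
            if not conserved(r, "R"):
                continue
            spacings = [
                int(u[y] - u[r])
                for u in ungapped
                if u[y] >= 0 and u[r] >= 0
            ]
            if not spacings:
                continue
            med = int(statistics.median(spacings))
            if med > hi:
                break  # spacing only grows further upstream
            if med < lo:
                continue
            tail = ""
            for c in range(r + 1, min(r + 5, ncol)):
                ch = prof.consensus[c]
                if (
                    ch not in ("-",)
                    and prof.consensus_fraction[c] >= opts.conservation_min
                    and prof.gap_fraction[c] <= opts.gap_max
                ):
                    tail += ch
                else:
                    break
            tail = tail[:4]
            return MotifCall(
                found=True,
                y_column=y,
                r_column=r,
                median_spacing=med,
                label=f"R{tail}-Y",
                y_conservation=float(prof.consensus_fraction[y]),
                r_conservation=float(prof.consensus_fraction[r]),
            )
    return MotifCall(found=False, reason="no qualifying R...Y pair")
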