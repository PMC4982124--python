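"""Multiple alignment of kinase domains and the classical filters.

The aligner is a classic progressive scheme: a k-mer-distance guide tree
(average linkage) orders pairwise profile-profile merges performed by
affine-gap dynamic programming under BLOSUM62.  It is deterministic for a
fixed input order and sufficient for the substitution-dominated,
equal-domain alignments this pipeline produces; a pre-computed alignment
from an external aligner can be supplied anywhere an Alignment is accepted.

Filters implemented after alignment:

* removal of short kinase domains (< 100 aa by default),
* gap-rich column trimming at a configurable gap-fraction cutoff,
* redundancy reduction at 99 % maximum / 30 % minimum pairwise identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform

from ._templates import AMINO_ACIDS

log = logging.getLogger(__name__)

try:
    from numba import njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def njit(*a, **k):
        return a[0] if a and callable(a[0]) else (lambda f: f)

_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

DEFAULT_GAP_OPEN = -12.0
DEFAULT_GAP_EXTEND = -1.0


def blosum62() -> np.ndarray:
    """BLOSUM62 as a dense 20x20 array in AMINO_ACIDS order."""
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = m[a][b]
    return out


class DegenerateAlignmentError(ValueError):
    """An operation removed every column (or every residue of a row)."""


@dataclass
class Alignment:
    """An ordered set of equal-length gapped rows."""
    ids: list[str]
    rows: list[str]

    def __post_init__(self):
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in count")
        if self.rows:
            L = len(self.rows[0])
            for name, row in zip(self.ids, self.rows):
                if len(row) != L:
                    raise ValueError(f"row {name} has length {len(row)}, "
                                     f"expected {L}")
                if L and set(row) == {"-"}:
                    raise ValueError(f"row {name} is all gaps")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def __len__(self) -> int:
        return len(self.rows)

    def row(self, name: str) -> str:
        return self.rows[self.ids.index(name)]

    def degapped(self, name: str) -> str:
        return self.row(name).replace("-", "")

    def to_mapping(self) -> dict[str, str]:
        return dict(zip(self.ids, self.rows))

    @classmethod
    def from_mapping(cls, rows: Mapping[str, str]) -> "Alignment":
        return cls(list(rows), list(rows.values()))


# ---------------------------------------------------------------------------
# Affine-gap profile dynamic programming (Gotoh)

_NEG = -1e30


@njit(cache=True)
def _gotoh_fill(S, gap_open, gap_extend):  # pragma: no cover - jitted
    La, Lb = S.shape
    M = np.full((La + 1, Lb + 1), _NEG)
    X = np.full((La + 1, Lb + 1), _NEG)   # gap in B (consume A)
    Y = np.full((La + 1, Lb + 1), _NEG)   # gap in A (consume B)
    tbM = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    tbX = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    tbY = np.zeros((La + 1, Lb + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, La + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        tbX[i, 0] = 1
    for j in range(1, Lb + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        tbY[0, j] = 2
    for i in range(1, La + 1):
        for j in range(1, Lb + 1):
            # match
            best, arg = M[i - 1, j - 1], 0
            if X[i - 1, j - 1] > best:
                best, arg = X[i - 1, j - 1], 1
            if Y[i - 1, j - 1] > best:
                best, arg = Y[i - 1, j - 1], 2
            M[i, j] = best + S[i - 1, j - 1]
            tbM[i, j] = arg
            # gap in B
            best, arg = M[i - 1, j] + gap_open, 0
            if X[i - 1, j] + gap_extend > best:
                best, arg = X[i - 1, j] + gap_extend, 1
            if Y[i - 1, j] + gap_open > best:
                best, arg = Y[i - 1, j] + gap_open, 2
            X[i, j] = best
            tbX[i, j] = arg
            # gap in A
            best, arg = M[i, j - 1] + gap_open, 0
            if Y[i, j - 1] + gap_extend > best:
                best, arg = Y[i, j - 1] + gap_extend, 1
            if X[i, j - 1] + gap_open > best:
                best, arg = X[i, j - 1] + gap_open, 2
            Y[i, j] = best
            tbY[i, j] = arg
    return M, X, Y, tbM, tbX, tbY


def _gotoh_path(S: np.ndarray, gap_open: float, gap_extend: float,
                ) -> tuple[float, list[tuple[int, int]]]:
    """Best global path through the column-score matrix.

    Gap convention: the first gapped column of a run costs *gap_open*,
    every further column *gap_extend*.  Returns (score, path) where the
    path lists (column-of-A, column-of-B) pairs, -1 marking a gap.
    """
    La, Lb = S.shape
    if La == 0 or Lb == 0:
        path = [(i, -1) for i in range(La)] + [(-1, j) for j in range(Lb)]
        n_gaps = La + Lb
        score = (gap_open + (n_gaps - 1) * gap_extend) if n_gaps else 0.0
        return score, path
    M, X, Y, tbM, tbX, tbY = _gotoh_fill(
        np.ascontiguousarray(S, dtype=np.float64),
        float(gap_open), float(gap_extend))
    states = (M[La, Lb], X[La, Lb], Y[La, Lb])
    state = int(np.argmax(states))
    score = float(states[state])
    path: list[tuple[int, int]] = []
    i, j = La, Lb
    while i > 0 or j > 0:
        if state == 0:
            path.append((i - 1, j - 1))
            state = int(tbM[i, j])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((i - 1, -1))
            state = int(tbX[i, j])
            i -= 1
        else:
            path.append((-1, j - 1))
            state = int(tbY[i, j])
            j -= 1
    path.reverse()
    return score, path


def _encode(seq: str) -> np.ndarray:
    try:
        return np.array([_AA_INDEX[c] for c in seq], dtype=np.intp)
    except KeyError as exc:
        raise ValueError(f"unknown amino acid {exc} in sequence") from exc


def _profile(rows: Sequence[str]) -> np.ndarray:
    """Column frequency profile (L, 20); gaps contribute nothing."""
    L = len(rows[0])
    prof = np.zeros((L, 20))
    for row in rows:
        for k, c in enumerate(row):
            if c != "-":
                prof[k, _AA_INDEX[c]] += 1.0
    return prof / len(rows)


def align_profiles(rows_a: Sequence[str], rows_b: Sequence[str],
                   subs: np.ndarray, gap_open: float, gap_extend: float,
                   ) -> tuple[float, list[str], list[str]]:
    """Merge two sub-alignments by profile-profile DP."""
    pa, pb = _profile(rows_a), _profile(rows_b)
    S = pa @ subs @ pb.T
    score, path = _gotoh_path(S, gap_open, gap_extend)
    new_a = ["".join(r[ia] if ia >= 0 else "-" for ia, _ in path)
             for r in rows_a]
    new_b = ["".join(r[jb] if jb >= 0 else "-" for _, jb in path)
             for r in rows_b]
    return score, new_a, new_b


def pairwise_global_score(seq_a: str, seq_b: str,
                          subs: np.ndarray | None = None,
                          gap_open: float = DEFAULT_GAP_OPEN,
                          gap_extend: float = DEFAULT_GAP_EXTEND) -> float:
    """Global affine-gap alignment score of two sequences."""
    subs = blosum62() if subs is None else subs
    score, _, _ = align_profiles([seq_a], [seq_b], subs, gap_open,
                                 gap_extend)
    return score


def _kmer_sets(seqs: Sequence[str], k: int = 3) -> list[set[str]]:
    return [{s[i:i + k] for i in range(max(len(s) - k + 1, 1))}
            for s in seqs]


def progressive_align(sequences: Mapping[str, str],
                      gap_open: float = DEFAULT_GAP_OPEN,
                      gap_extend: float = DEFAULT_GAP_EXTEND,
                      subs: np.ndarray | None = None) -> Alignment:
    """Progressively align sequences along a k-mer-distance guide tree."""
    ids = list(sequences)
    seqs = [sequences[i] for i in ids]
    if not ids:
        return Alignment([], [])
    if len(ids) == 1:
        return Alignment(ids, [seqs[0]])
    subs = blosum62() if subs is None else subs
    for s in seqs:
        _encode(s)  # validate alphabet up front
    kmers = _kmer_sets(seqs)
    n = len(ids)
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = len(kmers[i] & kmers[j])
            dm[i, j] = dm[j, i] = 1.0 - shared / max(
                min(len(kmers[i]), len(kmers[j])), 1)
    Z = linkage(squareform(dm, checks=False), method="average")
    root = to_tree(Z)

    def merge(node) -> tuple[list[int], list[str]]:
        if node.is_leaf():
            return [node.id], [seqs[node.id]]
        idx_l, rows_l = merge(node.left)
        idx_r, rows_r = merge(node.right)
        _, new_l, new_r = align_profiles(rows_l, rows_r, subs, gap_open,
                                         gap_extend)
        return idx_l + idx_r, new_l + new_r

    order, rows = merge(root)
    by_input = {o: r for o, r in zip(order, rows)}
    return Alignment(ids, [by_input[i] for i in range(n)])


# ---------------------------------------------------------------------------
# Filters

def filter_short(sequences: Mapping[str, str],
                 min_len: int = 100) -> dict[str, str]:
    """Drop sequences strictly shorter than *min_len* residues."""
    kept = {}
    for name, seq in sequences.items():
        if len(seq) < min_len:
            log.info("filter_short: removed %s (%d aa < %d)", name,
                     len(seq), min_len)
        else:
            kept[name] = seq
    return kept


def trim_gap_columns(aln: Alignment, max_gap_fraction: float = 0.9,
                     ) -> tuple[Alignment, list[int]]:
    """Remove columns whose gap fraction exceeds the cutoff.

    Returns the trimmed alignment and the original indices of the kept
    columns (the column provenance map).  Idempotent at a fixed cutoff.
    """
    if not aln.rows:
        return aln, []
    mat = np.array([list(r) for r in aln.rows])
    gap_frac = (mat == "-").mean(axis=0)
    kept = [int(c) for c in np.flatnonzero(gap_frac <= max_gap_fraction)]
    if not kept:
        raise DegenerateAlignmentError(
            f"all {aln.length} columns exceed gap fraction "
            f"{max_gap_fraction}")
    rows = ["".join(mat[r, kept]) for r in range(len(aln.rows))]
    for name, row in zip(aln.ids, rows):
        if set(row) == {"-"}:
            raise DegenerateAlignmentError(
                f"row {name} lost every residue during trimming")
    return Alignment(list(aln.ids), rows), kept


# ---------------------------------------------------------------------------
# Redundancy reduction

@dataclass
class SimilarityMatrix:
    """Pairwise percent identity, symmetric, diagonal 100."""
    ids: list[str]
    values: np.ndarray

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10
    aligner.extend_gap_score = -0.5
    return aligner


def percent_identity(seq_a: str, seq_b: str,
                     aligner: Align.PairwiseAligner | None = None) -> float:
    """Identity over global-alignment columns, terminal gaps excluded."""
    if seq_a == seq_b:
        return 100.0
    if not seq_a or not seq_b:
        return 0.0
    aligner = aligner or _global_aligner()
    aln = aligner.align(seq_a, seq_b)[0]
    segs_a, segs_b = aln.aligned
    if len(segs_a) == 0:
        return 0.0
    matches = 0
    columns = 0
    for (sa, ea), (sb, eb) in zip(segs_a, segs_b):
        columns += ea - sa
        matches += sum(1 for x, y in zip(seq_a[sa:ea], seq_b[sb:eb])
                       if x == y)
    for k in range(1, len(segs_a)):
        columns += (segs_a[k][0] - segs_a[k - 1][1])
        columns += (segs_b[k][0] - segs_b[k - 1][1])
    return 100.0 * matches / columns if columns else 0.0


def identity_matrix(sequences: Mapping[str, str]) -> SimilarityMatrix:
    ids = list(sequences)
    aligner = _global_aligner()
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            pid = percent_identity(sequences[ids[i]], sequences[ids[j]],
                                   aligner)
            vals[i, j] = vals[j, i] = pid
    return SimilarityMatrix(ids, vals)


def decrease_redundancy(sequences: Mapping[str, str],
                        max_similarity: float = 99.0,
                        min_similarity: float = 30.0,
                        protected: frozenset | set = frozenset(),
                        ) -> dict[str, str]:
    """Remove near-identical and unrelated sequences.

    First, while any pair exceeds *max_similarity* percent identity, the
    shorter member is dropped (ties keep the lexicographically smaller id;
    *protected* ids are never dropped).  Second, any remaining unprotected
    sequence whose best identity to the other kept sequences falls below
    *min_similarity* is removed (evaluated simultaneously against the
    post-first-step set).
    """
    if not sequences:
        return {}
    sim = identity_matrix(sequences)
    ids = sim.ids
    alive = set(ids)
    pairs = [(i, j) for i in range(len(ids)) for j in range(i + 1, len(ids))
             if sim.values[i, j] > max_similarity]
    # deterministic processing order: most similar first
    pairs.sort(key=lambda p: (-sim.values[p[0], p[1]], ids[p[0]],
                              ids[p[1]]))
    for i, j in pairs:
        a, b = ids[i], ids[j]
        if a not in alive or b not in alive:
            continue
        if a in protected and b in protected:
            continue
        if a in protected:
            drop = b
        elif b in protected:
            drop = a
        else:
            la, lb = len(sequences[a]), len(sequences[b])
            if la != lb:
                drop = a if la < lb else b
            else:
                drop = max(a, b)  # keep the lexicographically smaller id
        alive.discard(drop)
        log.info("decrease_redundancy: removed %s (> %.3g%% identical)",
                 drop, max_similarity)
    if len(alive) > 1:
        snapshot = sorted(alive)
        to_drop = set()
        for a in snapshot:
            if a in protected:
                continue
            best = max(sim.get(a, b) for b in snapshot if b != a)
            if best < min_similarity:
                to_drop.add(a)
                log.info("decrease_redundancy: removed %s (best identity "
                         "%.3g%% < %.3g%%)", a, best, min_similarity)
        alive -= to_drop
    return {name: sequences[name] for name in ids if name in alive}
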