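"""Cross-species orthology (BBH) and synteny blocks (anchor chaining).

Ortholog pairs are reciprocal top-scoring protein matches (bidirectional
best hits) between the two species, optionally confirmed by co-membership
in a well-supported clade of the joint phylogeny.  At the corpus sizes of
a single gene family, exact local alignment replaces a heuristic search:
every query-subject pair is scored by Smith-Waterman-style dynamic
programming (optionally restricted by a shared-k-mer prefilter).

Synteny blocks are chains of collinear maximal exact k-mer anchors between
two nucleotide sequences (both strands), with a hard minimum block length
of 1,000 bp by default.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .phylo import Clade

log = logging.getLogger(__name__)

DEFAULT_MIN_BLOCK_LENGTH = 1000
DEFAULT_ANCHOR_K = 21
DEFAULT_MAX_ANCHOR_GAP = 5000


@dataclass(frozen=True)
class OrthologPair:
    gene_a: str
    gene_b: str
    bbh: bool = True
    clade_confirmed: bool | None = None  # None = untestable

    def key(self) -> tuple[str, str]:
        return (self.gene_a, self.gene_b)


@dataclass(frozen=True)
class Anchor:
    """A maximal exact match: *length* bp at pos_a / pos_b (0-based)."""
    pos_a: int
    pos_b: int
    length: int
    orientation: str  # "same" | "inverted"


@dataclass(frozen=True)
class SyntenyBlock:
    chrom_a: str
    start_a: int
    end_a: int
    chrom_b: str
    start_b: int
    end_b: int
    orientation: str
    length: int  # end_a - start_a + 1


# ---------------------------------------------------------------------------
# Protein similarity search

def _local_aligner(matrix: str | None = "BLOSUM62",
                   match: float = 2.0, mismatch: float = -1.0,
                   gap_open: float = -11.0, gap_extend: float = -1.0,
                   ) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(matrix)
    else:
        aligner.match_score = match
        aligner.mismatch_score = mismatch
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i:i + k] for i in range(max(len(seq) - k + 1, 1))}


def pairwise_similarity_search(queries: Mapping[str, str],
                               subjects: Mapping[str, str],
                               matrix: str | None = "BLOSUM62",
                               match: float = 2.0, mismatch: float = -1.0,
                               gap_open: float = -11.0,
                               gap_extend: float = -1.0,
                               prefilter_top: int | None = None,
                               prefilter_k: int = 5) -> pd.DataFrame:
    """Score every query against subjects by exact local alignment.

    Returns a hit table (query_id, subject_id, score, identity, rank) with
    dense per-query ranks; score ties are broken by percent identity, then
    lexicographic subject id.  Identity is computed lazily, only where
    needed to order ties.  With *prefilter_top* set, only the subjects
    sharing the most *prefilter_k*-mers with the query are aligned.
    """
    if not queries or not subjects:
        raise ValueError("query and subject sets must be non-empty")
    aligner = _local_aligner(matrix, match, mismatch, gap_open, gap_extend)
    subj_ids = sorted(subjects)
    subj_kmers = ({s: _kmer_set(subjects[s], prefilter_k)
                   for s in subj_ids} if prefilter_top else None)
    rows = []
    for q in sorted(queries):
        qseq = queries[q]
        targets = subj_ids
        if prefilter_top and prefilter_top < len(subj_ids):
            qk = _kmer_set(qseq, prefilter_k)
            scored = sorted(subj_ids,
                            key=lambda s: (-len(qk & subj_kmers[s]), s))
            targets = scored[:prefilter_top]
        hits = []
        for s in targets:
            score = float(aligner.score(qseq, subjects[s]))
            hits.append([q, s, score])
        # rank by score; resolve ties by identity, then id
        hits.sort(key=lambda h: (-h[2], h[1]))
        ident: dict[str, float] = {}
        k = 0
        while k < len(hits) - 1:
            j = k
            while j + 1 < len(hits) and hits[j + 1][2] == hits[k][2]:
                j += 1
            if j > k:
                for h in hits[k:j + 1]:
                    ident[h[1]] = _local_identity(aligner, qseq,
                                                  subjects[h[1]])
                hits[k:j + 1] = sorted(
                    hits[k:j + 1], key=lambda h: (-ident[h[1]], h[1]))
            k = j + 1
        for rank, h in enumerate(hits, start=1):
            rows.append((h[0], h[1], h[2], ident.get(h[1], np.nan), rank))
    return pd.DataFrame(rows, columns=["query_id", "subject_id", "score",
                                       "identity", "rank"])


def _local_identity(aligner: Align.PairwiseAligner, a: str, b: str) -> float:
    aln = aligner.align(a, b)[0]
    segs_a, segs_b = aln.aligned
    matches = columns = 0
    for (sa, ea), (sb, eb) in zip(segs_a, segs_b):
        columns += ea - sa
        matches += sum(1 for x, y in zip(a[sa:ea], b[sb:eb]) if x == y)
    for k in range(1, len(segs_a)):
        columns += (segs_a[k][0] - segs_a[k - 1][1])
        columns += (segs_b[k][0] - segs_b[k - 1][1])
    return 100.0 * matches / columns if columns else 0.0


def bidirectional_best_hits(hits_ab: pd.DataFrame,
                            hits_ba: pd.DataFrame) -> list[OrthologPair]:
    """Pairs (a, b) where each is the other's rank-1 hit."""
    best_ab = {r.query_id: r.subject_id
               for r in hits_ab[hits_ab["rank"] == 1].itertuples()}
    best_ba = {r.query_id: r.subject_id
               for r in hits_ba[hits_ba["rank"] == 1].itertuples()}
    pairs = []
    for a, b in sorted(best_ab.items()):
        if best_ba.get(b) == a:
            pairs.append(OrthologPair(a, b))
    return pairs


def confirm_orthologs_by_clade(pairs: Sequence[OrthologPair],
                               clades: Sequence[Clade],
                               tree_tips: set[str] | None = None,
                               ) -> list[OrthologPair]:
    """Flag pairs whose members co-occur in a well-supported clade.

    Pairs with a member absent from the tree are flagged untestable
    (``clade_confirmed=None``); unconfirmed pairs are retained, flagged
    False.
    """
    out = []
    for p in pairs:
        if tree_tips is not None and (p.gene_a not in tree_tips
                                      or p.gene_b not in tree_tips):
            out.append(OrthologPair(p.gene_a, p.gene_b, p.bbh, None))
            continue
        confirmed = any(p.gene_a in c.tips and p.gene_b in c.tips
                        for c in clades)
        out.append(OrthologPair(p.gene_a, p.gene_b, p.bbh, confirmed))
    return out


# ---------------------------------------------------------------------------
# k-mer anchors

_COMP = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def _kmer_codes(seq: str, k: int) -> np.ndarray:
    """2-bit-packed k-mer codes; k-mers containing non-ACGT get code -1."""
    trans = np.full(256, -1, dtype=np.int64)
    for i, b in enumerate("ACGT"):
        trans[ord(b)] = i
        trans[ord(b.lower())] = i
    codes = trans[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(codes) - k + 1
    if n <= 0:
        return np.empty(0, dtype=np.int64)
    val = np.zeros(n, dtype=np.int64)
    bad = np.zeros(n, dtype=bool)
    for j in range(k):
        window = codes[j:j + n]
        val = (val << 2) | np.maximum(window, 0)
        bad |= window < 0
    val[bad] = -1
    return val


try:
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is a hard dependency
    def _njit(*a, **k):
        return a[0] if a and callable(a[0]) else (lambda f: f)


@_njit(cache=True)
def _sorted_intersect(a, b):  # pragma: no cover - jitted
    """Common values of two sorted int64 arrays (linear merge)."""
    out = np.empty(min(a.size, b.size), dtype=np.int64)
    i = j = n = 0
    while i < a.size and j < b.size:
        if a[i] < b[j]:
            i += 1
        elif a[i] > b[j]:
            j += 1
        else:
            out[n] = a[i]
            n += 1
            i += 1
            j += 1
    return out[:n]


class _SeqIndex:
    """Sorted k-mer code index of one sequence (cacheable)."""

    def __init__(self, seq: str, k: int):
        self.codes = _kmer_codes(seq, k)
        self.order = np.argsort(self.codes, kind="stable")
        self.sorted = self.codes[self.order]
        valid = self.sorted >= 0
        sv = self.sorted[valid]
        if sv.size:
            keep = np.empty(sv.size, dtype=bool)
            keep[0] = True
            np.not_equal(sv[1:], sv[:-1], out=keep[1:])
            self.unique = sv[keep]
        else:
            self.unique = sv


def _match_positions(ia: "_SeqIndex", ib: "_SeqIndex",
                     max_occurrence: int) -> tuple[np.ndarray, np.ndarray]:
    """All (pos_a, pos_b) with equal k-mer codes, repeat-capped.

    Only the k-mers common to both sequences (typically a tiny fraction)
    are expanded to positions, so a pair of large sequences with little
    homology costs little beyond the cached per-sequence sort.
    """
    if len(ib.unique) == 0 or len(ia.unique) == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z
    common = _sorted_intersect(ia.unique, ib.unique)
    if common.size == 0:
        z = np.empty(0, dtype=np.int64)
        return z, z
    pos_a_parts, pos_b_parts = [], []
    la = np.searchsorted(ia.sorted, common, side="left")
    ra = np.searchsorted(ia.sorted, common, side="right")
    lb = np.searchsorted(ib.sorted, common, side="left")
    rb = np.searchsorted(ib.sorted, common, side="right")
    for i in range(common.size):
        na, nb = ra[i] - la[i], rb[i] - lb[i]
        if na > max_occurrence or nb > max_occurrence:
            continue
        a_pos = ia.order[la[i]:ra[i]]
        b_pos = ib.order[lb[i]:rb[i]]
        pos_a_parts.append(np.repeat(a_pos, nb))
        pos_b_parts.append(np.tile(b_pos, na))
    if not pos_a_parts:
        z = np.empty(0, dtype=np.int64)
        return z, z
    return np.concatenate(pos_a_parts), np.concatenate(pos_b_parts)


def _merge_diagonal_runs(pos_a: np.ndarray, pos_b: np.ndarray, k: int,
                         orientation: str, len_b: int) -> list[Anchor]:
    """Merge overlapping same-diagonal seed matches into maximal runs."""
    if pos_a.size == 0:
        return []
    diag = pos_a - pos_b
    order = np.lexsort((pos_a, diag))
    pos_a, pos_b, diag = pos_a[order], pos_b[order], diag[order]
    breaks = np.flatnonzero((np.diff(diag) != 0)
                            | (np.diff(pos_a) > k)) + 1
    anchors = []
    for seg in np.split(np.arange(pos_a.size), breaks):
        a0 = int(pos_a[seg[0]])
        a1 = int(pos_a[seg[-1]]) + k  # exclusive
        b0 = int(pos_b[seg[0]])
        length = a1 - a0
        if orientation == "same":
            anchors.append(Anchor(a0, b0, length, "same"))
        else:
            # b positions refer to the reverse complement; convert the run
            # start back to forward-strand coordinates of sequence B
            b_end_rc = int(pos_b[seg[-1]]) + k
            anchors.append(Anchor(a0, len_b - b_end_rc, length, "inverted"))
    return anchors


def find_anchors(seq_a: str, seq_b: str, k: int = DEFAULT_ANCHOR_K,
                 max_occurrence: int = 10,
                 index_a: _SeqIndex | None = None,
                 index_b: tuple[_SeqIndex, _SeqIndex] | None = None,
                 ) -> list[Anchor]:
    """Maximal exact shared k-mer runs between two sequences, both strands.

    k-mers occurring more than *max_occurrence* times in either sequence
    (repeats) are skipped.  Positions are 0-based on the forward strands.
    Pre-built :class:`_SeqIndex` objects (forward for A; forward and
    reverse-complement for B) may be supplied to amortise indexing across
    many pairs.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    ia = index_a or _SeqIndex(seq_a, k)
    if index_b is None:
        index_b = (_SeqIndex(seq_b, k), _SeqIndex(_revcomp(seq_b), k))
    anchors: list[Anchor] = []
    for orientation, ib in zip(("same", "inverted"), index_b):
        pa, pb = _match_positions(ia, ib, max_occurrence)
        anchors.extend(_merge_diagonal_runs(pa, pb, k, orientation,
                                            len(seq_b)))
    anchors.sort(key=lambda a: (a.pos_a, a.pos_b, a.orientation))
    return anchors


def chain_synteny_blocks(anchors: Sequence[Anchor],
                         max_anchor_gap: int = DEFAULT_MAX_ANCHOR_GAP,
                         min_block_length: int = DEFAULT_MIN_BLOCK_LENGTH,
                         chrom_a: str = "a", chrom_b: str = "b",
                         ) -> list[SyntenyBlock]:
    """Chain collinear anchors into blocks; enforce the length floor.

    Same-orientation anchors chain when the gaps on both sequences are
    <= *max_anchor_gap* and the order is collinear (b advances with a;
    reversed for inverted anchors).  Blocks spanning fewer than
    *min_block_length* bp on sequence A are discarded.  Coordinates are
    1-based inclusive.
    """
    blocks: list[SyntenyBlock] = []
    for orientation in ("same", "inverted"):
        subset = sorted((a for a in anchors if a.orientation == orientation),
                        key=lambda a: (a.pos_a, a.pos_b))
        chain: list[Anchor] = []
        for anchor in subset + [None]:
            if anchor is not None and chain:
                prev = chain[-1]
                gap_a = anchor.pos_a - (prev.pos_a + prev.length)
                if orientation == "same":
                    gap_b = anchor.pos_b - (prev.pos_b + prev.length)
                else:
                    gap_b = prev.pos_b - (anchor.pos_b + anchor.length)
                if (-prev.length < gap_a <= max_anchor_gap
                        and -prev.length < gap_b <= max_anchor_gap):
                    chain.append(anchor)
                    continue
            if chain:
                start_a = chain[0].pos_a + 1
                end_a = chain[-1].pos_a + chain[-1].length
                bs = min(a.pos_b for a in chain) + 1
                be = max(a.pos_b + a.length for a in chain)
                length = end_a - start_a + 1
                if length >= min_block_length:
                    blocks.append(SyntenyBlock(chrom_a, start_a, end_a,
                                               chrom_b, bs, be,
                                               orientation, length))
            chain = [anchor] if anchor is not None else []
    blocks.sort(key=lambda b: (b.start_a, b.start_b, b.orientation))
    return blocks


def genome_synteny(genome_a: Mapping[str, str], genome_b: Mapping[str, str],
                   k: int = DEFAULT_ANCHOR_K,
                   max_anchor_gap: int = DEFAULT_MAX_ANCHOR_GAP,
                   min_block_length: int = DEFAULT_MIN_BLOCK_LENGTH,
                   ) -> list[SyntenyBlock]:
    """Genome-vs-genome blocks over all chromosome pairs."""
    blocks = []
    idx_a = {ca: _SeqIndex(genome_a[ca], k) for ca in sorted(genome_a)}
    idx_b = {cb: (_SeqIndex(genome_b[cb], k),
                  _SeqIndex(_revcomp(genome_b[cb]), k))
             for cb in sorted(genome_b)}
    for ca in sorted(genome_a):
        for cb in sorted(genome_b):
            anchors = find_anchors(genome_a[ca], genome_b[cb], k,
                                   index_a=idx_a[ca], index_b=idx_b[cb])
            blocks.extend(chain_synteny_blocks(
                anchors, max_anchor_gap, min_block_length, ca, cb))
    return blocks


def gene_genome_synteny(genes: Mapping[str, str],
                        genome: Mapping[str, str],
                        k: int = DEFAULT_ANCHOR_K,
                        max_anchor_gap: int = DEFAULT_MAX_ANCHOR_GAP,
                        min_block_length: int = DEFAULT_MIN_BLOCK_LENGTH,
                        ) -> list[SyntenyBlock]:
    """Gene-vs-genome mode: each gene's matches in the other genome.

    A gene matching several loci yields one block per locus.
    """
    blocks = []
    idx = {chrom: (_SeqIndex(genome[chrom], k),
                   _SeqIndex(_revcomp(genome[chrom]), k))
           for chrom in sorted(genome)}
    for gid in sorted(genes):
        for chrom in sorted(genome):
            anchors = find_anchors(genes[gid], genome[chrom], k,
                                   index_b=idx[chrom])
            blocks.extend(chain_synteny_blocks(
                anchors, max_anchor_gap, min_block_length, gid, chrom))
    return blocks


def blocks_to_frame(blocks: Sequence[SyntenyBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [(b.chrom_a, b.start_a, b.end_a, b.chrom_b, b.start_b, b.end_b,
          b.orientation, b.length) for b in blocks],
        columns=["chrom_a", "start_a", "end_a", "chrom_b", "start_b",
                 "end_b", "orientation", "length"])
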