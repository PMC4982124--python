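"""Distance phylogenies of kinase domains and clade-based classification.

Trees are estimated by neighbor-joining on Poisson-corrected p-distances
computed from the kinase-domain alignment, with nonparametric bootstrap
(column resampling) providing per-edge support.  Queries inherit the
subfamily group (I-XVI) of the smallest well-supported clade they share
with label-homogeneous reference tips, mirroring the practice of
classifying receptor kinases by co-clustering with labelled exemplars;
group XII is subsequently split into XIIa/XIIb by the same rule restricted
to XII exemplars.  An externally estimated tree in Newick format (supports
as internal-node labels) can be substituted for the built-in estimate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .align import Alignment

log = logging.getLogger(__name__)

DEFAULT_SUPPORT_THRESHOLD = 0.70
DEFAULT_D_MAX = 5.0


@dataclass
class DistanceMatrix:
    ids: list[str]
    values: np.ndarray  # symmetric, zero diagonal

    def validate(self) -> None:
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-8):
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")


@dataclass
class TreeNode:
    name: str | None = None
    length: float = 0.0
    support: float | None = None
    children: list["TreeNode"] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def tips(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf()]


@dataclass
class PhyloTree:
    """Unrooted tree stored with an arbitrary (trifurcating) root."""
    root: TreeNode
    outgroup_ids: frozenset = frozenset()

    @property
    def tip_names(self) -> list[str]:
        return self.root.tips()

    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.root.walk()
                if n is not self.root and not n.is_leaf()]

    def bipartitions(self) -> dict[frozenset, TreeNode]:
        """Canonical bipartition side -> internal node defining the edge.

        The canonical side is the one *not* containing the anchor (the
        lexicographically smallest tip), so bipartitions compare across
        trees over the same tips.
        """
        all_tips = frozenset(self.tip_names)
        anchor = min(all_tips)
        out: dict[frozenset, TreeNode] = {}
        for node in self.internal_nodes():
            below = frozenset(node.tips())
            side = all_tips - below if anchor in below else below
            if 0 < len(side) < len(all_tips):
                out[side] = node
        return out

    def edge_sides(self) -> list[tuple[frozenset, frozenset, float | None]]:
        """(tips below, tips above, support) per internal edge."""
        all_tips = frozenset(self.tip_names)
        return [(frozenset(n.tips()), all_tips - frozenset(n.tips()),
                 n.support) for n in self.internal_nodes()]

    def newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf():
                return f"{node.name}:{node.length:.6f}"
            inner = ",".join(fmt(c) for c in node.children)
            label = "" if node.support is None else f"{node.support:.4f}"
            return f"({inner}){label}:{node.length:.6f}"
        inner = ",".join(fmt(c) for c in self.root.children)
        return f"({inner});"

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.newick() + "\n")


def read_newick(path) -> PhyloTree:
    """Read a Newick tree (internal-node labels read as supports)."""
    import dendropy
    tree = dendropy.Tree.get(path=str(path), schema="newick")

    def convert(dnode) -> TreeNode:
        node = TreeNode(
            name=dnode.taxon.label.replace(" ", "_") if dnode.taxon else None,
            length=dnode.edge.length or 0.0)
        if dnode.child_nodes():
            label = dnode.label
            if label is not None:
                try:
                    node.support = float(label)
                except ValueError:
                    pass
            node.children = [convert(c) for c in dnode.child_nodes()]
        return node

    return PhyloTree(root=convert(tree.seed_node))


# ---------------------------------------------------------------------------
# Distances

def _encode_alignment(aln: Alignment) -> np.ndarray:
    mat = np.frombuffer("".join(aln.rows).encode(),
                        dtype=np.uint8).reshape(len(aln.rows), aln.length)
    return mat


def _distances_from_codes(mat: np.ndarray, ids: list[str],
                          d_max: float, strict: bool) -> np.ndarray:
    gap = mat != ord("-")
    shared = gap[:, None, :] & gap[None, :, :]
    n_shared = shared.sum(axis=2)
    diff = ((mat[:, None, :] != mat[None, :, :]) & shared).sum(axis=2)
    if strict and (n_shared == 0).any():
        i, j = np.argwhere(n_shared == 0)[0]
        if i != j:
            raise ValueError(f"sequences {ids[i]!r} and {ids[j]!r} share "
                             "no non-gap columns")
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(n_shared > 0, diff / np.maximum(n_shared, 1), 1.0)
        d = -np.log(1.0 - p)
    saturated = ~np.isfinite(d)
    if saturated.any() and strict:
        log.warning("%d sequence pairs are saturated (p >= 1); distance "
                    "capped at %.3g", int(saturated.sum()) // 2, d_max)
    d[saturated] = d_max
    d = np.minimum(d, d_max)
    np.fill_diagonal(d, 0.0)
    return d


def compute_distances(aln: Alignment, d_max: float = DEFAULT_D_MAX,
                      ) -> DistanceMatrix:
    """Poisson-corrected distances d = -ln(1 - p) over shared columns.

    p is the mismatch proportion over columns where both rows are
    ungapped; saturated pairs (p >= 1) are capped at *d_max* with a
    warning, and a pair with zero shared columns is an error.
    """
    if len(aln) < 2:
        raise ValueError("need at least two aligned rows")
    mat = _encode_alignment(aln)
    d = _distances_from_codes(mat, aln.ids, d_max, strict=True)
    return DistanceMatrix(list(aln.ids), d)


# ---------------------------------------------------------------------------
# Neighbor joining

def build_nj_tree(dm: DistanceMatrix) -> PhyloTree:
    """Standard neighbor-joining with deterministic tie-breaks.

    Q-matrix ties are broken by the lexicographically smallest pair of
    cluster representatives (each cluster represented by its smallest tip
    id).  Negative branch lengths are clamped to zero with the deficit
    moved onto the sister branch, preserving the pair's summed length.
    """
    dm.validate()
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    size = 2 * n - 2
    D = np.zeros((size, size))
    D[:n, :n] = dm.values
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    reps: list[str] = list(dm.ids)
    active = list(range(n))
    nxt = n
    while len(active) > 3:
        m = len(active)
        idx = np.array(active)
        Dsub = D[np.ix_(idx, idx)]
        r = Dsub.sum(axis=1)
        Q = (m - 2) * Dsub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        tol = 1e-9 * max(1.0, abs(qmin))
        cand = np.argwhere(Q <= qmin + tol)
        best = None
        for a, b in cand:
            if a >= b:
                continue
            key = tuple(sorted((reps[active[a]], reps[active[b]])))
            if best is None or key < best[0]:
                best = (key, int(a), int(b))
        _, i, j = best
        ai, aj = active[i], active[j]
        d_ij = Dsub[i, j]
        li = 0.5 * d_ij + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d_ij - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode(children=[nodes[ai], nodes[aj]])
        nodes[ai].length, nodes[aj].length = li, lj
        for k in active:
            if k in (ai, aj):
                continue
            dk = 0.5 * (D[ai, k] + D[aj, k] - d_ij)
            D[nxt, k] = D[k, nxt] = max(dk, 0.0)
        nodes.append(parent)
        reps.append(min(reps[ai], reps[aj]))
        active = [k for k in active if k not in (ai, aj)] + [nxt]
        nxt += 1
    a, b, c = active
    la = 0.5 * (D[a, b] + D[a, c] - D[b, c])
    lb = 0.5 * (D[a, b] + D[b, c] - D[a, c])
    lc = 0.5 * (D[a, c] + D[b, c] - D[a, b])
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    root = TreeNode(children=[nodes[a], nodes[b], nodes[c]])
    return PhyloTree(root=root)


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


# ---------------------------------------------------------------------------
# Bootstrap support

def bootstrap_support(aln: Alignment, n_replicates: int = 100,
                      seed: int | np.random.Generator | None = None,
                      d_max: float = DEFAULT_D_MAX) -> PhyloTree:
    """NJ tree with bootstrap bipartition support.

    Columns are resampled with replacement *n_replicates* times; the
    support of an internal edge is the fraction of replicate trees
    containing the same bipartition.  Saturated or non-overlapping pairs
    in replicates are capped at *d_max* rather than erroring out.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    base = build_nj_tree(compute_distances(aln, d_max))
    mat = _encode_alignment(aln)
    counts: dict[frozenset, int] = {
        side: 0 for side in base.bipartitions()}
    L = aln.length
    for _ in range(n_replicates):
        cols = rng.integers(0, L, size=L)
        sub = mat[:, cols]
        d = _distances_from_codes(sub, aln.ids, d_max, strict=False)
        rep = build_nj_tree(DistanceMatrix(list(aln.ids), d))
        for side in rep.bipartitions():
            if side in counts:
                counts[side] += 1
    for side, node in base.bipartitions().items():
        node.support = counts[side] / n_replicates
    return base


# ---------------------------------------------------------------------------
# Clade-based subfamily assignment

@dataclass(frozen=True)
class Clade:
    tips: frozenset
    support: float
    parent: int | None = None  # index of the smallest enclosing clade


def find_well_supported_clades(tree: PhyloTree,
                               support_threshold: float =
                               DEFAULT_SUPPORT_THRESHOLD) -> list[Clade]:
    """Clades (rooted-subtree tip sets) whose edge support > threshold.

    Nested clades carry a ``parent`` link to their smallest enclosing
    well-supported clade.
    """
    raw = [(frozenset(n.tips()), n.support) for n in tree.internal_nodes()
           if n.support is not None and n.support > support_threshold]
    raw.sort(key=lambda t: (len(t[0]), sorted(t[0])))
    clades = []
    for k, (tips, support) in enumerate(raw):
        parent = None
        for k2 in range(k + 1, len(raw)):
            if tips < raw[k2][0]:
                parent = k2
                break
        clades.append(Clade(tips, support, parent))
    return clades


def _sides_containing(tree: PhyloTree):
    """Per internal edge, (side tips, support) for both orientations."""
    out = []
    for below, above, support in tree.edge_sides():
        if support is None:
            continue
        out.append((below, support))
        out.append((above, support))
    return out


def assign_subfamily_groups(tree: PhyloTree,
                            reference_labels: Mapping[str, str],
                            support_threshold: float =
                            DEFAULT_SUPPORT_THRESHOLD) -> dict[str, str]:
    """Label query tips by co-clustering with labelled reference tips.

    Each unlabelled tip takes the label of the smallest clade (bipartition
    side) containing it whose defining edge has support > threshold and
    whose reference tips all share one label.  Tips in no such clade are
    ``unassigned``.  Reference tips always keep their prior label.
    """
    tips = set(tree.tip_names)
    refs = {t: lab for t, lab in reference_labels.items() if t in tips}
    if not refs:
        raise ValueError("tree contains no labelled reference tips")
    sides = sorted(_sides_containing(tree), key=lambda t: len(t[0]))
    assignment: dict[str, str] = {}
    for tip in sorted(tips):
        if tip in refs:
            assignment[tip] = refs[tip]
            continue
        label = "unassigned"
        for side, support in sides:
            if tip not in side or support <= support_threshold:
                continue
            labels = {refs[t] for t in side if t in refs}
            if len(labels) == 1:
                label = labels.pop()
                break
        assignment[tip] = label
    return assignment


def split_group_xii(tree: PhyloTree, assignment: Mapping[str, str],
                    reference_labels: Mapping[str, str],
                    support_threshold: float = DEFAULT_SUPPORT_THRESHOLD,
                    ) -> dict[str, str]:
    """Refine XII tips into XIIa / XIIb by clade homogeneity.

    *reference_labels* carries the fine exemplar labels (XIIa / XIIb).
    With no XIIb exemplar in the tree every XII tip becomes XIIa, with a
    warning.
    """
    tips = set(tree.tip_names)
    fine_refs = {t: lab for t, lab in reference_labels.items()
                 if t in tips and lab in ("XIIa", "XIIb")}
    out = dict(assignment)
    xii_tips = [t for t, lab in assignment.items()
                if lab == "XII" and t in tips]
    if not any(lab == "XIIb" for lab in fine_refs.values()):
        log.warning("no XIIb reference exemplar in tree; labelling all "
                    "XII tips XIIa")
        for t in xii_tips:
            out[t] = "XIIa"
        return out
    sides = sorted(_sides_containing(tree), key=lambda t: len(t[0]))
    for tip in xii_tips:
        if tip in fine_refs:
            out[tip] = fine_refs[tip]
            continue
        label = "unassigned"
        for side, support in sides:
            if tip not in side or support <= support_threshold:
                continue
            labels = {fine_refs[t] for t in side if t in fine_refs}
            if len(labels) == 1:
                label = labels.pop()
                break
        out[tip] = label
    return out
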