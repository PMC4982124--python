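"""Chromosomal arrangement: gene clusters and tandem-duplicated paralogs.

Family genes are mapped onto chromosomes; genes whose inter-gene gap is at
most 200 kb are chained into clusters, and co-clustered genes that also
fall in one well-supported phylogenetic clade are called tandem-duplicated
paralogs.  A deterministic plain-text chromosome map stands in for a
graphical map renderer.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import GeneLocus
from .phylo import Clade

DEFAULT_CLUSTER_WINDOW = 200_000


@dataclass(frozen=True)
class GeneCluster:
    cluster_id: str
    chromosome: str
    members: tuple[str, ...]   # ordered along the chromosome
    span: tuple[int, int]


@dataclass(frozen=True)
class TandemParalogSet:
    members: tuple[str, ...]
    cluster_id: str
    supporting_clade: frozenset


def detect_clusters(loci: Iterable[GeneLocus],
                    window: int = DEFAULT_CLUSTER_WINDOW,
                    ) -> list[GeneCluster]:
    """Single-linkage chaining of genes within *window* bp per chromosome.

    The inter-gene distance is the gap (next start - previous cluster end);
    genes with gap <= window chain transitively.  Singleton genes form no
    cluster.  Order-invariant: loci are sorted internally.
    """
    seen: set[str] = set()
    by_chrom: dict[str, list[GeneLocus]] = defaultdict(list)
    for locus in loci:
        if locus.gene_id in seen:
            raise ValueError(f"duplicate gene id {locus.gene_id!r}")
        seen.add(locus.gene_id)
        by_chrom[locus.chromosome].append(locus)
    clusters: list[GeneCluster] = []
    serial = 0
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        current: list[GeneLocus] = []
        current_end = None
        for g in genes + [None]:
            if g is not None and (current_end is None
                                  or g.start - current_end <= window):
                current.append(g)
                current_end = max(current_end or 0, g.end)
                continue
            if len(current) >= 2:
                serial += 1
                clusters.append(GeneCluster(
                    f"CL{serial:03d}", chrom,
                    tuple(x.gene_id for x in current),
                    (min(x.start for x in current),
                     max(x.end for x in current))))
            if g is not None:
                current = [g]
                current_end = g.end
    return clusters


def clustered_genes(clusters: Iterable[GeneCluster]) -> set[str]:
    return {m for c in clusters for m in c.members}


def identify_tandem_paralogs(clusters: Sequence[GeneCluster],
                             clades: Sequence[Clade],
                             ) -> list[TandemParalogSet]:
    """Co-clustered genes lying in one well-supported clade.

    For each clade x cluster with >= 2 shared genes a candidate set forms;
    each gene joins at most one set — the candidate with the largest clade
    wins, ties broken by higher support then deterministically by id.
    """
    candidates = []
    for cluster in clusters:
        members = set(cluster.members)
        for clade in clades:
            shared = members & clade.tips
            if len(shared) >= 2:
                candidates.append((len(clade.tips), clade.support,
                                   cluster, clade, shared))
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2].cluster_id,
                                   sorted(t[4])))
    used: set[str] = set()
    out: list[TandemParalogSet] = []
    for _, _, cluster, clade, shared in candidates:
        avail = [g for g in cluster.members
                 if g in shared and g not in used]
        if len(avail) >= 2:
            used.update(avail)
            out.append(TandemParalogSet(tuple(avail), cluster.cluster_id,
                                        clade.tips))
    return out


def cluster_composition_stats(clusters: Sequence[GeneCluster],
                              tandem_sets: Sequence[TandemParalogSet],
                              family_genes: Iterable[str],
                              ) -> dict[str, float]:
    """Summary of the clustered fraction of a gene family."""
    family_genes = set(family_genes)
    in_clusters = clustered_genes(clusters) & family_genes
    tandem_genes = {g for s in tandem_sets for g in s.members}
    clusters_with_tandem = {s.cluster_id for s in tandem_sets}
    n_clusters = len(clusters)
    return {
        "n_genes": len(family_genes),
        "n_genes_in_clusters": len(in_clusters),
        "fraction_genes_in_clusters":
            len(in_clusters) / len(family_genes) if family_genes else 0.0,
        "n_clusters": n_clusters,
        "n_tandem_genes": len(tandem_genes),
        "fraction_clusters_with_tandem":
            len(clusters_with_tandem) / n_clusters if n_clusters else 0.0,
    }


# ---------------------------------------------------------------------------
# Text chromosome map

def render_chromosome_map(loci: Sequence[GeneLocus],
                          clusters: Sequence[GeneCluster] = (),
                          chromosome_lengths: Mapping[str, int] | None = None,
                          ) -> str:
    """Deterministic text map: one track per chromosome, genes in order.

    Lines are tab-separated (``chromosome  start  end  strand  gene
    cluster-or--``) so the map parses back losslessly.
    """
    cluster_of = {m: c.cluster_id for c in clusters for m in c.members}
    by_chrom: dict[str, list[GeneLocus]] = defaultdict(list)
    for locus in loci:
        if chromosome_lengths is not None:
            length = chromosome_lengths.get(locus.chromosome)
            if length is not None and locus.end > length:
                raise ValueError(
                    f"gene {locus.gene_id} ends at {locus.end}, beyond "
                    f"{locus.chromosome} length {length}")
        by_chrom[locus.chromosome].append(locus)
    lines = []
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda g: (g.start, g.gene_id))
        length = (chromosome_lengths or {}).get(chrom, "")
        lines.append(f"# {chrom}\t{length}\t{len(genes)} genes")
        for g in genes:
            lines.append(f"{chrom}\t{g.start}\t{g.end}\t{g.strand}\t"
                         f"{g.gene_id}\t{cluster_of.get(g.gene_id, '-')}")
    return "\n".join(lines) + ("\n" if lines else "")


def parse_chromosome_map(text: str) -> list[GeneLocus]:
    """Invert :func:`render_chromosome_map` (gene lines only)."""
    out = []
    for line in text.splitlines():
        if not line or line.startswith("#"):
            continue
        chrom, start, end, strand, gene, _ = line.split("\t")
        out.append(GeneLocus(gene, chrom, int(start), int(end), strand))
    return out


def clusters_to_frame(clusters: Sequence[GeneCluster]) -> pd.DataFrame:
    return pd.DataFrame(
        [(c.cluster_id, c.chromosome, ",".join(c.members),
          c.span[0], c.span[1]) for c in clusters],
        columns=["cluster_id", "chromosome", "members", "span_start",
                 "span_end"])
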