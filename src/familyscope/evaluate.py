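"""Truth-recovery metrics on synthetic datasets.

Helpers that run the pipeline's stages in memory against a generated
:class:`~familyscope.simulate.Dataset` and score the results against its
truth table: tier counts, subfamily-group recovery, motif confusion,
BBH precision/recall.  They are the measurement layer used by the
acceptance checks and by ad-hoc benchmarking.
"""

from __future__ import annotations

import numpy as np

from . import align as al
from . import classify as cl
from . import homology as ho
from . import motifs as mo
from . import phylo as ph
from .io import ProteinRecord
from .simulate import Dataset


def bundle_records(dataset: Dataset, species: str) -> list[ProteinRecord]:
    bundle = dataset.species[species]
    return [ProteinRecord(pid, species, seq, pid.rsplit(".t", 1)[0],
                          pid.endswith(".t1"))
            for pid, seq in bundle.proteome.items()]


def classify_species(dataset: Dataset, species: str):
    """Primary-transcript records, tier calls and KD units for a species."""
    bundle = dataset.species[species]
    primary = cl.filter_primary_transcripts(
        bundle_records(dataset, species))
    classified = cl.classify_proteins(primary, bundle.domains)
    lrr = {c.protein_id for c in classified if c.tier == "LRR-RLK"}
    units = cl.extract_kinase_domains(
        [r for r in primary if r.protein_id in lrr], bundle.domains)
    return primary, classified, units


def reference_units(dataset: Dataset):
    """Reference KD units and their unit-level group labels."""
    ref = dataset.reference
    records = [ProteinRecord(pid, "reference", seq, pid)
               for pid, seq in ref.proteome.items()]
    units = cl.extract_kinase_domains(records, ref.domains)
    labels = {u.unit_id: ref.labels[u.protein_id] for u in units}
    return units, labels


def aligned_kds(dataset: Dataset, species: str,
                min_len: int = 100, max_gap_fraction: float = 0.9,
                redundancy: tuple[float, float] = (99.0, 30.0)):
    """Filtered KD alignment of one species' queries plus the references."""
    _, _, units = classify_species(dataset, species)
    ref_units, ref_labels = reference_units(dataset)
    seqs = cl.unit_sequences(units)
    seqs.update(cl.unit_sequences(ref_units))
    seqs = al.filter_short(seqs, min_len)
    seqs = al.decrease_redundancy(seqs, *redundancy,
                                  protected=frozenset(ref_labels))
    aln = al.progressive_align(seqs)
    aln, _ = al.trim_gap_columns(aln, max_gap_fraction)
    return aln, units, ref_labels


def subfamily_recovery(dataset: Dataset, species: str, seed: int,
                       n_replicates: int = 100,
                       support_threshold: float = 0.70,
                       ) -> tuple[int, int]:
    """(correctly labelled query KDs, total query KDs with truth)."""
    aln, units, ref_labels = aligned_kds(dataset, species)
    tree = ph.bootstrap_support(aln, n_replicates,
                                np.random.default_rng(seed))
    coarse = {k: ("XII" if v in ("XIIa", "XIIb") else v)
              for k, v in ref_labels.items()}
    assignment = ph.assign_subfamily_groups(tree, coarse,
                                            support_threshold)
    assignment = ph.split_group_xii(tree, assignment, ref_labels,
                                    support_threshold)
    truth = dataset.truth
    n = good = 0
    for u in units:
        gene = u.protein_id.rsplit(".t", 1)[0]
        if gene in truth.family_of_gene:
            n += 1
            good += (assignment.get(u.unit_id)
                     == truth.subfamily_of_gene(gene))
    return good, n


def motif_confusion(dataset: Dataset, species: str) -> dict:
    """Counts of (planted class -> called class) for one species."""
    aln, units, ref_labels = aligned_kds(dataset, species)
    anchor = next(r for r in sorted(ref_labels)
                  if r in aln.ids and aln.degapped(r).count("HRD") == 1)
    calls = {c.protein_id: c for c in mo.call_motifs(aln, anchor)}
    truth = dataset.truth
    confusion: dict[tuple[str, str], int] = {}
    for u in units:
        gene = u.protein_id.rsplit(".t", 1)[0]
        if gene in truth.motif_class_of_gene:
            key = (truth.motif_class_of_gene[gene],
                   calls[u.unit_id].motif_class)
            confusion[key] = confusion.get(key, 0) + 1
    return confusion


def bbh_metrics(dataset: Dataset, prefilter_top: int | None = 40,
                ) -> tuple[float, float, int]:
    """(precision, recall, n planted) of BBH ortholog recovery."""
    prot = {sp: {p: s for p, s in dataset.species[sp].proteome.items()
                 if p.endswith(".t1")}
            for sp in ("speciesA", "speciesB")}
    hits_ab = ho.pairwise_similarity_search(prot["speciesA"],
                                            prot["speciesB"],
                                            prefilter_top=prefilter_top)
    hits_ba = ho.pairwise_similarity_search(prot["speciesB"],
                                            prot["speciesA"],
                                            prefilter_top=prefilter_top)
    pairs = ho.bidirectional_best_hits(hits_ab, hits_ba)
    got = {(p.gene_a.rsplit(".t", 1)[0], p.gene_b.rsplit(".t", 1)[0])
           for p in pairs}
    want = set(map(tuple, dataset.truth.ortholog_pairs))
    tp = len(got & want)
    precision = tp / len(got) if got else 1.0
    recall = tp / len(want) if want else 1.0
    return precision, recall, len(want)
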