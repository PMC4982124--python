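"""Domain-architecture classification: kinases, TM kinases and LRR-RLKs.

A receptor-like kinase survey proceeds as a funnel over the proteome: first
every protein with a kinase domain (Pfam PF00069 / PF07714), then those
also carrying a transmembrane helix, then those additionally bearing
leucine-rich repeats — the putative LRR-RLKs.  Receptor-like cytoplasmic
kinases fall out at the TM step; proteins with LRRs but no kinase domain
never enter the funnel.  Splice variants are removed up front so each gene
contributes one protein.

Kinase-domain extraction resolves proteins whose kinase annotation is split
into several hits: nearby fragments of one truncated domain are merged,
genuinely tandem kinase domains are kept as separate units.
"""

from __future__ import annotations

import logging
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from ._templates import KINASE_ACCESSIONS, LRR_ACCESSIONS, TM_ACCESSION
from .io import DomainAnnotation, ProteinRecord

log = logging.getLogger(__name__)

TIERS = ("none", "kinase", "TM-kinase", "LRR-RLK")

DEFAULT_KINASE_ACCESSIONS = frozenset(KINASE_ACCESSIONS)
DEFAULT_LRR_ACCESSIONS = frozenset(LRR_ACCESSIONS)
DEFAULT_TM_ACCESSION = TM_ACCESSION

# Automatic stand-in for case-by-case curation of split kinase hits: two
# hits merge iff the gap between them is small and the merged span stays
# below ~1.5x a typical ~300 aa protein-kinase domain.
DEFAULT_MERGE_GAP_MAX = 100
DEFAULT_MERGED_LEN_MAX = 450


@dataclass(frozen=True)
class ClassifiedProtein:
    protein_id: str
    tier: str  # one of TIERS; tiers nest: LRR-RLK < TM-kinase < kinase


@dataclass(frozen=True)
class KinaseDomainUnit:
    """One (possibly merged) kinase-domain unit on a protein."""
    protein_id: str
    unit_index: int
    start: int
    end: int
    sequence: str
    merged_from: int

    @property
    def unit_id(self) -> str:
        return (self.protein_id if self.unit_index == 0 and self.single
                else f"{self.protein_id}/kd{self.unit_index + 1}")

    single: bool = True


def filter_primary_transcripts(
        records: Iterable[ProteinRecord]) -> list[ProteinRecord]:
    """Keep one protein per gene: the primary transcript.

    A gene whose transcripts are all flagged non-primary retains its
    longest protein (ties broken by lexicographic protein id) with a
    warning.
    """
    by_gene: dict[str, list[ProteinRecord]] = defaultdict(list)
    for rec in records:
        by_gene[rec.gene_id].append(rec)
    kept: list[ProteinRecord] = []
    for gene_id, recs in by_gene.items():
        primary = [r for r in recs if r.is_primary_transcript]
        if primary:
            if len(primary) > 1:
                log.warning("gene %s has %d primary transcripts; keeping "
                            "the longest", gene_id, len(primary))
            kept.append(max(primary,
                            key=lambda r: (len(r), r.protein_id)))
        else:
            log.warning("gene %s has no primary-flagged transcript; "
                        "keeping the longest protein", gene_id)
            kept.append(max(recs, key=lambda r: (len(r), r.protein_id)))
    return kept


def classify_proteins(records: Iterable[ProteinRecord],
                      annotations: Iterable[DomainAnnotation],
                      lrr_accessions: frozenset = DEFAULT_LRR_ACCESSIONS,
                      kinase_accessions: frozenset =
                      DEFAULT_KINASE_ACCESSIONS,
                      tm_accession: str = DEFAULT_TM_ACCESSION,
                      ) -> list[ClassifiedProtein]:
    """Assign each protein its tier in the nested classification funnel."""
    if not lrr_accessions or not kinase_accessions:
        raise ValueError("accession sets must be non-empty")
    has: dict[str, set[str]] = defaultdict(set)
    for a in annotations:
        if a.accession in kinase_accessions:
            has[a.protein_id].add("KD")
        elif a.accession == tm_accession:
            has[a.protein_id].add("TM")
        elif a.accession in lrr_accessions:
            has[a.protein_id].add("LRR")
    out = []
    for rec in records:
        marks = has.get(rec.protein_id, set())
        if "KD" not in marks:
            tier = "none"
        elif "TM" not in marks:
            tier = "kinase"
        elif "LRR" not in marks:
            tier = "TM-kinase"
        else:
            tier = "LRR-RLK"
        out.append(ClassifiedProtein(rec.protein_id, tier))
    return out


def funnel_counts(classified: Iterable[ClassifiedProtein]) -> dict[str, int]:
    """Cumulative funnel counts (each tier includes the tiers below it)."""
    tally = {t: 0 for t in TIERS}
    for c in classified:
        tally[c.tier] += 1
    return {
        "kinase": (tally["kinase"] + tally["TM-kinase"]
                   + tally["LRR-RLK"]),
        "TM-kinase": tally["TM-kinase"] + tally["LRR-RLK"],
        "LRR-RLK": tally["LRR-RLK"],
    }


def extract_kinase_domains(records: Iterable[ProteinRecord],
                           annotations: Iterable[DomainAnnotation],
                           merge_gap_max: int = DEFAULT_MERGE_GAP_MAX,
                           merged_len_max: int = DEFAULT_MERGED_LEN_MAX,
                           kinase_accessions: frozenset =
                           DEFAULT_KINASE_ACCESSIONS,
                           ) -> list[KinaseDomainUnit]:
    """Extract merged kinase-domain units per protein.

    Overlapping raw hits are unioned (and logged).  Two disjoint hits merge
    into one unit iff their gap is <= *merge_gap_max* and the merged span
    is <= *merged_len_max*; otherwise the protein carries several units
    (a tandem-kinase protein).
    """
    seqs = {r.protein_id: r.sequence for r in records}
    hits: dict[str, list[tuple[int, int]]] = defaultdict(list)
    for a in annotations:
        if a.accession in kinase_accessions and a.protein_id in seqs:
            hits[a.protein_id].append((a.start, a.end))
    units: list[KinaseDomainUnit] = []
    for pid in sorted(hits):
        intervals = sorted(hits[pid])
        merged: list[list[int]] = []  # [start, end, n_hits]
        for s, e in intervals:
            if merged and s <= merged[-1][1] + 1 + merge_gap_max:
                gap = s - merged[-1][1] - 1
                span = max(merged[-1][1], e) - merged[-1][0] + 1
                if gap <= 0:
                    log.info("%s: overlapping kinase hits unioned", pid)
                    merged[-1][1] = max(merged[-1][1], e)
                    merged[-1][2] += 1
                    continue
                if span <= merged_len_max:
                    merged[-1][1] = max(merged[-1][1], e)
                    merged[-1][2] += 1
                    continue
            merged.append([s, e, 1])
        single = len(merged) == 1
        for i, (s, e, n) in enumerate(merged):
            units.append(KinaseDomainUnit(pid, i, s, e,
                                          seqs[pid][s - 1:e], n,
                                          single=single))
    return units


def unit_sequences(units: Sequence[KinaseDomainUnit]) -> dict[str, str]:
    """Map unit id -> amino-acid sequence, preserving input order."""
    return {u.unit_id: u.sequence for u in units}


def protein_of_unit(unit_id: str) -> str:
    """Invert :attr:`KinaseDomainUnit.unit_id` back to the protein id."""
    return unit_id.rsplit("/kd", 1)[0]
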