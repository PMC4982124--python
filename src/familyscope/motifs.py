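"""Catalytic-loop location and RD / non-RD / ACF classification.

Most protein kinases carry an H-R-D tripeptide in the catalytic loop, the
aspartate being the catalytic residue.  Kinases lacking the arginine
(non-RD kinases) are strongly enriched among pattern-recognition
receptors; domains showing neither motif are recorded as ACF (alternative
catalytic function).  Because the target motif is known a priori, the loop
is located by anchoring on a reference row containing a literal HRD run
and projecting its H/R/D alignment columns onto every other row.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .align import Alignment

log = logging.getLogger(__name__)

MOTIF_CLASSES = ("RD", "nonRD", "ACF")


@dataclass(frozen=True)
class CatalyticLoop:
    protein_id: str
    H_col: int
    R_col: int
    D_col: int
    residues: tuple[str, str, str]  # residues observed at those columns


@dataclass(frozen=True)
class MotifCall:
    protein_id: str
    motif_class: str           # RD | nonRD | ACF
    r_position_residue: str    # amino acid, or "-" for a gap


def locate_catalytic_loop(aln: Alignment, reference_id: str,
                          ) -> list[CatalyticLoop]:
    """Project the reference row's H/R/D columns onto every row.

    The reference row must contain a literal H-R-D run in its ungapped
    sequence; its first occurrence anchors the loop.
    """
    ref_row = aln.row(reference_id)
    ungapped = ref_row.replace("-", "")
    pos = ungapped.find("HRD")
    if pos < 0:
        raise ValueError(
            f"reference {reference_id!r} has no H-R-D run; choose another "
            "anchor sequence")
    # map ungapped residue indices to alignment columns
    cols = [c for c, ch in enumerate(ref_row) if ch != "-"]
    h_col, r_col, d_col = cols[pos], cols[pos + 1], cols[pos + 2]
    loops = []
    for name, row in zip(aln.ids, aln.rows):
        loops.append(CatalyticLoop(
            name, h_col, r_col, d_col,
            (row[h_col], row[r_col], row[d_col])))
    return loops


def classify_rd_motif(loop: CatalyticLoop) -> MotifCall:
    """RD if R precedes a present catalytic D; non-RD if D is present with
    anything else (including a gap, logged) at the R position; ACF when
    the catalytic aspartate itself is absent."""
    h, r, d = loop.residues
    if d != "D":
        return MotifCall(loop.protein_id, "ACF", r)
    if r == "R":
        return MotifCall(loop.protein_id, "RD", r)
    if r == "-":
        log.info("%s: gap at the R position with D present; classed "
                 "non-RD", loop.protein_id)
    return MotifCall(loop.protein_id, "nonRD", r)


def call_motifs(aln: Alignment, reference_id: str) -> list[MotifCall]:
    return [classify_rd_motif(lp)
            for lp in locate_catalytic_loop(aln, reference_id)]


def summarize_motifs(calls: Iterable[MotifCall],
                     assignment: Mapping[str, str] | None = None,
                     ) -> pd.DataFrame:
    """Per-group, per-class counts, fractions and R-position spectrum."""
    rows = []
    for c in calls:
        group = assignment.get(c.protein_id, "unassigned") \
            if assignment else "all"
        rows.append((group, c.motif_class, c.r_position_residue))
    df = pd.DataFrame(rows, columns=["group", "motif_class", "residue"])
    if df.empty:
        return pd.DataFrame(columns=["group", "motif_class", "count",
                                     "fraction", "residues"])
    out = (df.groupby(["group", "motif_class"], sort=True)
             .agg(count=("residue", "size"),
                  residues=("residue",
                            lambda s: ",".join(f"{k}:{v}" for k, v in
                                               s.value_counts()
                                               .sort_index().items())))
             .reset_index())
    totals = out.groupby("group")["count"].transform("sum")
    out["fraction"] = out["count"] / totals
    return out[["group", "motif_class", "count", "fraction", "residues"]]
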