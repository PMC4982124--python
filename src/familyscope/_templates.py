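"""Protein architecture templates for the synthetic genome generator.

A planted LRR-RLK protein is assembled N- to C-terminal as

    signal/N-term | LRR repeats | linker | TM helix | juxtamembrane | kinase domain | tail

so that the domain-annotation table can be emitted with fixed, exact
coordinates (evolution in the generator is substitution-only; there are no
indels, hence coordinates are stable across a family).

The kinase-domain template carries a single literal HRD catalytic loop; its
position defines the site at which RD / non-RD / ACF motifs are planted.
"""

from __future__ import annotations

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

# Ser/Thr protein-kinase-like domain, 288 aa, exactly one HRD run.
KD_TEMPLATE = (
    "LGSGGFGSVYKGRLSDGSLVAVKVLNLQNEGASKSFIDECNALRNIRHRNLVKIITACSN"
    "IDNQGNDFKAIVYDFMPNGSLEDWLHPETSDQAERSLNLHQRLNIAIDVASALEYLHWHC"
    "ETPIVHRDLKPSNVLLDENMTAHVGDFGLARFLSEKWDNRTAMIGVKGTVGYAPPEYGMG"
    "SEVSTYGDVYSYGILLLEMFTGKRPTDEMFKDGLNLHNFAKMALPERVMEIVDPKLLSTE"
    "ERDWTMLAHLASNFQIGLACSVESPKERMNMVDVTRELNAIKDNFCTG"
)
assert KD_TEMPLATE.count("HRD") == 1
# 0-based offsets of the H, R, D loop residues inside KD_TEMPLATE
KD_LOOP_OFFSET = KD_TEMPLATE.index("HRD")

# Canonical kinase motifs (glycine-rich loop, VAIK lysine, catalytic loop,
# DFG, APE) are held invariant while ancestors diverge: they are the
# positions real kinases conserve, and they anchor deep alignments.
KD_CONSERVED_MOTIFS = ("LGSGGFGSVY", "VAVKVL", "HRDLKPSN", "VGDFGLAR",
                       "GTVGYAPPE", "GDVYSYGILLLEM", "RMNMVDVTREL")


def conserved_kd_offsets() -> tuple[int, ...]:
    """0-based KD-template offsets of the conserved motif residues."""
    out: set[int] = set()
    for motif in KD_CONSERVED_MOTIFS:
        idx = KD_TEMPLATE.index(motif)
        out.update(range(idx, idx + len(motif)))
    return tuple(sorted(out))

N_TERM = "MKLLSKLSLVLFLSLFLLSSSSA"          # signal-peptide-like
LRR_UNIT = "LPSLRELDLSNNNLSGEIPSSLGNL"       # one 25-aa plant LRR repeat
LINKER = "TTSSGSNKKSII"
TM_TEMPLATE = "WIWLAVGIGVGLLSLVLIAVILWIR"    # 25-aa hydrophobic helix
JUXTA = "KRRKKEAELEMYA"
C_TAIL = "EMTDSIHSLS"

# Pfam accessions used by the classifier; the generator plants these verbatim.
KINASE_ACCESSIONS = ("PF00069", "PF07714")
LRR_ACCESSIONS = (
    "PF00560",  # LRR_1
    "PF01462",  # LRRNT
    "PF01816",  # LRV
    "PF08263",  # LRRNT_2
    "PF12799",  # LRR_4
    "PF13306",  # LRR_5
    "PF13855",  # LRR_8
    "PF14580",  # LRR_9
    "PF01463",  # LRRCT
    "PF07723",  # LRR_2
    "PF07725",  # LRR_3
)
# TM evidence rides in the same table under a reserved accession (TMHMM role).
TM_ACCESSION = "TMHELIX"

# Accessions the generator cycles through for successive LRR repeats.
_LRR_CYCLE = ("PF13855", "PF00560", "PF08263", "PF12799")


def build_architecture(n_lrr: int, kinase_accession: str = "PF00069",
                       with_lrr: bool = True, with_tm: bool = True):
    """Assemble a template protein and its domain rows.

    Returns ``(sequence, domains, kd_span, loop_positions)`` where *domains*
    is a list of ``(accession, start, end)`` with 1-based inclusive protein
    coordinates, *kd_span* the kinase-domain (start, end) and
    *loop_positions* the 0-based protein indices of the H, R and D residues.
    """
    parts: list[str] = [N_TERM]
    domains: list[tuple[str, int, int]] = []
    pos = len(N_TERM)
    if with_lrr:
        for i in range(n_lrr):
            parts.append(LRR_UNIT)
            domains.append((_LRR_CYCLE[i % len(_LRR_CYCLE)],
                            pos + 1, pos + len(LRR_UNIT)))
            pos += len(LRR_UNIT)
    parts.append(LINKER)
    pos += len(LINKER)
    if with_tm:
        parts.append(TM_TEMPLATE)
        domains.append((TM_ACCESSION, pos + 1, pos + len(TM_TEMPLATE)))
        pos += len(TM_TEMPLATE)
    parts.append(JUXTA)
    pos += len(JUXTA)
    kd_start = pos  # 0-based
    parts.append(KD_TEMPLATE)
    domains.append((kinase_accession, pos + 1, pos + len(KD_TEMPLATE)))
    pos += len(KD_TEMPLATE)
    parts.append(C_TAIL)
    seq = "".join(parts)
    loop = tuple(kd_start + KD_LOOP_OFFSET + i for i in range(3))
    return seq, domains, (kd_start + 1, kd_start + len(KD_TEMPLATE)), loop


# Subfamily labels: groups I-XVI with the XII split into XIIa / XIIb.
GROUP_LABELS = (
    "I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X", "XI",
    "XIIa", "XIIb", "XIII", "XIV", "XV", "XVI",
)
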