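"""Synthetic two-species genomes with planted LRR-RLK families.

The generator emulates the inputs of a genome-wide receptor-like-kinase
survey: two related species that share a set of gene families, plus a
labelled reference proteome (the *Arabidopsis* role) whose exemplars carry
subfamily group labels I-XVI (XII split into XIIa/XIIb).  Every planted
feature that a downstream stage must recover is recorded in a machine-
readable :class:`TruthTable`:

* family membership and subfamily group of every gene,
* cross-species ortholog pairs (lineages present in both species),
* tandem arrays placed within the 200 kb clustering window,
* RD / non-RD / ACF catalytic-loop classes,
* copied genomic segments (planted synteny blocks).

Evolution is substitution-only (no indels): a family ancestor protein is
drawn from the architecture template, member lineages diverge from it, and
each species copy accumulates nucleotide substitutions at the configured
rate.  Genes are single-exon CDS, so each emitted protein is the exact
translation of its genomic CDS.  Catalytic-loop codons and domain-boundary
codons are masked from mutation so planted annotations stay valid.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from . import _templates as T
from .io import DomainAnnotation, write_fasta, write_gff3, write_domain_table

# Amino-acid divergence between family ancestors, and between member
# lineages within a family.  Families must be far apart relative to members
# so that neighbor-joining separates them cleanly.
FAMILY_DIVERGENCE = 0.30
MEMBER_DIVERGENCE = 0.10
OUTGROUP_DIVERGENCE = 0.30

_STOPS = {"TAA", "TAG", "TGA"}
_BASES = "ACGT"

# Codon chosen per amino acid during back-translation (one synonymous codon
# drawn at random from the standard table, stops excluded).
_CODONS: dict[str, list[str]] = {}
for _b1 in _BASES:
    for _b2 in _BASES:
        for _b3 in _BASES:
            _codon = _b1 + _b2 + _b3
            if _codon in _STOPS:
                continue
            _CODONS.setdefault(str(Seq(_codon).translate()), []).append(_codon)


class ConfigError(ValueError):
    """Invalid generator configuration."""


class CapacityError(ConfigError):
    """Chromosomes too short to hold the planted genes without overlap."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic dataset.

    Defaults give a desk-scale two-species dataset with one family per
    subfamily label, motif-class frequencies matching the roughly
    1:2.6:0.4 RD : non-RD : ACF split reported for LRR-XII receptor
    kinases, and C/G dominating the non-RD residue spectrum.
    """
    n_families: int = 17
    members_per_family_range: tuple[int, int] = (2, 4)
    n_chromosomes: int = 3
    chromosome_length: int = 5_000_000
    tandem_array_fraction: float = 0.375
    ortholog_fraction: float = 0.8
    motif_class_probs: Mapping[str, float] = field(
        default_factory=lambda: {"RD": 0.25, "nonRD": 0.65, "ACF": 0.10})
    nonRD_residue_weights: Mapping[str, float] = field(
        default_factory=lambda: {"C": 0.60, "G": 0.36, "S": 0.02,
                                 "Y": 0.01, "W": 0.01})
    mutation_rate: float = 0.0
    seed: int = 0
    # decoy tiers exercising the classification funnel
    n_tm_kinase_decoys: int = 0
    n_kinase_decoys: int = 0
    # plumbing knobs
    alt_transcript_fraction: float = 0.25
    planted_segment_lengths: tuple[int, ...] = (2000,)
    n_outgroup: int = 3
    correlate_xii_motifs: bool = True

    def validate(self) -> None:
        if self.n_families < 0:
            raise ConfigError("n_families must be >= 0")
        lo, hi = self.members_per_family_range
        if not (1 <= lo <= hi):
            raise ConfigError("members_per_family_range must satisfy "
                              "1 <= min <= max")
        if self.n_chromosomes < 1 or self.chromosome_length < 1:
            raise ConfigError("need at least one chromosome of positive "
                              "length")
        for name, probs, keys in (
                ("motif_class_probs", self.motif_class_probs,
                 {"RD", "nonRD", "ACF"}),
                ("nonRD_residue_weights", self.nonRD_residue_weights,
                 {"C", "G", "S", "Y", "W"})):
            if set(probs) - keys:
                raise ConfigError(f"{name}: unknown keys {set(probs) - keys}")
            if abs(sum(probs.values()) - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1")
        if not (0.0 <= self.mutation_rate <= 0.5):
            raise ConfigError("mutation_rate must be in [0, 0.5]")
        for frac in (self.tandem_array_fraction, self.ortholog_fraction,
                     self.alt_transcript_fraction):
            if not (0.0 <= frac <= 1.0):
                raise ConfigError("fractions must be in [0, 1]")


@dataclass
class TruthTable:
    """Ground truth for every downstream stage."""
    family_of_gene: dict[str, int] = field(default_factory=dict)
    subfamily_of_family: dict[int, str] = field(default_factory=dict)
    ortholog_pairs: list[tuple[str, str]] = field(default_factory=list)
    tandem_arrays: list[dict] = field(default_factory=list)
    motif_class_of_gene: dict[str, str] = field(default_factory=dict)
    motif_residue_of_gene: dict[str, str] = field(default_factory=dict)
    planted_blocks: list[dict] = field(default_factory=list)
    tier_of_gene: dict[str, str] = field(default_factory=dict)
    species_of_gene: dict[str, str] = field(default_factory=dict)

    def genes_of_species(self, species: str) -> list[str]:
        return [g for g, s in self.species_of_gene.items() if s == species]

    def subfamily_of_gene(self, gene_id: str) -> str:
        return self.subfamily_of_family[self.family_of_gene[gene_id]]

    def to_json(self, path: str | Path) -> None:
        payload = asdict(self)
        payload["subfamily_of_family"] = {
            str(k): v for k, v in self.subfamily_of_family.items()}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            payload = json.load(fh)
        payload["subfamily_of_family"] = {
            int(k): v for k, v in payload["subfamily_of_family"].items()}
        payload["ortholog_pairs"] = [tuple(p)
                                     for p in payload["ortholog_pairs"]]
        return cls(**payload)


@dataclass
class SpeciesBundle:
    species: str
    genome: dict[str, str]
    gff_rows: list[dict]
    proteome: dict[str, str]
    domains: list[DomainAnnotation]

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "genome.fasta", self.genome)
        write_fasta(outdir / "proteome.fasta", self.proteome)
        write_gff3(outdir / "annotation.gff3", self.gff_rows)
        write_domain_table(outdir / "domains.tsv", self.domains)


@dataclass
class ReferenceBundle:
    proteome: dict[str, str]
    domains: list[DomainAnnotation]
    labels: dict[str, str]          # reference protein id -> group label

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(outdir / "proteome.fasta", self.proteome)
        write_domain_table(outdir / "domains.tsv", self.domains)
        with open(outdir / "labels.tsv", "w") as fh:
            fh.write("protein_id\tgroup\n")
            for pid, lab in self.labels.items():
                fh.write(f"{pid}\t{lab}\n")


@dataclass
class Dataset:
    species: dict[str, SpeciesBundle]
    reference: ReferenceBundle
    truth: TruthTable
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, bundle in self.species.items():
            bundle.write(outdir / name)
        self.reference.write(outdir / "reference")
        self.truth.to_json(outdir / "truth.json")


# ---------------------------------------------------------------------------
# Sequence-level operations

def plant_kinase_motif(kd_template: str, motif_class: str,
                       residue: str | None = None,
                       loop_index: int | None = None) -> str:
    """Write an RD / non-RD / ACF catalytic loop into a kinase domain.

    The designated site is the literal ``HRD`` run of the domain template
    (located at *loop_index* when given, else by search).  RD leaves
    H-R-D; non-RD substitutes *residue* (anything but R) for the arginine;
    ACF replaces the catalytic aspartate with alanine.
    """
    if loop_index is None:
        idx = kd_template.find("HRD")
    else:
        idx = loop_index
        if kd_template[idx:idx + 3] != "HRD":
            idx = -1
    if idx < 0:
        raise ValueError("kinase-domain template lacks the designated "
                         "H-R-D catalytic-loop site")
    loop = list(kd_template[idx:idx + 3])
    if motif_class == "RD":
        pass
    elif motif_class == "nonRD":
        if residue is None or residue == "R":
            raise ValueError("non-RD motif requires a residue other than R "
                             f"(got {residue!r})")
        loop[1] = residue
    elif motif_class == "ACF":
        loop[2] = "A"
    else:
        raise ValueError(f"unknown motif class {motif_class!r}")
    return kd_template[:idx] + "".join(loop) + kd_template[idx + 3:]


def mutate_sequence(seq: str, rate: float,
                    seed: int | np.random.Generator | None = None,
                    masked: Sequence[int] = ()) -> str:
    """Substitute nucleotides independently at the given per-site rate.

    Positions listed in *masked* (0-based) are never touched.  Substituted
    sites receive one of the three other bases uniformly; the expected
    substituted fraction over unmasked sites equals *rate*.
    """
    if not (0.0 <= rate <= 0.5):
        raise ValueError(f"rate must be in [0, 0.5], got {rate}")
    if rate == 0.0 or not seq:
        return seq
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hit = rng.random(arr.size) < rate
    if len(masked):
        hit[np.asarray(list(masked), dtype=np.intp)] = False
    idx = np.flatnonzero(hit)
    lut = {ord(b): [ord(c) for c in _BASES if c != b] for b in _BASES}
    choices = rng.integers(0, 3, size=idx.size)
    for i, c in zip(idx, choices):
        arr[i] = lut[arr[i]][c]
    return arr.tobytes().decode()


def _mutate_protein(seq: str, rate: float, rng: np.random.Generator,
                    masked: Sequence[int] = ()) -> str:
    """Amino-acid level substitution used to derive ancestors."""
    arr = list(seq)
    hit = rng.random(len(arr)) < rate
    for p in masked:
        hit[p] = False
    for i in np.flatnonzero(hit):
        alternatives = T.AMINO_ACIDS.replace(arr[i], "")
        arr[i] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(arr)


def back_translate(protein: str, rng: np.random.Generator) -> str:
    """One synonymous codon per residue, drawn at random (no stops)."""
    out = []
    for aa in protein:
        codons = _CODONS[aa]
        out.append(codons[rng.integers(0, len(codons))])
    return "".join(out)


def _repair_stops(cds: str, ancestor: str) -> str:
    """Revert any codon mutated into a stop back to its ancestral codon."""
    out = []
    for i in range(0, len(cds), 3):
        codon = cds[i:i + 3]
        out.append(ancestor[i:i + 3] if codon in _STOPS else codon)
    return "".join(out)


def _random_dna(rng: np.random.Generator, length: int) -> np.ndarray:
    return np.frombuffer(b"ACGT", dtype=np.uint8)[
        rng.integers(0, 4, size=length)]


# ---------------------------------------------------------------------------
# Dataset assembly

@dataclass
class _Gene:
    gene_id: str
    species: str
    family: int | None
    protein: str
    cds: str
    domains: list[tuple[str, int, int]]
    tier: str
    motif_class: str | None = None
    residue: str | None = None
    alt: bool = False
    # placement, filled later
    chromosome: str = ""
    start: int = 0
    end: int = 0
    strand: str = "+"


def _sample(rng: np.random.Generator, weights: Mapping[str, float]) -> str:
    keys = sorted(weights)
    p = np.array([weights[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=p / p.sum())]


def _conserved_positions(kd_span: tuple[int, int],
                         loop: tuple[int, ...]) -> tuple[int, ...]:
    """Protein positions held invariant during ancestor divergence."""
    kd_start = kd_span[0] - 1
    out = set(loop)
    out.update(kd_start + off for off in T.conserved_kd_offsets())
    return tuple(sorted(out))


_XIIA_PROBS = {"RD": 0.05, "nonRD": 0.90, "ACF": 0.05}
_XIIB_PROBS = {"RD": 0.90, "nonRD": 0.05, "ACF": 0.05}


def generate_dataset(config: GeneratorConfig) -> Dataset:
    """Generate the two species bundles, the reference bundle and the truth.

    Deterministic: the same config (including seed) yields byte-identical
    files from :meth:`Dataset.write`.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    truth = TruthTable()
    genes: dict[str, list[_Gene]] = {"speciesA": [], "speciesB": []}
    ref_proteome: dict[str, str] = {}
    ref_domains: list[DomainAnnotation] = []
    ref_labels: dict[str, str] = {}
    # family id -> per-species ordered member gene lists (for tandem units)
    members_by_family: dict[int, dict[str, list[_Gene]]] = {}

    lo, hi = config.members_per_family_range
    for fam in range(config.n_families):
        label = T.GROUP_LABELS[fam % len(T.GROUP_LABELS)]
        truth.subfamily_of_family[fam] = label
        n_lrr = int(rng.integers(3, 6))
        kin_acc = T.KINASE_ACCESSIONS[int(rng.integers(0, 2))]
        base, domains, kd_span, loop = T.build_architecture(n_lrr, kin_acc)
        conserved = _conserved_positions(kd_span, loop)
        family_seq = _mutate_protein(base, FAMILY_DIVERGENCE, rng,
                                     masked=conserved)
        members_by_family[fam] = {"speciesA": [], "speciesB": []}
        if config.correlate_xii_motifs and label == "XIIa":
            class_probs = _XIIA_PROBS
        elif config.correlate_xii_motifs and label == "XIIb":
            class_probs = _XIIB_PROBS
        else:
            class_probs = config.motif_class_probs
        n_members = int(rng.integers(lo, hi + 1))
        for mem in range(n_members):
            member_seq = _mutate_protein(family_seq, MEMBER_DIVERGENCE, rng,
                                         masked=conserved)
            motif_class = _sample(rng, class_probs)
            residue = (_sample(rng, config.nonRD_residue_weights)
                       if motif_class == "nonRD" else None)
            kd = member_seq[kd_span[0] - 1:kd_span[1]]
            kd = plant_kinase_motif(kd, motif_class, residue,
                                    loop_index=T.KD_LOOP_OFFSET)
            member_seq = (member_seq[:kd_span[0] - 1] + kd
                          + member_seq[kd_span[1]:])
            cds = back_translate(member_seq, rng)
            shared = rng.random() < config.ortholog_fraction
            if shared:
                targets = ["speciesA", "speciesB"]
            else:
                # unpaired members of a family all go to one species, so
                # they act as within-species paralog decoys rather than
                # spurious cross-species reciprocal bests
                targets = ["speciesA" if fam % 2 == 0 else "speciesB"]
            masked_aa = set(loop)
            for acc, s, e in domains:
                masked_aa.update((s - 1, e - 1))
            masked_nt = [3 * p + o for p in sorted(masked_aa)
                         for o in range(3)]
            made: list[str] = []
            for sp in targets:
                tag = sp[-1]
                gene_id = f"{tag}_f{fam:02d}m{mem:02d}"
                cds_sp = mutate_sequence(cds, config.mutation_rate, rng,
                                         masked=masked_nt)
                cds_sp = _repair_stops(cds_sp, cds)
                prot_sp = str(Seq(cds_sp).translate())
                gene = _Gene(gene_id, sp, fam, prot_sp, cds_sp,
                             list(domains), "LRR-RLK", motif_class,
                             residue if motif_class == "nonRD" else None)
                genes[sp].append(gene)
                members_by_family[fam][sp].append(gene)
                truth.family_of_gene[gene_id] = fam
                truth.species_of_gene[gene_id] = sp
                truth.tier_of_gene[gene_id] = "LRR-RLK"
                truth.motif_class_of_gene[gene_id] = motif_class
                if motif_class == "nonRD":
                    truth.motif_residue_of_gene[gene_id] = residue
                made.append(gene_id)
            if len(made) == 2:
                truth.ortholog_pairs.append((made[0], made[1]))
        # labelled reference exemplars (two for XIIb, mirroring its paired
        # archetype receptors; one elsewhere)
        n_refs = 2 if label == "XIIb" else 1
        for r in range(n_refs):
            ref_seq = _mutate_protein(family_seq, MEMBER_DIVERGENCE, rng,
                                      masked=conserved)
            if label == "XIIa":
                ref_class, ref_res = "nonRD", "C"
            else:
                ref_class, ref_res = "RD", None
            kd = ref_seq[kd_span[0] - 1:kd_span[1]]
            kd = plant_kinase_motif(kd, ref_class, ref_res,
                                    loop_index=T.KD_LOOP_OFFSET)
            ref_seq = (ref_seq[:kd_span[0] - 1] + kd
                       + ref_seq[kd_span[1]:])
            pid = f"REF_f{fam:02d}" + (f"_{r}" if n_refs > 1 else "")
            ref_proteome[pid] = ref_seq
            ref_labels[pid] = label
            for acc, s, e in domains:
                ref_domains.append(DomainAnnotation(pid, acc, s, e))

    # decoy tiers: TM kinases without LRRs, and cytoplasmic kinases (RLCK
    # role) without a TM helix
    for kind, count, with_tm, tier in (
            ("tmk", config.n_tm_kinase_decoys, True, "TM-kinase"),
            ("rlck", config.n_kinase_decoys, False, "kinase")):
        for d in range(count):
            base, domains, kd_span, loop = T.build_architecture(
                0, "PF00069", with_lrr=False, with_tm=with_tm)
            seq = _mutate_protein(base, OUTGROUP_DIVERGENCE, rng,
                                  masked=_conserved_positions(kd_span,
                                                              loop))
            cds = back_translate(seq, rng)
            for sp in ("speciesA", "speciesB"):
                tag = sp[-1]
                gene_id = f"{tag}_{kind}{d:02d}"
                cds_sp = _repair_stops(
                    mutate_sequence(cds, config.mutation_rate, rng), cds)
                gene = _Gene(gene_id, sp, None, str(Seq(cds_sp).translate()),
                             cds_sp, list(domains), tier)
                genes[sp].append(gene)
                truth.species_of_gene[gene_id] = sp
                truth.tier_of_gene[gene_id] = tier

    # outgroup kinases for tree rooting (reference bundle only): one
    # diverged outgroup ancestor, members drawn from it like a family
    if config.n_families > 0 and config.n_outgroup > 0:
        base, domains, kd_span, loop = T.build_architecture(
            0, "PF00069", with_lrr=False, with_tm=False)
        conserved = _conserved_positions(kd_span, loop)
        out_ancestor = _mutate_protein(base, OUTGROUP_DIVERGENCE, rng,
                                       masked=conserved)
        for o in range(config.n_outgroup):
            seq = _mutate_protein(out_ancestor, MEMBER_DIVERGENCE, rng,
                                  masked=conserved)
            kd = plant_kinase_motif(seq[kd_span[0] - 1:kd_span[1]], "RD",
                                    loop_index=T.KD_LOOP_OFFSET)
            seq = seq[:kd_span[0] - 1] + kd + seq[kd_span[1]:]
            pid = f"OUT_{o}"
            ref_proteome[pid] = seq
            ref_labels[pid] = "outgroup"
            for acc, s, e in domains:
                ref_domains.append(DomainAnnotation(pid, acc, s, e))

    # which families form tandem arrays
    n_tandem = round(config.tandem_array_fraction * config.n_families)
    tandem_families = set(
        rng.permutation(config.n_families)[:n_tandem].tolist())

    # shared genomic segments planted as synteny ground truth
    segments = []
    if config.n_families > 0:
        for length in config.planted_segment_lengths:
            segments.append(_random_dna(rng, length).tobytes().decode())

    bundles: dict[str, SpeciesBundle] = {}
    segment_placements: dict[str, list[tuple[str, int, int]]] = {}
    for sp in ("speciesA", "speciesB"):
        bundles[sp], placed = _assemble_species(
            sp, genes[sp], members_by_family, tandem_families, segments,
            config, rng, truth)
        segment_placements[sp] = placed
    for i in range(len(segments)):
        ca, sa, ea = segment_placements["speciesA"][i]
        cb, sb, eb = segment_placements["speciesB"][i]
        truth.planted_blocks.append(
            {"chrom_a": ca, "start_a": sa, "end_a": ea,
             "chrom_b": cb, "start_b": sb, "end_b": eb,
             "length": len(segments[i])})

    reference = ReferenceBundle(ref_proteome, ref_domains, ref_labels)
    return Dataset(bundles, reference, truth, config)


def _assemble_species(sp: str, sp_genes: list[_Gene],
                      members_by_family, tandem_families, segments,
                      config: GeneratorConfig, rng: np.random.Generator,
                      truth: TruthTable):
    """Place genes and segments on chromosomes and emit one bundle."""
    # placement units: a tandem family is placed as one contiguous unit
    units: list[list[_Gene | str]] = []
    tandem_unit_index: dict[int, int] = {}
    placed_single: set[str] = set()
    for fam in sorted(tandem_families):
        fam_members = members_by_family.get(fam, {}).get(sp, [])
        if len(fam_members) >= 2:
            tandem_unit_index[fam] = len(units)
            units.append(list(fam_members))
            placed_single.update(g.gene_id for g in fam_members)
    for g in sp_genes:
        if g.gene_id not in placed_single:
            units.append([g])
    for seg in segments:
        units.append([seg])

    order = rng.permutation(len(units))
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    cursors = {c: int(rng.integers(10_000, 30_000)) for c in chrom_names}
    placed_segments: list[tuple[str, int, int]] = []
    seg_place_tmp: dict[int, tuple[str, int, int]] = {}
    gene_rows: list[_Gene] = []
    for k, uidx in enumerate(order.tolist()):
        unit = units[uidx]
        chrom = chrom_names[k % len(chrom_names)]
        pos = cursors[chrom]
        for j, item in enumerate(unit):
            if j > 0:  # intra-array gap, well inside the 200 kb rule
                pos += int(rng.integers(5_000, 20_000))
            if isinstance(item, str):       # planted segment
                length = len(item)
                if pos + length > config.chromosome_length:
                    raise CapacityError(
                        f"{sp}/{chrom}: planted segment of {length} bp does "
                        f"not fit below position {config.chromosome_length}")
                seg_place_tmp[segments.index(item)] = (chrom, pos + 1,
                                                       pos + length)
                pos += length
            else:
                length = len(item.cds)
                if pos + length > config.chromosome_length:
                    raise CapacityError(
                        f"{sp}/{chrom}: gene {item.gene_id} ({length} bp) "
                        f"does not fit; increase chromosome_length or "
                        f"reduce the number of planted genes")
                item.chromosome = chrom
                item.start = pos + 1
                item.end = pos + length
                item.strand = "+" if rng.random() < 0.5 else "-"
                gene_rows.append(item)
                pos += length
        cursors[chrom] = pos + int(rng.integers(210_000, 250_000))

    for i in sorted(seg_place_tmp):
        placed_segments.append(seg_place_tmp[i])

    # tandem-array truth (ordered along the chromosome)
    for fam, uidx in tandem_unit_index.items():
        arr = sorted((g for g in units[uidx]), key=lambda g: g.start)
        truth.tandem_arrays.append(
            {"species": sp, "chromosome": arr[0].chromosome,
             "genes": [g.gene_id for g in arr]})

    # genome: random background, genes and segments written in place
    chrom_arrays = {c: _random_dna(rng, config.chromosome_length)
                    for c in chrom_names}
    for g in gene_rows:
        seq = g.cds if g.strand == "+" else str(
            Seq(g.cds).reverse_complement())
        chrom_arrays[g.chromosome][g.start - 1:g.end] = np.frombuffer(
            seq.encode(), dtype=np.uint8)
    for i, (chrom, s, e) in enumerate(placed_segments):
        chrom_arrays[chrom][s - 1:e] = np.frombuffer(
            segments[i].encode(), dtype=np.uint8)
    genome = {c: a.tobytes().decode() for c, a in chrom_arrays.items()}

    # GFF3 + proteome + domains; a fraction of genes get an alternative
    # (non-primary) transcript so the splice-variant filter has work to do
    gff_rows: list[dict] = []
    proteome: dict[str, str] = {}
    domain_rows: list[DomainAnnotation] = []
    for g in sorted(gene_rows, key=lambda g: (g.chromosome, g.start)):
        gff_rows.append(_gff(g.chromosome, "gene", g.start, g.end, g.strand,
                             f"ID={g.gene_id}"))
        pid = f"{g.gene_id}.t1"
        gff_rows.append(_gff(g.chromosome, "mRNA", g.start, g.end, g.strand,
                             f"ID={pid};Parent={g.gene_id};primary=true"))
        gff_rows.append(_gff(g.chromosome, "CDS", g.start, g.end, g.strand,
                             f"ID={pid}.cds;Parent={pid}", phase="0"))
        proteome[pid] = g.protein
        for acc, s, e in g.domains:
            domain_rows.append(DomainAnnotation(pid, acc, s, e))
        if rng.random() < config.alt_transcript_fraction:
            trim = 60  # drop the last 20 codons
            if g.strand == "+":
                a_start, a_end = g.start, g.end - trim
            else:
                a_start, a_end = g.start + trim, g.end
            apid = f"{g.gene_id}.t2"
            gff_rows.append(_gff(g.chromosome, "mRNA", a_start, a_end,
                                 g.strand,
                                 f"ID={apid};Parent={g.gene_id};"
                                 "primary=false"))
            gff_rows.append(_gff(g.chromosome, "CDS", a_start, a_end,
                                 g.strand, f"ID={apid}.cds;Parent={apid}",
                                 phase="0"))
            alt_prot = g.protein[:len(g.protein) - trim // 3]
            proteome[apid] = alt_prot
            for acc, s, e in g.domains:
                if e <= len(alt_prot):
                    domain_rows.append(DomainAnnotation(apid, acc, s, e))
    return SpeciesBundle(sp, genome, gff_rows, proteome,
                         domain_rows), placed_segments


def _gff(seqid, ftype, start, end, strand, attributes, phase="."):
    return {"seqid": seqid, "source": "famsim", "type": ftype,
            "start": start, "end": end, "score": ".", "strand": strand,
            "phase": phase, "attributes": attributes}
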