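"""End-to-end orchestration of the LRR-RLK survey on a two-species bundle.

Stages run in a fixed order — classify, align/filter, phylogeny + group
assignment, motifs, chromosomal arrangement, orthology + synteny — each
writing its outputs before the next starts, so a failing stage leaves the
earlier results on disk.  The final report collects the classification
funnel, per-group counts, motif-class counts, cluster/tandem/ortholog/
synteny counts and provenance (config hash + seed); identical config and
seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import align as al
from . import arrange as ar
from . import classify as cl
from . import homology as ho
from . import motifs as mo
from . import phylo as ph
from .io import load_inputs, read_fasta, read_gff3, gene_loci_from_gff

log = logging.getLogger(__name__)

SPECIES = ("speciesA", "speciesB")


class PipelineError(RuntimeError):
    """Failure of a named pipeline stage."""


@dataclass
class PipelineConfig:
    input_dir: str = "."
    out_dir: str = "out"
    run_id: str = "run"
    seed: int = 0
    min_kd_len: int = 100
    max_gap_fraction: float = 0.9
    redundancy_max: float = 99.0
    redundancy_min: float = 30.0
    support_threshold: float = 0.70
    bootstrap_replicates: int = 100
    cluster_window: int = 200_000
    min_block_length: int = 1000
    anchor_k: int = 21
    max_anchor_gap: int = 5000
    prefilter_top: int = 40
    run_synteny: bool = True

    def validate(self) -> None:
        if not (0.0 <= self.max_gap_fraction <= 1.0):
            raise ValueError("max_gap_fraction must be in [0, 1]")
        if not (0.0 <= self.support_threshold <= 1.0):
            raise ValueError("support_threshold must be in [0, 1]")
        if self.bootstrap_replicates < 1:
            raise ValueError("bootstrap_replicates must be >= 1")
        if self.min_block_length < 1 or self.cluster_window < 0:
            raise ValueError("length parameters must be positive")

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def digest(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    funnel: dict = field(default_factory=dict)
    group_counts: dict = field(default_factory=dict)
    motif_counts: dict = field(default_factory=dict)
    cluster_stats: dict = field(default_factory=dict)
    tandem_counts: dict = field(default_factory=dict)
    ortholog_counts: dict = field(default_factory=dict)
    synteny_counts: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        blob = json.dumps(dataclasses.asdict(self), indent=1,
                          sort_keys=True)
        if path is not None:
            Path(path).write_text(blob + "\n")
        return blob


def _stage(name: str):
    def deco(fn):
        def wrapped(*a, **k):
            try:
                return fn(*a, **k)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


@dataclass
class _SpeciesState:
    records: list
    annotations: list
    gff: object
    classified: list
    units: list
    kd_seqs: dict
    tree: ph.PhyloTree | None = None
    assignment: dict | None = None
    calls: list | None = None


def _coarse(labels: dict[str, str]) -> dict[str, str]:
    return {k: ("XII" if v in ("XIIa", "XIIb") else v)
            for k, v in labels.items()}


@_stage("classify")
def _classify_species(cfg: PipelineConfig, species: str,
                      outdir: Path) -> _SpeciesState:
    base = Path(cfg.input_dir) / species
    for fname in ("proteome.fasta", "annotation.gff3", "domains.tsv"):
        if not (base / fname).exists():
            raise FileNotFoundError(f"missing input {base / fname}")
    records, annotations = load_inputs(base / "proteome.fasta",
                                       base / "annotation.gff3",
                                       base / "domains.tsv", species)
    gff = read_gff3(base / "annotation.gff3")
    primary = cl.filter_primary_transcripts(records)
    classified = cl.classify_proteins(primary, annotations)
    lrr_ids = {c.protein_id for c in classified if c.tier == "LRR-RLK"}
    units = cl.extract_kinase_domains(
        [r for r in primary if r.protein_id in lrr_ids], annotations)
    kd_seqs = cl.unit_sequences(units)
    with open(outdir / f"classification_{species}.tsv", "w") as fh:
        fh.write("protein_id\ttier\n")
        for c in sorted(classified, key=lambda c: c.protein_id):
            fh.write(f"{c.protein_id}\t{c.tier}\n")
    return _SpeciesState(primary, annotations, gff, classified, units,
                         kd_seqs)


def _reference_kds(cfg: PipelineConfig):
    # the reference bundle has no gene models; read proteome + domains only
    base = Path(cfg.input_dir) / "reference"
    proteome = read_fasta(base / "proteome.fasta")
    from .io import read_domain_table, ProteinRecord
    lengths = {k: len(v) for k, v in proteome.items()}
    annotations = read_domain_table(base / "domains.tsv", lengths)
    records = [ProteinRecord(k, "reference", v, k) for k, v in
               proteome.items()]
    units = cl.extract_kinase_domains(records, annotations)
    labels = {}
    with open(base / "labels.tsv") as fh:
        next(fh)
        for line in fh:
            pid, lab = line.rstrip("\n").split("\t")
            labels[pid] = lab
    # label the KD unit ids rather than the protein ids
    unit_labels = {}
    for u in units:
        unit_labels[u.unit_id] = labels[u.protein_id]
    return cl.unit_sequences(units), unit_labels


def _build_tree(cfg: PipelineConfig, kd_seqs: dict[str, str],
                protected: set[str], seed: int, outdir: Path, tag: str):
    seqs = al.filter_short(kd_seqs, cfg.min_kd_len)
    seqs = al.decrease_redundancy(seqs, cfg.redundancy_max,
                                  cfg.redundancy_min,
                                  protected=frozenset(protected))
    aln = al.progressive_align(seqs)
    aln, _ = al.trim_gap_columns(aln, cfg.max_gap_fraction)
    with open(outdir / f"kd_{tag}.aln.fasta", "w") as fh:
        for name, row in zip(aln.ids, aln.rows):
            fh.write(f">{name}\n{row}\n")
    tree = ph.bootstrap_support(aln, cfg.bootstrap_replicates,
                                np.random.default_rng(seed))
    tree.write(outdir / f"tree_{tag}.nwk")
    return aln, tree


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Run every stage on the bundle under ``config.input_dir``."""
    config.validate()
    outdir = Path(config.out_dir) / config.run_id
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    report = RunReport(provenance={"config_sha256": config.digest(),
                                   "seed": config.seed,
                                   "run_id": config.run_id})
    seed_seq = np.random.SeedSequence(config.seed)
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in seed_seq.spawn(4)]

    # -- classify -----------------------------------------------------
    states: dict[str, _SpeciesState] = {}
    for sp in SPECIES:
        states[sp] = _classify_species(config, sp, outdir)
        funnel = cl.funnel_counts(states[sp].classified)
        funnel["kd_units"] = len(states[sp].units)
        report.funnel[sp] = funnel
    ref_kds, ref_labels = _stage("classify")(_reference_kds)(config)

    # -- phylogeny + subfamily assignment -----------------------------
    @_stage("phylo")
    def _phylo(sp: str, seed: int):
        st = states[sp]
        merged = dict(st.kd_seqs)
        merged.update(ref_kds)
        aln, tree = _build_tree(config, merged, set(ref_kds), seed,
                                outdir, sp)
        st.tree = tree
        coarse = ph.assign_subfamily_groups(tree, _coarse(ref_labels),
                                            config.support_threshold)
        fine = ph.split_group_xii(tree, coarse, ref_labels,
                                  config.support_threshold)
        st.assignment = fine
        with open(outdir / f"groups_{sp}.tsv", "w") as fh:
            fh.write("tip_id\tgroup\n")
            for tip in sorted(fine):
                fh.write(f"{tip}\t{fine[tip]}\n")
        return aln

    alignments = {}
    for i, sp in enumerate(SPECIES):
        alignments[sp] = _phylo(sp, seeds[0] + i)
        counts = _group_counts_by_protein(states[sp], ref_labels)
        report.group_counts[sp] = counts

    # -- motifs -------------------------------------------------------
    @_stage("motifs")
    def _motifs(sp: str):
        st = states[sp]
        aln = alignments[sp]
        anchor = _pick_anchor(aln, ref_labels)
        calls = mo.call_motifs(aln, anchor)
        query_tips = {u.unit_id for u in st.units}
        calls = [c for c in calls if c.protein_id in query_tips]
        st.calls = calls
        tip_groups = st.assignment or {}
        summary = mo.summarize_motifs(calls, tip_groups)
        summary.to_csv(outdir / f"motifs_{sp}.tsv", sep="\t", index=False)
        tally: dict[str, int] = {c: 0 for c in mo.MOTIF_CLASSES}
        for c in calls:
            tally[c.motif_class] += 1
        report.motif_counts[sp] = tally

    for sp in SPECIES:
        _motifs(sp)

    # -- chromosomal arrangement --------------------------------------
    @_stage("arrange")
    def _arrange(sp: str):
        st = states[sp]
        lrr_ids = {c.protein_id for c in st.classified
                   if c.tier == "LRR-RLK"}
        gene_of = {r.protein_id: r.gene_id for r in st.records}
        family_genes = {gene_of[p] for p in lrr_ids}
        loci = [lo for lo in gene_loci_from_gff(st.gff)
                if lo.gene_id in family_genes]
        clusters = ar.detect_clusters(loci, config.cluster_window)
        clades = ph.find_well_supported_clades(st.tree,
                                               config.support_threshold)
        gene_clades = [ph.Clade(frozenset(
            gene_of.get(cl.protein_of_unit(t)) for t in c.tips
            if cl.protein_of_unit(t) in gene_of), c.support)
            for c in clades]
        tandem = ar.identify_tandem_paralogs(clusters, gene_clades)
        stats = ar.cluster_composition_stats(clusters, tandem, family_genes)
        report.cluster_stats[sp] = stats
        report.tandem_counts[sp] = {
            "n_sets": len(tandem),
            "n_genes": sum(len(t.members) for t in tandem)}
        ar.clusters_to_frame(clusters).to_csv(
            outdir / f"clusters_{sp}.tsv", sep="\t", index=False)
        with open(outdir / f"map_{sp}.txt", "w") as fh:
            fh.write(ar.render_chromosome_map(loci, clusters))
        return clusters, tandem

    for sp in SPECIES:
        _arrange(sp)

    # -- orthology + synteny ------------------------------------------
    @_stage("homology")
    def _homology():
        prot = {}
        for sp in SPECIES:
            lrr_ids = {c.protein_id for c in states[sp].classified
                       if c.tier == "LRR-RLK"}
            prot[sp] = {r.protein_id: r.sequence for r in
                        states[sp].records if r.protein_id in lrr_ids}
        if not prot[SPECIES[0]] or not prot[SPECIES[1]]:
            report.ortholog_counts = {"n_bbh": 0, "n_confirmed": 0}
            return
        hits_ab = ho.pairwise_similarity_search(
            prot[SPECIES[0]], prot[SPECIES[1]],
            prefilter_top=config.prefilter_top)
        hits_ba = ho.pairwise_similarity_search(
            prot[SPECIES[1]], prot[SPECIES[0]],
            prefilter_top=config.prefilter_top)
        pairs = ho.bidirectional_best_hits(hits_ab, hits_ba)
        # joint two-species tree for clade confirmation; every tip is
        # protected from redundancy removal so both members of an
        # identical ortholog twin stay in the tree
        joint = {}
        for sp in SPECIES:
            joint.update(states[sp].kd_seqs)
        _, joint_tree = _build_tree(config, joint, set(joint), seeds[1],
                                    outdir, "joint")
        clades = ph.find_well_supported_clades(joint_tree,
                                               config.support_threshold)
        prot_clades = [ph.Clade(frozenset(cl.protein_of_unit(t)
                                          for t in c.tips), c.support)
                       for c in clades]
        tips = {cl.protein_of_unit(t) for t in joint_tree.tip_names}
        pairs = ho.confirm_orthologs_by_clade(pairs, prot_clades, tips)
        with open(outdir / "orthologs.tsv", "w") as fh:
            fh.write("protein_a\tprotein_b\tbbh\tclade_confirmed\n")
            for p in pairs:
                fh.write(f"{p.gene_a}\t{p.gene_b}\t{p.bbh}\t"
                         f"{p.clade_confirmed}\n")
        report.ortholog_counts = {
            "n_bbh": len(pairs),
            "n_confirmed": sum(1 for p in pairs if p.clade_confirmed)}

    _homology()

    @_stage("synteny")
    def _synteny():
        if not config.run_synteny:
            report.synteny_counts = {"n_blocks": None}
            return
        ga = read_fasta(Path(config.input_dir) / SPECIES[0]
                        / "genome.fasta")
        gb = read_fasta(Path(config.input_dir) / SPECIES[1]
                        / "genome.fasta")
        blocks = ho.genome_synteny(ga, gb, config.anchor_k,
                                   config.max_anchor_gap,
                                   config.min_block_length)
        ho.blocks_to_frame(blocks).to_csv(outdir / "synteny_blocks.tsv",
                                          sep="\t", index=False)
        report.synteny_counts = {"n_blocks": len(blocks)}

    _synteny()

    report.to_json(outdir / "report.json")
    (outdir / "tables.txt").write_text(render_tables(report))
    return report


def _pick_anchor(aln: al.Alignment, ref_labels: dict[str, str]) -> str:
    """Deterministically choose a reference row with a unique HRD run."""
    refs = [r for r in sorted(ref_labels) if r in aln.ids]
    candidates = refs or sorted(aln.ids)
    for rid in candidates:
        if aln.degapped(rid).count("HRD") == 1:
            return rid
    for rid in candidates:
        if "HRD" in aln.degapped(rid):
            return rid
    raise ValueError("no alignment row contains an H-R-D catalytic loop")


def _group_counts_by_protein(state: _SpeciesState,
                             ref_labels: dict[str, str]) -> dict[str, int]:
    """Per-group counts over LRR-RLK proteins (first KD unit's label)."""
    assignment = state.assignment or {}
    label_of_protein: dict[str, str] = {}
    for u in state.units:
        pid = u.protein_id
        if pid not in label_of_protein:
            label_of_protein[pid] = assignment.get(u.unit_id, "unassigned")
    counts: dict[str, int] = {}
    for lab in label_of_protein.values():
        counts[lab] = counts.get(lab, 0) + 1
    return dict(sorted(counts.items()))


# ---------------------------------------------------------------------------
# Publication-style summary tables

_GROUP_ORDER = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX",
                "X", "XI", "XIIa", "XIIb", "XIII", "XIV", "XV", "XVI",
                "outgroup", "unassigned")


def render_tables(report: RunReport) -> str:
    """Funnel table (KD units in parentheses) and per-group matrix."""
    species = sorted(report.funnel)
    lines = ["Protein classification funnel", ""]
    header = f"{'tier':<22}" + "".join(f"{sp:>14}" for sp in species)
    lines.append(header)
    for tier in ("kinase", "TM-kinase"):
        row = f"{tier:<22}" + "".join(
            f"{report.funnel[sp][tier]:>14}" for sp in species)
        lines.append(row)
    row = f"{'LRR-RLK (KDs)':<22}"
    for sp in species:
        f = report.funnel[sp]
        row += f"{f['LRR-RLK']} ({f['kd_units']})".rjust(14)
    lines.append(row)
    lines += ["", "Receptors per subfamily group", ""]
    lines.append(f"{'group':<14}" + "".join(f"{sp:>14}" for sp in species))
    groups = [g for g in _GROUP_ORDER
              if any(g in report.group_counts.get(sp, {})
                     for sp in species)]
    totals = {sp: 0 for sp in species}
    for g in groups:
        row = f"{'LRR ' + g if g not in ('outgroup', 'unassigned') else g:<14}"
        for sp in species:
            n = report.group_counts.get(sp, {}).get(g, 0)
            totals[sp] += n
            row += f"{n:>14}"
        lines.append(row)
    lines.append(f"{'Total':<14}" + "".join(
        f"{totals[sp]:>14}" for sp in species))
    for sp in species:
        expected = report.funnel[sp]["LRR-RLK"]
        if totals[sp] != expected:
            lines.append(f"# WARNING {sp}: group total {totals[sp]} != "
                         f"LRR-RLK count {expected}")
    return "\n".join(lines) + "\n"
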