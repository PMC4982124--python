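# Methods

## The problem

Plant receptor-like kinases (RLKs) are single-pass transmembrane proteins
with an extracellular domain, a TM helix and a cytoplasmic Ser/Thr kinase
domain (KD).  The LRR-RLK subfamily — extracellular leucine-rich repeats —
is the largest, and its group XII harbours pattern-recognition receptors
(FLS2, EFR, XA21) whose kinases are typically *non-RD*: they lack the
arginine that precedes the catalytic aspartate of the H-R-D catalytic-loop
motif.  A genome-wide survey of this family proceeds from annotated
proteomes through domain-architecture filtering, KD phylogenetics against
labelled reference exemplars, motif classification, and genomic-arrangement
analyses (tandem duplication, orthology, synteny).  `familyscope`
implements that survey as a deterministic, testable pipeline.

## Classification funnel

Proteins are classified from a domain-annotation table alone (an
InterProScan-like TSV; TM evidence rides in the same table under the
reserved accession `TMHELIX`, standing in for a TM predictor's output):

* **kinase** — carries PF00069 (Pkinase) or PF07714 (Pkinase_Tyr);
* **TM-kinase** — additionally a TM helix;  proteins whose only TM overlaps
  the KD still count (no topology reasoning is attempted);
* **LRR-RLK** — additionally at least one of the 11 LRR Pfam families
  (PF00560, PF01462, PF01816, PF08263, PF12799, PF13306, PF13855, PF14580,
  PF01463, PF07723, PF07725).

Tiers nest by construction.  Alternative splice variants are removed first
(one primary transcript per gene; a gene with no primary flag keeps its
longest protein, with a warning).  Receptor-like cytoplasmic kinases fall
out at the TM step; they are not modelled separately.

**Kinase-domain units.**  Some proteins carry several kinase hits: either
fragments of one truncated domain or genuine tandem domains.  Curating
these case by case does not scale, so a fixed rule replaces it: overlapping
hits are unioned; disjoint hits merge into one unit iff the gap is
≤ 100 aa *and* the merged span is ≤ 450 aa (a typical protein-kinase domain
is ~250–300 aa; 450 bounds a merged unit below ~1.5× that).  Anything else
stays a separate unit, so the unit count can exceed the protein count.

## Alignment and filters

The KD aligner is a classic progressive scheme: 3-mer-set distances feed
an average-linkage guide tree; profile–profile merges use affine-gap
dynamic programming (Gotoh; first gap column costs `gap_open` = −12,
further columns `gap_extend` = −1) under BLOSUM62, with profile columns
scored as frequency-weighted sums.  This replaces an external aligner to
keep the pipeline self-contained; a pre-computed aligned FASTA can be
supplied instead (`familyscope align --precomputed`).

Filters, in pipeline order: sequences shorter than 100 aa are dropped
(strict `<`); redundancy is reduced at 99 % maximum / 30 % minimum
pairwise identity — of any pair above the maximum the longer sequence is
kept (ties keep the lexicographically smaller id), then sequences whose
best identity to the kept set falls below the minimum are removed
simultaneously; identity is computed over global-alignment columns
excluding terminal gaps (the external tool that inspired the step does not
publish its exact metric).  After alignment, columns with a gap fraction
above 0.9 are trimmed — a fixed configurable cutoff standing in for a
slope-based heuristic defined elsewhere.  Reference exemplars are
protected from redundancy removal so labels survive filtering.  Rows with
"large inserted gap regions" have no published threshold; the trimming
report exposes per-column gap fractions rather than guessing one.

## Phylogeny and group assignment

Distances are Poisson-corrected p-distances, d = −ln(1 − p), over shared
non-gap columns; saturated pairs (p ≥ 1) are capped at d_max = 5 with a
warning, and a pair sharing no columns is an error.  Trees are built by
standard neighbor-joining with deterministic tie-breaks (Q-matrix ties go
to the lexicographically smallest pair of cluster representatives) and
negative branch lengths clamped to zero with the deficit moved to the
sister branch.  Support is nonparametric bootstrap: columns resampled with
replacement, the replicate NJ tree's bipartitions counted against the base
tree.  Full likelihood inference, model selection and rate heterogeneity
are deliberately out of scope — the clade logic downstream only needs a
reasonable topology with honest support values, and the distance/NJ path
is exact on additive inputs (tested against that property).  An externally
estimated Newick tree with supports can be substituted.

A query tip receives the label of the smallest bipartition side containing
it whose defining edge has support > 0.70 and whose reference tips all
share one label.  The tree is treated as unrooted: both sides of every
internal edge are candidate clades.  A query lying between two
differently-labelled reference clades therefore finds no homogeneous side
and stays `unassigned` — the ambiguous case is surfaced, not guessed.
Group XII is refined into XIIa/XIIb by the same rule restricted to the XII
exemplars (two XIIb exemplars mirror the paired archetype receptors); with
no XIIb exemplar present, all XII tips become XIIa with a warning.

## RD / non-RD / ACF motifs

The catalytic loop is found by anchoring on a reference row whose ungapped
sequence contains a literal H-R-D run (the motif is known a priori, so
de-novo motif discovery is unnecessary and nondeterministic) and
projecting its H/R/D columns onto every row.  Classification reads two
columns: catalytic D present and R at the arginine position → **RD**;
D present, anything else (including a gap, which is logged) → **non-RD**
with the residue recorded; D absent → **ACF** (alternative catalytic
function).  The partition is total by construction.  The non-RD residue
spectrum reports C, G, S, Y and W distinctly; the field's usage of
"tryptophan (Y)" conflates tyrosine (Y) and tryptophan (W), so both
letters are reported and neither is privileged.

## Genomic arrangement

Genes on one chromosome chain into a cluster when the inter-gene gap
(next start − previous cluster end) is ≤ 200,000 bp, transitively;
the gap measure is length-robust (start-to-start would penalise long
genes) and configurable.  Tandem-duplicated paralogs are genes sharing a
cluster *and* a well-supported clade; each gene joins at most one set
(largest clade wins, ties by higher support).  This operationalises
"proximity + same clade" with the only quantified distance in the
procedure, the 200 kb rule.  The chromosome map is rendered as
deterministic tab-separated text that parses back losslessly.

## Orthology and synteny

At single-family corpus sizes (hundreds of proteins) a heuristic search is
unnecessary: every query–subject pair is scored by exact local alignment
(Smith–Waterman via Biopython's PairwiseAligner, BLOSUM62), ranked by
score with ties broken by percent identity then id; an optional
shared-k-mer prefilter bounds the number of alignments per query.
Ortholog pairs are bidirectional best hits (each the other's rank-1), then
flagged `clade_confirmed` when both members co-occur in a well-supported
clade of the joint two-species KD tree (every tip protected from
redundancy removal there, so identical ortholog twins both stay).

Synteny: maximal exact shared k-mer runs (k = 21, both strands, k-mers
occurring > 10 times skipped as repeats) are chained when collinear and
within 5,000 bp on both sequences; blocks shorter than **1,000 bp** are
discarded — the one stated parameter of the original procedure, kept as a
hard floor.  Genome-vs-genome and gene-vs-genome modes share the anchor
machinery.  A gene matching several loci yields one block per locus.

## Synthetic data: what it emulates and what it does not

The generator plants two related species and a labelled reference
proteome.  Protein architecture is template-based (N-terminal signal,
3–5 LRR repeats of 25 aa, one TM helix, a 288-aa kinase domain, short
linkers); a family ancestor diverges from the template at 0.30
substitutions/site (amino-acid level), member lineages at 0.10, and each
species copy accumulates nucleotide substitutions at the configured
`mutation_rate`.  The canonical kinase motifs (glycine-rich loop, VAIK,
H-R-D catalytic loop, DFG, APE and two C-lobe blocks — ~70 of 288
positions) are held invariant during divergence: real kinases conserve
exactly these positions, and they are what anchors deep alignments.
Catalytic-loop and domain-boundary codons are masked from nucleotide
mutation; codons mutated into stops revert to the ancestral codon, so
every emitted protein is the exact translation of its single-exon CDS.

Placement: tandem families are laid out as contiguous arrays (5–20 kb
intra-array gaps, comfortably inside the 200 kb rule); all other genes and
the planted copied segments are spaced ≥ 210 kb apart so no spurious
clusters arise; unpaired members of a family all go to one species, so
they act as within-species paralog decoys for BBH rather than spurious
cross-species reciprocal bests.  A fraction of genes receives a
non-primary alternative transcript (3'-truncated) to exercise the splice
filter.  Default study conditions: 17 families (one per group label
I–XI, XIIa, XIIb, XIII–XVI), 2–4 members each, 80 % ortholog fraction,
37.5 % tandem families, motif classes RD 0.25 / non-RD 0.65 / ACF 0.10
(group XIIa skews non-RD and XIIb skews RD unless decorrelated), non-RD
residues C 0.60 / G 0.36 / S 0.02 / Y 0.01 / W 0.01 — C and G dominate
with S/Y/W rare, matching the residue spectrum reported for this receptor
group, and the class split matches the roughly 70 % non-RD share of the
XII receptors.

What the generator does **not** emulate — and therefore what passing
tests do not show about real data: indels and alignment uncertainty,
intron structure, realistic codon usage and substitution models, rate
heterogeneity across sites beyond the conserved-motif mask, domain
annotation errors (the planted table is exact), genome repeats and
assembly artifacts, and gene families whose true history involves
whole-genome duplication.  Recovery rates on this generator are upper
bounds for annotation-driven steps and sanity checks for the statistical
ones.

## Numerical choices and degenerate inputs

* All randomness flows from `numpy.random.default_rng` seeded explicitly;
  identical config + seed ⇒ byte-identical outputs (tested).
* NJ tie-breaks, redundancy-removal order, hit-table tie-breaks and table
  renderings are all deterministic and documented above.
* Degenerate inputs fail loudly: infeasible gene placement raises a
  capacity error; an all-gap trimmed alignment, a pair with no shared
  columns, a reference without an H-R-D run, a domain row outside its
  protein — each raises a specific error naming the offender.
* Problem sizes in the test-suite and acceptance runs (6–25 families,
  2–6 Mb chromosomes, 25–100 bootstrap replicates) are chosen so the full
  suite completes in minutes on one CPU while every planted structure is
  still present in multiple copies.

## Known limitations

* The progressive aligner has no iterative refinement; on data with
  indels or very deep divergence an external alignment should be supplied.
* Bootstrap-on-NJ support is not comparable numerically to
  likelihood-based support measures; only the 0.70 thresholding behaviour
  is relied on.
* The tandem-paralog rule (cluster + clade) is one defensible
  operationalisation of "proximity and same clade"; counts under other
  definitions will differ.
* BBH finds one-to-one orthologs only; in-paralog fans after duplication
  yield at most one pair, which is the intended behaviour of the method,
  not a defect of the implementation.
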