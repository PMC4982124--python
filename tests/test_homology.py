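"""Similarity search, BBH orthology, anchors and synteny chaining."""

import numpy as np
import pytest

from familyscope import homology as ho
from familyscope.phylo import Clade
from familyscope.simulate import (GeneratorConfig, generate_dataset,
                                  mutate_sequence)


def brute_force_local(a, b, match=2.0, mismatch=-1.0, gap=-2.0):
    """Independent Smith-Waterman scorer with linear gaps."""
    n, m = len(a), len(b)
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] else mismatch
            H[i][j] = max(0.0, H[i - 1][j - 1] + s, H[i - 1][j] + gap,
                          H[i][j - 1] + gap)
            best = max(best, H[i][j])
    return best


class TestSimilaritySearch:
    def test_identical_subject_rank_one(self):
        queries = {"q": "MKVLITGAGQRIG"}
        subjects = {"same": "MKVLITGAGQRIG", "other": "WWYYFFPPHHNNQQ"}
        hits = ho.pairwise_similarity_search(queries, subjects)
        top = hits[hits["rank"] == 1].iloc[0]
        assert top["subject_id"] == "same"

    def test_toy_scores_match_brute_force(self):
        # linear gaps: open == extend
        queries = {"q1": "MKVRLA", "q2": "AVRLMK"}
        subjects = {"s1": "MKVVLA", "s2": "RLARLA", "s3": "WWPPHH"}
        hits = ho.pairwise_similarity_search(
            queries, subjects, matrix=None, match=2.0, mismatch=-1.0,
            gap_open=-2.0, gap_extend=-2.0)
        for row in hits.itertuples():
            expected = brute_force_local(queries[row.query_id],
                                         subjects[row.subject_id])
            assert row.score == pytest.approx(expected)

    def test_ranks_dense_per_query(self):
        queries = {"q": "MKVLITGAGQRIG"}
        subjects = {f"s{i}": "MKVLITGAGQRIG"[:8 + i] for i in range(5)}
        hits = ho.pairwise_similarity_search(queries, subjects)
        assert sorted(hits["rank"]) == [1, 2, 3, 4, 5]

    def test_empty_sets_rejected(self):
        with pytest.raises(ValueError):
            ho.pairwise_similarity_search({}, {"s": "MKV"})


class TestBBH:
    def _hits(self, ranks):
        import pandas as pd
        rows = [(q, s, 100.0 - r, 90.0, r) for (q, s, r) in ranks]
        return pd.DataFrame(rows, columns=["query_id", "subject_id",
                                           "score", "identity", "rank"])

    def test_mutual_rank_one_emitted(self):
        ab = self._hits([("a1", "b1", 1), ("a1", "b2", 2)])
        ba = self._hits([("b1", "a1", 1), ("b2", "a1", 1)])
        pairs = ho.bidirectional_best_hits(ab, ba)
        assert [(p.gene_a, p.gene_b) for p in pairs] == [("a1", "b1")]

    def test_one_way_best_not_emitted(self):
        ab = self._hits([("a1", "b1", 1)])
        ba = self._hits([("b1", "a2", 1), ("b1", "a1", 2)])
        assert ho.bidirectional_best_hits(ab, ba) == []

    def test_symmetric_under_species_swap(self):
        ds = generate_dataset(GeneratorConfig(
            seed=21, n_families=5, members_per_family_range=(2, 3),
            n_chromosomes=2, chromosome_length=3_000_000))
        prot = {sp: {p: s for p, s in ds.species[sp].proteome.items()
                     if p.endswith(".t1")}
                for sp in ("speciesA", "speciesB")}
        ab = ho.pairwise_similarity_search(prot["speciesA"],
                                           prot["speciesB"])
        ba = ho.pairwise_similarity_search(prot["speciesB"],
                                           prot["speciesA"])
        fwd = {(p.gene_a, p.gene_b)
               for p in ho.bidirectional_best_hits(ab, ba)}
        rev = {(p.gene_b, p.gene_a)
               for p in ho.bidirectional_best_hits(ba, ab)}
        assert fwd == rev

    def test_planted_pairs_recovered_with_paralog_decoys(self,
                                                         noisy_dataset):
        truth = noisy_dataset.truth
        prot = {sp: {p: s
                     for p, s in noisy_dataset.species[sp].proteome.items()
                     if p.endswith(".t1")}
                for sp in ("speciesA", "speciesB")}
        ab = ho.pairwise_similarity_search(prot["speciesA"],
                                           prot["speciesB"],
                                           prefilter_top=30)
        ba = ho.pairwise_similarity_search(prot["speciesB"],
                                           prot["speciesA"],
                                           prefilter_top=30)
        got = {(p.gene_a.rsplit(".t", 1)[0], p.gene_b.rsplit(".t", 1)[0])
               for p in ho.bidirectional_best_hits(ab, ba)}
        want = set(map(tuple, truth.ortholog_pairs))
        assert want and got == want


class TestCladeConfirmation:
    def test_pair_in_clade_confirmed(self):
        pairs = [ho.OrthologPair("a1", "b1")]
        clades = [Clade(frozenset({"a1", "b1", "x"}), 0.9)]
        out = ho.confirm_orthologs_by_clade(pairs, clades)
        assert out[0].clade_confirmed is True

    def test_pair_split_across_clades_flagged(self):
        pairs = [ho.OrthologPair("a1", "b1")]
        clades = [Clade(frozenset({"a1", "x"}), 0.9),
                  Clade(frozenset({"b1", "y"}), 0.9)]
        out = ho.confirm_orthologs_by_clade(pairs, clades)
        assert out[0].bbh and out[0].clade_confirmed is False

    def test_member_missing_from_tree_untestable(self):
        pairs = [ho.OrthologPair("a1", "b1")]
        out = ho.confirm_orthologs_by_clade(pairs, [], tree_tips={"a1"})
        assert out[0].clade_confirmed is None


class TestFindAnchors:
    def test_identical_sequences_single_full_anchor(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=5000))
        anchors = [a for a in ho.find_anchors(seq, seq)
                   if a.orientation == "same"]
        full = [a for a in anchors if a.length == 5000]
        assert len(full) == 1
        assert (full[0].pos_a, full[0].pos_b) == (0, 0)

    def test_no_shared_kmers_empty(self, rng):
        a = "".join(rng.choice(list("AC"), size=2000))
        b = "".join(rng.choice(list("GT"), size=2000))
        assert ho.find_anchors(a, b) == []

    def test_reverse_complement_detected(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        rc = ho._revcomp(seq)
        anchors = ho.find_anchors(seq, rc)
        inv = [a for a in anchors if a.orientation == "inverted"]
        assert any(a.length == 3000 for a in inv)

    def test_mutated_copy_tiles_most_of_segment(self, rng):
        # a 2 kb copy at 1% divergence: anchors cover >= 80% of it
        background_a = "".join(rng.choice(list("ACGT"), size=6000))
        segment = "".join(rng.choice(list("ACGT"), size=2000))
        seg_mut = mutate_sequence(segment, 0.01, seed=3)
        seq_a = background_a[:2000] + segment + background_a[2000:]
        background_b = "".join(rng.choice(list("ACGT"), size=5000))
        seq_b = background_b[:1000] + seg_mut + background_b[1000:]
        anchors = ho.find_anchors(seq_a, seq_b)
        covered = set()
        for a in (x for x in anchors if x.orientation == "same"):
            if 2000 <= a.pos_a < 4000:
                covered.update(range(a.pos_a, a.pos_a + a.length))
        assert len(covered) >= 0.8 * 2000

    def test_small_k_rejected(self):
        with pytest.raises(ValueError):
            ho.find_anchors("ACGTACGT", "ACGTACGT", k=4)


class TestChainSyntenyBlocks:
    def test_single_long_anchor_is_block(self):
        anchors = [ho.Anchor(100, 200, 1200, "same")]
        blocks = ho.chain_synteny_blocks(anchors)
        assert len(blocks) == 1
        assert blocks[0].length == 1200

    def test_short_anchor_below_floor_discarded(self):
        anchors = [ho.Anchor(100, 200, 800, "same")]
        assert ho.chain_synteny_blocks(anchors) == []

    def test_two_collinear_anchors_merge(self):
        # 600 bp anchors 3 kb apart chain into one 4.2 kb block
        anchors = [ho.Anchor(0, 0, 600, "same"),
                   ho.Anchor(3600, 3600, 600, "same")]
        blocks = ho.chain_synteny_blocks(anchors, max_anchor_gap=5000)
        assert len(blocks) == 1
        assert (blocks[0].start_a, blocks[0].end_a) == (1, 4200)

    def test_distant_anchors_split_then_filtered(self):
        anchors = [ho.Anchor(0, 0, 600, "same"),
                   ho.Anchor(50_600, 50_600, 600, "same")]
        # each candidate block is 600 bp < 1000 -> none survive
        assert ho.chain_synteny_blocks(anchors, max_anchor_gap=5000) == []

    def test_inverted_chain_requires_reversed_collinearity(self):
        anchors = [ho.Anchor(0, 4000, 600, "inverted"),
                   ho.Anchor(1000, 3000, 600, "inverted")]
        blocks = ho.chain_synteny_blocks(anchors, max_anchor_gap=5000)
        assert len(blocks) == 1
        assert blocks[0].orientation == "inverted"

    def test_every_block_meets_length_floor(self, rng):
        anchors = []
        pos = 0
        for _ in range(30):
            pos += int(rng.integers(100, 8000))
            anchors.append(ho.Anchor(pos, pos + 17, int(rng.integers(
                25, 900)), "same"))
        for b in ho.chain_synteny_blocks(anchors):
            assert b.length >= 1000

    def test_planted_segment_yields_block_and_short_does_not(self):
        ds = generate_dataset(GeneratorConfig(
            seed=31, n_families=2, members_per_family_range=(2, 2),
            n_chromosomes=1, chromosome_length=2_000_000,
            planted_segment_lengths=(2000, 800)))
        blocks = ho.genome_synteny(ds.species["speciesA"].genome,
                                   ds.species["speciesB"].genome)
        long_seg = next(b for b in ds.truth.planted_blocks
                        if b["length"] == 2000)
        short_seg = next(b for b in ds.truth.planted_blocks
                         if b["length"] == 800)

        def covering(seg):
            return [b for b in blocks
                    if b.chrom_a == seg["chrom_a"]
                    and b.start_a <= seg["start_a"] + 50
                    and b.end_a >= seg["end_a"] - 50]

        assert covering(long_seg)
        assert not covering(short_seg)
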