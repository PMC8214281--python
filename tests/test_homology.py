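"""Hit filtering, collinearity chaining, block labelling, BBH, quartets,
and ancestral-content inference."""

import numpy as np
import pytest

import quartetconv as qc
from quartetconv.homology import (
    best_chain,
    block_anchor_ks,
    chain_collinear_blocks,
    homology_pipeline,
    infer_ancestral_content,
)
from quartetconv.records import CollinearBlock, GeneRecord, HomologyHit

from oracles import best_chain_brute


def _hit(q, s, e=1e-10, score=200.0):
    return HomologyHit(query=q, subject=s, evalue=e, bitscore=score)


def _gene(gid, genome="A", chrom="chr1", rank=0, start=None, cds=""):
    start = start or (rank * 1000 + 1)
    return GeneRecord(gene_id=gid, genome=genome, chrom=chrom, start=start,
                      end=start + 99, rank=rank, cds=cds)


class TestFilterHits:
    def test_thresholds_strict(self):
        hits = [
            _hit("a", "b", e=1e-6, score=150.0),  # retained
            _hit("a", "c", e=1e-4, score=500.0),  # E-value too high
            _hit("a", "d", e=1e-10, score=100.0),  # score not strictly above
            _hit("a", "a", e=0.0, score=999.0),  # self-hit
        ]
        kept = qc.filter_hits(hits)
        assert [(h.query, h.subject) for h in kept] == [("a", "b")]

    def test_bad_thresholds_rejected(self):
        with pytest.raises(ValueError):
            qc.filter_hits([], max_evalue=0.0)


class TestRemoveLargeFamilies:
    def _genes(self, n):
        return {f"g{i}": _gene(f"g{i}", rank=i) for i in range(n)}

    def test_family_of_30_removed(self):
        genes = self._genes(31)
        hits = [_hit("g0", f"g{i}") for i in range(1, 30)]  # 29 partners -> family 30
        hits += [_hit(f"g{i}", "g0") for i in range(1, 30)]
        hits.append(_hit("g30", "g1"))
        kept = qc.remove_large_families(hits, genes, max_copies=30)
        assert all(h.query != "g0" and h.subject != "g0" for h in kept)

    def test_small_family_kept_and_empty_ok(self):
        genes = self._genes(6)
        hits = [_hit("g0", f"g{i}") for i in range(1, 6)]
        assert qc.remove_large_families(hits, genes) == hits
        assert qc.remove_large_families([], genes) == []


class TestChaining:
    def _setup(self, points, max_gap=50, min_anchors=5):
        genes_a = {f"a{r}": _gene(f"a{r}", "A", "chr1", r) for r, _ in points}
        genes_b = {f"b{r}": _gene(f"b{r}", "B", "chr1", r) for _, r in points}
        hits = [_hit(f"a{ra}", f"b{rb}") for ra, rb in points]
        return chain_collinear_blocks(hits, genes_a, genes_b, max_gap, min_anchors)

    def test_perfect_diagonal_one_block(self):
        blocks = self._setup([(i, i) for i in range(6)])
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 6
        assert blocks[0].orientation == "+"

    def test_sixty_gene_gap_splits_chain_below_threshold(self):
        pts = [(0, 0), (1, 1), (2, 2), (63, 63), (64, 64), (65, 65)]
        blocks = self._setup(pts, max_gap=50, min_anchors=5)
        assert blocks == []
        blocks = self._setup(pts, max_gap=50, min_anchors=3)
        assert sorted(b.n_anchors for b in blocks) == [3, 3]

    def test_antidiagonal_descending_block(self):
        blocks = self._setup([(i, 6 - i) for i in range(7)])
        assert len(blocks) == 1
        assert blocks[0].n_anchors == 7
        assert blocks[0].orientation == "-"

    def test_matches_exhaustive_chain_search(self):
        rng = np.random.default_rng(123)
        for trial in range(300):
            n = int(rng.integers(2, 13))
            max_gap = int(rng.integers(1, 6))
            pts = set()
            while len(pts) < n:
                pts.add((int(rng.integers(0, 15)), int(rng.integers(0, 15))))
            pts = sorted(pts)
            got_chain, got_ori = best_chain(pts, max_gap)
            exp_chain, exp_ori = best_chain_brute(pts, max_gap)
            assert (got_chain, got_ori) == (exp_chain, exp_ori), (pts, max_gap)


class TestLabelRelation:
    def _block(self, same_genome):
        return CollinearBlock(
            block_id="B1", genome_a="A", genome_b="A" if same_genome else "B",
            chrom_a="chr1", chrom_b="chr2", anchors=[("a", "b")] * 5,
        )

    def test_within_genome_always_paralogous(self):
        assert qc.label_block_relation(self._block(True), [0.62] * 5) == "paralogous"

    def test_between_genome_cutoff(self):
        assert qc.label_block_relation(self._block(False), [0.04] * 5) == "orthologous"
        assert qc.label_block_relation(self._block(False), [0.66] * 5) == "paralogous"

    def test_too_few_ks_ambiguous(self):
        assert qc.label_block_relation(self._block(False), [0.04, 0.05]) == "ambiguous"


class TestBBH:
    def test_mutual_best_reported(self):
        ab = [_hit("a1", "b1", score=300), _hit("a1", "b2", score=200)]
        ba = [_hit("b1", "a1", score=300), _hit("b2", "a2", score=100)]
        assert qc.best_bidirectional_hits(ab, ba) == [("a1", "b1")]

    def test_non_mutual_not_reported(self):
        ab = [_hit("a1", "b1", score=300)]
        ba = [_hit("b1", "a2", score=300)]
        assert qc.best_bidirectional_hits(ab, ba) == []

    def test_score_tie_broken_by_evalue(self):
        ab = [_hit("a1", "b1", e=1e-20, score=300), _hit("a1", "b2", e=1e-10, score=300)]
        ba = [_hit("b1", "a1", score=300), _hit("b2", "a1", score=300)]
        assert qc.best_bidirectional_hits(ab, ba) == [("a1", "b1")]


class TestBuildQuartets:
    def test_both_orthologues_required(self):
        qs = qc.build_quartets([("o1", "o2")], [("o1", "s1"), ("o2", "s2")], "A", "B")
        assert len(qs) == 1
        q = qs[0]
        assert (q.o1, q.o2, q.s1, q.s2) == ("o1", "o2", "s1", "s2")
        assert qc.build_quartets([("o1", "o2")], [("o1", "s1")], "A", "B") == []

    def test_deduplicated_on_unordered_pair(self):
        qs = qc.build_quartets(
            [("o1", "o2"), ("o2", "o1")], [("o1", "s1"), ("o2", "s2")], "A", "B"
        )
        assert len(qs) == 1


class TestAncestralContent:
    def test_rule_examples(self):
        genomes = {
            g: {f"{g}{i}": _gene(f"{g}{i}", genome=g, rank=i) for i in range(3)}
            for g in ("A", "B", "C")
        }
        orth = {
            # locus 0 in all three; locus 1 in A,B only; locus 2 in A only
            ("A", "B"): [("A0", "B0"), ("A1", "B1")],
            ("A", "C"): [("A0", "C0")],
            ("B", "C"): [("B0", "C0")],
        }
        n, losses = infer_ancestral_content(orth, genomes)
        assert n == 2  # locus 2, seen in one genome, is not counted ancestral
        assert losses["C"] == pytest.approx(0.5)
        assert losses["A"] == losses["B"] == 0.0

    def test_needs_three_genomes(self):
        with pytest.raises(ValueError):
            infer_ancestral_content({}, {"A": {}, "B": {}})


@pytest.fixture(scope="module")
def result(small_sim):
    import tempfile

    import quartetconv.io as qio

    with tempfile.TemporaryDirectory() as td:
        paths = qc.write_dataset(small_sim, td)
        hits = qio.read_homology_tsv(paths["homology"])
    return homology_pipeline(small_sim.genomes, hits)


class TestOnSimulatedData:
    def test_every_retained_pair_in_exactly_one_quartet(self, clean_sim):
        import quartetconv.io as qio
        import tempfile

        with tempfile.TemporaryDirectory() as td:
            paths = qc.write_dataset(clean_sim, td)
            hits = qio.read_homology_tsv(paths["homology"])
        res = homology_pipeline(clean_sim.genomes, hits)
        for (ga, gb), quartets in res.quartets.items():
            pairs = [frozenset((q.o1, q.o2)) for q in quartets]
            assert len(pairs) == len(set(pairs))
            # with no loss and no rearrangement every paralogue pair shows up
            assert len(pairs) == len(clean_sim.families)

    def test_quartet_symmetry(self, result):
        for (ga, gb) in result.quartets:
            fwd = {
                frozenset((frozenset((q.o1, q.o2)), frozenset((q.s1, q.s2))))
                for q in result.quartets[(ga, gb)]
            }
            rev = {
                frozenset((frozenset((q.o1, q.o2)), frozenset((q.s1, q.s2))))
                for q in result.quartets[(gb, ga)]
            }
            assert fwd == rev

    def test_blocks_monotonic_and_gap_bounded(self, result, small_sim):
        ranks = {
            r.gene_id: r.rank for recs in small_sim.genomes.values() for r in recs
        }
        for blk in result.blocks:
            ra = [ranks[a] for a, _ in blk.anchors]
            rb = [ranks[b] for _, b in blk.anchors]
            assert ra == sorted(ra)
            assert rb == sorted(rb) or rb == sorted(rb, reverse=True)
            for (x1, y1), (x2, y2) in zip(zip(ra, rb), zip(ra[1:], rb[1:])):
                assert abs(x2 - x1) - 1 <= 50 and abs(y2 - y1) - 1 <= 50

    def test_loss_rates_recovered(self, result, small_sim):
        true = dict(zip(small_sim.config.genome_names, small_sim.config.loss_rates))
        for g, rate in result.loss_rates.items():
            assert abs(rate - true[g]) < 0.06  # wide bound at this small n


class TestBlockPermutation:
    def test_real_diagonal_significant_random_not(self):
        from quartetconv.homology import block_permutation_pvalue

        rng = np.random.default_rng(6)
        diagonal = [(i, i) for i in range(10)]
        p_diag = block_permutation_pvalue(diagonal, 10, max_gap=3, rounds=200,
                                          rng=np.random.default_rng(1))
        assert p_diag < 0.05
        # a random plot's own best chain is typical of its shuffles
        scattered = [(i, int(j)) for i, j in zip(range(10), rng.permutation(100)[:10])]
        chain, _ = best_chain(scattered, 3)
        p_rand = block_permutation_pvalue(scattered, len(chain), max_gap=3,
                                          rounds=200, rng=np.random.default_rng(2))
        assert p_rand > 0.05
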