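"""Collinearity, homology classification, and quartet construction.

From filtered all-vs-all homology hits and ranked gene annotations this
module chains collinear blocks on the rank–rank dot-plot (weighted DP,
ascending and descending diagonals, bounded intervening-gene gaps),
separates paralogous from orthologous blocks by the synonymous distance
of their anchors, supplements anchors with bidirectional best hits inside
labelled homologous regions, and assembles homologous gene quartets —
a paralogue pair (O1, O2) in genome A joined to its orthologues (S1, S2)
in genome B.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .records import CollinearBlock, GeneRecord, HomologyHit, Quartet
from .seqdist import pair_distances

__all__ = [
    "filter_hits",
    "remove_large_families",
    "chain_collinear_blocks",
    "best_chain",
    "label_block_relation",
    "block_anchor_ks",
    "best_bidirectional_hits",
    "build_quartets",
    "infer_ancestral_content",
    "HomologyResult",
    "homology_pipeline",
]

DEFAULT_MAX_EVALUE = 1e-5
DEFAULT_MIN_SCORE = 100.0
DEFAULT_MAX_GAP = 50
DEFAULT_MIN_ANCHORS = 5  # blocks with more than four collinear gene pairs
DEFAULT_FAMILY_CAP = 30
DEFAULT_KS_CUTOFF = 0.3


def filter_hits(
    hits: list[HomologyHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[HomologyHit]:
    """Keep hits with E-value strictly below ``max_evalue`` and score
    strictly above ``min_score``; self-hits are dropped."""
    if max_evalue <= 0 or min_score <= 0:
        raise ValueError("thresholds must be positive")
    return [
        h
        for h in hits
        if h.query != h.subject and h.evalue < max_evalue and h.bitscore > min_score
    ]


def remove_large_families(
    hits: list[HomologyHit],
    genes: dict[str, GeneRecord],
    max_copies: int = DEFAULT_FAMILY_CAP,
) -> list[HomologyHit]:
    """Drop genes belonging to large families from the collinearity input.

    A gene's family size is its number of distinct within-genome partners
    surviving the hit filter, plus itself; genes with family size >=
    ``max_copies`` are removed (hits touching them discarded).
    """
    partners: dict[str, set[str]] = defaultdict(set)
    for h in hits:
        gq, gs = genes.get(h.query), genes.get(h.subject)
        if gq is None or gs is None:
            continue
        if gq.genome == gs.genome:
            partners[h.query].add(h.subject)
            partners[h.subject].add(h.query)
    big = {g for g, p in partners.items() if len(p) + 1 >= max_copies}
    return [h for h in hits if h.query not in big and h.subject not in big]


# ---------------------------------------------------------------------------
# collinearity chaining


def _chain_dp(points: list[tuple[int, int]], max_gap: int, descending: bool):
    """Best strictly monotonic chain through dot-plot points.

    Points are (rankA, rankB); chains ascend on A and ascend (or descend)
    on B, with at most ``max_gap`` intervening genes between consecutive
    anchors on both axes.  Anchors score 1.  Returns the chain as a list
    of point indices; among equal-length chains the lexicographically
    smallest (rankA, rankB) sequence is chosen, which makes extraction
    deterministic.
    """
    if not points:
        return []
    order = sorted(range(len(points)), key=lambda i: points[i])
    best_len = [1] * len(points)
    best_path: list[tuple] = [(points[i],) for i in range(len(points))]
    for oi, i in enumerate(order):
        ra, rb = points[i]
        for j in order[:oi]:
            qa, qb = points[j]
            if qa >= ra or ra - qa - 1 > max_gap:
                continue
            if descending:
                if qb <= rb or qb - rb - 1 > max_gap:
                    continue
            else:
                if qb >= rb or rb - qb - 1 > max_gap:
                    continue
            cand_len = best_len[j] + 1
            cand_path = best_path[j] + (points[i],)
            if cand_len > best_len[i] or (
                cand_len == best_len[i] and cand_path < best_path[i]
            ):
                best_len[i] = cand_len
                best_path[i] = cand_path
    # choose max length; among ties the lexicographically smallest path
    max_len = max(best_len)
    cands = [best_path[i] for i in range(len(points)) if best_len[i] == max_len]
    return list(min(cands))


def best_chain(points: list[tuple[int, int]], max_gap: int):
    """Best chain over both orientations; ties prefer ascending, then the
    lexicographically smaller anchor sequence.  Returns (chain, orientation)."""
    asc = _chain_dp(points, max_gap, descending=False)
    desc = _chain_dp(points, max_gap, descending=True)
    if len(asc) > len(desc):
        return asc, "+"
    if len(desc) > len(asc):
        return desc, "-"
    if not asc:
        return [], "+"
    return (asc, "+") if asc <= desc else (desc, "-")


def chain_collinear_blocks(
    hits: list[HomologyHit],
    genes_a: dict[str, GeneRecord],
    genes_b: dict[str, GeneRecord],
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    block_prefix: str = "B",
) -> list[CollinearBlock]:
    """Chain collinear blocks between two gene sets.

    For every chromosome pair the hits form a rank–rank dot-plot; blocks
    are extracted greedily (best chain, remove its anchors, repeat) until
    no chain reaches ``min_anchors``.  For a genome compared with itself
    pass the same dict twice: mirrored pairs and the self-diagonal are
    collapsed.
    """
    same = genes_a is genes_b or (
        genes_a and genes_b and next(iter(genes_a.values())).genome == next(iter(genes_b.values())).genome
    )
    cells: dict[tuple[str, str], dict[tuple[int, int], tuple[str, str]]] = defaultdict(dict)
    for h in hits:
        ga, gb = genes_a.get(h.query), genes_b.get(h.subject)
        if ga is None or gb is None:
            continue
        if same and ga.gene_id == gb.gene_id:
            continue
        if same and (ga.chrom, ga.rank) > (gb.chrom, gb.rank):
            ga, gb = gb, ga  # canonical orientation collapses mirrored hits
        cells[(ga.chrom, gb.chrom)].setdefault((ga.rank, gb.rank), (ga.gene_id, gb.gene_id))

    blocks: list[CollinearBlock] = []
    counter = 0
    genome_a = next(iter(genes_a.values())).genome if genes_a else "?"
    genome_b = next(iter(genes_b.values())).genome if genes_b else "?"
    for (ca, cb) in sorted(cells):
        remaining = dict(cells[(ca, cb)])
        while remaining:
            chain, orientation = best_chain(list(remaining), max_gap)
            if len(chain) < min_anchors:
                break
            counter += 1
            anchors = [remaining[pt] for pt in chain]
            for pt in chain:
                del remaining[pt]
            blocks.append(
                CollinearBlock(
                    block_id=f"{block_prefix}{counter:04d}",
                    genome_a=genome_a, genome_b=genome_b,
                    chrom_a=ca, chrom_b=cb,
                    anchors=anchors, orientation=orientation,
                )
            )
    return blocks


def block_permutation_pvalue(
    points: list[tuple[int, int]],
    observed_anchors: int,
    max_gap: int = DEFAULT_MAX_GAP,
    rounds: int = 1000,
    rng: np.random.Generator | None = None,
) -> float:
    """Permutation significance of a chained block.

    Shuffles the second-axis ranks among the dot-plot points (destroying
    order conservation while keeping the marginal rank sets), re-chains,
    and asks how often a chain of >= ``observed_anchors`` arises by
    chance: p = (1 + hits) / (rounds + 1).  An optional complement to the
    min-anchor threshold for borderline blocks.
    """
    rng = np.random.default_rng() if rng is None else rng
    ra = [p[0] for p in points]
    rb = np.array([p[1] for p in points])
    hits = 0
    for _ in range(rounds):
        perm = rng.permutation(rb)
        shuffled = list(zip(ra, (int(x) for x in perm)))
        chain, _ = best_chain(shuffled, max_gap)
        if len(chain) >= observed_anchors:
            hits += 1
    return (1 + hits) / (rounds + 1)


def block_anchor_ks(block: CollinearBlock, cds: dict[str, str], max_anchors: int = 50) -> list[float]:
    """Synonymous distances (JC-corrected Ps) of up to ``max_anchors``
    evenly spaced anchors; saturated or uncomputable pairs are skipped."""
    anchors = block.anchors
    if len(anchors) > max_anchors:
        idx = np.linspace(0, len(anchors) - 1, max_anchors).astype(int)
        anchors = [anchors[i] for i in idx]
    values = []
    for ga, gb in anchors:
        sa, sb = cds.get(ga, ""), cds.get(gb, "")
        if not sa or not sb or len(sa) != len(sb):
            continue
        try:
            d = pair_distances(sa, sb, ga, gb)
        except ValueError:
            continue
        if d.Ps is not None:
            values.append(d.Ps)
    return values


def label_block_relation(
    block: CollinearBlock,
    anchor_ks: list[float],
    ks_cutoff: float = DEFAULT_KS_CUTOFF,
) -> str:
    """Label a block paralogous / orthologous / ambiguous.

    Within-genome blocks are paralogous by construction.  Between-genome
    blocks are orthologous when the median anchor Ks falls below the
    cutoff (default 0.3, between the orthologue and WGD-paralogue modes)
    and paralogous above it; blocks with fewer than three computable Ks
    values are ambiguous and excluded from quartet building.
    """
    block.median_ks = float(np.median(anchor_ks)) if anchor_ks else None
    if block.genome_a == block.genome_b:
        block.relation = "paralogous"
    elif len(anchor_ks) < 3:
        block.relation = "ambiguous"
    elif block.median_ks < ks_cutoff:
        block.relation = "orthologous"
    else:
        block.relation = "paralogous"
    return block.relation


def best_bidirectional_hits(
    hits_ab: list[HomologyHit], hits_ba: list[HomologyHit]
) -> list[tuple[str, str]]:
    """Pairs (a, b) where each is the other's best hit.

    Directional best = highest bit score, ties broken by lower E-value,
    then lexicographic subject id.
    """

    def bests(hits: list[HomologyHit]) -> dict[str, str]:
        best: dict[str, HomologyHit] = {}
        for h in hits:
            if h.query == h.subject:
                continue
            cur = best.get(h.query)
            if cur is None or (-h.bitscore, h.evalue, h.subject) < (
                -cur.bitscore, cur.evalue, cur.subject
            ):
                best[h.query] = h
        return {q: h.subject for q, h in best.items()}

    fwd = bests(hits_ab)
    rev = bests(hits_ba)
    return sorted((a, b) for a, b in fwd.items() if rev.get(b) == a)


def build_quartets(
    paralog_pairs_a: list[tuple[str, str]],
    ortholog_pairs_ab: list[tuple[str, str]],
    genome_a: str,
    genome_b: str,
    source_blocks: dict | None = None,
) -> list[Quartet]:
    """Assemble quartets: a quartet is emitted iff both paralogues have an
    orthologue in genome B; deduplicated on the unordered paralogue pair.

    ``ortholog_pairs_ab`` is reduced to a 1:1 mapping first-come (pass it
    ordered by priority: block anchors before BBH supplements).
    """
    a_to_b: dict[str, str] = {}
    used_b: set[str] = set()
    for a, b in ortholog_pairs_ab:
        if a in a_to_b or b in used_b:
            continue
        a_to_b[a] = b
        used_b.add(b)
    quartets = []
    seen = set()
    for o1, o2 in paralog_pairs_a:
        s1, s2 = a_to_b.get(o1), a_to_b.get(o2)
        if s1 is None or s2 is None or s1 == s2:
            continue
        key = frozenset((o1, o2))
        if key in seen:
            continue
        seen.add(key)
        quartets.append(
            Quartet(
                genome_a=genome_a, genome_b=genome_b,
                o1=o1, o2=o2, s1=s1, s2=s2,
                source_blocks=tuple((source_blocks or {}).get(key, ())),
            )
        )
    return quartets


def infer_ancestral_content(
    ortholog_pairs: dict[tuple[str, str], list[tuple[str, str]]],
    genomes: dict[str, dict[str, GeneRecord]],
) -> tuple[int, dict[str, float]]:
    """Ancestral locus count and per-genome loss rates from orthologue
    connectivity across three (or more) genomes.

    Loci are connected components of the orthologue graph; a component is
    counted ancestral when it contains genes from at least two genomes,
    and a genome's loss rate is the fraction of ancestral loci it lacks.
    """
    if len(genomes) < 3:
        raise ValueError("ancestral-content inference needs three genomes")
    parent: dict[str, str] = {}

    def find(x: str) -> str:
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: str, y: str) -> None:
        rx, ry = find(x), find(y)
        if rx != ry:
            parent[ry] = rx

    gene_genome = {
        gid: genome for genome, recs in genomes.items() for gid in recs
    }
    for pairs in ortholog_pairs.values():
        for a, b in pairs:
            union(a, b)
    components: dict[str, set[str]] = defaultdict(set)
    for gid in parent:
        if gid in gene_genome:
            components[find(gid)].add(gene_genome[gid])
    ancestral = [gs for gs in components.values() if len(gs) >= 2]
    n_anc = len(ancestral)
    losses = {
        genome: (
            sum(1 for gs in ancestral if genome not in gs) / n_anc if n_anc else 0.0
        )
        for genome in genomes
    }
    return n_anc, losses


# ---------------------------------------------------------------------------
# assembled homology stage


@dataclass
class HomologyResult:
    blocks: list[CollinearBlock]
    paralog_pairs: dict[str, list[tuple[str, str]]]  # genome -> pairs
    ortholog_pairs: dict[tuple[str, str], list[tuple[str, str]]]  # (gA,gB) -> pairs
    quartets: dict[tuple[str, str], list[Quartet]]
    ancestral_count: int
    loss_rates: dict[str, float]


def _in_labelled_region(
    pair: tuple[str, str],
    blocks: list[CollinearBlock],
    genes_a: dict[str, GeneRecord],
    genes_b: dict[str, GeneRecord],
) -> bool:
    ga, gb = genes_a.get(pair[0]), genes_b.get(pair[1])
    if ga is None or gb is None:
        return False
    for blk in blocks:
        ranks_a = [genes_a[x].rank for x, _ in blk.anchors if x in genes_a]
        ranks_b = [genes_b[y].rank for _, y in blk.anchors if y in genes_b]
        for (ca, cb, ra, rb) in (
            (blk.chrom_a, blk.chrom_b, ga, gb),
            (blk.chrom_b, blk.chrom_a, gb, ga),
        ):
            if ra.chrom == ca and rb.chrom == cb and ranks_a and ranks_b:
                if (
                    min(ranks_a) <= ra.rank <= max(ranks_a)
                    and min(ranks_b) <= rb.rank <= max(ranks_b)
                ):
                    return True
    return False


def homology_pipeline(
    genomes: dict[str, list[GeneRecord]],
    hits: list[HomologyHit],
    max_evalue: float = DEFAULT_MAX_EVALUE,
    min_score: float = DEFAULT_MIN_SCORE,
    max_gap: int = DEFAULT_MAX_GAP,
    min_anchors: int = DEFAULT_MIN_ANCHORS,
    family_cap: int = DEFAULT_FAMILY_CAP,
    ks_cutoff: float = DEFAULT_KS_CUTOFF,
) -> HomologyResult:
    """Run the homology stage end to end: filter hits, drop large
    families, chain blocks within and between genomes, label relations,
    supplement with BBH pairs inside labelled regions, build quartets,
    and estimate ancestral gene content and per-genome loss rates."""
    gene_index = {g: {r.gene_id: r for r in recs} for g, recs in genomes.items()}
    all_genes = {gid: rec for idx in gene_index.values() for gid, rec in idx.items()}
    cds = {gid: rec.cds for gid, rec in all_genes.items()}

    kept = filter_hits(hits, max_evalue, min_score)
    chained_input = remove_large_families(kept, all_genes, family_cap)

    def hits_between(ga: str, gb: str) -> list[HomologyHit]:
        return [
            h
            for h in chained_input
            if h.query in gene_index[ga] and h.subject in gene_index[gb]
        ]

    def bbh_between(ga: str, gb: str) -> list[tuple[str, str]]:
        ab = [h for h in kept if h.query in gene_index[ga] and h.subject in gene_index[gb]]
        ba = [h for h in kept if h.query in gene_index[gb] and h.subject in gene_index[ga]]
        return best_bidirectional_hits(ab, ba)

    names = sorted(genomes)
    blocks: list[CollinearBlock] = []
    paralog_pairs: dict[str, list[tuple[str, str]]] = {}
    for g in names:
        gblocks = chain_collinear_blocks(
            hits_between(g, g), gene_index[g], gene_index[g],
            max_gap, min_anchors, block_prefix=f"{g}_P",
        )
        for blk in gblocks:
            label_block_relation(blk, block_anchor_ks(blk, cds), ks_cutoff)
        para_blocks = [b for b in gblocks if b.relation == "paralogous"]
        pairs = [a for b in para_blocks for a in b.anchors]
        anchor_set = {frozenset(p) for p in pairs}
        for pair in bbh_between(g, g):
            if frozenset(pair) in anchor_set:
                continue
            if _in_labelled_region(pair, para_blocks, gene_index[g], gene_index[g]):
                pairs.append(pair)
                anchor_set.add(frozenset(pair))
        paralog_pairs[g] = pairs
        blocks.extend(gblocks)

    ortholog_pairs: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for i, ga in enumerate(names):
        for gb in names[i + 1 :]:
            gblocks = chain_collinear_blocks(
                hits_between(ga, gb), gene_index[ga], gene_index[gb],
                max_gap, min_anchors, block_prefix=f"{ga}_{gb}_O",
            )
            for blk in gblocks:
                label_block_relation(blk, block_anchor_ks(blk, cds), ks_cutoff)
            orth_blocks = [b for b in gblocks if b.relation == "orthologous"]
            pairs = [a for b in orth_blocks for a in b.anchors]
            pair_set = {frozenset(p) for p in pairs}
            for pair in bbh_between(ga, gb):
                if frozenset(pair) in pair_set:
                    continue
                if _in_labelled_region(pair, orth_blocks, gene_index[ga], gene_index[gb]):
                    pairs.append(pair)
                    pair_set.add(frozenset(pair))
            ortholog_pairs[(ga, gb)] = pairs
            blocks.extend(gblocks)

    quartets: dict[tuple[str, str], list[Quartet]] = {}
    for (ga, gb), orth in ortholog_pairs.items():
        quartets[(ga, gb)] = build_quartets(paralog_pairs[ga], orth, ga, gb)
        quartets[(gb, ga)] = build_quartets(
            paralog_pairs[gb], [(b, a) for a, b in orth], gb, ga
        )

    n_anc, losses = infer_ancestral_content(ortholog_pairs, gene_index)
    return HomologyResult(
        blocks=blocks,
        paralog_pairs=paralog_pairs,
        ortholog_pairs=ortholog_pairs,
        quartets=quartets,
        ancestral_count=n_anc,
        loss_rates=losses,
    )
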