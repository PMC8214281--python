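"""Conversion detection within homologous gene quartets.

Whole-gene conversion is called from two topology tests on the quartet
(O1, O2 paralogues in one genome; S1, S2 their orthologues in the other):

* WCV (Ks criterion): Ks(O1,O2) < min(Ks(O1,S1), Ks(O2,S2)), strictly —
  the paralogues look younger than the species split.  Confidence comes
  from bootstrap resampling of aligned codon columns (default 1000
  replicates).
* WCV (identity criterion): amino-acid identity id(O1,O2) strictly above
  both orthologue identities.  Strict inequalities mean ties never call,
  so zero-divergence quartets are guaranteed silent.

Partial conversion (PCV) scores each ungapped aligned site
s(i) = dO(i) − dP(i), where dP marks a paralogue difference and dO is the
mean of the two orthologue-pair differences; runs where orthologues
differ but paralogues agree score positive.  All maximal-scoring
subsequences (Ruzzo–Tompa) of length >= 10 nt are candidate tracts;
weaker tracts must beat the best segment of shuffled score arrays in a
bootstrap, and accepted tracts are masked and the search repeated so
multiple conversion events per gene are recovered.

Donors are inferred from which paralogue keeps the higher orthologue
identity (on the tract, for PCV); calls are merged per genome across
quartets, and events in the two sibling genomes are assigned to period A
(before their split: detected in both) or B (after: detected in one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import ConversionCall, Quartet
from .seqdist import (
    QuartetAlignment,
    distances_from_sums,
    pair_site_arrays,
    pairwise_gap_and_identity,
)

__all__ = [
    "SiteScores",
    "QuartetContext",
    "detect_wcv_ks",
    "detect_wcv_identity",
    "build_site_scores",
    "ruzzo_tompa",
    "max_segment_sum",
    "detect_pcv",
    "infer_donor",
    "analyze_quartet",
    "merge_calls",
    "assign_period",
    "build_pair_map",
]

DEFAULT_N_BOOT = 1000
DEFAULT_SUPPORT = 0.95
DEFAULT_MIN_TRACT_LEN = 10
DEFAULT_MIN_TRACT_SCORE = 2.0
DEFAULT_STRONG_SCORE = 4.0
DEFAULT_DONOR_MARGIN = 0.005

_PAIRS = {
    "A": {"para": (0, 1), "orth": ((0, 2), (1, 3))},
    "B": {"para": (2, 3), "orth": ((0, 2), (1, 3))},
}


@dataclass
class QuartetContext:
    """Per-quartet precomputation shared by the detectors."""

    quartet: Quartet
    alignment: QuartetAlignment
    arrays: dict[tuple[int, int], dict[str, np.ndarray]]

    @classmethod
    def build(cls, quartet: Quartet, alignment: QuartetAlignment) -> "QuartetContext":
        needed = {(0, 1), (2, 3), (0, 2), (1, 3)}
        arrays = {
            pair: pair_site_arrays(alignment.nt[pair[0]], alignment.nt[pair[1]])
            for pair in needed
        }
        return cls(quartet=quartet, alignment=alignment, arrays=arrays)

    def genome(self, side: str) -> str:
        return self.quartet.genome_a if side == "A" else self.quartet.genome_b

    def paralogues(self, side: str) -> tuple[str, str]:
        q = self.quartet
        return (q.o1, q.o2) if side == "A" else (q.s1, q.s2)

    def distances(self, pair: tuple[int, int]):
        arr = self.arrays[pair]
        n = int(arr["valid"].sum())
        if n == 0:
            return None
        return distances_from_sums(
            float(arr["s_sites"].sum()), float(arr["n_sites"].sum()),
            float(arr["syn_diff"].sum()), float(arr["nsyn_diff"].sum()),
            float(arr["aa_match"].sum()), n,
        )


def _boot_ps(arr: dict[str, np.ndarray], counts: np.ndarray) -> np.ndarray:
    """Bootstrap synonymous proportions from codon-column resampling
    counts (n_boot × n_columns); saturated replicates come out as inf."""
    s = counts @ arr["s_sites"]
    sd = counts @ arr["syn_diff"]
    with np.errstate(divide="ignore", invalid="ignore"):
        ps = np.where(s > 0, sd / np.maximum(s, 1e-300), 0.0)
    return ps


def detect_wcv_ks(
    ctx: QuartetContext,
    side: str = "A",
    n_boot: int = DEFAULT_N_BOOT,
    support_threshold: float = DEFAULT_SUPPORT,
    rng: np.random.Generator | None = None,
) -> ConversionCall | None:
    """Whole-gene conversion by the Ks topology criterion, with codon-
    column bootstrap support.

    A call is emitted iff Ks(paralogues) < min(Ks of both orthologue
    pairs), strictly, all four distances are computable (unsaturated),
    and the bootstrap frequency of the inequality reaches the support
    threshold.
    """
    rng = np.random.default_rng() if rng is None else rng
    spec = _PAIRS[side]
    pairs = [spec["para"], *spec["orth"]]
    dists = [ctx.distances(p) for p in pairs]
    if any(d is None or d.Ps is None for d in dists):
        return None
    ks_para, ks_o1, ks_o2 = (d.Ps for d in dists)
    if not (ks_para < ks_o1 and ks_para < ks_o2):
        return None
    n_cols = len(ctx.arrays[pairs[0]]["valid"])
    counts = rng.multinomial(n_cols, np.full(n_cols, 1.0 / n_cols), size=n_boot)
    ps = [_boot_ps(ctx.arrays[p], counts) for p in pairs]
    p_sat = 0.75
    ok = (
        (ps[0] < ps[1]) & (ps[0] < ps[2])
        & (ps[0] < p_sat) & (ps[1] < p_sat) & (ps[2] < p_sat)
    )
    support = float(ok.mean())
    if support < support_threshold:
        return None
    g1, g2 = ctx.paralogues(side)
    return ConversionCall(
        genome=ctx.genome(side), gene1=g1, gene2=g2,
        methods={"wcv_ks"}, support=support,
    )


def detect_wcv_identity(ctx: QuartetContext, side: str = "A") -> ConversionCall | None:
    """Whole-gene conversion by the amino-acid identity criterion:
    id(paralogues) strictly above both orthologue identities (site-by-site
    over each pair's ungapped columns); ties never call."""
    spec = _PAIRS[side]
    aa = ctx.alignment.aa

    def ident(pair: tuple[int, int]) -> float:
        return pairwise_gap_and_identity(aa[pair[0]], aa[pair[1]])[1]

    id_para = ident(spec["para"])
    id_o1, id_o2 = (ident(p) for p in spec["orth"])
    if not (id_para > id_o1 and id_para > id_o2):
        return None
    g1, g2 = ctx.paralogues(side)
    return ConversionCall(
        genome=ctx.genome(side), gene1=g1, gene2=g2, methods={"wcv_identity"}
    )


@dataclass
class SiteScores:
    """Per-site conversion scores for one genome side of a quartet.

    ``scores[i]`` = dO(i) − dP(i) over the alignment columns ungapped in
    all four rows; ``aln_pos`` maps each scored site back to its 1-based
    alignment coordinate and ``cds_pos`` to the 1-based CDS coordinate in
    each of the two paralogues.
    """

    scores: np.ndarray
    aln_pos: np.ndarray
    cds_pos: dict[str, np.ndarray]


def build_site_scores(ctx: QuartetContext, side: str = "A") -> SiteScores:
    """Site score array s = dO − dP for one genome side.

    dP(i) is 1 where the paralogues differ; dO(i) averages the two
    orthologue-pair differences, so s ∈ {−1, −0.5, 0, 0.5, 1}.
    """
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in ctx.alignment.nt]
    gap = np.full(rows[0].shape, False)
    for r in rows:
        gap |= r == b"-"
    keep = ~gap
    spec = _PAIRS[side]
    i, j = spec["para"]
    dP = (rows[i] != rows[j])[keep].astype(float)
    (a1, b1), (a2, b2) = spec["orth"]
    dO = 0.5 * (
        (rows[a1] != rows[b1])[keep].astype(float)
        + (rows[a2] != rows[b2])[keep].astype(float)
    )
    aln_pos = np.nonzero(keep)[0] + 1
    cds_pos = {}
    for gid, row_idx in zip(ctx.alignment.ids, range(4)):
        ungapped = np.cumsum(rows[row_idx] != b"-")
        cds_pos[gid] = ungapped[keep]
    return SiteScores(scores=dO - dP, aln_pos=aln_pos, cds_pos=cds_pos)


def ruzzo_tompa(scores: np.ndarray) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences of ``scores``.

    Returns (start, end, total) with 0-based half-open coordinates.  A
    reported segment has strictly positive partial sums over all its
    prefixes and suffixes and cannot be extended to a longer segment with
    that property (the Ruzzo–Tompa maximal segments); segments therefore
    begin and end on positive scores and are mutually disjoint.
    """
    # stack of candidate segments: (start, end, L, R) with L/R cumulative
    # scores just before the segment and at its end
    stack: list[list] = []
    cum = 0.0
    for k, x in enumerate(np.asarray(scores, dtype=float)):
        prev = cum
        cum += x
        if x <= 0:
            continue
        cur = [k, k + 1, prev, cum]
        while True:
            # rightmost stacked segment whose left cumulative is below ours
            j = len(stack) - 1
            while j >= 0 and stack[j][2] >= cur[2]:
                j -= 1
            if j < 0 or stack[j][3] >= cur[3]:
                stack.append(cur)
                break
            # stacked segment j is dominated: merge it (and everything
            # after it) into the current candidate and retry
            merged = [stack[j][0], cur[1], stack[j][2], cur[3]]
            del stack[j:]
            cur = merged
    return [(int(s), int(e), r - l) for s, e, l, r in stack]


def max_segment_sum(scores: np.ndarray) -> np.ndarray:
    """Row-wise maximum contiguous-segment sum (Kadane via cumulative
    minima); accepts a 1-D or 2-D array, empty segments score 0."""
    arr = np.asarray(scores, dtype=float)
    x = np.atleast_2d(arr)
    cum = np.cumsum(x, axis=1)
    zeros = np.zeros((x.shape[0], 1))
    cmin = np.minimum.accumulate(np.concatenate([zeros, cum], axis=1), axis=1)
    best = np.maximum(np.max(cum - cmin[:, :-1], axis=1), 0.0)
    return best if arr.ndim > 1 else float(best[0])


def detect_pcv(
    scores: np.ndarray,
    min_len: int = DEFAULT_MIN_TRACT_LEN,
    min_score: float = DEFAULT_MIN_TRACT_SCORE,
    strong_score: float = DEFAULT_STRONG_SCORE,
    n_boot: int = DEFAULT_N_BOOT,
    support_threshold: float = DEFAULT_SUPPORT,
    rng: np.random.Generator | None = None,
) -> list[tuple[int, int, float, float]]:
    """Partial-conversion tracts from a site score array.

    Maximal-scoring subsequences of length >= ``min_len`` and sum >=
    ``min_score`` are candidates; those below ``strong_score`` must beat
    the best segment of a shuffled score array in at least
    ``support_threshold`` of ``n_boot`` shuffles.  Accepted tracts are
    masked (scores zeroed) and the search repeated, so shorter fragments
    behind a large tract are still recovered.  Returns (start, end, sum,
    support) tuples, 0-based half-open on the scored-site axis,
    non-overlapping and sorted.
    """
    rng = np.random.default_rng() if rng is None else rng
    work = np.asarray(scores, dtype=float).copy()
    out: list[tuple[int, int, float, float]] = []
    if work.size == 0:
        return out
    while True:
        accepted = []
        for start, end, total in ruzzo_tompa(work):
            if end - start < min_len or total < min_score:
                continue
            if total >= strong_score:
                support = 1.0
            else:
                shuffles = np.tile(work, (n_boot, 1))
                shuffles = rng.permuted(shuffles, axis=1)
                null_max = max_segment_sum(shuffles)
                support = float((total > null_max).mean())
                if support < support_threshold:
                    continue
            accepted.append((start, end, total, support))
        if not accepted:
            break
        for start, end, total, support in accepted:
            out.append((start, end, total, support))
            work[start:end] = 0.0
    return sorted(out)


def infer_donor(
    ctx: QuartetContext,
    side: str,
    site_mask: np.ndarray | None = None,
    min_margin: float = DEFAULT_DONOR_MARGIN,
) -> str:
    """Donor gene for a conversion call on one genome side.

    The paralogue whose orthologue identity stays higher is the donor
    (its sequence was not overwritten); a margin below ``min_margin``, or
    uncomputable identities, give "uncertain".  ``site_mask`` restricts
    the comparison to tract columns (codon columns overlapping the tract)
    for partial events.
    """
    spec = _PAIRS[side]
    idents = []
    for pair in spec["orth"]:
        arr = ctx.arrays[pair]
        valid = arr["valid"]
        match = arr["aa_match"]
        if site_mask is not None:
            valid = valid & site_mask
            match = match & site_mask
        n = int(valid.sum())
        if n == 0:
            return "uncertain"
        idents.append(float(match.sum()) / n)
    g1, g2 = ctx.paralogues(side)
    if abs(idents[0] - idents[1]) < min_margin:
        return "uncertain"
    return g1 if idents[0] > idents[1] else g2


def analyze_quartet(
    ctx: QuartetContext,
    sides: tuple[str, ...] = ("A", "B"),
    n_boot: int = DEFAULT_N_BOOT,
    support_threshold: float = DEFAULT_SUPPORT,
    min_tract_len: int = DEFAULT_MIN_TRACT_LEN,
    min_tract_score: float = DEFAULT_MIN_TRACT_SCORE,
    strong_score: float = DEFAULT_STRONG_SCORE,
    donor_margin: float = DEFAULT_DONOR_MARGIN,
    rng: np.random.Generator | None = None,
) -> list[ConversionCall]:
    """Run all three detectors on one aligned quartet and combine the
    per-side results into at most one call per genome side."""
    rng = np.random.default_rng() if rng is None else rng
    calls: list[ConversionCall] = []
    for side in sides:
        g1, g2 = ctx.paralogues(side)
        call = ConversionCall(genome=ctx.genome(side), gene1=g1, gene2=g2)
        wcv_ks = detect_wcv_ks(ctx, side, n_boot, support_threshold, rng)
        if wcv_ks:
            call.methods |= wcv_ks.methods
            call.support = wcv_ks.support
        wcv_id = detect_wcv_identity(ctx, side)
        if wcv_id:
            call.methods |= wcv_id.methods
        if call.is_wcv:
            call.donor = infer_donor(ctx, side, min_margin=donor_margin)
        else:
            ss = build_site_scores(ctx, side)
            tracts = detect_pcv(
                ss.scores, min_tract_len, min_tract_score, strong_score,
                n_boot, support_threshold, rng,
            )
            if tracts:
                call.methods.add("pcv")
                donors = set()
                n_cols = ctx.alignment.length // 3
                for start, end, total, support in tracts:
                    codon_mask = np.zeros(n_cols, dtype=bool)
                    cols = (ss.aln_pos[start:end] - 1) // 3
                    codon_mask[np.unique(cols)] = True
                    tract_donor = infer_donor(ctx, side, codon_mask, donor_margin)
                    donors.add(tract_donor)
                    acceptor = g1 if tract_donor == g2 else g2
                    cds = ss.cds_pos[acceptor][start:end]
                    call.tracts.append((int(cds[0]), int(cds[-1])))
                    call.aln_tracts.append(
                        (int(ss.aln_pos[start]), int(ss.aln_pos[end - 1]))
                    )
                    call.tract_support.append(support)
                call.donor = donors.pop() if len(donors) == 1 else "uncertain"
        if call.methods:
            calls.append(call)
    return calls


def merge_calls(calls: list[ConversionCall]) -> list[ConversionCall]:
    """Merge calls for the same unordered paralogue pair within a genome.

    Method flags are OR-combined, overlapping tracts unioned, donors kept
    only when consistent, and the best bootstrap support retained.
    Idempotent.
    """
    merged: dict[tuple, ConversionCall] = {}
    donors: dict[tuple, set[str]] = {}
    for c in calls:
        key = (c.genome, c.pair)
        if key not in merged:
            g1, g2 = sorted((c.gene1, c.gene2))
            merged[key] = ConversionCall(genome=c.genome, gene1=g1, gene2=g2)
            donors[key] = set()
        m = merged[key]
        m.methods |= c.methods
        if c.support is not None and (m.support is None or c.support > m.support):
            m.support = c.support
        if c.donor != "uncertain":
            donors[key].add(c.donor)
        tagged = sorted(
            list(zip(m.tracts, m.tract_support)) + list(zip(c.tracts, c.tract_support))
        )
        new_tracts: list[tuple[int, int]] = []
        new_support: list[float] = []
        for (s, e), sup in tagged:
            if new_tracts and s <= new_tracts[-1][1] + 1:
                ps, pe = new_tracts[-1]
                new_tracts[-1] = (ps, max(pe, e))
                new_support[-1] = max(new_support[-1], sup)
            else:
                new_tracts.append((s, e))
                new_support.append(sup)
        m.tracts, m.tract_support = new_tracts, new_support
        m.aln_tracts = []  # alignment frames differ across quartets
        if c.period != "unassigned":
            m.period = c.period
    for key, m in merged.items():
        m.donor = donors[key].pop() if len(donors[key]) == 1 else "uncertain"
    return sorted(merged.values(), key=lambda c: (c.genome, c.gene1, c.gene2))


def build_pair_map(quartets: list[Quartet]) -> dict[frozenset, frozenset]:
    """Orthologous-position map between paralogue pairs of two genomes,
    derived from the quartets linking them (both directions)."""
    out: dict[frozenset, frozenset] = {}
    for q in quartets:
        a = frozenset((q.o1, q.o2))
        b = frozenset((q.s1, q.s2))
        out.setdefault(a, b)
        out.setdefault(b, a)
    return out


def assign_period(
    merged_calls: dict[str, list[ConversionCall]],
    sibling_genomes: tuple[str, str],
    pair_map: dict[frozenset, frozenset],
) -> dict[str, dict[str, int]]:
    """Assign period A/B to the sibling genomes' calls.

    A converted pair found (at the orthologous position, via
    ``pair_map``) in both siblings converted before their split: period
    A; found in exactly one: period B.  Other genomes stay unassigned.
    Returns per-genome counts and the B/(A+B) fraction.
    """
    sib1, sib2 = sibling_genomes
    if sib1 not in merged_calls or sib2 not in merged_calls:
        for calls in merged_calls.values():
            for c in calls:
                c.period = "unassigned"
        return {}
    pairs2 = {c.pair for c in merged_calls[sib2]}
    pairs1 = {c.pair for c in merged_calls[sib1]}
    for genome, other_pairs in ((sib1, pairs2), (sib2, pairs1)):
        for c in merged_calls[genome]:
            counterpart = pair_map.get(c.pair)
            c.period = "A" if (counterpart in other_pairs) else "B"
    summary = {}
    for genome in sibling_genomes:
        a = sum(1 for c in merged_calls[genome] if c.period == "A")
        b = sum(1 for c in merged_calls[genome] if c.period == "B")
        summary[genome] = {
            "period_A": a,
            "period_B": b,
            "fraction_B": b / (a + b) if a + b else 0.0,
        }
    return summary
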