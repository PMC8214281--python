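"""Independent brute-force oracles used by the test suite.

These are deliberately naive re-derivations — built from the Biopython
codon table and explicit enumeration — and share no code with the
package's implementations.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from Bio.Seq import Seq

BASES = "TCAG"

from functools import lru_cache


@lru_cache(maxsize=None)
def _aa(codon: str) -> str:
    return str(Seq(codon).translate())


def ng_pair_brute(codons_a: list[str], codons_b: list[str]):
    """Nei–Gojobori sums for an aligned codon list pair, by enumeration.

    Returns (S, N, Sd, Nd, aa_matches, n_codons).  Site counts exclude
    stop-codon mutations from the per-position denominator; differences
    average over all minimal mutational paths avoiding stops (falling
    back to all paths when none avoids a stop).
    """
    S = N = Sd = Nd = 0.0
    matches = 0
    n = 0
    for ca, cb in zip(codons_a, codons_b):
        if "-" in ca or "-" in cb or _aa(ca) == "*" or _aa(cb) == "*":
            continue
        n += 1
        matches += _aa(ca) == _aa(cb)
        for codon in (ca, cb):
            for pos in range(3):
                syn = tot = 0
                for b in BASES:
                    if b == codon[pos]:
                        continue
                    mut = codon[:pos] + b + codon[pos + 1 :]
                    if _aa(mut) == "*":
                        continue
                    tot += 1
                    syn += _aa(mut) == _aa(codon)
                if tot:
                    S += 0.5 * syn / tot
                    N += 0.5 * (1 - syn / tot)
        diff = [i for i in range(3) if ca[i] != cb[i]]
        if not diff:
            continue
        paths = []
        for order in permutations(diff):
            cur = ca
            steps = []
            clean = True
            for pos in order:
                nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
                if _aa(nxt) == "*":
                    clean = False
                steps.append((_aa(cur), _aa(nxt)))
                cur = nxt
            paths.append((clean, steps))
        usable = [s for ok, s in paths if ok] or [s for _, s in paths]
        sd = nd = 0.0
        for steps in usable:
            for a1, a2 in steps:
                if a1 == a2:
                    sd += 1
                else:
                    nd += 1
        Sd += sd / len(usable)
        Nd += nd / len(usable)
    return S, N, Sd, Nd, matches, n


def maximal_segments_brute(scores) -> list[tuple[int, int, float]]:
    """All maximal-scoring subsequences by direct enumeration.

    A segment qualifies when all proper prefixes and suffixes have
    strictly positive sums; maximal segments are those not strictly
    contained in another qualifying segment.
    """
    s = np.asarray(scores, dtype=float)
    n = len(s)
    c = np.concatenate([[0.0], np.cumsum(s)])
    cands = []
    for i in range(n):
        running_min = np.inf  # min of c[i+1..j] -> all prefixes positive
        running_max = c[i]  # max of c[i..j-1] -> all suffixes positive
        for j in range(i + 1, n + 1):
            running_min = min(running_min, c[j])
            if j > i + 1:
                running_max = max(running_max, c[j - 1])
            if running_min - c[i] > 0 and c[j] - running_max > 0:
                cands.append((i, j, c[j] - c[i]))
    out = [
        x
        for x in cands
        if not any(
            y[0] <= x[0] and x[1] <= y[1] and (y[0] < x[0] or y[1] > x[1])
            for y in cands
        )
    ]
    return sorted(out)


def best_chain_brute(points: list[tuple[int, int]], max_gap: int):
    """Best monotonic chain by exhaustive subset enumeration.

    Considers every subset of points, keeps those forming a valid
    ascending or descending chain under the gap constraint, and returns
    the longest (ties: ascending first, then lexicographically smallest
    anchor sequence) together with its orientation.
    """

    def valid(seq: list[tuple[int, int]], descending: bool) -> bool:
        for (a1, b1), (a2, b2) in zip(seq, seq[1:]):
            if a2 <= a1 or a2 - a1 - 1 > max_gap:
                return False
            if descending:
                if b2 >= b1 or b1 - b2 - 1 > max_gap:
                    return False
            else:
                if b2 <= b1 or b2 - b1 - 1 > max_gap:
                    return False
        return True

    best = None
    best_key = None
    pts = sorted(points)
    for size in range(1, len(pts) + 1):
        for combo in combinations(pts, size):
            seq = list(combo)
            for orientation, descending in (("+", False), ("-", True)):
                if not valid(seq, descending):
                    continue
                key = (-size, seq, 0 if orientation == "+" else 1)
                if best_key is None or key < best_key:
                    best, best_key = (seq, orientation), key
    return best if best is not None else ([], "+")
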