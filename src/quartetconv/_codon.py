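"""Codon-level lookup tables for Nei–Gojobori site and difference counting.

Everything here is precomputed once at import: per-codon synonymous /
nonsynonymous site counts and, for every ordered codon pair, the
path-averaged synonymous / nonsynonymous difference counts.  The rest of
the package only does table lookups, which keeps per-pair distance
computation vectorisable.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np

BASES = "TCAG"
CODONS = [a + b + c for a in BASES for b in BASES for c in BASES]
CODON_INDEX = {c: i for i, c in enumerate(CODONS)}

# Standard genetic code (NCBI table 1).
_AA = (
    "FFLLSSSSYY**CC*W"
    "LLLLPPPPHHQQRRRR"
    "IIIMTTTTNNKKSSRR"
    "VVVVAAAADDEEGGGG"
)
AA_BY_CODON = {c: _AA[i] for i, c in enumerate(CODONS)}
STOP_CODONS = frozenset(c for c in CODONS if AA_BY_CODON[c] == "*")


def _one_step_neighbours(codon: str, pos: int):
    for b in BASES:
        if b != codon[pos]:
            yield codon[:pos] + b + codon[pos + 1 :]


def _site_counts(codon: str) -> tuple[float, float]:
    """Synonymous/nonsynonymous site counts for one codon.

    Per position the synonymous fraction is the share of one-step
    neighbours encoding the same amino acid; neighbours that are stop
    codons are excluded from the denominator so S + N = 3 for every
    sense codon.
    """
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} has no site counts")
    s_total = 0.0
    for pos in range(3):
        neighbours = [n for n in _one_step_neighbours(codon, pos) if n not in STOP_CODONS]
        if not neighbours:  # cannot happen with the standard code
            continue
        syn = sum(1 for n in neighbours if AA_BY_CODON[n] == AA_BY_CODON[codon])
        s_total += syn / len(neighbours)
    return s_total, 3.0 - s_total


def _pair_diffs(a: str, b: str) -> tuple[float, float]:
    """Path-averaged (syn, nonsyn) difference counts between two codons.

    All minimal mutational paths are enumerated; paths passing through a
    stop codon are discarded (unless every path does, in which case all
    paths are used so the pair still gets a value).  Steps are classified
    by whether the amino acid changes.
    """
    diff_pos = [i for i in range(3) if a[i] != b[i]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in permutations(diff_pos):
        cur = a
        steps = []
        ok = True
        for pos in order:
            nxt = cur[:pos] + b[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
            steps.append((cur, nxt))
            cur = nxt
        paths.append((ok, steps))
    usable = [steps for ok, steps in paths if ok] or [steps for _, steps in paths]
    sd = nd = 0.0
    for steps in usable:
        for cur, nxt in steps:
            if AA_BY_CODON[cur] == AA_BY_CODON[nxt]:
                sd += 1.0
            else:
                nd += 1.0
    k = len(usable)
    return sd / k, nd / k


def _build_tables():
    n = len(CODONS)
    s_sites = np.full(n, np.nan)
    n_sites = np.full(n, np.nan)
    syn_diff = np.full((n, n), np.nan)
    nsyn_diff = np.full((n, n), np.nan)
    aa_equal = np.zeros((n, n), dtype=bool)
    sense = np.array([c not in STOP_CODONS for c in CODONS])
    for i, a in enumerate(CODONS):
        if not sense[i]:
            continue
        s_sites[i], n_sites[i] = _site_counts(a)
        for j, b in enumerate(CODONS):
            if not sense[j]:
                continue
            syn_diff[i, j], nsyn_diff[i, j] = _pair_diffs(a, b)
            aa_equal[i, j] = AA_BY_CODON[a] == AA_BY_CODON[b]
    return s_sites, n_sites, syn_diff, nsyn_diff, aa_equal, sense


S_SITES, N_SITES, SYN_DIFF, NSYN_DIFF, AA_EQUAL, SENSE = _build_tables()

_BASE_CODE = {"T": 0, "C": 1, "A": 2, "G": 3, "U": 0}

from functools import lru_cache


@lru_cache(maxsize=200_000)
def codon_indices(seq: str) -> np.ndarray:
    """Map a nucleotide string to codon indices; -1 marks codons that are
    gapped, ambiguous, or stop codons."""
    if len(seq) % 3:
        raise ValueError("sequence length not a multiple of 3")
    out = np.full(len(seq) // 3, -1, dtype=np.int64)
    s = seq.upper()
    for k in range(len(out)):
        c = s[3 * k : 3 * k + 3]
        try:
            idx = 16 * _BASE_CODE[c[0]] + 4 * _BASE_CODE[c[1]] + _BASE_CODE[c[2]]
        except KeyError:
            continue
        if SENSE[idx]:
            out[k] = idx
    return out


def translate(cds: str) -> str:
    """Translate an ungapped CDS; raises on internal stops / bad length."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    aa = []
    s = cds.upper().replace("U", "T")
    for k in range(0, len(s), 3):
        codon = s[k : k + 3]
        if codon not in CODON_INDEX:
            raise ValueError(f"unrecognised codon {codon!r} at nt {k + 1}")
        res = AA_BY_CODON[codon]
        if res == "*":
            if k == len(s) - 3:
                break  # trailing stop tolerated, dropped
            raise ValueError(f"internal stop codon at nt {k + 1}")
        aa.append(res)
    return "".join(aa)
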