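"""Sequence distances for homologous gene quartets.

Implements the pairwise machinery the conversion tests rest on:

* codon-aware alignment of the four CDS in a quartet (progressive pairwise
  global alignment of the translated proteins, back-translated to codons);
* the divergence filters that discard unreliable quartets (pairwise gap
  fraction > 50% of the alignment, or amino-acid identity < 40%);
* Nei–Gojobori proportions of synonymous/nonsynonymous differences per
  site (pS, pN) with unweighted averaging over minimal mutational paths,
  and their Jukes–Cantor corrections Ps, Pn = -(3/4)·ln(1 - (4/3)·p).

Columns containing a gap anywhere in a codon are excluded whole-codon for
the pair concerned, which keeps the synonymous/nonsynonymous site sums
consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from . import _codon
from ._codon import CODON_INDEX, S_SITES, N_SITES, SYN_DIFF, NSYN_DIFF, AA_EQUAL
from .records import PairDistances

__all__ = [
    "QuartetRejected",
    "QuartetAlignment",
    "align_quartet",
    "filter_quartet",
    "ng_site_counts",
    "jc_correct",
    "jc_invert",
    "pair_site_arrays",
    "pair_distances",
]

JC_SATURATION = 0.75


class QuartetRejected(ValueError):
    """Raised when a quartet cannot be aligned; carries a reason code."""

    def __init__(self, reason: str, detail: str = ""):
        self.reason = reason
        super().__init__(f"{reason}: {detail}" if detail else reason)


@dataclass
class QuartetAlignment:
    """Codon-structured alignment of the four quartet CDS.

    Row order is (o1, o2, s1, s2).  Degapping any nucleotide row recovers
    the input CDS exactly.
    """

    ids: tuple[str, str, str, str]
    nt: tuple[str, str, str, str]
    aa: tuple[str, str, str, str]

    def __post_init__(self):
        lengths = {len(r) for r in self.nt}
        if len(lengths) != 1:
            raise ValueError("nucleotide rows differ in length")
        if lengths.pop() % 3:
            raise ValueError("alignment length not a multiple of 3")

    @property
    def length(self) -> int:
        return len(self.nt[0])

    def gap_fraction(self, row: int) -> float:
        s = self.nt[row]
        return s.count("-") / len(s) if s else 0.0

    def row(self, gene_id: str) -> str:
        return self.nt[self.ids.index(gene_id)]


@lru_cache(maxsize=1)
def _protein_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.mode = "global"
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    return aligner


def _merge_center_star(center: str, others: list[str]) -> list[str]:
    """Merge pairwise alignments of `center` against each other protein
    into one multiple alignment (center-star, first sequence as center)."""
    aligner = _protein_aligner()
    pairwise = []
    for other in others:
        aln = aligner.align(center, other)[0]
        a, b = str(aln[0]), str(aln[1])
        pairwise.append((a, b))
    L = len(center)
    # gaps_k[i]: columns inserted before center residue i (i == L: after end)
    per_aln_gaps = []
    for a, _ in pairwise:
        gaps = [0] * (L + 1)
        i = 0
        for ch in a:
            if ch == "-":
                gaps[i] += 1
            else:
                i += 1
        per_aln_gaps.append(gaps)
    merged = [max(g[i] for g in per_aln_gaps) if per_aln_gaps else 0 for i in range(L + 1)]

    def expand(a: str, b: str, gaps: list[int]) -> str:
        out = []
        i = 0  # center residue index
        k = 0  # position in pairwise alignment
        for i in range(L + 1):
            run = []
            while k < len(a) and a[k] == "-":
                run.append(b[k])
                k += 1
            run.extend("-" * (merged[i] - gaps[i]))
            out.extend(run)
            if i < L:
                out.append(b[k])
                k += 1
        return "".join(out)

    rows = []
    center_row = []
    for i in range(L):
        center_row.extend("-" * merged[i])
        center_row.append(center[i])
    center_row.extend("-" * merged[L])
    rows.append("".join(center_row))
    for (a, b), gaps in zip(pairwise, per_aln_gaps):
        rows.append(expand(a, b, gaps))
    return rows


def _back_translate(aa_row: str, cds: str) -> str:
    out = []
    k = 0
    for ch in aa_row:
        if ch == "-":
            out.append("---")
        else:
            out.append(cds[k : k + 3])
            k += 3
    # trailing stop codon, if present in the CDS, is dropped with the protein
    return "".join(out)


def align_quartet(
    ids: tuple[str, str, str, str],
    cds: tuple[str, str, str, str],
) -> QuartetAlignment:
    """Align the four CDS of a quartet, codon-aware.

    Proteins are aligned by progressive pairwise global alignment (BLOSUM62,
    affine gaps; first sequence as the star center) and the alignment is
    back-translated to codons.  Quartets whose CDS cannot be translated are
    rejected with a reason code.
    """
    if len(ids) != 4 or len(cds) != 4:
        raise ValueError("a quartet has exactly four sequences")
    proteins = []
    clean_cds = []
    for gid, seq in zip(ids, cds):
        seq = seq.upper().replace("U", "T")
        try:
            prot = _codon.translate(seq)
        except ValueError as exc:
            raise QuartetRejected("untranslatable_cds", f"{gid}: {exc}") from exc
        if not prot:
            raise QuartetRejected("empty_cds", gid)
        proteins.append(prot)
        clean_cds.append(seq[: 3 * len(prot)])  # drop trailing stop codon
    if len({len(p) for p in proteins}) == 1 and all(p for p in proteins):
        aa_rows = list(proteins)  # equal-length proteins: gap-free alignment
    else:
        aa_rows = _merge_center_star(proteins[0], proteins[1:])
    nt_rows = tuple(_back_translate(r, c) for r, c in zip(aa_rows, clean_cds))
    return QuartetAlignment(ids=tuple(ids), nt=nt_rows, aa=tuple(aa_rows))


def alignment_from_rows(
    ids: tuple[str, str, str, str],
    nt_rows: tuple[str, str, str, str],
) -> QuartetAlignment:
    """Build a QuartetAlignment from externally aligned CDS rows.

    Accepts codon-structured rows ('-' gaps); amino-acid rows are derived
    codon-wise, with any codon containing a gap rendered as '-'.  Use this
    to reproduce results under a third-party alignment.
    """
    aa_rows = []
    for row in nt_rows:
        row = row.upper().replace("U", "T")
        aa = []
        for k in range(0, len(row), 3):
            codon = row[k : k + 3]
            if "-" in codon:
                aa.append("-")
            else:
                aa.append(_codon.AA_BY_CODON.get(codon, "X"))
        aa_rows.append("".join(aa))
    return QuartetAlignment(ids=tuple(ids), nt=tuple(r.upper().replace("U", "T") for r in nt_rows), aa=tuple(aa_rows))


def quartet_alignment_from_fasta(path, ids: tuple[str, str, str, str]) -> QuartetAlignment:
    """Load an externally aligned quartet from an aligned FASTA file."""
    from .io import read_fasta

    seqs = read_fasta(path)
    missing = [g for g in ids if g not in seqs]
    if missing:
        raise QuartetRejected("missing_aligned_sequence", ", ".join(missing))
    return alignment_from_rows(tuple(ids), tuple(seqs[g] for g in ids))


def pairwise_gap_and_identity(aa_a: str, aa_b: str) -> tuple[float, float]:
    """Gap fraction and amino-acid identity for one aligned protein pair.

    The pairwise alignment length excludes columns gapped in both rows;
    the gap fraction is the share of those columns gapped in either row,
    and identity is computed over the fully ungapped columns.
    """
    both = sum(1 for x, y in zip(aa_a, aa_b) if x == "-" and y == "-")
    pair_len = len(aa_a) - both
    if pair_len == 0:
        return 1.0, 0.0
    gapped = sum(1 for x, y in zip(aa_a, aa_b) if (x == "-") != (y == "-"))
    ungapped = [(x, y) for x, y in zip(aa_a, aa_b) if x != "-" and y != "-"]
    ident = (
        sum(1 for x, y in ungapped if x == y) / len(ungapped) if ungapped else 0.0
    )
    return gapped / pair_len, ident


def filter_quartet(
    alignment: QuartetAlignment,
    max_gap_fraction: float = 0.5,
    min_aa_identity: float = 0.4,
) -> tuple[bool, str | None]:
    """Keep/drop decision for a quartet, applied to all six pairwise
    comparisons: drop if any pairwise gap fraction exceeds
    ``max_gap_fraction`` or any pairwise amino-acid identity falls below
    ``min_aa_identity``."""
    n = len(alignment.aa)
    for i in range(n):
        for j in range(i + 1, n):
            gap_frac, ident = pairwise_gap_and_identity(alignment.aa[i], alignment.aa[j])
            if gap_frac > max_gap_fraction:
                return False, (
                    f"gap_fraction {gap_frac:.3f} > {max_gap_fraction} "
                    f"({alignment.ids[i]} vs {alignment.ids[j]})"
                )
            if ident < min_aa_identity:
                return False, (
                    f"aa_identity {ident:.3f} < {min_aa_identity} "
                    f"({alignment.ids[i]} vs {alignment.ids[j]})"
                )
    return True, None


def ng_site_counts(codon: str) -> tuple[float, float]:
    """Nei–Gojobori synonymous/nonsynonymous site counts for one codon.

    Mutations to stop codons are excluded from the per-position
    denominator, so S + N = 3 for every sense codon.
    """
    codon = codon.upper().replace("U", "T")
    idx = CODON_INDEX.get(codon)
    if idx is None:
        raise ValueError(f"not a codon: {codon!r}")
    if not _codon.SENSE[idx]:
        raise ValueError(f"stop codon {codon!r}")
    return float(S_SITES[idx]), float(N_SITES[idx])


def jc_correct(p: float) -> float | None:
    """Jukes–Cantor multiple-hit correction d = -(3/4)·ln(1 - (4/3)·p).

    Returns None at or beyond the saturation point p >= 3/4.
    """
    if p < 0:
        raise ValueError("negative proportion")
    if p >= JC_SATURATION:
        return None
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def jc_invert(d: float) -> float:
    """Inverse of the JC correction: p = (3/4)·(1 - e^(-4d/3))."""
    if d < 0:
        raise ValueError("negative distance")
    return 0.75 * -math.expm1(-4.0 * d / 3.0)


def pair_site_arrays(nt_a: str, nt_b: str) -> dict[str, np.ndarray]:
    """Per-codon-column NG contributions for one aligned nucleotide pair.

    Returns arrays over all codon columns of the alignment with entries
    zeroed where the column is unusable for this pair (gap anywhere in
    either codon, ambiguity, or stop).  Keys: ``valid``, ``s_sites``,
    ``n_sites``, ``syn_diff``, ``nsyn_diff``, ``aa_match``.
    Keeping the invalid columns in place (as zeros) lets quartet-level
    bootstrap resampling share one column index across all pairs.
    """
    if len(nt_a) != len(nt_b):
        raise ValueError("aligned rows differ in length")
    ia = _codon.codon_indices(nt_a)
    ib = _codon.codon_indices(nt_b)
    valid = (ia >= 0) & (ib >= 0)
    iav = np.where(valid, ia, 0)
    ibv = np.where(valid, ib, 0)
    z = valid.astype(float)
    return {
        "valid": valid,
        "s_sites": 0.5 * (S_SITES[iav] + S_SITES[ibv]) * z,
        "n_sites": 0.5 * (N_SITES[iav] + N_SITES[ibv]) * z,
        "syn_diff": SYN_DIFF[iav, ibv] * z,
        "nsyn_diff": NSYN_DIFF[iav, ibv] * z,
        "aa_match": AA_EQUAL[iav, ibv] & valid,
    }


def distances_from_sums(
    s_sites: float,
    n_sites: float,
    syn_diff: float,
    nsyn_diff: float,
    aa_match: float,
    n_codons: int,
    id1: str = "a",
    id2: str = "b",
) -> PairDistances:
    ps = syn_diff / s_sites if s_sites > 0 else 0.0
    pn = nsyn_diff / n_sites if n_sites > 0 else 0.0
    return PairDistances(
        id1=id1,
        id2=id2,
        pn=pn,
        ps=ps,
        Pn=jc_correct(pn),
        Ps=jc_correct(ps),
        aa_identity=aa_match / n_codons if n_codons else 0.0,
        n_sites=n_codons,
    )


def pair_distances(nt_a: str, nt_b: str, id1: str = "a", id2: str = "b") -> PairDistances:
    """Nei–Gojobori pN/pS, JC-corrected Pn/Ps, and amino-acid identity for
    one aligned (or equal-length unaligned) CDS pair.

    Codon columns with a gap, ambiguity, or stop in either sequence are
    excluded whole-codon.  Sites are averaged over the two sequences and
    multi-nucleotide codon differences are decomposed by unweighted
    averaging over minimal mutational paths (stop-containing paths
    excluded).  Corrected values are None past JC saturation.
    """
    arr = pair_site_arrays(nt_a, nt_b)
    n_codons = int(arr["valid"].sum())
    if n_codons == 0:
        raise ValueError(f"no comparable codon columns between {id1} and {id2}")
    return distances_from_sums(
        float(arr["s_sites"].sum()),
        float(arr["n_sites"].sum()),
        float(arr["syn_diff"].sum()),
        float(arr["nsyn_diff"].sum()),
        float(arr["aa_match"].sum()),
        n_codons,
        id1,
        id2,
    )
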