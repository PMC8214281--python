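"""Shared domain records.

Coordinates are GFF3-style throughout: 1-based, inclusive.  `rank` is the
0-based index of a gene along its chromosome ordered by start coordinate
(ties broken by gene id).
"""

from __future__ import annotations

from dataclasses import dataclass, field


@dataclass(frozen=True)
class GeneRecord:
    """A gene: genomic placement plus coding sequence."""

    gene_id: str
    genome: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    rank: int = -1
    cds: str = ""

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(f"{self.gene_id}: start > end")
        if self.cds and len(self.cds) % 3:
            raise ValueError(f"{self.gene_id}: CDS length not a multiple of 3")


@dataclass(frozen=True)
class HomologyHit:
    """One directional homology hit (BLAST outfmt-6 essentials)."""

    query: str
    subject: str
    evalue: float
    bitscore: float
    pident: float = 0.0
    length: int = 0

    def __post_init__(self):
        if self.evalue < 0:
            raise ValueError("negative E-value")


@dataclass
class CollinearBlock:
    """A chained run of homologous gene pairs between two chromosomes."""

    block_id: str
    genome_a: str
    genome_b: str
    chrom_a: str
    chrom_b: str
    anchors: list[tuple[str, str]]
    orientation: str = "+"  # "+" ascending on B axis, "-" descending
    relation: str = "unlabelled"  # paralogous | orthologous | ambiguous
    median_ks: float | None = None

    @property
    def n_anchors(self) -> int:
        return len(self.anchors)


@dataclass(frozen=True)
class Quartet:
    """Paralogue pair (o1, o2) in genome A with orthologues (s1, s2) in
    genome B; the unit of conversion inference."""

    genome_a: str
    genome_b: str
    o1: str
    o2: str
    s1: str
    s2: str
    source_blocks: tuple[str, ...] = ()

    def __post_init__(self):
        if self.o1 == self.o2 or self.s1 == self.s2:
            raise ValueError("degenerate quartet")

    @property
    def key(self) -> tuple:
        return (self.genome_a, self.genome_b, frozenset((self.o1, self.o2)))


@dataclass
class PairDistances:
    """Nei–Gojobori proportions, JC-corrected rates, and amino-acid
    identity for one homologous pair.

    pn/ps are raw proportions of differences per nonsynonymous/synonymous
    site; Pn/Ps are the Jukes–Cantor corrected values (None when the
    proportion is at or past the JC saturation point of 3/4).
    """

    id1: str
    id2: str
    pn: float
    ps: float
    Pn: float | None
    Ps: float | None
    aa_identity: float
    n_sites: int

    @property
    def saturated(self) -> bool:
        return self.Pn is None or self.Ps is None


@dataclass(frozen=True)
class TruthEvent:
    """A simulator-implanted conversion event (ground truth).

    Tract coordinates are 1-based inclusive positions in the acceptor CDS;
    whole-gene events span the full CDS.
    """

    genome: str
    donor: str
    acceptor: str
    kind: str  # "whole" | "partial"
    start: int
    end: int
    epoch: str  # "pre-variety-split" | "post-variety-split"

    def __post_init__(self):
        if self.kind not in ("whole", "partial"):
            raise ValueError(f"bad event kind {self.kind!r}")
        if self.epoch not in ("pre-variety-split", "post-variety-split"):
            raise ValueError(f"bad epoch {self.epoch!r}")
        if self.start < 1 or self.end < self.start:
            raise ValueError("bad tract coordinates")
        if self.kind == "partial" and self.end - self.start + 1 < 10:
            raise ValueError("partial tract shorter than 10 nt")


@dataclass
class ConversionCall:
    """A detected conversion for one paralogue pair in one genome."""

    genome: str
    gene1: str
    gene2: str
    methods: set[str] = field(default_factory=set)  # wcv_ks, wcv_identity, pcv
    donor: str = "uncertain"
    support: float | None = None
    tracts: list[tuple[int, int]] = field(default_factory=list)  # acceptor CDS, 1-based incl.
    aln_tracts: list[tuple[int, int]] = field(default_factory=list)  # alignment nt coords
    tract_support: list[float] = field(default_factory=list)
    period: str = "unassigned"  # A | B | unassigned

    @property
    def pair(self) -> frozenset:
        return frozenset((self.gene1, self.gene2))

    @property
    def is_wcv(self) -> bool:
        return bool(self.methods & {"wcv_ks", "wcv_identity"})

    @property
    def is_pcv(self) -> bool:
        return "pcv" in self.methods
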