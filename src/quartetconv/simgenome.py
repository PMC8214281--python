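"""Synthetic multi-genome datasets with ancient-WGD structure.

The generator emulates the evolutionary situation the detection pipeline
assumes: an ancestral gene set duplicated by a whole-genome duplication
(paralogue pairs diverged to a synonymous distance peaking near 0.65),
three descendant genomes — one early-diverging lineage and two recently
split sibling varieties — with low orthologue divergence, per-genome gene
loss, and implanted whole- or partial-gene conversion events with known
donors, tracts, and epochs (before or after the sibling split).

Substitutions follow a site-independent Jukes–Cantor-like proposal
process; nonsynonymous proposals are accepted with a configurable factor
(default 0.4, so simulated Pn/Ps sits in the empirically typical 0.4–0.5
band) and proposals creating stop codons are always rejected, keeping
ORFs intact.  Conversion events are implanted after all drift by default,
so truth tracts are exact; optional post-event drift is available for
sensitivity studies.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from ._codon import AA_BY_CODON, CODONS, STOP_CODONS
from .records import GeneRecord, TruthEvent
from .seqdist import jc_invert

__all__ = [
    "SimConfig",
    "Family",
    "SimDataset",
    "simulate_ancestor",
    "evolve_wgd_and_speciate",
    "implant_conversions",
    "simulate",
    "write_dataset",
]

_SENSE_CODONS = [c for c in CODONS if c not in STOP_CODONS]


class SimConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset.

    Divergence targets are on the Jukes–Cantor-corrected scale
    (substitutions per synonymous site).  ``genome_names`` orders the
    genomes as (early-diverging lineage, sibling 1, sibling 2).
    """

    n_genes: int = 300
    n_chromosomes: int = 4  # per descendant genome; even, paired as homoeologues
    gene_length_codons: tuple[int, int] = (150, 450)
    gene_spacing: int = 10_000  # start-to-start spacing along a chromosome
    paralog_ks_target: float = 0.65
    ortholog_ks_target: float = 0.05  # early lineage vs siblings
    sibling_ks_target: float = 0.02  # between the two sibling genomes
    loss_rates: tuple[float, float, float] = (0.0613, 0.1331, 0.0789)
    wcv_rate: float = 0.0
    pcv_rate: float = 0.0
    fraction_pre_split: float = 0.84  # share of sibling events preceding their split
    tract_length: tuple[int, int] = (20, 200)  # partial-tract nt range
    donor_bias: float = 0.5  # probability the privileged copy (copy 1) donates
    nonsyn_acceptance: float = 0.4
    drift_after_implant: float = 0.0  # extra Ks applied after implanting
    genome_names: tuple[str, str, str] = ("G1", "X1", "X2")
    seed: int = 0

    def __post_init__(self):
        if self.n_genes < 4:
            raise SimConfigError("n_genes must be >= 4")
        if self.n_chromosomes < 2 or self.n_chromosomes % 2:
            raise SimConfigError("n_chromosomes must be even and >= 2")
        lo, hi = self.gene_length_codons
        if lo < 2 or hi < lo:
            raise SimConfigError("bad gene_length_codons range")
        if self.gene_spacing <= 3 * hi:
            raise SimConfigError("gene_spacing must exceed the longest CDS")
        for name, val in (
            ("wcv_rate", self.wcv_rate),
            ("pcv_rate", self.pcv_rate),
            ("fraction_pre_split", self.fraction_pre_split),
            ("donor_bias", self.donor_bias),
            ("nonsyn_acceptance", self.nonsyn_acceptance),
        ):
            if not 0.0 <= val <= 1.0:
                raise SimConfigError(f"{name} must lie in [0, 1]")
        if len(self.loss_rates) != 3 or any(not 0.0 <= r <= 1.0 for r in self.loss_rates):
            raise SimConfigError("loss_rates must be three values in [0, 1]")
        for name, t in (
            ("paralog_ks_target", self.paralog_ks_target),
            ("ortholog_ks_target", self.ortholog_ks_target),
            ("sibling_ks_target", self.sibling_ks_target),
        ):
            if t < 0 or not np.isfinite(t) or jc_invert(t) >= 0.75:
                raise SimConfigError(f"{name} implies a saturated proportion (p >= 0.75)")
        if self.paralog_ks_target != 0 and self.paralog_ks_target <= self.ortholog_ks_target:
            raise SimConfigError("paralog_ks_target must exceed ortholog_ks_target")
        if self.sibling_ks_target > self.ortholog_ks_target:
            raise SimConfigError("sibling_ks_target cannot exceed ortholog_ks_target")
        if self.tract_length[0] < 10 or self.tract_length[1] < self.tract_length[0]:
            raise SimConfigError("tract lengths must be >= 10 nt and ordered")
        if self.drift_after_implant < 0:
            raise SimConfigError("drift_after_implant must be >= 0")
        if len(set(self.genome_names)) != 3:
            raise SimConfigError("three distinct genome names required")


@dataclass
class Family:
    """One ancestral locus family: the two WGD copies in each genome.

    ``genes[genome]`` maps to a two-slot list (copy 1, copy 2); a slot is
    None where that locus was lost.
    """

    anc_id: str
    genes: dict[str, list[str | None]] = field(default_factory=dict)


@dataclass
class SimDataset:
    config: SimConfig
    ancestor: list[GeneRecord]
    genomes: dict[str, list[GeneRecord]]
    families: list[Family]
    truth: list[TruthEvent]

    def genome_index(self) -> dict[str, GeneRecord]:
        return {g.gene_id: g for recs in self.genomes.values() for g in recs}


def _mutate(seq: str, t: float, omega: float, rng: np.random.Generator) -> str:
    """Apply the JC-like proposal process at rate ``t`` proposals per nt.

    Synonymous proposals are always accepted, nonsynonymous ones with
    probability ``omega``, stop-creating ones never; the realised
    synonymous distance per synonymous site is therefore ~ ``t``.
    """
    if t <= 0:
        return seq
    L = len(seq)
    n_prop = int(rng.poisson(t * L))
    if n_prop == 0:
        return seq
    s = list(seq)
    sites = rng.integers(0, L, n_prop)
    alts = rng.integers(0, 3, n_prop)
    draws = rng.random(n_prop)
    for site, alt, u in zip(sites, alts, draws):
        old = s[site]
        new = [b for b in "TCAG" if b != old][alt]
        c0 = site - site % 3
        codon_old = "".join(s[c0 : c0 + 3])
        pos = site - c0
        codon_new = codon_old[:pos] + new + codon_old[pos + 1 :]
        if codon_new in STOP_CODONS:
            continue
        if AA_BY_CODON[codon_new] == AA_BY_CODON[codon_old] or u < omega:
            s[site] = new
    return "".join(s)


def _assign_ranks(records: list[GeneRecord]) -> list[GeneRecord]:
    """Recompute per-chromosome ranks by start coordinate (ties by id)."""
    out = []
    by_chrom: dict[str, list[GeneRecord]] = {}
    for rec in records:
        by_chrom.setdefault(rec.chrom, []).append(rec)
    for chrom in sorted(by_chrom):
        genes = sorted(by_chrom[chrom], key=lambda r: (r.start, r.gene_id))
        for rank, rec in enumerate(genes):
            out.append(
                GeneRecord(
                    gene_id=rec.gene_id,
                    genome=rec.genome,
                    chrom=rec.chrom,
                    start=rec.start,
                    end=rec.end,
                    strand=rec.strand,
                    rank=rank,
                    cds=rec.cds,
                )
            )
    return out


def simulate_ancestor(config: SimConfig, rng: np.random.Generator | None = None) -> list[GeneRecord]:
    """Generate the pre-WGD ancestral gene set.

    Genes start with ATG, contain no stop codons, and are packed along
    ``n_chromosomes / 2`` ancestral chromosomes with fixed start-to-start
    spacing, in input order with strictly increasing coordinates.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    n_chrom_anc = config.n_chromosomes // 2
    lo, hi = config.gene_length_codons
    per_chrom = np.array_split(np.arange(config.n_genes), n_chrom_anc)
    records = []
    width = len(str(config.n_genes))
    for ci, idxs in enumerate(per_chrom, start=1):
        for slot, i in enumerate(idxs):
            n_codons = int(rng.integers(lo, hi + 1))
            body = rng.integers(0, len(_SENSE_CODONS), n_codons - 1)
            cds = "ATG" + "".join(_SENSE_CODONS[k] for k in body)
            start = 1 + slot * config.gene_spacing
            records.append(
                GeneRecord(
                    gene_id=f"g{i + 1:0{width}d}",
                    genome="ancestor",
                    chrom=f"chr{ci}",
                    start=start,
                    end=start + len(cds) - 1,
                    strand="+",
                    rank=slot,
                    cds=cds,
                )
            )
    return records


def evolve_wgd_and_speciate(
    ancestor: list[GeneRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[GeneRecord]], list[Family]]:
    """Duplicate the ancestor (WGD), diverge the copies, speciate into the
    three genomes, and apply per-genome gene loss.

    Branch lengths are arranged so the realised pairwise synonymous
    distances match the configured targets: paralogue divergence is
    applied pre-speciation at (paralogue − orthologue)/2 per copy, and the
    species tree ((sib1, sib2), early) contributes the orthologue targets.
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    g_early, g_sib1, g_sib2 = config.genome_names
    t_para = max(0.0, (config.paralog_ks_target - config.ortholog_ks_target) / 2.0)
    t_early = config.ortholog_ks_target / 2.0
    t_sib = config.sibling_ks_target / 2.0
    t_sib_anc = t_early - t_sib
    omega = config.nonsyn_acceptance
    n_chrom_anc = config.n_chromosomes // 2

    genomes: dict[str, list[GeneRecord]] = {g: [] for g in config.genome_names}
    families: list[Family] = []
    for anc in ancestor:
        fam = Family(anc_id=anc.gene_id, genes={g: [None, None] for g in config.genome_names})
        chrom_no = int(anc.chrom.removeprefix("chr"))
        for copy in (1, 2):
            chrom = f"chr{chrom_no}" if copy == 1 else f"chr{chrom_no + n_chrom_anc}"
            copy_seq = _mutate(anc.cds, t_para, omega, rng)
            seq_early = _mutate(copy_seq, t_early, omega, rng)
            seq_sib_anc = _mutate(copy_seq, t_sib_anc, omega, rng)
            tip_seqs = {
                g_early: seq_early,
                g_sib1: _mutate(seq_sib_anc, t_sib, omega, rng),
                g_sib2: _mutate(seq_sib_anc, t_sib, omega, rng),
            }
            for genome in config.genome_names:
                gene_id = f"{genome}_{anc.gene_id}_c{copy}"
                genomes[genome].append(
                    GeneRecord(
                        gene_id=gene_id,
                        genome=genome,
                        chrom=chrom,
                        start=anc.start,
                        end=anc.start + len(tip_seqs[genome]) - 1,
                        strand=anc.strand,
                        cds=tip_seqs[genome],
                    )
                )
                fam.genes[genome][copy - 1] = gene_id
        families.append(fam)

    # per-genome gene loss: each locus independently deleted
    for gi, genome in enumerate(config.genome_names):
        rate = config.loss_rates[gi]
        if rate <= 0:
            continue
        keep_mask = rng.random(len(genomes[genome])) >= rate
        lost = {rec.gene_id for rec, keep in zip(genomes[genome], keep_mask) if not keep}
        genomes[genome] = [rec for rec in genomes[genome] if rec.gene_id not in lost]
        for fam in families:
            fam.genes[genome] = [
                None if gid in lost else gid for gid in fam.genes[genome]
            ]
    genomes = {g: _assign_ranks(recs) for g, recs in genomes.items()}
    return genomes, families


def implant_conversions(
    genomes: dict[str, list[GeneRecord]],
    families: list[Family],
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict[str, list[GeneRecord]], list[TruthEvent]]:
    """Implant whole- and partial-gene conversion events.

    Only families with both copies retained are eligible.  Sibling events
    are split into pre-split events (applied identically, with the same
    donor copy, in both sibling genomes) and post-split events (one
    genome); events in the early-diverging lineage are lineage-specific.
    A family receives at most one event per lineage.  With
    ``drift_after_implant`` at its default of 0 the acceptor tract equals
    the donor tract exactly in the output.
    """
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    g_early, g_sib1, g_sib2 = config.genome_names
    seqs = {rec.gene_id: rec.cds for recs in genomes.values() for rec in recs}
    truth: list[TruthEvent] = []

    def retained(fam: Family, genome: str) -> bool:
        return all(fam.genes[genome][c] is not None for c in (0, 1))

    def pick_donor_copy() -> int:
        return 0 if rng.random() < config.donor_bias else 1

    def _splice(donor_seq: str, acceptor_seq: str, start: int, end: int) -> str:
        end = min(end, len(acceptor_seq), len(donor_seq))
        return acceptor_seq[: start - 1] + donor_seq[start - 1 : end] + acceptor_seq[end:]

    def _orf_ok(seq: str) -> bool:
        for k in range(0, len(seq) - 2, 3):
            if seq[k : k + 3] in STOP_CODONS:
                return False
        return True

    def sample_tract(fam: Family, target_genomes: list[str], donor_copy: int) -> tuple[int, int]:
        """Sample a tract that keeps every affected ORF stop-free.

        A tract boundary inside a codon splices donor and acceptor halves
        together and can create a stop; such tracts are resampled, never
        truncated or shifted.
        """
        lo, hi = config.tract_length
        cds_len = min(
            min(len(seqs[fam.genes[g][0]]), len(seqs[fam.genes[g][1]]))
            for g in target_genomes
        )
        for _ in range(1000):
            length = int(rng.integers(lo, hi + 1))
            if length > cds_len:
                continue
            start = int(rng.integers(1, cds_len - length + 2))
            end = start + length - 1
            ok = all(
                _orf_ok(
                    _splice(
                        seqs[fam.genes[g][donor_copy]],
                        seqs[fam.genes[g][1 - donor_copy]],
                        start, end,
                    )
                )
                for g in target_genomes
            )
            if ok:
                return start, end
        raise SimConfigError(
            f"cannot sample a valid tract of >= {lo} nt inside a {cds_len} nt CDS"
        )

    def apply(genome: str, fam: Family, donor_copy: int, kind: str, epoch: str,
              tract: tuple[int, int] | None) -> None:
        donor = fam.genes[genome][donor_copy]
        acceptor = fam.genes[genome][1 - donor_copy]
        d, a = seqs[donor], seqs[acceptor]
        if kind == "whole":
            seqs[acceptor] = d
            start, end = 1, len(d)
        else:
            start, end = tract
            end = min(end, len(a), len(d))
            seqs[acceptor] = _splice(d, a, start, end)
        truth.append(
            TruthEvent(genome=genome, donor=donor, acceptor=acceptor,
                       kind=kind, start=start, end=end, epoch=epoch)
        )

    converted: dict[str, set[str]] = {g: set() for g in config.genome_names}
    for fam in families:
        draws = rng.random(4)  # early wcv/pcv, sibling wcv/pcv
        donor_copy = pick_donor_copy()
        epoch_draw = rng.random()
        # early-diverging lineage: lineage-specific events only
        if retained(fam, g_early):
            if draws[0] < config.wcv_rate:
                apply(g_early, fam, donor_copy, "whole", "post-variety-split", None)
                converted[g_early].add(fam.anc_id)
            elif draws[1] < config.pcv_rate:
                apply(g_early, fam, donor_copy, "partial", "post-variety-split",
                      sample_tract(fam, [g_early], donor_copy))
                converted[g_early].add(fam.anc_id)
        # sibling lineage: pre-split events shared, post-split in one genome
        sib_retained = [g for g in (g_sib1, g_sib2) if retained(fam, g)]
        if not sib_retained:
            continue
        pre = epoch_draw < config.fraction_pre_split
        targets = sib_retained if pre else [sib_retained[int(rng.integers(0, len(sib_retained)))]]
        epoch = "pre-variety-split" if pre else "post-variety-split"
        if draws[2] < config.wcv_rate:
            for g in targets:
                apply(g, fam, donor_copy, "whole", epoch, None)
                converted[g].add(fam.anc_id)
        elif draws[3] < config.pcv_rate:
            tract = sample_tract(fam, targets, donor_copy)
            for g in targets:
                apply(g, fam, donor_copy, "partial", epoch, tract)
                converted[g].add(fam.anc_id)

    omega = config.nonsyn_acceptance
    out: dict[str, list[GeneRecord]] = {}
    for genome, recs in genomes.items():
        new_recs = []
        for rec in recs:
            cds = seqs[rec.gene_id]
            if config.drift_after_implant > 0:
                cds = _mutate(cds, config.drift_after_implant / 2.0, omega, rng)
            new_recs.append(
                GeneRecord(
                    gene_id=rec.gene_id, genome=rec.genome, chrom=rec.chrom,
                    start=rec.start, end=rec.start + len(cds) - 1,
                    strand=rec.strand, rank=rec.rank, cds=cds,
                )
            )
        out[genome] = new_recs
    return out, truth


def simulate(config: SimConfig) -> SimDataset:
    """Run the full generator: ancestor → WGD + speciation + loss →
    implanted conversions.  Deterministic for a fixed config."""
    rng = np.random.default_rng(config.seed)
    ancestor = simulate_ancestor(config, rng)
    genomes, families = evolve_wgd_and_speciate(ancestor, config, rng)
    genomes, truth = implant_conversions(genomes, families, config, rng)
    return SimDataset(config=config, ancestor=ancestor, genomes=genomes,
                      families=families, truth=truth)


def write_dataset(dataset: SimDataset, outdir) -> dict[str, str]:
    """Write the dataset in the formats the pipeline consumes.

    Per genome one CDS FASTA and one GFF3; one homology TSV in BLAST
    outfmt-6 columns (similarities computed within known homologous
    families — unrelated genes would not survive the E-value/score filter
    anyway); the truth TSV; and a YAML manifest with config and seed.
    """
    import yaml
    from pathlib import Path

    from .io import write_fasta, write_gff3, write_homology_tsv, write_truth_tsv
    from ._codon import translate

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    prots: dict[str, str] = {}
    for genome in dataset.config.genome_names:
        recs = dataset.genomes[genome]
        fasta = outdir / f"{genome}.cds.fasta"
        gff = outdir / f"{genome}.gff3"
        write_fasta(recs, fasta)
        write_gff3(recs, gff)
        paths[f"{genome}.fasta"] = str(fasta)
        paths[f"{genome}.gff3"] = str(gff)
        for rec in recs:
            prots[rec.gene_id] = translate(rec.cds)

    hits = []
    for fam in dataset.families:
        members = [
            gid
            for genome in dataset.config.genome_names
            for gid in fam.genes[genome]
            if gid is not None
        ]
        for q in members:
            for s in members:
                pq, ps_ = prots[q], prots[s]
                n = min(len(pq), len(ps_))
                matches = sum(1 for x, y in zip(pq, ps_) if x == y)
                pident = 100.0 * matches / n if n else 0.0
                bitscore = 2.0 * matches
                evalue = 0.0 if bitscore > 600 else 2.0 ** (-bitscore)
                hits.append(
                    (q, s, pident, n, n - matches, 0, 1, len(pq), 1, len(ps_),
                     evalue, bitscore)
                )
    homology = outdir / "homology.tsv"
    write_homology_tsv(hits, homology)
    paths["homology"] = str(homology)

    truth_path = outdir / "truth.tsv"
    write_truth_tsv(dataset.truth, truth_path)
    paths["truth"] = str(truth_path)

    manifest = outdir / "manifest.yaml"
    cfg = asdict(dataset.config)
    cfg["genome_names"] = list(cfg["genome_names"])
    with open(manifest, "w") as fh:
        yaml.safe_dump(
            {"config": cfg, "seed": dataset.config.seed, "files": paths},
            fh, sort_keys=True,
        )
    paths["manifest"] = str(manifest)
    return paths
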