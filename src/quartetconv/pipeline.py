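"""End-to-end orchestration: simulate or load → homology → quartets →
distances → conversion detection → genome statistics → reports.

`run` executes the stages into a run directory with per-stage outputs, a
machine-readable summary JSON, and a manifest recording the config hash
and seed; `report_table1` renders the per-genome conversion summary
(paralogue count, WCV/PCV counts with percentages, conversion rate,
period split) as a table.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import convdetect, genomestats, homology, io, seqdist
from .records import ConversionCall, GeneRecord, PairDistances
from .simgenome import SimConfig, simulate, write_dataset

logger = logging.getLogger("quartetconv")

__all__ = ["RunConfig", "RunResult", "run", "report_table1", "summarize_calls"]


@dataclass
class RunConfig:
    """Configuration of one pipeline run.

    Exactly one of ``simulation`` or ``inputs`` must be given.  ``inputs``
    maps each genome name to {"fasta": ..., "gff3": ...} and requires
    ``homology`` (BLAST outfmt-6 TSV).  Threshold defaults follow the
    published procedure where it states one (1e-5 / 100 hit filters, gap
    50, family cap 30, 50% gap / 40% identity quartet filters, 10 nt
    tracts, 1000 bootstraps, 500-kb bins, 10^6 permutation rounds).
    """

    simulation: SimConfig | None = None
    inputs: dict[str, dict[str, str]] | None = None
    homology_path: str | None = None
    expression_path: str | None = None
    sibling_genomes: tuple[str, str] | None = None
    chrom_pair_of_interest: tuple[str, str] | None = None
    outdir: str = "runs/run"
    seed: int = 0
    log_level: str = "INFO"
    max_evalue: float = 1e-5
    min_score: float = 100.0
    max_gap: int = 50
    min_anchors: int = 5
    family_cap: int = 30
    ks_cutoff: float = 0.3
    max_gap_fraction: float = 0.5
    min_aa_identity: float = 0.4
    n_boot: int = 1000
    support_threshold: float = 0.95
    min_tract_len: int = 10
    min_tract_score: float = 2.0
    strong_score: float = 4.0
    donor_margin: float = 0.005
    bin_width: int = 500_000
    outer_span: int = 2_000_000
    permutation_rounds: int = 1_000_000
    rate_denominator: str = "total"

    def __post_init__(self):
        if (self.simulation is None) == (self.inputs is None):
            raise ValueError("exactly one of simulation or inputs required")
        if self.inputs is not None and self.homology_path is None:
            raise ValueError("file inputs require a homology table")

    def config_hash(self) -> str:
        d = asdict(self)
        blob = yaml.safe_dump(d, sort_keys=True, default_flow_style=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    config: RunConfig
    outdir: Path
    genomes: dict[str, list[GeneRecord]]
    homology: homology.HomologyResult
    paralog_distances: dict[str, dict[frozenset, PairDistances]]
    merged_calls: dict[str, list[ConversionCall]]
    period_summary: dict
    summary: dict
    truth: list = field(default_factory=list)


def _round_half_up(x: float, nd: int) -> float:
    return float(Decimal(repr(x)).quantize(Decimal(10) ** -nd, rounding=ROUND_HALF_UP))


def summarize_calls(
    paralogue_count: int,
    calls: list[ConversionCall],
    chrom_of_pair: dict[str, str] | None = None,
    chrom_pair_of_interest: tuple[str, str] | None = None,
) -> dict:
    """Per-genome summary counts in the layout of the headline table.

    WCV-I counts calls satisfying the Ks criterion only, WCV-II those
    satisfying the identity criterion (the two are disjoint); PCV counts
    calls with at least one partial tract.  Percentages are relative to
    the paralogue count (2 decimals, half-up); the conversion rate is
    all-converted / paralogues to 3 decimals.
    """
    wcv_i = sum(1 for c in calls if "wcv_ks" in c.methods and "wcv_identity" not in c.methods)
    wcv_ii = sum(1 for c in calls if "wcv_identity" in c.methods)
    pcv = sum(1 for c in calls if c.is_pcv)
    n_all = len(calls)
    interest = 0
    if chrom_pair_of_interest and chrom_of_pair:
        want = set(chrom_pair_of_interest)
        for c in calls:
            chroms = {chrom_of_pair.get(c.gene1), chrom_of_pair.get(c.gene2)}
            if chroms <= want:
                interest += 1

    def pct(n: int) -> float | None:
        return _round_half_up(100.0 * n / paralogue_count, 2) if paralogue_count else None

    out = {
        "paralogues": paralogue_count,
        "wcv_i": wcv_i, "wcv_i_pct": pct(wcv_i),
        "wcv_ii": wcv_ii, "wcv_ii_pct": pct(wcv_ii),
        "wcv": wcv_i + wcv_ii, "wcv_pct": pct(wcv_i + wcv_ii),
        "pcv": pcv, "pcv_pct": pct(pcv),
        "all_converted": n_all,
        "conversion_rate": _round_half_up(n_all / paralogue_count, 3) if paralogue_count else None,
        "period_A": sum(1 for c in calls if c.period == "A"),
        "period_B": sum(1 for c in calls if c.period == "B"),
    }
    if chrom_pair_of_interest:
        out["chrom_pair_cv"] = interest
        out["chrom_pair_cv_pct_of_converted"] = (
            _round_half_up(100.0 * interest / n_all, 2) if n_all else None
        )
    # share-of-converted percentages (the headline table's in-cell style)
    for key in ("wcv_i", "wcv_ii", "pcv"):
        out[f"{key}_share_of_converted_pct"] = (
            _round_half_up(100.0 * out[key] / n_all, 2) if n_all else None
        )
    return out


def report_table1(summary: dict) -> pd.DataFrame:
    """Render the per-genome summary as the headline conversion table.

    Columns: paralogues; WCV-I/WCV-II/PCV counts with percentages of the
    paralogue count; all converted; conversion rate (3 decimals); period
    A/B counts where assigned.  Genomes with zero paralogues show dashes.
    """
    rows = {}
    for genome, s in summary.items():
        if not s["paralogues"]:
            rows[genome] = {k: "-" for k in (
                "paralogues", "WCV-I", "WCV-II", "PCV", "all_converted",
                "conversion_rate", "period_A", "period_B")}
            continue
        rows[genome] = {
            "paralogues": s["paralogues"],
            "WCV-I": f"{s['wcv_i']} ({s['wcv_i_pct']:.2f}%)",
            "WCV-II": f"{s['wcv_ii']} ({s['wcv_ii_pct']:.2f}%)",
            "PCV": f"{s['pcv']} ({s['pcv_pct']:.2f}%)",
            "all_converted": s["all_converted"],
            "conversion_rate": f"{s['conversion_rate']:.3f}",
            "period_A": s["period_A"],
            "period_B": s["period_B"],
        }
    return pd.DataFrame(rows).T


def _load_inputs(config: RunConfig):
    genomes = {}
    for name, paths in config.inputs.items():
        cds = io.read_fasta(paths["fasta"])
        genomes[name] = io.read_gff3_genes(paths["gff3"], name, cds)
    hits = io.read_homology_tsv(config.homology_path, permissive=True)
    return genomes, hits


def _paralog_pair_distances(
    pairs: list[tuple[str, str]], cds: dict[str, str]
) -> dict[frozenset, PairDistances]:
    out = {}
    for g1, g2 in pairs:
        s1, s2 = cds.get(g1, ""), cds.get(g2, "")
        if not s1 or not s2:
            continue
        if len(s1) != len(s2):
            try:
                aln = seqdist.align_quartet((g1, g2, g1, g2), (s1, s2, s1, s2))
                s1, s2 = aln.nt[0], aln.nt[1]
            except seqdist.QuartetRejected:
                continue
        try:
            out[frozenset((g1, g2))] = seqdist.pair_distances(s1, s2, g1, g2)
        except ValueError:
            continue
    return out


def run(config: RunConfig) -> RunResult:
    """Execute the full pipeline into ``config.outdir``."""
    outdir = io.ensure_dir(config.outdir)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    fh = logging.FileHandler(outdir / "run.log")
    logger.addHandler(fh)
    try:
        return _run_stages(config, outdir)
    finally:
        logger.removeHandler(fh)
        fh.close()


def _run_stages(config: RunConfig, outdir: Path) -> RunResult:
    rng = np.random.default_rng(config.seed)
    truth = []
    if config.simulation is not None:
        logger.info("stage simulate: %d genes", config.simulation.n_genes)
        dataset = simulate(config.simulation)
        write_dataset(dataset, outdir / "simulate")
        genomes = dataset.genomes
        hits = io.read_homology_tsv((outdir / "simulate" / "homology.tsv"))
        truth = dataset.truth
        sibling = config.sibling_genomes or tuple(config.simulation.genome_names[1:])
    else:
        logger.info("stage load: %d genomes", len(config.inputs))
        genomes, hits = _load_inputs(config)
        sibling = config.sibling_genomes

    logger.info("stage homology: %d hits", len(hits))
    hom = homology.homology_pipeline(
        genomes, hits,
        max_evalue=config.max_evalue, min_score=config.min_score,
        max_gap=config.max_gap, min_anchors=config.min_anchors,
        family_cap=config.family_cap, ks_cutoff=config.ks_cutoff,
    )
    stage = io.ensure_dir(outdir / "homology")
    io.write_blocks_tsv(hom.blocks, stage / "blocks.tsv")
    for (ga, gb), qs in hom.quartets.items():
        io.write_quartets_tsv(qs, stage / f"quartets_{ga}_{gb}.tsv")

    cds = {r.gene_id: r.cds for recs in genomes.values() for r in recs}
    names = sorted(genomes)

    logger.info("stage detect: analysing quartets")
    raw_calls: dict[str, list[ConversionCall]] = {g: [] for g in names}
    accepted_pairs: dict[str, set[frozenset]] = {g: set() for g in names}
    for (ga, gb), quartets in sorted(hom.quartets.items()):
        for q in quartets:
            try:
                aln = seqdist.align_quartet(
                    (q.o1, q.o2, q.s1, q.s2),
                    (cds[q.o1], cds[q.o2], cds[q.s1], cds[q.s2]),
                )
            except seqdist.QuartetRejected as exc:
                logger.debug("quartet %s rejected: %s", q.key, exc)
                continue
            keep, reason = seqdist.filter_quartet(
                aln, config.max_gap_fraction, config.min_aa_identity
            )
            if not keep:
                logger.debug("quartet %s filtered: %s", q.key, reason)
                continue
            accepted_pairs[ga].add(frozenset((q.o1, q.o2)))
            ctx = convdetect.QuartetContext.build(q, aln)
            calls = convdetect.analyze_quartet(
                ctx, sides=("A",),
                n_boot=config.n_boot, support_threshold=config.support_threshold,
                min_tract_len=config.min_tract_len,
                min_tract_score=config.min_tract_score,
                strong_score=config.strong_score,
                donor_margin=config.donor_margin, rng=rng,
            )
            raw_calls[ga].extend(calls)

    merged = {g: convdetect.merge_calls(raw_calls[g]) for g in names}
    period_summary = {}
    if sibling and all(s in merged for s in sibling):
        key = tuple(sorted(sibling))
        sib_quartets = hom.quartets.get((key[0], key[1]), []) + hom.quartets.get(
            (key[1], key[0]), []
        )
        pair_map = convdetect.build_pair_map(sib_quartets)
        period_summary = convdetect.assign_period(merged, tuple(sibling), pair_map)
    stage = io.ensure_dir(outdir / "detect")
    for g in names:
        io.write_calls_tsv(merged[g], stage / f"calls_{g}.tsv")
        io.write_tracts_bed(
            [c for c in merged[g] if c.tracts], stage / f"tracts_{g}.tsv"
        )

    logger.info("stage distances: paralogue pair distances")
    paralog_distances = {
        g: _paralog_pair_distances(hom.paralog_pairs[g], cds) for g in names
    }

    logger.info("stage stats")
    stats_dir = io.ensure_dir(outdir / "stats")
    chrom_of_pair = {gid: rec.chrom for recs in genomes.values() for gid, rec in
                     ((r.gene_id, r) for r in recs)}
    summary = {}
    for g in names:
        summary[g] = summarize_calls(
            len(accepted_pairs[g]), merged[g], chrom_of_pair,
            config.chrom_pair_of_interest,
        )
    summary["_ancestral"] = {
        "ancestral_loci": hom.ancestral_count,
        "loss_rates": {g: round(r, 4) for g, r in hom.loss_rates.items()},
    }
    if period_summary:
        summary["_periods"] = period_summary

    # positional enrichment per genome
    enrichment = {}
    for g in names:
        dup_genes = sorted({gid for pair in accepted_pairs[g] for gid in pair})
        gene_map = {r.gene_id: r for r in genomes[g]}
        converted_ids = {gid for c in merged[g] for gid in (c.gene1, c.gene2)}
        chrom_lengths = {}
        for r in genomes[g]:
            chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), r.end + 1000)
        records = [gene_map[gid] for gid in dup_genes if gid in gene_map]
        if not records:
            continue
        bins = genomestats.bin_genes(records, converted_ids, chrom_lengths, config.bin_width)
        try:
            perm = genomestats.fold_increase_and_permute(
                bins, config.outer_span, config.permutation_rounds,
                seed=int(rng.integers(0, 2**31 - 1)),
                rate_denominator=config.rate_denominator,
            )
            enrichment[g] = {
                "fold_increase": None if np.isinf(perm.observed_fold) else round(perm.observed_fold, 4),
                "rounds": perm.rounds,
                "p_value": perm.p_value,
            }
        except ValueError as exc:
            enrichment[g] = {"error": str(exc)}
    if enrichment:
        summary["_enrichment"] = enrichment
        with open(stats_dir / "enrichment.json", "w") as fh:
            json.dump(enrichment, fh, indent=2)

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=str)
    report = report_table1({g: summary[g] for g in names})
    report.to_csv(outdir / "table1.tsv", sep="\t")
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "genomes": names,
                "n_quartets": {f"{a}_{b}": len(v) for (a, b), v in hom.quartets.items()},
            },
            fh,
        )
    return RunResult(
        config=config, outdir=outdir, genomes=genomes, homology=hom,
        paralog_distances=paralog_distances, merged_calls=merged,
        period_summary=period_summary, summary=summary, truth=truth,
    )
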