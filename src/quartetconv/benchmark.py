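"""Parameter-recovery scoring against simulator truth tables.

The simulator records every implanted conversion as a TruthEvent; after a
pipeline run these helpers score the detector against that ground truth:
sensitivity and false-positive rate for whole-gene calls, recall and
tract-boundary error for partial calls, donor accuracy, and period-label
accuracy for the sibling genomes.  Also here: the null calibration of the
subtelomeric permutation test under uniform conversion placement.
"""

from __future__ import annotations

import numpy as np

from . import genomestats
from .records import GeneRecord, TruthEvent

__all__ = ["recovery_metrics", "permutation_null_calibration", "measure_ks"]


def recovery_metrics(result) -> dict:
    """Score a pipeline run against its simulation truth table.

    Matches merged calls to truth events by genome and unordered gene
    pair.  A partial event counts as recalled when a detected tract
    overlaps the true tract; boundary error is measured on the
    best-overlapping tract, both edges, in acceptor CDS nucleotides.
    Donor accuracy is computed over calls with an unambiguous donor;
    period accuracy over truth events in the sibling genomes (epoch
    "pre-variety-split" must surface as period A, "post" as B).
    """
    truth: list[TruthEvent] = result.truth
    if not truth:
        raise ValueError("run has no truth table (not a simulation run?)")
    calls = {g: {c.pair: c for c in cs} for g, cs in result.merged_calls.items()}
    sim_cfg = result.config.simulation
    siblings = set(sim_cfg.genome_names[1:])

    wcv_hit = wcv_tot = pcv_hit = pcv_tot = 0
    boundary_errors: list[int] = []
    donor_ok = donor_tot = donor_uncertain = 0
    period_ok = period_tot = 0
    for t in truth:
        pair = frozenset((t.donor, t.acceptor))
        c = calls.get(t.genome, {}).get(pair)
        if t.kind == "whole":
            wcv_tot += 1
            if c is not None and c.is_wcv:
                wcv_hit += 1
        else:
            pcv_tot += 1
            if c is not None and c.is_pcv:
                overlapping = [
                    tr for tr in c.tracts if tr[0] <= t.end and tr[1] >= t.start
                ]
                if overlapping:
                    pcv_hit += 1
                    best = max(
                        overlapping,
                        key=lambda tr: min(tr[1], t.end) - max(tr[0], t.start),
                    )
                    boundary_errors += [abs(best[0] - t.start), abs(best[1] - t.end)]
        if c is not None:
            if c.donor == "uncertain":
                donor_uncertain += 1
            else:
                donor_tot += 1
                donor_ok += c.donor == t.donor
            if t.genome in siblings:
                period_tot += 1
                want = "A" if t.epoch == "pre-variety-split" else "B"
                period_ok += c.period == want

    converted_pairs = {g: set() for g in result.merged_calls}
    for t in truth:
        converted_pairs.setdefault(t.genome, set()).add(frozenset((t.donor, t.acceptor)))
    false_wcv = false_pcv = n_unconverted = 0
    for g, by_pair in calls.items():
        for pair, c in by_pair.items():
            if pair not in converted_pairs.get(g, set()):
                false_wcv += c.is_wcv
                false_pcv += c.is_pcv
    for g, s in result.summary.items():
        if g.startswith("_"):
            continue
        n_unconverted += s["paralogues"] - len(converted_pairs.get(g, set()))

    def frac(a, b):
        return a / b if b else float("nan")

    return {
        "wcv_events": wcv_tot,
        "wcv_sensitivity": frac(wcv_hit, wcv_tot),
        "pcv_events": pcv_tot,
        "pcv_recall": frac(pcv_hit, pcv_tot),
        "pcv_boundary_error_median_nt": (
            float(np.median(boundary_errors)) if boundary_errors else float("nan")
        ),
        "donor_calls": donor_tot,
        "donor_uncertain": donor_uncertain,
        "donor_accuracy": frac(donor_ok, donor_tot),
        "period_calls": period_tot,
        "period_accuracy": frac(period_ok, period_tot),
        "unconverted_pairs": n_unconverted,
        "false_wcv_calls": false_wcv,
        "false_pcv_calls": false_pcv,
        "wcv_fpr": frac(false_wcv, n_unconverted),
        "pcv_fpr": frac(false_pcv, n_unconverted),
    }


def permutation_null_calibration(
    genes: list[GeneRecord],
    chrom_lengths: dict[str, int],
    converted_fraction: float = 0.1,
    n_replicates: int = 100,
    rounds: int = 1000,
    outer_span: int = 2_000_000,
    bin_width: int = 500_000,
    seed: int = 0,
) -> dict:
    """Null calibration of the subtelomeric enrichment test.

    For each replicate a ``converted_fraction`` of the genes is marked
    converted uniformly at random (no positional preference), and the
    fold-increase permutation test is run with ``rounds`` rounds.  Under
    this null, p-values should exceed 0.05 in the large majority of
    replicates.  Returns the fraction of replicates with p > 0.05 and the
    mean observed fold.
    """
    rng = np.random.default_rng(seed)
    gene_ids = [g.gene_id for g in genes]
    n_conv = max(1, int(round(converted_fraction * len(gene_ids))))
    p_values, folds = [], []
    for _ in range(n_replicates):
        converted = set(rng.choice(gene_ids, size=n_conv, replace=False))
        bins = genomestats.bin_genes(genes, converted, chrom_lengths, bin_width)
        res = genomestats.fold_increase_and_permute(
            bins, outer_span, rounds=rounds, seed=int(rng.integers(0, 2**31 - 1))
        )
        p_values.append(res.p_value)
        if np.isfinite(res.observed_fold):
            folds.append(res.observed_fold)
    p_values = np.array(p_values)
    return {
        "n_replicates": n_replicates,
        "fraction_p_above_0.05": float((p_values > 0.05).mean()),
        "mean_fold": float(np.mean(folds)) if folds else float("nan"),
        "median_p": float(np.median(p_values)),
    }


def measure_ks(dataset, max_families: int | None = None) -> dict:
    """Measured mean pairwise synonymous distances of a simulated dataset
    (paralogue pairs in the early lineage; orthologues across the first
    split), via the package's own NG/JC machinery."""
    from .seqdist import pair_distances

    idx = dataset.genome_index()
    g_early, g_sib1, _ = dataset.config.genome_names
    ks_para, ks_orth = [], []
    fams = dataset.families[:max_families] if max_families else dataset.families
    for fam in fams:
        e = fam.genes[g_early]
        s = fam.genes[g_sib1]
        if e[0] and e[1]:
            d = pair_distances(idx[e[0]].cds, idx[e[1]].cds)
            if d.Ps is not None:
                ks_para.append(d.Ps)
        if e[0] and s[0]:
            d = pair_distances(idx[e[0]].cds, idx[s[0]].cds)
            if d.Ps is not None:
                ks_orth.append(d.Ps)
    return {
        "paralog_ks_mean": float(np.mean(ks_para)) if ks_para else float("nan"),
        "ortholog_ks_mean": float(np.mean(ks_orth)) if ks_orth else float("nan"),
        "n_paralog_pairs": len(ks_para),
        "n_ortholog_pairs": len(ks_orth),
    }
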