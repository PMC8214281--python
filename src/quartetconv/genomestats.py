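"""Genome-scale summaries of conversion calls.

Positional enrichment follows the chromosome-arm binning scheme:
duplicated genes are assigned to fixed-width bins (default 500 kb)
ordered from the nearer chromosome terminus toward the centre, the
conversion rate is computed per bin, the outermost bins of each arm are
compared with all other bins as a fold increase of means, and
significance comes from a permutation test that shuffles the bin-level
rates between the outer and inner groups.

Also provided: OLS regression of per-chromosome conversion rates on
block counts, converted-vs-nonconverted comparisons of substitution
rates (Welch t-tests on Pn, Ps, Pn/Ps) and of expression (twofold-change
fractions and mean FPKM differences), per-category Pearson chi-square
tests, and cross-genome donor-consistency counts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .records import ConversionCall, GeneRecord, PairDistances

__all__ = [
    "ArmBin",
    "PermutationResult",
    "bin_genes",
    "fold_increase_and_permute",
    "block_rate_regression",
    "compare_converted_vs_nonconverted",
    "expression_compare",
    "category_chisq",
    "donor_consistency",
]

DEFAULT_BIN_WIDTH = 500_000
DEFAULT_ROUNDS = 1_000_000


@dataclass
class ArmBin:
    """One fixed-width bin on a chromosome arm, indexed from the terminus."""

    genome: str
    chrom: str
    arm: str  # "left" | "right"
    bin_index: int
    bin_width: int
    converted: int = 0
    nonconverted: int = 0

    @property
    def total(self) -> int:
        return self.converted + self.nonconverted

    def rate(self, denominator: str = "total") -> float:
        if denominator == "total":
            den = self.total
        elif denominator == "nonconverted":
            den = self.nonconverted
        else:
            raise ValueError("denominator must be 'total' or 'nonconverted'")
        return self.converted / den if den else float("nan")


@dataclass
class PermutationResult:
    observed_fold: float
    rounds: int
    p_value: float
    seed: int | None = None


def bin_genes(
    genes: list[GeneRecord],
    converted_ids: set[str],
    chrom_lengths: dict[str, int],
    bin_width: int = DEFAULT_BIN_WIDTH,
) -> list[ArmBin]:
    """Assign duplicated genes to chromosome-arm bins.

    A gene's arm is the nearer terminus (midpoint rule for the bin
    index); every gene lands in exactly one bin.  Genes beyond the stated
    chromosome length raise, naming the gene.
    """
    bins: dict[tuple[str, str, str, int], ArmBin] = {}
    for g in genes:
        length = chrom_lengths.get(g.chrom)
        if length is None:
            raise ValueError(f"no chromosome length for {g.chrom}")
        if g.end > length:
            raise ValueError(f"gene {g.gene_id} extends beyond {g.chrom} ({length} bp)")
        mid = (g.start + g.end) // 2
        dist_left = mid - 1
        dist_right = length - mid
        if dist_left <= dist_right:
            arm, dist = "left", dist_left
        else:
            arm, dist = "right", dist_right
        idx = int(dist // bin_width)
        key = (g.genome, g.chrom, arm, idx)
        if key not in bins:
            bins[key] = ArmBin(
                genome=g.genome, chrom=g.chrom, arm=arm,
                bin_index=idx, bin_width=bin_width,
            )
        if g.gene_id in converted_ids:
            bins[key].converted += 1
        else:
            bins[key].nonconverted += 1
    return [bins[k] for k in sorted(bins)]


def fold_increase_and_permute(
    bins: list[ArmBin],
    outer_span: int,
    rounds: int = DEFAULT_ROUNDS,
    seed: int | None = None,
    rate_denominator: str = "total",
    exact: bool = False,
) -> PermutationResult:
    """Fold increase of the outer-arm conversion rate and its permutation p.

    ``outer_span`` (bp) selects the first ``outer_span // bin_width`` bins
    of each arm as the outer group; the fold increase divides the mean
    outer-bin rate by the mean rate of all other bins.  The permutation
    test shuffles bin-level rates between the groups; p = (1 + #{permuted
    fold >= observed}) / (rounds + 1).  ``exact`` enumerates all
    assignments instead (p = #{fold >= observed} / n_assignments),
    feasible for small bin counts.
    """
    if not bins:
        raise ValueError("no bins")
    k_bins = max(1, outer_span // bins[0].bin_width)
    rates = np.array([b.rate(rate_denominator) for b in bins])
    outer_mask = np.array([b.bin_index < k_bins for b in bins])
    rates_ok = ~np.isnan(rates)
    rates, outer_mask = rates[rates_ok], outer_mask[rates_ok]
    n_outer = int(outer_mask.sum())
    n_inner = int((~outer_mask).sum())
    if n_outer == 0 or n_inner == 0:
        raise ValueError("outer or complement bin group is empty")

    def fold(outer_vals: np.ndarray, inner_vals: np.ndarray) -> float:
        inner_mean = inner_vals.mean()
        outer_mean = outer_vals.mean()
        if inner_mean == 0:
            return math.inf if outer_mean > 0 else 1.0
        return outer_mean / inner_mean

    observed = fold(rates[outer_mask], rates[~outer_mask])
    n = len(rates)
    if exact:
        from itertools import combinations

        hits = total = 0
        idx = np.arange(n)
        for combo in combinations(idx, n_outer):
            mask = np.zeros(n, dtype=bool)
            mask[list(combo)] = True
            total += 1
            if fold(rates[mask], rates[~mask]) >= observed - 1e-9 * max(1.0, abs(observed)):
                hits += 1
        return PermutationResult(observed, total, hits / total, seed)

    rng = np.random.default_rng(seed)
    hits = 0
    chunk = max(1, min(rounds, int(2e7) // max(n, 1)))
    done = 0
    sum_all = rates.sum()
    while done < rounds:
        m = min(chunk, rounds - done)
        perm = rng.permuted(np.tile(rates, (m, 1)), axis=1)
        outer_sum = perm[:, :n_outer].sum(axis=1)
        inner_mean = (sum_all - outer_sum) / n_inner
        outer_mean = outer_sum / n_outer
        with np.errstate(divide="ignore", invalid="ignore"):
            folds = np.where(
                inner_mean == 0,
                np.where(outer_mean > 0, np.inf, 1.0),
                outer_mean / np.where(inner_mean == 0, 1.0, inner_mean),
            )
        # tolerance so reassignments identical to the observed grouping are
        # counted despite summation-order rounding
        thresh = observed - 1e-9 * max(1.0, abs(observed)) if np.isfinite(observed) else observed
        hits += int((folds >= thresh).sum())
        done += m
    p = (1 + hits) / (rounds + 1)
    return PermutationResult(observed, rounds, p, seed)


def block_rate_regression(
    block_counts: dict[str, float],
    conversion_rates: dict[str, float],
    exclude: set[str] | None = None,
) -> dict[str, float]:
    """OLS of per-chromosome conversion rate on block count (or length).

    ``exclude`` removes chromosomes (e.g. the strongly converted
    homoeologous pairs) before fitting.  Returns slope, intercept, R²,
    two-sided p for the slope, and n.
    """
    exclude = exclude or set()
    chroms = sorted(set(block_counts) & set(conversion_rates) - exclude)
    if len(chroms) < 3:
        raise ValueError("need at least three chromosomes after exclusion")
    x = np.array([block_counts[c] for c in chroms], dtype=float)
    y = np.array([conversion_rates[c] for c in chroms], dtype=float)
    if np.allclose(y, y[0]):
        return {"slope": 0.0, "intercept": float(y[0]), "r_squared": 0.0,
                "p_value": 1.0, "n": len(chroms)}
    res = stats.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p_value": float(res.pvalue),
        "n": len(chroms),
    }


def _welch(a: np.ndarray, b: np.ndarray) -> float:
    if len(a) < 2 or len(b) < 2:
        raise ValueError("group size < 2")
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_converted_vs_nonconverted(
    distances: dict[frozenset, PairDistances],
    converted_pairs: set[frozenset],
) -> pd.DataFrame:
    """Welch t-tests of Pn, Ps, and Pn/Ps between converted and
    nonconverted pairs (pairs with Ps = 0 are excluded from the ratio;
    saturated pairs are excluded throughout)."""
    rows = {}
    groups = {"converted": [], "nonconverted": []}
    for pair, d in distances.items():
        if d.saturated:
            continue
        groups["converted" if pair in converted_pairs else "nonconverted"].append(d)
    for metric in ("Pn", "Ps", "Pn/Ps"):
        vals = {}
        for name, ds in groups.items():
            if metric == "Pn":
                v = [d.Pn for d in ds]
            elif metric == "Ps":
                v = [d.Ps for d in ds]
            else:
                v = [d.Pn / d.Ps for d in ds if d.Ps and d.Ps > 0]
            vals[name] = np.array(v, dtype=float)
        rows[metric] = {
            "converted_mean": float(vals["converted"].mean()) if len(vals["converted"]) else float("nan"),
            "nonconverted_mean": float(vals["nonconverted"].mean()) if len(vals["nonconverted"]) else float("nan"),
            "n_converted": len(vals["converted"]),
            "n_nonconverted": len(vals["nonconverted"]),
            "p_value": _welch(vals["converted"], vals["nonconverted"]),
        }
    return pd.DataFrame(rows).T


def expression_compare(
    expression: pd.DataFrame,
    pairs: list[tuple[str, str]],
    converted_pairs: set[frozenset],
    sample: str,
) -> pd.DataFrame:
    """Expression divergence of converted vs nonconverted duplicate pairs.

    Pairs with either member unexpressed (FPKM 0) or missing are removed;
    a pair is twofold-different when max/min > 2; the mean absolute FPKM
    difference is compared by Welch t-test on the raw values.
    """
    if sample not in expression.columns:
        raise ValueError(f"sample {sample!r} not in expression matrix")
    col = expression[sample]
    groups: dict[str, list[float]] = {"converted": [], "nonconverted": []}
    twofold: dict[str, int] = {"converted": 0, "nonconverted": 0}
    counts: dict[str, int] = {"converted": 0, "nonconverted": 0}
    for g1, g2 in pairs:
        if g1 not in col.index or g2 not in col.index:
            continue
        e1, e2 = float(col[g1]), float(col[g2])
        if e1 <= 0 or e2 <= 0:
            continue  # genes with no expression removed
        name = "converted" if frozenset((g1, g2)) in converted_pairs else "nonconverted"
        counts[name] += 1
        if max(e1, e2) / min(e1, e2) > 2:
            twofold[name] += 1
        groups[name].append(abs(e1 - e2))
    p = _welch(np.array(groups["converted"]), np.array(groups["nonconverted"]))
    rows = {
        name: {
            "n_pairs": counts[name],
            "twofold_fraction": twofold[name] / counts[name] if counts[name] else float("nan"),
            "mean_abs_difference": float(np.mean(groups[name])) if groups[name] else float("nan"),
            "p_value": p,
        }
        for name in ("converted", "nonconverted")
    }
    return pd.DataFrame(rows).T


def category_chisq(
    gene_categories: dict[str, set[str]],
    converted_genes: set[str],
    all_genes: set[str],
) -> pd.DataFrame:
    """Per-category converted vs nonconverted percentages with Pearson
    chi-square (no continuity correction) on the 2×2 membership table."""
    nonconverted = all_genes - converted_genes
    rows = {}
    for category, members in sorted(gene_categories.items()):
        cv_in = len(converted_genes & members)
        ncv_in = len(nonconverted & members)
        if cv_in + ncv_in == 0:
            continue  # empty category skipped
        table = np.array(
            [
                [cv_in, len(converted_genes) - cv_in],
                [ncv_in, len(nonconverted) - ncv_in],
            ]
        )
        warning = ""
        if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
            chi2, p = 0.0, 1.0  # degenerate table: no association measurable
        else:
            chi2, p, _, expected = stats.chi2_contingency(table, correction=False)
            if (expected < 1).any():
                warning = "expected cell < 1"
        rows[category] = {
            "converted_pct": 100.0 * cv_in / len(converted_genes) if converted_genes else float("nan"),
            "nonconverted_pct": 100.0 * ncv_in / len(nonconverted) if nonconverted else float("nan"),
            "chi2": float(chi2),
            "p_value": float(p),
            "warning": warning,
        }
    return pd.DataFrame(rows).T


def donor_consistency(
    merged_calls: dict[str, list[ConversionCall]],
    ortholog_groups: dict[str, str],
) -> dict[str, float]:
    """Cross-genome donor agreement.

    ``ortholog_groups`` maps each gene id to its orthologous-locus label
    (genes at the same ancestral position share a label).  Reports how
    many loci are converted in >= 2 genomes, act as donors in >= 2
    genomes, and have the same donor locus in all genomes; "uncertain"
    donors are excluded from the donor numerators.
    """
    from collections import defaultdict

    conv_genomes: dict[str, set[str]] = defaultdict(set)
    donor_genomes: dict[str, set[str]] = defaultdict(set)
    pair_donors: dict[frozenset, dict[str, str]] = defaultdict(dict)
    n_genomes = len(merged_calls)
    for genome, calls in merged_calls.items():
        for c in calls:
            for gid in (c.gene1, c.gene2):
                locus = ortholog_groups.get(gid)
                if locus:
                    conv_genomes[locus].add(genome)
            if c.donor != "uncertain":
                donor_locus = ortholog_groups.get(c.donor)
                if donor_locus:
                    donor_genomes[donor_locus].add(genome)
                    pair_key = frozenset(
                        ortholog_groups.get(g, g) for g in (c.gene1, c.gene2)
                    )
                    pair_donors[pair_key][genome] = donor_locus
    n_conv = len(conv_genomes)
    conv_ge2 = sum(1 for gs in conv_genomes.values() if len(gs) >= 2)
    n_donor = len(donor_genomes)
    donor_ge2 = sum(1 for gs in donor_genomes.values() if len(gs) >= 2)
    same_all_loci = {
        next(iter(dm.values()))
        for dm in pair_donors.values()
        if len(dm) == n_genomes and len(set(dm.values())) == 1
    }
    same_all = len(same_all_loci)
    return {
        "converted_loci": n_conv,
        "converted_in_ge2_genomes": conv_ge2,
        "converted_in_ge2_pct": 100.0 * conv_ge2 / n_conv if n_conv else float("nan"),
        "donor_loci": n_donor,
        "donor_in_ge2_genomes": donor_ge2,
        "donor_in_ge2_pct": 100.0 * donor_ge2 / n_donor if n_donor else float("nan"),
        "same_donor_all_genomes": same_all,
        "same_donor_all_pct": 100.0 * same_all / n_donor if n_donor else float("nan"),
    }
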