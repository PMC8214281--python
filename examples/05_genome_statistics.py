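"""Genome-distribution statistics of conversion calls.

Demonstrates the positional machinery on synthetic data: 500-kb
chromosome-arm bins, the subtelomeric fold-increase permutation test,
the per-chromosome block-count regression, and the converted-vs-
nonconverted substitution-rate comparison.
"""

import numpy as np

import quartetconv as qc
from quartetconv import genomestats

rng = np.random.default_rng(5)
ds = qc.simulate(qc.SimConfig(n_genes=800, n_chromosomes=2, seed=5))
genes = ds.genomes["G1"]
chrom_lengths = {}
for r in genes:
    chrom_lengths[r.chrom] = max(chrom_lengths.get(r.chrom, 0), r.end + 1000)

# converted set biased toward chromosome ends (2x base rate in outer 2 Mb)
converted = set()
for g in genes:
    dist = min(g.start, chrom_lengths[g.chrom] - g.end)
    p = 0.20 if dist < 2_000_000 else 0.10
    if rng.random() < p:
        converted.add(g.gene_id)

bins = genomestats.bin_genes(genes, converted, chrom_lengths, bin_width=500_000)
print(f"{len(genes)} duplicated genes in {len(bins)} arm bins of 500 kb")
res = genomestats.fold_increase_and_permute(
    bins, outer_span=2_000_000, rounds=100_000, seed=1
)
print(f"outer-2-Mb fold increase: {res.observed_fold:.2f}, "
      f"permutation p = {res.p_value:.2e} ({res.rounds} rounds)")
print("a fold > 1 with small p means conversion concentrates near the termini,")
print("as implanted here; under uniform placement p stays > 0.05.")
print()

# block-count regression on toy per-chromosome data
counts = {f"chr{i}": float(c) for i, c in enumerate([4, 7, 9, 12, 15, 18], 1)}
rates = {f"chr{i}": r for i, r in enumerate([0.08, 0.11, 0.12, 0.15, 0.17, 0.21], 1)}
reg = qc.block_rate_regression(counts, rates)
print(f"conversion rate vs block count: R^2 = {reg['r_squared']:.2f}, "
      f"slope = {reg['slope']:.4f}, p = {reg['p_value']:.3g} (n = {reg['n']})")
print("a positive slope links chromosome rearrangement (more, shorter blocks)")
print("with the local conversion rate.")
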