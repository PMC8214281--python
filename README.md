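# quartetconv

Detection of **ongoing gene conversion between ancient whole-genome-duplication
(WGD) paralogues** from comparative genomics, with a bundled synthetic-genome
simulator for end-to-end validation.

## The problem

Paralogue pairs created by an ancient polyploidy (in grasses, the ρ WGD,
~100 Mya) should have drifted far apart: their synonymous divergence peaks
around Ks ≈ 0.65. Orthologues between closely related genomes — such as the
*japonica* and *indica* rice subspecies, separated only ~0.4 Mya — should be
nearly identical (Ks ≈ 0.02–0.10). Nonreciprocal recombination between
homoeologous regions (gene conversion) overwrites one duplicate (the
*acceptor*) with its partner's sequence (the *donor*), making an ancient pair
look abruptly young. This package detects such events, locates the converted
tracts, identifies donors, dates events relative to a recent genome split, and
summarises their genomic distribution.

## The method

The unit of inference is the **homologous gene quartet**: a paralogue pair
(O1, O2) in genome A joined with its orthologues (S1, S2) in genome B.
Without conversion, similarity obeys orthologues > paralogues; conversion
after speciation inverts that topology.

- **Quartet construction** — homology hits (BLAST outfmt-6; E < 1e-5,
  score > 100, gene families of ≥ 30 copies removed) are chained into
  collinear blocks on the rank–rank dot-plot (weighted DP, ascending and
  descending diagonals, ≤ 50 intervening genes, ≥ 5 anchors). Blocks are
  labelled paralogous or orthologous by their median anchor Ks and
  supplemented with bidirectional best hits inside labelled regions.
- **Distances** — codon-aware alignment (protein-guided, back-translated),
  then Nei–Gojobori counting: per-codon synonymous/nonsynonymous sites,
  multi-hit codons averaged over minimal mutational paths, and the
  Jukes–Cantor correction `d = −(3/4)·ln(1 − (4/3)p)` giving Pn and Ps.
  Quartets with > 50% pairwise gaps or < 40% amino-acid identity are dropped.
- **Whole-gene conversion (WCV)** — Ks criterion:
  `Ks(O1,O2) < min(Ks(O1,S1), Ks(O2,S2))`, strict, with support from 1000
  bootstrap resamplings of codon columns; identity criterion: amino-acid
  identity of the paralogues strictly above both orthologue identities.
- **Partial conversion (PCV)** — per-site scores `s(i) = dO(i) − dP(i)`
  (orthologue minus paralogue difference); all maximal-scoring subsequences
  (Ruzzo–Tompa) of ≥ 10 nt are candidate tracts, weak tracts must beat
  shuffled score arrays in a bootstrap, and accepted tracts are masked so the
  search recovers multiple events per gene.
- **Donors and periods** — the paralogue retaining higher orthologue identity
  (on the tract, for PCV) is the donor; events shared by the two sibling
  genomes at the orthologous position predate their split (period A), events
  in one genome postdate it (period B).
- **Genome statistics** — 500-kb chromosome-arm bins with a fold-increase
  permutation test for subtelomeric enrichment, per-chromosome block-count
  regression, Welch t-tests of Pn/Ps between converted and nonconverted
  pairs, expression-divergence comparisons, and Pearson chi-square tests on
  gene categories.

The simulator (`quartetconv.simgenome`) generates all of this structure with
a known truth table — WGD paralogy at a target Ks, a species tree
((sibling1, sibling2), early lineage), gene loss, and implanted conversions —
so every detector is validated by parameter recovery.

## Worked example

```python
import quartetconv as qc

sim = qc.SimConfig(n_genes=150, seed=11, wcv_rate=0.06, pcv_rate=0.10,
                   loss_rates=(0.02, 0.04, 0.03), donor_bias=1.0)
cfg = qc.RunConfig(simulation=sim, outdir="runs/demo", seed=1,
                   permutation_rounds=2000)
result = qc.run(cfg)
print(qc.report_table1({g: s for g, s in result.summary.items()
                        if not g.startswith("_")}).to_string())
```

prints

```
   paralogues      WCV-I      WCV-II          PCV all_converted conversion_rate period_A period_B
G1        145  0 (0.00%)  10 (6.90%)  20 (13.79%)            30           0.207        0        0
X1        142  0 (0.00%)  13 (9.15%)  15 (10.56%)            28           0.197       21        7
X2        144  0 (0.00%)  11 (7.64%)   12 (8.33%)            23           0.160       21        2
```

Each row is one genome: the number of paralogue pairs in accepted quartets,
whole-gene calls by the Ks-only criterion (WCV-I) and the identity criterion
(WCV-II), partial-tract calls (PCV), the merged converted-pair total, the
conversion rate (converted / paralogues), and the period split for the two
sibling genomes. Scoring the same run against the simulator's truth table
(`qc.recovery_metrics(result)`) gives WCV sensitivity 1.000 over 34 implanted
whole conversions, PCV recall 0.958 over 48 implanted tracts with a median
tract-boundary error of 2 nt, donor accuracy 1.000, and period accuracy
0.980.

The `examples/` directory holds one short script per capability (simulation,
quartet distances, detection, tract delimitation, genome statistics); each
prints its numbers with a line on what they mean. A thin CLI mirrors the
pipeline: `quartetconv simulate`, `quartetconv run-all --config cfg.yaml`,
`quartetconv report <rundir>`.

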