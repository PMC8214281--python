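# Methods

This note documents the models, parameters, numerical choices, and known
limitations of `quartetconv`. It is the package's own account of its
science; every empirical number quoted here is computed by the test suite
or by `scripts/acceptance.py`.

## Evolutionary setting and the quartet test

The package targets duplicate pairs created by an ancient whole-genome
duplication that long predates the divergence of the genomes being
compared. In that regime a homologous gene quartet — paralogues (O1, O2)
in genome A, orthologues (S1, S2) in genome B — has a fixed expected
topology: each orthologue pair coalesces at the speciation, the paralogue
pair at the WGD. Gene conversion after speciation replaces the acceptor's
sequence with the donor's, so the paralogues become more similar than at
least one orthologue pair. All detectors reduce to pairwise similarity
comparisons within the quartet; no explicit tree is built, which is exactly
adequate because only one topology change is possible under the model.

The approach assumes the two divergence scales are well separated
(paralogue Ks ≈ 0.65 versus orthologue Ks ≈ 0.02–0.10 in the rice-like
setting). As the scales approach each other, strict-inequality tests lose
power and the false-call risk of stochastic rate variation grows.

## Sequence distances

**Alignment.** Quartet CDS are translated (quartets with untranslatable
CDS are rejected with a reason code), proteins are aligned by progressive
pairwise global alignment (BLOSUM62, gap open −10, extend −0.5, first
sequence as the star centre), and the alignment is back-translated to
codons. Equal-length proteins skip the aligner — their progressive global
alignment is gap-free by construction. Externally aligned FASTA can be
substituted where exact reproduction of a third-party alignment matters.

**Divergence filters.** A quartet is dropped when any of its six protein
pairs has a gap fraction above 0.5 of the pairwise alignment length or an
amino-acid identity below 0.4. Both thresholds are exposed.

**Nei–Gojobori with Jukes–Cantor correction.** Synonymous/nonsynonymous
site counts per codon use the standard one-step-neighbour fractions with
stop-codon mutations excluded from the per-position denominator, so
S + N = 3 for every sense codon. Codon pairs differing at 2–3 positions
are decomposed by unweighted averaging over all minimal mutational paths;
paths through stop codons are excluded (with a fallback to all paths when
every path is blocked, which cannot arise between sense codons under the
standard code without at least one stop-free path being absent — the
fallback exists for completeness). Sites are averaged over the two
sequences; codon columns with a gap anywhere in either codon are excluded
whole-codon for that pair, keeping site sums consistent. Raw proportions
pN = Nd/N and pS = Sd/S are corrected as d = −(3/4)·ln(1 − (4/3)p),
denoted Pn and Ps; p ≥ 0.75 is reported as saturated (None) and excluded
from Ks-based tests. The entire computation is table-driven (64-codon site
vectors, 64×64 path-averaged difference matrices precomputed at import)
and is checked exactly against an independent brute-force enumeration in
the tests.

## Whole-gene conversion

*Ks criterion (WCV-I).* A call requires Ks(O1,O2) < min(Ks(O1,S1),
Ks(O2,S2)), strictly, with all four distances computable. Confidence is a
bootstrap over codon columns: columns are resampled with replacement
(multinomial column counts shared across the pairs, so the resampling is
coherent within the quartet), the inequality re-evaluated, and the call
kept when the bootstrap frequency reaches the support threshold (default
0.95 over 1000 replicates; both exposed). Codon columns, not single
nucleotides, are the resampling unit so synonymous/nonsynonymous site
counts stay meaningful; nucleotide-level resampling is deliberately not
offered.

*Identity criterion (WCV-II).* Amino-acid identity of the paralogues must
strictly exceed both orthologue identities, computed site by site over
each pair's ungapped columns. No bootstrap: the criterion is already the
stricter one in practice.

All inequalities are strict, so ties — in particular the all-identical
quartets of a zero-divergence control — can never produce a call. In
reporting, WCV-I counts calls that satisfy the Ks criterion *only*, and
WCV-II counts identity-criterion calls; the two are disjoint and sum to
the whole-gene total, matching the headline-table convention in which the
identity criterion dominates the counts.

## Partial-gene conversion

Per ungapped alignment site, dP(i) ∈ {0,1} marks a paralogue difference
and dO(i) ∈ {0, 0.5, 1} averages the two orthologue-pair differences; the
score is s(i) = dO(i) − dP(i). Converted tracts make paralogues locally
identical while the acceptor drifts from its orthologue, so they appear
as runs of positive s against a negative background (the background mean
is strongly negative because paralogue differences dominate outside the
tract).

Tracts are all maximal-scoring subsequences of s in the Ruzzo–Tompa
sense — segments whose every prefix and suffix has strictly positive
partial sum, not extendable to a longer such segment (the implementation
is the linear-time stack algorithm, verified against exhaustive
enumeration). Candidates must span ≥ 10 nt (the published minimum) and
reach a minimum score (default 2.0). Segments below a "strong" score
(default 4.0) additionally face a shuffle bootstrap: the current score
array is permuted 1000 times and the segment is kept only when its sum
exceeds the best segment of the shuffle in ≥ 95% of replicates. Accepted
tracts are masked (scores zeroed) and the search repeats, so several
events per gene are recovered. The scoring constants reconstruct a
procedure whose published description lists the steps but not the
numbers; all of them are configuration parameters.

Tract coordinates are reported both in alignment space and in acceptor
CDS space (1-based inclusive). Boundary precision is limited by the
informative-site density: a tract edge can only be placed at the
outermost site where an orthologue pair differs inside the homogenized
region, which at rice-like divergences puts the median boundary error at
about 2 nt (measured by the acceptance run).

## Donor inference, merging, periods

The donor is the paralogue whose orthologue identity stays higher —
its sequence was not overwritten — compared on the tract's codon columns
for partial events and genome-wide for whole events. Margins below 0.005
give "uncertain" rather than a guess. Calls for the same unordered
paralogue pair arising from different quartets are merged: method flags
OR-combined, overlapping tracts unioned, donors kept only when
consistent. Merging is idempotent.

For the two sibling genomes, a converted pair detected at the orthologous
position in both siblings is assigned to period A (conversion before
their split); detected in exactly one, period B. The orthologous-position
map comes from the quartets linking the siblings. With fewer than two
sibling genomes, periods stay unassigned.

## Homology and quartet construction

Hits are filtered at E-value < 1e-5 and score > 100 (strict), self-hits
removed; genes whose within-genome family (distinct surviving partners
plus self) reaches 30 members are excluded from collinearity input but
not from best-hit supplementation. Chaining runs per chromosome pair on
the rank–rank dot-plot: anchors score 1, chains are strictly monotonic
(ascending or descending on the second axis) with at most 50 intervening
genes between consecutive anchors on both axes, blocks need ≥ 5 anchors
("more than four collinear gene pairs"), and extraction is greedy —
best chain, remove its anchors, repeat — with ties broken by the
lexicographically smallest (rankA, rankB) anchor sequence for
determinism. The published pipeline's external collinearity tool applies
a statistical significance test; here the anchor-count threshold plays
that role, with an optional permutation significance test
(`block_permutation_pvalue`: shuffle the second-axis ranks, re-chain,
count chains reaching the observed anchor count) for borderline blocks.

Between-genome blocks are labelled orthologous when the median anchor Ks
falls below 0.3 — a cutoff placed between the orthologue (~0.05) and
WGD-paralogue (~0.65) modes, configurable — and paralogous above it;
within-genome blocks are paralogous by construction; blocks with fewer
than three computable Ks values are ambiguous and excluded from quartet
building. Bidirectional best hits (best = highest bit score, then lowest
E-value, then lexicographic subject) supplement anchor pairs, but only
inside the rank span of an already-labelled block of the right relation,
which prevents a lost orthologue's cross-copy best hit from contaminating
the orthology map. Orthologue pairs are reduced to 1:1 with block anchors
taking priority over supplements. A quartet is emitted iff both
paralogues have orthologues in the partner genome.

Ancestral gene content is estimated from connected components of the
orthologue graph: a component containing genes of ≥ 2 of the 3 genomes
counts as an ancestral locus, and a genome's loss rate is the fraction of
ancestral loci it lacks. The ≥2-of-3 rule is this package's choice (the
published analysis does not state its rule); it cannot see loci lost in
two genomes, which biases recovered loss rates downward by roughly the
product of loss rates (~1–2 points at 6–13% loss) — the acceptance run
reports the recovered values next to the simulated truth.

## Genome statistics

Genes are assigned to fixed-width bins (default 500 kb) on the nearer
chromosome arm, by gene midpoint (the published method does not specify
start/midpoint/end). The fold increase divides the mean rate of the
outermost bins of each arm (the outer span in bp is a parameter — the
published analysis itself uses 0–2 Mb for one genome and 0–6 Mb for the
others, so no single default is privileged) by the mean of all other
bins. The permutation test shuffles bin-level rates between the groups;
p = (1 + hits)/(rounds + 1) with 10^6 rounds by default, an exact
enumeration mode for small bin counts, and a guarded "inf" fold when the
complement mean is zero. Comparisons use a small relative tolerance so
regroupings identical to the observed one always count as hits despite
summation-order rounding.

The per-bin conversion *rate* divides converted genes by the bin total by
default; the published text defines the rate against nonconverted genes
while the printed tables are more consistent with the total — both
denominators are available (`rate_denominator`). Per-distance-class
summaries are means of per-bin rates, not pooled counts, for the same
reason.

Block-count regression is OLS (scipy `linregress`) of per-chromosome
conversion rate on block count or length, with an optional chromosome
exclusion list. Converted-vs-nonconverted comparisons use Welch's
unequal-variance t-test on Pn, Ps, and Pn/Ps (pairs with Ps = 0 excluded
from the ratio; saturated pairs excluded throughout) — the published
analysis says only "t-test", and Welch is the safer default. Expression
comparisons drop pairs with an unexpressed member, call a pair
twofold-different when max/min > 2, and compare mean absolute FPKM
differences by Welch; category tests are Pearson chi-square without
continuity correction on the 2×2 membership table, with a warning
attached when an expected cell is below 1. Donor consistency maps genes
to orthologous-locus labels and reports loci converted in ≥ 2 genomes,
loci donating in ≥ 2 genomes, and loci that are the unanimous donor in
all genomes.

## The simulator

`simgenome` generates the study conditions, not a general-purpose
evolver. An ancestral gene set (default 150–450 codons per gene, uniform;
ATG start; no stops) is packed on chromosomes at fixed 10-kb start-to-start
spacing — enough genome length to exercise 500-kb binning. A WGD copies
every gene onto a homoeologous chromosome; substitutions follow a
site-independent JC-like proposal process in which synonymous proposals
are always accepted, nonsynonymous ones with probability 0.4 (placing
simulated Pn/Ps in the empirically typical 0.4–0.5 band), and
stop-creating ones never. Proposals per nucleotide equal the target
synonymous branch length, which makes the realised JC-corrected Ps track
the target directly; paralogue divergence is applied pre-speciation at
(paralogue − orthologue)/2 per copy so tip paralogue Ks lands on the
target after the species branches are added.

Divergence defaults: paralogue Ks 0.65 (the WGD age signature), early
lineage vs siblings 0.05 — the published work gives no orthologue Ks for
that split, so the value is chosen from the magnitude of its orthologue
substitution levels (0.022–0.100) and flagged here rather than asserted —
and 0.02 between siblings. Gene loss defaults to the published per-genome
rates (6.13/13.31/7.89%), applied per locus independently.

Conversion events are implanted *after* all drift by default, so truth
tracts are exact (`drift_after_implant` adds post-event drift for
sensitivity studies). Whole events copy the donor CDS over the acceptor;
partial events copy one tract with length uniform on 20–200 nt. Tracts
whose codon-splitting boundaries would create a chimeric stop codon are
resampled — never truncated or shifted — keeping every ORF valid. Events
in the sibling lineage are pre-split with probability 0.84 (the share of
sibling conversions predating the variety split in the published period
table) and then applied identically, with the same donor copy, in both
siblings; post-split events go to one genome. The `donor_bias` parameter
makes one copy the "privileged" donor with the given probability.

What the simulator does **not** model: introns and intergenic sequence
beyond spacing, indels (so real-data alignment uncertainty is untested by
construction), rate variation among sites and lineages, rearrangements
beyond gene loss, and drift between a pre-split conversion and the
sibling split (pre-split events are implanted at the tips, an
idealisation that makes period-A detection slightly easier than in real
data). Passing recovery tests therefore demonstrates correctness of the
inference machinery under the stated model, not robustness to every
real-data nuisance.

## Problem sizes and determinism

The test suite and acceptance script size their simulations to be
informative at desk scale: parameter recovery uses 500 ancestral genes
(≈ 230 whole and ≈ 240 partial implanted events, ≈ 1000 unconverted
pairs), divergence/loss calibration 2000 genes, the permutation null 100
replicates of 1000 rounds. Every random choice flows from a single seed
(simulation, bootstraps, permutations), and a fixed seed reproduces
byte-identical simulator output and identical summaries.

## Known limitations

- Strict-inequality WCV tests are conservative by design; conversions old
  enough for substantial post-event drift shade into the undetectable.
- PCV boundary placement cannot beat the informative-site spacing
  (~1/0.15 sites at default divergences).
- The NG/JC distance underestimates large divergences slightly (two-fold
  degenerate sites saturate faster than the JC model assumes); the
  simulated paralogue Ks measures ≈ 0.60 against a 0.65 target, within
  the stated ±15% calibration band.
- Donor inference compares only the two within-quartet candidates;
  conversion from a locus outside the quartet is out of scope.
- The ancestral-content estimator is blind to loci lost in all but one
  genome (downward loss-rate bias ≈ 1–2 points at realistic loss rates).
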