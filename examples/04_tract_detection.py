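"""Partial-conversion tract detection on a hand-built quartet.

Site scores s(i) = dO(i) − dP(i) compare the orthologue difference (mean
of the two orthologue pairs) with the paralogue difference at each
ungapped site; a converted tract makes the paralogues locally identical
while the acceptor drifts from its orthologue, producing a run of
positive scores that the maximal-scoring-segment search (Ruzzo–Tompa)
delimits.
"""

import numpy as np

import quartetconv as qc
from quartetconv import convdetect

rng = np.random.default_rng(3)
ds = qc.simulate(qc.SimConfig(n_genes=10, seed=3, loss_rates=(0, 0, 0)))
idx = ds.genome_index()
fam = ds.families[0]
o1, o2 = fam.genes["G1"]
s1, s2 = fam.genes["X1"]
cds = {g: idx[g].cds for g in (o1, o2, s1, s2)}

# implant a 60-nt conversion tract: positions 91-150 of O2 overwritten by O1
start, end = 91, 150
cds[o2] = cds[o2][: start - 1] + cds[o1][start - 1 : end] + cds[o2][end:]
print(f"implanted tract {start}-{end} nt (donor O1 -> acceptor O2)")

aln = qc.align_quartet((o1, o2, s1, s2), tuple(cds[g] for g in (o1, o2, s1, s2)))
ctx = convdetect.QuartetContext.build(
    qc.Quartet(genome_a="G1", genome_b="X1", o1=o1, o2=o2, s1=s1, s2=s2), aln
)
scores = convdetect.build_site_scores(ctx, side="A")
tracts = convdetect.detect_pcv(scores.scores, rng=rng)
for t_start, t_end, total, support in tracts:
    cds_pos = scores.cds_pos[o2]
    print(f"detected tract: CDS {cds_pos[t_start]}-{cds_pos[t_end - 1]} nt, "
          f"score {total:.1f}, bootstrap support {support:.2f}")
    # donor inference restricted to the tract's codon columns: only there
    # does the acceptor's orthologue identity drop
    mask = np.zeros(aln.length // 3, dtype=bool)
    mask[np.unique((scores.aln_pos[t_start:t_end] - 1) // 3)] = True
    donor = convdetect.infer_donor(ctx, "A", site_mask=mask)
    print(f"inferred donor: {donor} (truth: {o1})")
print()
print("the detected boundaries track the outermost sites where the orthologue")
print("pair differs inside the homogenized region, so they sit within a few")
print("nucleotides of the implanted tract.")
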