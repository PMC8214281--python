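"""Align one homologous gene quartet and compute its pairwise distances.

A quartet joins paralogues (O1, O2) in one genome with their orthologues
(S1, S2) in another.  The Nei–Gojobori proportions of synonymous (pS)
and nonsynonymous (pN) differences per site, their Jukes–Cantor
corrections Ps/Pn, and amino-acid identity are the raw material of every
conversion test.
"""

import quartetconv as qc

ds = qc.simulate(qc.SimConfig(n_genes=10, seed=7, loss_rates=(0, 0, 0)))
idx = ds.genome_index()
fam = ds.families[0]
o1, o2 = fam.genes["G1"]
s1, s2 = fam.genes["X1"]

aln = qc.align_quartet((o1, o2, s1, s2),
                       tuple(idx[g].cds for g in (o1, o2, s1, s2)))
keep, reason = qc.filter_quartet(aln)
print(f"quartet of {len(aln.nt[0])} aligned nt, passes divergence filters: {keep}")

pairs = [("O1-O2 (paralogues)", 0, 1), ("O1-S1 (orthologues)", 0, 2),
         ("O2-S2 (orthologues)", 1, 3)]
print(f"{'pair':24s} {'pN':>7s} {'pS':>7s} {'Pn':>7s} {'Ps':>7s} {'aa id':>7s}")
for name, i, j in pairs:
    d = qc.pair_distances(aln.nt[i], aln.nt[j])
    print(f"{name:24s} {d.pn:7.4f} {d.ps:7.4f} {d.Pn:7.4f} {d.Ps:7.4f} "
          f"{d.aa_identity:7.4f}")
print()
print("without conversion the paralogue Ps (~0.65, the WGD age) far exceeds")
print("the orthologue Ps (~0.05, the speciation age); Pn/Ps ~ 0.4 reflects")
print("purifying selection on amino-acid changes.")
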