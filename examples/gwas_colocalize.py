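"""Mixed-model GWAS and co-localization with swept windows.

Simulates a panel with one selected QTL for ear length, runs the P+K
scan, builds +-150 kb associated regions and intersects them with the
sweep scan's windows to produce candidate regions with resident genes.
"""

import sweepmap as sm

locus = (3, 1_050_000)
cfg = sm.SimConfig(
    n_a=40, n_b=80, n_snps=1500, n_chrom=10, chrom_len=2_000_000,
    swept_loci=[(*locus, "A")], qtl=[(*locus, 1.0, "EL")],
    sweep_init_freq=0.05, h2_target=0.6, seed=3,
)
g = sm.simulate_populations(cfg)
phen = sm.simulate_phenotypes(g, cfg)
genes = sm.simulate_genes(g, 150, seed=3)

kin = sm.compute_kinship(g)
res = sm.fit_mlm(g, phen, kin, trait="EL", environment="E1", n_pcs=3)
sig = sm.significant_snps(res, alpha=1e-3)
print(f"significant SNPs at p <= 1e-3: {len(sig)} of {len(res)} tested")

assoc = sm.build_regions(sig, genes, flank=150_000)
stats = sm.window_stats(g, size=100_000)
_, sweeps = sm.call_sweeps(stats, tail=0.10)
cands = sm.overlap_regions(sweeps, assoc)
table = sm.candidate_gene_table(cands, genes)
print(f"associated regions: {len(assoc)}; candidates overlapping sweeps: {len(table)}")
print(table[["chrom", "assoc_start", "assoc_end", "trait", "n_genes", "min_p"]])
# A candidate region is an associated region that overlaps a swept window;
# its gene list is read from the associated span so flanking genes are kept.
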