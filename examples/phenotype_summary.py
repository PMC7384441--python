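"""Trait summaries, heritability and group contrasts on simulated ear traits."""

import sweepmap as sm

cfg = sm.SimConfig(
    n_a=26, n_b=95, n_snps=800, n_chrom=5, chrom_len=2_000_000,
    qtl=[(1, 1_000_000, 1.2, "EL"), (1, 1_000_000, 1.1, "FL"),
         (2, 1_000_000, 0.8, "EL"), (2, 1_000_000, 0.9, "FL")],
    h2_target=0.70, seed=9,
)
g = sm.simulate_populations(cfg)
phen = sm.simulate_phenotypes(g, cfg)

print(sm.summarize(phen).round(3))
for trait in ("EL", "FL"):
    print(f"{trait}: H2 = {sm.trait_h2(phen, trait):.1f}%")

groups = dict(zip(g.samples, g.group))
print(sm.group_contrast(phen, groups).round(4))
print(sm.trait_correlations(phen).round(3))
# SV% is the coefficient of variation; H2 is broad-sense heritability on an
# entry-mean basis over the two environments; stars mark Welch-test group
# differences (*, **, *** at p<0.05, 0.01, 0.001).
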