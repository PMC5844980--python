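"""Replicate consistency, alpha diversity and the depth-adjusted group test.

Simulates the full cohort (101 subjects in groups O/V/VG, two technical
replicates each) at the OTU-table level, checks that replicate pairs are
mutual nearest neighbours under Bray-Curtis and keeps the deeper
replicate, then computes alpha diversity and tests the planted richness
difference (V > O) with sequencing depth as a covariate and Tukey-Kramer
pairwise comparisons.
"""

import numpy as np

import ampliem as am

cfg = am.SimulationConfig(seed=7)
study = am.simulate_study(cfg)
counts = am.simulate_counts(study.references, study.truth, cfg, per_replicate=True)

table = am.OtuTable(counts)
pairs = {s: (f"{s}_1", f"{s}_2") for s in study.metadata.index}
table, report = am.select_replicates(table, pairs)
print(f"replicate pairs consistent: {int(report['consistent'].sum())}/{len(report)}")

alpha = am.alpha_table(table.counts)
groups = study.metadata["group"]
print("\nmean alpha diversity by diet group:")
print(alpha.join(groups).groupby("group")[["richness", "chao1", "shannon"]].mean().round(2))

depth = np.log10(table.counts.sum(axis=0))
res = am.anova_tukey(alpha["richness"], groups.loc[alpha.index], covariate=depth)
print(f"\ndepth-adjusted ANOVA on richness: F = {res.f:.2f}, p = {res.p:.4g}")
print("Tukey-Kramer pairwise comparisons:")
print(res.pairwise.round(4))
# the V-vs-O estimate reflects the planted richness offset; the adjusted
# p-value shows the effect survives controlling for library size.
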