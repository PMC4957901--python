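"""Classify miRNA expression dynamics into the 27 transition patterns.

Per-time-point log2 fold-changes become signed pseudo fold-changes
(phiFC), differences between consecutive time points become transitions,
and a mu +/- 0.4 sigma band discretizes each transition into '+', '0' or
'-'.  The resulting 3-character pattern sorts every miRNA into one of
3^3 = 27 classes, grouped into monotone trends.
"""

from mirprog import SimulationConfig, build_profiles, simulate_counts
from mirprog.dynamics import pattern_summary
from mirprog.quantify import differential_expression_all

config = SimulationConfig(seed=1)
mirna_counts, _, truth = simulate_counts(config)

de = differential_expression_all(mirna_counts)
logfc = de.pivot(index="feature", columns="timepoint", values="logFC")
logfc = logfc[["w6", "w8", "w10", "w12"]]
profiles = build_profiles(logfc)

print("trend group sizes (of", len(profiles), "miRNAs):")
print(profiles["trend_group"].value_counts().to_string())

promoters = profiles.loc[sorted(truth.promoter_ids)]
print("\nplanted promoter patterns (expected: rising, so only '+'/'0'):")
print(promoters["pattern"].value_counts().to_string())

print("\nmost common patterns with median phiFC trajectory:")
summary = pattern_summary(profiles).sort_values("n_features", ascending=False)
print(summary.head(5).to_string(index=False, float_format="%.2f"))
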