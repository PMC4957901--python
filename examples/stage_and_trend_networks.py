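"""Infer stage-specific and trend-matched miRNA-mRNA networks.

Candidate target predictions are screened by Spearman correlation across
all 24 samples (miRNAs repress, so only negative correlations survive),
then admitted per stage (both ends differentially expressed with
opposite signs) or by exact opposite transition patterns.
"""

from mirprog import (
    SimulationConfig, degree_stats, filter_by_correlation,
    signed_concordance, simulate_annotations, simulate_counts,
    simulate_interaction_db, stage_network, trend_network, build_profiles,
)
from mirprog.quantify import differential_expression_all, quantile_normalize, rpkm

config = SimulationConfig(seed=1)
mirna_counts, mrna_counts, truth = simulate_counts(config)
candidates = simulate_interaction_db(truth)

filtered = filter_by_correlation(
    candidates, quantile_normalize(mirna_counts.values), rpkm(mrna_counts)
)
print(f"correlation filter: {len(filtered)} of {len(candidates)} candidate "
      "pairs keep a strictly negative Spearman rho")

de_mi = differential_expression_all(mirna_counts)
de_mr = differential_expression_all(mrna_counts)
true = truth.true_interactions
for tp in ("w6", "w8", "w10", "w12"):
    edges = stage_network(filtered, de_mi, de_mr, tp)
    stats = degree_stats(edges)
    pairs = set(zip(edges["mirna"], edges["gene"]))
    precision = len(pairs & true) / len(pairs) if pairs else float("nan")
    print(f"stage {tp}: {stats['n_edges']} edges, "
          f"{stats['mean_targets_per_mirna']:.1f} targets/miRNA, "
          f"precision vs planted couplings {precision:.2f}")

profiles_mi = build_profiles(de_mi.pivot(index="feature", columns="timepoint",
                                         values="logFC")[["w6", "w8", "w10", "w12"]])
profiles_mr = build_profiles(de_mr.pivot(index="feature", columns="timepoint",
                                         values="logFC")[["w6", "w8", "w10", "w12"]])
trend = trend_network(filtered, profiles_mi, profiles_mr)
print(f"trend network: {len(trend)} edges from exact opposite-pattern matches")

# direction concordance between two stages, the statistic used to compare
# independent call sets (100 = every shared miRNA keeps its direction)
calls = {
    tp: dict(de_mi[(de_mi.timepoint == tp) & (de_mi.direction != "ns")]
             [["feature", "direction"]].to_numpy())
    for tp in ("w10", "w12")
}
pct = signed_concordance(calls["w10"], calls["w12"])
print(f"signed concordance of DE calls between w10 and w12: {pct:.2f}%")
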