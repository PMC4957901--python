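"""Build a synthetic tumor-progression dataset with planted regulation.

The generator emulates a four-time-point tumor/control study (weeks 6-12,
3 replicates per arm = 24 samples): promoter miRNAs rise in tumors,
suppressor miRNAs fall, their target genes move the opposite way, and a
few gene-term modules are planted in the annotations.
"""

from mirprog import SimulationConfig, simulate_annotations, simulate_counts, simulate_interaction_db

config = SimulationConfig(seed=1)
mirna_counts, mrna_counts, truth = simulate_counts(config)
annotations = simulate_annotations(truth, config)
interactions = simulate_interaction_db(truth)

print(f"miRNA matrix: {mirna_counts.values.shape[0]} features x "
      f"{mirna_counts.values.shape[1]} samples")
print(f"mRNA matrix:  {mrna_counts.values.shape[0]} features x "
      f"{mrna_counts.values.shape[1]} samples")
print(f"planted promoters: {len(truth.promoter_ids)}, "
      f"suppressors: {len(truth.suppressor_ids)}")
print(f"true miRNA->gene couplings: {len(truth.true_interactions)}, "
      f"independent decoys: {len(truth.decoy_interactions)}")
print(f"candidate interaction table: {len(interactions)} rows "
      "(what a sequence-based target database would supply)")
for i, (genes, terms, regulators) in enumerate(truth.planted_modules, 1):
    print(f"module {i}: {len(genes)} genes x {len(terms)} terms, "
          f"driven by {len(regulators)} miRNAs")
print(f"annotation sets: {len(annotations)} terms "
      "(planted modules plus random background annotations)")
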