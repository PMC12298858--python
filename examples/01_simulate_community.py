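"""Generate a synthetic barcode community and look at its structure.

Builds the default community (12 species on a Yule tree, 8 surveys,
geometric abundances, 20% mislabeled references) and prints what was
sampled. Run: python examples/01_simulate_community.py
"""

from barcodegap import CommunityConfig, generate_community

config = CommunityConfig(seed=42)
dataset, incidence, truth, tree = generate_community(config)

counts = dataset.counts_by_source()
print(f"records: {len(dataset)} ({counts['field']} field specimens, "
      f"{counts['reference']} reference accessions)")
print(f"true species: {truth.n_species}; observed in surveys: {incidence.s_obs}")
print(f"incidence frequencies Q_k: {incidence.q_counts}")
print(f"planted mislabeled references: {sorted(truth.mislabeled)}")

# Q_1 counts species seen in exactly one survey — the singleton-heavy
# signature of incomplete sampling that drives the Chao2 estimate upward.
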