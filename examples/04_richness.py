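"""Estimate how much diversity the surveys missed.

Builds the OTU-by-survey incidence table and computes the Chao2 asymptote
with a rarefaction/extrapolation curve and bootstrap confidence bands.
Run: python examples/04_richness.py
"""

from barcodegap import CommunityConfig, generate_community
from barcodegap.richness import bootstrap_curve, chao2

dataset, incidence, truth, _ = generate_community(CommunityConfig(seed=42))

print(f"T = {incidence.T} surveys, S_obs = {incidence.s_obs} species observed "
      f"(true richness {truth.n_species})")
print(f"singletons Q1 = {incidence.q(1)}, doubletons Q2 = {incidence.q(2)}")
print(f"Chao2 asymptote: {chao2(incidence):.2f}")

curve = bootstrap_curve(incidence, n_boot=1000, seed=42, t_max=100)
lo, hi = curve.asymptote_ci
print(f"95% bootstrap CI for the asymptote: ({lo:.2f}, {hi:.2f})")
for size in (2, incidence.T, 20, 100):
    row = curve.curve[curve.curve["size"] == size]
    if len(row):
        r = row.iloc[0]
        print(f"  S({size:>3}) = {r.estimate:5.2f}  [{r.lower:5.2f}, {r.upper:5.2f}]  ({r.phase})")

# The curve rises through the observed effort (interpolated), continues
# along the expected-discovery trajectory (extrapolated), and flattens
# toward the Chao2 asymptote — the estimated total richness, singletons
# and doubletons doing the inferential work.
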