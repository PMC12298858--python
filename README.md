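# barcodegap

Empirical barcode-gap OTU delineation for specimen barcode surveys.

Biodiversity surveys that sequence a DNA barcode (such as the fungal ITS
region) from field specimens face three chained questions: *what identity
threshold separates species?* — *how do the specimens cluster into
species-proxy units (OTUs) at that threshold, and which of them can be
named from reference databases?* — *how much of the community did the
surveys actually recover?* `barcodegap` implements that workflow as a
reusable, deterministic library for mycologists and barcoding researchers,
together with a synthetic community generator that makes every stage
testable without touching external databases.

## What it computes

**Threshold derivation.** All-vs-all pairwise identities are computed with
a semi-global aligner (terminal gaps free; match +1, mismatch −2, gap
5 + 2k; identity = matches over aligned columns, coverage = covered share
of the shorter sequence). Pairs with alignment coverage ≤ 70% are
discarded, the pooled identity histogram is scanned for the *barcode gap*
— the longest run of near-empty bins between the within- and
between-species modes — and the gap's upper edge becomes the clustering
threshold (falling back to the literature-standard 97% when no gap is
detectable). The association between identity and evolutionary relatedness
is reported as the r² of identity against cophenetic distance on a
supplied phylogeny or a neighbor-joining stand-in.

**OTU clustering.** Sequences become nodes of a similarity graph (edges:
identity ≥ threshold and aligned fraction ≥ 0.8) partitioned by an
in-package Leiden implementation with the constant Potts model
(resolution 1.0 on the percent-identity scale, beta 0.01, 10 iterations,
seeded). OTUs inherit species names from reference members; one reference
name scattered across several OTUs is flagged as the signature of database
mis-annotation.

**Richness.** OTU incidence across survey units drives the Chao2
asymptotic richness estimate

    S_chao2 = S_obs + ((T-1)/T) * Q1^2 / (2 * Q2)

(bias-corrected when Q2 = 0), exact sample-based rarefaction
S(t) = S_obs − Σ_k Q_k·C(T−k, t)/C(T, t), standard incidence-based
extrapolation toward the asymptote, and 95% confidence bands from a
bootstrap over sampling units.

See `docs/methods.md` for the full model description, parameter defaults
and limitations.

## Worked example

```python
from barcodegap import CommunityConfig, generate_community
from barcodegap.pairwise import all_vs_all
from barcodegap.gap import detect_gap, choose_threshold
from barcodegap.cluster import build_graph, leiden_partition

dataset, incidence, truth, tree = generate_community(CommunityConfig(seed=42))
hits = [h for h in all_vs_all(dataset, coverage_floor=0.0)
        if h.aligned_fraction > 0.7]
report = detect_gap([h.identity for h in hits])
threshold = choose_threshold(report)
graph = build_graph(hits, threshold, af_floor=0.8, all_ids=dataset.ids)
partition = leiden_partition(graph, seed=42)
print(report.gap_interval, threshold, partition.n_otus)
```

prints `(89.5, 97.5) 97.5 11`: the 53 generated sequences (33 field
specimens, 20 reference accessions from 12 true species) show an identity
gap between 89.5% and 97.5%, the derived 97.5% threshold yields 11 OTUs,
and (as `examples/03_otu_clustering.py` goes on to show) 9 of the 10 field
OTUs can be matched to reference names while all four planted reference
label swaps surface as names spanning multiple OTUs. The richness stage
(`examples/04_richness.py`) reports S_obs = 10 of 12 true species after 8
surveys, a Chao2 asymptote of 10.15 with 95% CI (8.00, 14.25) — the CI
covering the truth that the point estimate, as a lower bound, understates.

The same workflow is scriptable from the shell:

```bash
barcodegap simulate --n-species 12 --seed 42 --outdir community/
barcodegap run-all \
    --field-fasta community/field.fasta \
    --field-annotations community/field_annotations.tsv \
    --reference-fasta community/reference.fasta \
    --reference-annotations community/reference_annotations.tsv \
    --outdir runs/demo
```

which writes per-stage TSV/JSON artifacts, a manifest with config hash and
checksums, and a human-readable report; reruns with the same inputs and
seed are byte-identical. The `examples/` directory holds one short
narrative script per capability.

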