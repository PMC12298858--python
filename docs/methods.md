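# Methods

This note records the models, estimators, numerical conventions and design
choices behind `barcodegap`, at the level of detail a maintainer or reviewer
needs to interpret results and limitations.

## The analysis in one paragraph

Full-length barcode sequences (fungal ITS in the motivating use case) from
field specimens and named reference accessions are compared all-vs-all; the
pooled pairwise-identity distribution is used to locate the *barcode gap* —
the empty interval between the within-species and between-species identity
modes — whose upper edge becomes the identity threshold for clustering.
Sequences are clustered into OTUs by Leiden community detection on the
similarity graph (edges where identity and aligned fraction clear the
thresholds), OTUs inherit species names from their reference members, and
survey-level incidence of the OTUs feeds nonparametric richness estimation
(Chao2) with sample-based rarefaction, extrapolation and bootstrap
confidence bands.

## Pairwise identity and aligned fraction

Identity is defined on an optimal **semi-global alignment** (terminal gaps
free) under match +1, mismatch −2, and affine gap cost 5 + 2k for a k-column
gap run. The aligner is Biopython's `PairwiseAligner` with a custom
substitution matrix in which IUPAC ambiguity codes never score or count as
matches (conservative identity). Two conventions pin the statistics down:

* **identity** = 100 × matches / aligned columns, counted between the first
  and last aligned pair (terminal overhangs excluded);
* **aligned fraction** = covered span of the *shorter* sequence / its
  length, which makes every self-comparison exactly (100, 1.0).

`all_vs_all` verifies, per equal-length pair, whether the ungapped
alignment attains the optimal score (one O(L²) score evaluation, no
traceback); only then is the ungapped identity used, otherwise the full
traceback runs. The shortcut is exact by construction — it never reports a
value a full DP would not — and matters because the all-vs-all stage
dominates runtime. Symmetry under argument order is enforced by aligning
each pair in canonical (lexicographic) order, since co-optimal alignments
could otherwise let the traceback pick different representatives for (a, b)
and (b, a).

Pairs with aligned fraction at or below the coverage floor (default 0.7)
are excluded from the gap analysis and clustering: for unrelated sequences
the optimal semi-global alignment under this scoring collapses to a short
high-identity core with near-zero coverage, so the coverage floor is what
removes spurious partial matches.

## Barcode-gap detection

The identity histogram spans [0, 100] with 0.5-point bins. Within a search
window (default 85–100), bins whose counts are at or below the
`emptiness_quantile` (default 0.05) quantile of in-window counts qualify as
near-empty; the gap is the longest maximal run of qualifying bins, with
ties broken toward higher identity, and the clustering threshold is the
run's **upper edge** (the species side). Two guards make the historically
eyeballed judgment into a decision rule:

* a run must span at least `min_gap_bins` (default 2) bins — some bin
  always attains the in-window minimum, so a single sparse bin is noise,
  not bimodality;
* fewer than ~100 identity values triggers a warning, and an undetectable
  gap raises an error that advises a manual threshold rather than silently
  guessing. `choose_threshold` then falls back to 97%, the
  literature-standard criterion for full-length ITS.

The identity–relatedness association is summarised by ordinary least
squares of identity on cophenetic (patristic) distance: r² is the squared
Pearson correlation and the p-value the usual t-test with n − 2 degrees of
freedom. Nothing downstream consumes the fit; r² is reported because it is
the field's standard check that the barcode tracks phylogeny. r² is
invariant to affine rescaling of distances, which is why a neighbor-joining
stand-in tree (built from p-distances d = 1 − identity/100, with optional
Jukes–Cantor correction) is an acceptable substitute when no externally
inferred phylogeny is supplied; absolute distance scales differ from a
likelihood tree, so r² values are comparable only within one tree choice.

The NJ implementation is the standard Q-matrix agglomeration with
lexicographic tie-breaking on leaf labels, making it deterministic and
input-order invariant; on additive matrices it reproduces the input
distances exactly (validated to 1e-9 in tests).

## OTU clustering

Nodes are sequences; an edge joins every pair with identity ≥ threshold and
aligned fraction ≥ 0.8 (both inclusive; a strict-inequality mode exists
because ">97%" and "minimum 97%" both circulate as conventions). Stored
edge weights are identity/100.

Partitioning uses an in-package implementation of the **Leiden** algorithm
(local moving, refinement, aggregation) with the **constant Potts model**
(CPM) quality
H(P) = Σ_c [w_in(c) − γ·s_c(s_c−1)/2]. The refinement phase merges a
still-singleton vertex into well-connected sub-communities with probability
∝ exp(ΔH/θ); θ (the `beta` parameter, default 0.01) controls exploration
and the seed makes everything deterministic. Defaults: resolution 1.0,
beta 0.01, 10 move–refine–aggregate iterations.

The CPM resolution is interpreted on the **percent-identity scale** (edge
weights are multiplied by 100 inside the quality): similarity-clustering
tools in this field consume BLAST-style percent identities, and on the
fractional scale a resolution of 1.0 would exceed every possible edge
weight, making the all-singletons partition optimal — no threshold-passing
clique could survive. On the percent scale, resolution 1.0 never splits a
clique of ≥97%-identity sequences, and the partition coincides with the
connected components whenever the gap is clean; Leiden's contribution is
confined to ambiguous bridged clusters, where determinism under the seed is
the contract. The implementation is cross-checked in tests against
`leidenalg` (identical CPM quality and ARI = 1 on planted-partition
graphs); the library is used only as a test oracle, never in the pipeline.

OTU labels are canonicalised to the lexicographically smallest member id,
so partitions are stable under any input reordering.

## Taxonomy and mis-annotation screening

An OTU containing reference members with exactly one distinct species name
(after trimming, case-folding and whitespace collapsing) is *named*; with
two or more names it is a *conflict*; with none it is *unnamed*. The
matched fraction over field OTUs counts named-or-conflict by default
(assignability), with a strict mode counting only unambiguous names.
Synonym resolution is out of scope. The mis-annotation scan counts distinct
OTUs per reference name and flags names spanning more than one OTU — the
signature of a mislabeled accession or a diverging species complex; the
scan reports the signature, not a verdict, since distinguishing the two
requires phylogenetic context.

## Incidence-based richness

Sampling units are surveys; the incidence table is the OTU × unit presence
matrix and Q_k counts OTUs detected in exactly k of the T units.

* **Chao2** asymptote: S_obs + ((T−1)/T)·Q1²/(2Q2), with the bias-corrected
  form S_obs + ((T−1)/T)·Q1(Q1−1)/2 when Q2 = 0. The convention (classic
  (T−1)/T small-sample correction) is pinned here and carried in the curve
  metadata, since "Chao2" alone underdetermines it.
* **Rarefaction**: S(t) = S_obs − Σ_k Q_k·C(T−k, t)/C(T, t), the exact
  expectation over unit subsets (tests verify equality with exhaustive
  enumeration for T ≤ 8). Binomial ratios are evaluated exactly via
  `math.comb` in the public function and in log-gamma space in the
  vectorised bootstrap inner loop.
* **Extrapolation**: with Q̂0 = Chao2 − S_obs,
  S(T+t*) = S_obs + Q̂0·[1 − (1 − Q1/(Q1 + T·Q̂0))^t*], monotone in t* and
  approaching the Chao2 asymptote; the curve extends to 1500 units by
  default.
* **Uncertainty**: a distribution-free bootstrap resamples the T sampling
  units (columns) with replacement — not the OTUs — 1000 times; 95% bands
  are the 2.5/97.5 percentiles per curve size, widened where necessary to
  contain the observed-table point estimate (a raw percentile band need
  not). Curves are always emitted; when the asymptote's CI is wider than
  the estimate itself a warning flag marks the singleton-dominated regime
  in which accumulation results should not be over-read, rather than
  suppressing the output.

## The synthetic community generator

The generator is first-class, tested code: it defines the conditions under
which every statistical guarantee of the pipeline is exercised.

* **Species tree**: Yule (pure-birth) process conditioned on n species,
  implemented directly (waiting times Exp(k·λ), uniform lineage choice, one
  further Exp(n·λ) interval to the present so terminal branches are
  almost surely positive).
* **Divergence band**: node heights are remapped piecewise-linearly so the
  shallowest species pair carries an expected site-difference of
  `interspecific_floor × divergence_margin` and the deepest
  `interspecific_depth_cap` (defaults 0.08 × 1.5 and 0.30). The margin
  exists because a pair rescaled to an expected divergence exactly at the
  floor would fall below it in ~half of realisations (binomial symmetry);
  1.5× pushes that probability below 1% at L = 650. The cap reflects real
  congeneric barcode data, where between-species distances rarely exceed
  ~25–30%; it also keeps the substitution process far from Jukes–Cantor
  saturation.
* **Sequences**: Jukes–Cantor substitution along branches (the exact JC
  transition per branch, so expected leaf-pair differences equal the JC
  expectation of the path length); no indels by default, keeping identity
  arithmetic analytically checkable while the semi-global machinery is
  still exercised. Within-species variation is star-shaped: each specimen
  mutates from its species representative at a rate drawn uniformly below
  `intraspecific_ceiling`/2, so *pairwise* within-species divergence stays
  below the ceiling (two specimens r away from the representative are ~2r
  apart).
* **Surveys**: species abundance is geometric (default p = 0.5; a
  log-series alternative is exposed because the true abundance law of such
  communities is not known); detection per survey is
  1 − exp(−detect_scale·abundance), each detection yields one specimen.
  Defaults (12 species, 8 surveys, detect_scale 0.25) give the
  singleton-heavy, incomplete-but-not-hopeless sampling regime of real
  fruiting-body surveys at a scale the repeated-seed validation studies can
  afford; the statistical structure, not the absolute size, is what the
  recovery guarantees depend on.
* **References**: 80% of species carry named reference accessions, two per
  species. Mislabeling swaps names pairwise between accessions of distinct
  species at a 20% rate, matching the mis-annotation load reported for
  public fungal sequence databases. Two accessions per species matter: a
  swap is only *detectable* by the multi-OTU signature if the true name
  also remains on a correctly labelled accession.
* **Determinism**: one seed drives spawned, stage-separated RNG streams;
  identical config + seed reproduces every output file byte for byte.

What the generator does **not** emulate: indel variation (behind a flag,
off by default), rDNA intragenomic polymorphism, chimeras, partial-length
sequences (so the coverage filter passes nearly all synthetic pairs — its
rejection behaviour is exercised separately with unrelated random
sequences), non-uniform base composition, and any geographic or temporal
survey structure. Passing recovery tests on this generator therefore shows
the pipeline implements its stated statistics correctly under clean
bimodality; it does not show that real communities have a clean gap.

## Numerical and degenerate-input conventions

* Gap detection with < 100 values warns; no qualifying run raises a
  dedicated error. Histogram bins close on [0, 100] with the final bin
  including 100 exactly.
* Regression requires ≥ 3 usable pairs and nonzero variance on both axes.
* NJ requires a symmetric matrix with n ≥ 3; negative branch lengths on
  non-additive input are kept (standard NJ behaviour).
* Chao2 requires T ≥ 2; extrapolation with Q1 = 0 is flat at S_obs.
* Incidence rows never detected are dropped on construction.
* Leiden move gains use a 1e-12 tie tolerance and prefer the current
  community on ties; labels compact deterministically.
* The length sanity filter (default 400–1200 nt, the plausible span of a
  full-length ITS amplicon) warns rather than errors when everything is
  rejected.

## Validation scale

The repeated-seed studies run at the generator defaults: 100 seeds for
threshold and partition recovery (thresholds must land in the planted
window [100(1−floor), 100(1−ceiling)] and ARI must equal 1 in ≥ 95% of
seeds), 50 seeds for mislabel recovery (≥ 90% of planted swaps flagged) and
for Chao2 CI coverage on half-sampled surveys (≥ 90% coverage of the true
species count). The aligner is checked against an exhaustive DP oracle
(identity within 1 point on 200 ancestor-derived pairs of length 50–80;
exact score agreement on indel-bearing pairs, where co-optimal alignments
make single-alignment identity comparisons ill-posed), rarefaction against
exhaustive subset enumeration (T ≤ 8), and NJ against exact additive
recovery (< 1e-9).
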