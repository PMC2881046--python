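# Methods

## The model

A protein is represented by a 376-component vector: 132
biochemical/physicochemical descriptors (CTD blocks of six residue
groupings plus the 20 amino-acid composition fractions), its length, 22
binary subcellular-location flags, 220 KEGG pathway enrichment scores,
and the count of protein complexes it joins.  Classification of the four
half-life classes (short / medium / long / extra-long, from the protein
stability index) is hierarchical: a binary short-medium vs
long-extra-long stage, then a binary refinement within the branch.  Each
binary stage is a 1-nearest-neighbor classifier under the cosine-derived
distance d(**a**, **b**) = 1 − **a**·**b**/(‖**a**‖‖**b**‖), with its own
feature subset chosen by mRMR ranking followed by incremental feature
selection (IFS) under jackknife (leave-one-out) cross-validation.

## CTD descriptor conventions

* **Ordering.**  Each grouping's block is C, then T, then D.  Category
  order is fixed per grouping (hydrophobicity: P, N, H; the others: H, E,
  C); transition pairs follow (c₁c₂, c₁c₃, c₂c₃); distribution is
  category-major, quantile-minor.
* **Distribution quantile rule.**  The q-quantile occurrence of a
  category with n_c occurrences is occurrence number ⌈q·n_c⌉, clamped to
  ≥ 1, at 1-based sequence position, divided by the sequence length.
  This is the unique simple rule consistent with every entry of the
  worked 50-mer example (e.g. the 25% point of 10 occurrences is the 3rd
  one).
* **Degenerate inputs.**  A category with no occurrences contributes
  (0,0,0,0,0); a coded string with no adjacent changes has an all-zero
  transition block (homopolymers are legal inputs).  Both conventions
  keep the vector defined for every sequence without sentinel values.
* **Two-category layout.**  The solvent-accessibility grouping stores 7
  components — composition of *hidden*, the single hidden↔exposed
  transition fraction, and the distribution 5-tuple of *hidden* — since
  the exposed-category composition is determined by the hidden one.
* **Annotation tracks.**  Secondary structure (H/E/C) and accessibility
  (hidden/exposed) are *inputs*, aligned 1:1 with the sequence.  An
  optional deterministic stand-in (`propensity_tracks`) fills missing
  tracks from a per-residue most-likely-state table; it exists solely so
  synthetic pipelines are self-contained and is not a structure
  predictor.
* **Nonstandard residues** (B, Z, X, U, …) are rejected by default; an
  explicit sanitize mode drops them (and the aligned track positions)
  with a logged warning.
* All stored components are fractions in [0, 1]; percent rendering is
  presentation-only.

## Feature-space conventions

* **Length bounds** for benchmark assembly are inclusive: sequences of
  50–2700 residues are retained.
* **Enrichment score.**  −log₁₀ P(X ≥ k) under the hypergeometric null
  (drawing |neighborhood| genes from the universe with |pathway|
  successes), where the neighborhood is the protein plus its interaction
  partners and k is the observed overlap.  k = 0 gives score 0; an
  isolated protein (empty neighborhood) scores 0 on all 220 pathways so
  it remains encodable.  No multiple-testing correction is applied across
  pathways.  The tail probability comes from `scipy.stats.hypergeom.sf`
  and is floored at the smallest positive double before the log.
* **Pathway list.**  The 220 pathways are a configuration-supplied
  ordered list; any 220-pathway universe (including the synthetic one)
  is acceptable.
* **Standardization** uses population (ddof = 0) statistics, which makes
  the transform exactly idempotent; constant columns map to zero rather
  than erroring, because binary location flags can be constant in small
  training sets.  Parameters are always fitted on training rows only and
  applied to held-out samples.

## mRMR

Features are discretized at μ ± 1σ per column into three states
(discretization is applied after standardization, so thresholds sit at
≈ ±1).  Mutual information is the plug-in estimator over empirical
frequencies with 0·log 0 = 0, in bits; the log base cannot affect the
ranking (verified by a base-invariance test).  The ranking is the greedy
"difference" (MID) variant: redundancy is the *mean* MI with the
already-selected set, and the first round reduces to pure relevance
(redundancy of an empty set is taken as 0).  Ties at any round break
toward the smallest feature index, making the output deterministic.  The
pure-relevance (MaxRel) ordering is emitted for inspection but never
drives selection.

## Nearest neighbor, jackknife, IFS

* **Tie-breaking** at equal distance goes to the smallest training-row
  index.
* **Zero-norm vectors** (possible after standardizing constant features)
  have undefined direction; their distance is defined as the maximum, 2,
  with a logged warning.
* **Standardization during jackknifing.**  The default (`mode="refit"`)
  refits μ, σ on each leave-one-out fold, so nothing about the held-out
  sample leaks into the transform.  `mode="paper"` fits once globally and
  reuses the transform across folds — the classical protocol for this
  predictor, retained for comparability; its mild optimism (and the
  larger selection bias of ranking features once on the full set before
  IFS) is a known caveat of that protocol.  A one-row training fold (only
  possible at n = 2) transforms to the zero vector under the
  constant-column convention.
* **IFS** evaluates the nested prefixes S₁ ⊂ … ⊂ S_m of the mRMR order
  and selects the prefix at the accuracy peak, resolving plateaus to the
  smallest size (parsimony).  In global-standardization mode the curve is
  computed via incrementally updated Gram matrices (adding a feature adds
  a rank-one term), costing O(m·n²) overall; a test pins this fast path
  to per-size jackknife evaluation.  An optional `stride` evaluates every
  k-th size and then refines exactly around the provisional peak.
* Each of the three stage classifiers gets its own ranking and IFS run on
  its own sub-dataset; the three optimal subset sizes are dataset-specific
  outcomes, not constants.

## Synthetic benchmark generator

The generator emulates the *structure* of a labeled stability benchmark —
sequences of 50–2700 residues with annotation tracks, PSI values, location
flags, a 2000-gene universe with 220 pathways, neighbor sets and complex
counts — with class signal planted where the feature space can see it:

* per-class residue multinomials whose hydrophobic-group probability
  shifts linearly across classes by ±`hydrophobic_shift` (default 0.10, a
  moderate, clearly recoverable composition effect);
* annotation tracks from first-order Markov chains with stay-probability
  0.8 (mean run length 5, mimicking secondary-structure segments);
* neighbor sets drawing a `kegg_effect` fraction (default 0.5) of their
  ~21 members from the class's signature pathway, separating enrichment
  scores by class;
* location-flag probabilities tilted by ±`location_effect` (default 0.20)
  on four flags; complex counts Poisson with mean 1 + class·`complex_effect`
  (default slope 1); PSI drawn uniformly inside each class's defining bin
  so labels and PSI agree by construction;
* class proportions defaulting to the benchmark mix 223 : 446 : 706 : 496,
  apportioned to any n by largest remainder; lengths log-uniform in
  [50, 2700] so most proteins are a few hundred residues.

What the generator does **not** emulate: real amino-acid correlation
structure, true secondary-structure physics, scale-free interaction networks,
or any biological relation between sequence and half-life.  Passing tests
on synthetic data therefore demonstrate that the pipeline recovers planted
signal and that every computation is internally correct — not that the
features predict real protein stability.  Reproducing the original
benchmark accuracies would require the external resources (interaction
networks, pathway memberships, location annotations, complex catalogues)
that this package deliberately does not fetch.

A feature-level generator (`planted_feature_matrix`) produces Gaussian
matrices with a class mean-shift (default 1 sd) on the leading features,
for direct tests of mRMR/IFS signal recovery; the standard recovery study
uses n = 500 samples, 50 features, 5 informative, 20 seeds — small enough
to run in seconds yet large enough for stable mutual-information
estimates.

## Numerical choices

* MI guarded against tiny negative rounding (clipped at 0).
* Cosine distances clipped to [0, 2] against floating drift.
* Standardization idempotence holds to 1e−10; oracle comparisons
  (CTD, MI, hypergeometric, jackknife) are asserted at 1e−9–1e−12.

## Known limitations

* Real subcellular locations, pathway memberships, neighbor sets and
  complex counts must be supplied as inputs; the package computes scores
  from them but performs no database retrieval or sequence-similarity
  inference.
* The nearest-neighbor stage is k = 1 with cosine-derived distance only;
  alternative metrics and k > 1 voting are out of scope.
* IFS is the plain forward procedure over one fixed ranking; no floating
  or stochastic search.
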