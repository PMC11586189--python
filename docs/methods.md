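# Methods

## The degradation-potential score

The score answers: *what fraction of this community likely carries the
genes for a given hydrocarbon-degradation step?* It combines two sources:

* a genus-level relative-abundance table from 16S amplicon sequencing, and
* genome-database evidence of marker-gene presence (profile-HMM hits
  against reference genomes, reduced to a boolean genome × marker matrix).

For genus *g* with *n_g* reference genomes, the coefficient for marker set
*m* is the exact fraction of those genomes satisfying the set's combine
rule — `any` by default (any homolog or subunit profile counts; a function
such as "naphthalene dioxygenase" is a gene family, not one profile), `all`
for strict multi-subunit requirements. No smoothing or pseudo-counts are
applied: a genus whose genomes never carry the marker scores exactly 0,
even when isolates of that genus demonstrably degrade the compound (a known
bias of database-derived coefficients — culture collections and genome
databases undersample degradative plasmids and strain-level variation).

The community potential for sample *s* is
`100 × Σ_g rel(s, g) × c(g, m)` percent. Three deliberate choices:

* **No renormalization to scored taxa.** Genera without a coefficient
  (unclassified at genus, absent from the database) contribute zero but
  stay in the denominator, so the potential is a fraction of the *whole*
  community. The per-sample `unscored_fraction` reports how much abundance
  was unscorable; the invariant `potential ≤ 100 − unscored_fraction`
  always holds.
* **Exact name joins.** Genus matching trims whitespace and case-folds,
  nothing else. Fuzzy synonym resolution is unauditable and silently wrong
  more often than right.
* **Gene presence, not activity.** The score is a hypothesis-generating
  potential; copy number, expression and pathway completeness are out of
  scope.

## Kinetics

**Removal accounting.** Percent removal is always computed against the
mean of heat-killed controls from the same assay, so abiotic losses
(volatilisation in shaken flasks, extraction losses) cancel out of the
biological estimate. Negative removals — replicate above the control
mean — are reported as-is; truncating at zero would bias replicate means
upward and hide heterogeneity.

**Fixed-intercept first-order fits.** Residual concentration is modelled
as `ln y(t) = ln(100) + b·t`, with the intercept pinned at 100% at the
starting time: at t = 0 the residual is 100% by construction, and letting
the intercept float would let early noise masquerade as instantaneous
gain/loss. The natural-log base makes `−b` the first-order rate constant
and `t½ = ln 2/(−b)` directly; any other base rescales the slope but never
the half-life. With the intercept fixed, least squares has the closed form
`b = Σ tᵢ(ln yᵢ − ln 100)/Σ tᵢ²`, used verbatim (no pseudo-observation),
which makes the estimator exactly testable against independent oracles.
Records with non-positive residuals are a hard error (they cannot be
log-transformed and indicate a unit or accounting problem upstream).

When concentrations arrive in physical units (ng cm⁻², µg mL⁻¹), residual
percent is taken relative to the condition's mean concentration at the
experiment's earliest time — the same 100% anchor the intercept refers to.
A declared `percent` unit is used at face value. Units are metadata and are
never converted implicitly; refitting after rescaling the time unit
rescales the half-life by exactly the unit factor.

**Condition contrasts.** Comparing slopes across conditions is a single
no-intercept regression of log-residual deviations on per-condition time
dummies. The design is block-orthogonal, so each condition's slope equals
its separate fit; contrasts use a pooled residual variance with
`df = n_total − k` by default. Because the covariance structure of such
contrasts is a genuinely open choice, a per-condition (Welch–Satterthwaite)
variant is available via `variance="per_condition"`; pooled is the default
as the standard linear-model convention.

**Fit windows are explicit.** An early-window fit (e.g. the first 4 days,
before inoculum die-off and community turnover change the kinetics) and a
full-series fit answer different questions; the window is always a
parameter, never inferred from the data.

## Community-table operations

* **Filtering** keeps taxa whose domain matches the target (Bacteria by
  default) and drops organellar 16S (any lineage containing Chloroplast or
  Mitochondria at any rank) and domain-unclassified ASVs. An audit object
  counts every removal class. Counts are never altered; a filtered
  relative table is either re-closed to sum to 1 (default) or returned
  value-preserved in counts mode.
* **Rank collapse** groups by the full lineage prefix down to the target
  rank, so homonym genera under different families stay distinct. Taxa
  unclassified at the rank become `unclassified_<deepest parent>` bins,
  which participate in all downstream analyses like named taxa.
  Per-sample totals are conserved exactly.
* **Minor-taxon aggregation** retains a taxon iff it reaches the threshold
  (inclusive, so "reaching 2%" keeps a taxon peaking at exactly 2.0%) in
  at least one sample; everything else merges into one "Other genera" row.
  Idempotent and total-conserving.
* **Ordination** is column-centred PCA of Hellinger-transformed data
  (square roots of relative abundances), the Legendre–Gallagher recipe:
  Euclidean distance on transformed rows equals Hellinger distance, making
  PCA appropriate for compositions without the horseshoe artefacts of raw
  abundances. Columns are not scaled — the transform already fixes row
  geometry. Axis signs follow a fixed convention (largest-magnitude
  loading positive per axis) so score tables are reproducible across runs
  and BLAS builds. Zero-variance input returns all-zero scores with a
  degeneracy flag rather than NaNs.

## Nonparametric statistics

Kruskal–Wallis uses mid-ranks, the standard tie correction and the
chi-square approximation at every sample size; small-sample exactness is
delegated to a permutation oracle in the test suite rather than an exact
enumeration in the library. All-tied data returns H = 0, p = 1 — the
limiting value, and the only convention that keeps downstream pipelines
total. Dunn's pairwise z uses the tie-corrected rank variance; adjustments
supported are none, Bonferroni, Holm and Benjamini–Hochberg, with **Holm as
default** (FWER control without Bonferroni's conservatism); the default is
a package choice, not a claim about any particular study's method.

`screening_summary` keeps full-precision fractions internally and rounds to
one decimal only for display. When exclusive counts for two compounds are
supplied, the both-compounds overlap is derived from each side and
cross-checked; a mismatch is flagged, never reconciled.

## Synthetic data

Generators are pure functions of (parameters, seed). One global seed fans
out to per-generator substreams through fixed `SeedSequence` spawn keys, so
adding a generator never perturbs existing streams, and every generator
emits a truth record with both target parameters and realized quantities.

* **Communities**: Dirichlet rows with concentration vector
  `α_s = α₀ · exp(effect · Σ_f shift_f)`, one fixed standard-normal shift
  vector per (factor, level). This produces the heterogeneous,
  group-structured compositions of seasonal/host designs; `effect = 0`
  makes samples exchangeable (verified against a label-permutation null).
  Default Dirichlet concentration 1.0 per taxon gives realistically uneven
  communities; a 10% genus-unclassified fraction reflects typical amplicon
  classification rates. Lineages are synthetic and phylogenetically
  arbitrary (blocks of five genera per family); they exercise the
  collapse/filter machinery but carry no evolutionary signal, so passing
  tests say nothing about classifier accuracy on real lineages.
* **Genome traits**: independent Bernoulli presence per genome at the
  genus prevalence. Real genome databases have phylogenetic correlation
  within genera; independence is the right null for testing that
  coefficients equal counted fractions, which is exact regardless.
* **Decay**: `y(t) = 100 · 2^(−t/t½) · exp(ε)`, ε ~ N(0, σ²) —
  multiplicative log-normal noise keeps concentrations positive and
  matches the log-scale fitting model. The reference regime (half-lives 6
  and 24 days, times {0, 2, 4} days, 2 replicates, σ = 0.05) mirrors a
  realistic greenhouse design; at that size single-experiment estimates
  scatter widely (quartiles roughly ±25% for the slow condition), which is
  why recovery is asserted on the median across seeds, not point-wise.
* **Flasks**: controls at `nominal × (1 − abiotic loss)`, samples further
  reduced by true removal, log-normal replicate noise (σ = 0.02 by
  default, matching low-single-digit CVs of GC–MS quantification);
  defaults of 50 µg mL⁻¹ nominal naphthalene, 3 replicates and 35%
  control loss follow the shaken-flask regime the removal accounting was
  designed for.

## Numerical notes and limitations

* Relative-mode row sums are enforced to 1e-9; conservation checks in the
  pipeline hold exactly for counts and to 1e-12 for relative tables.
* The fixed-intercept slope is ill-conditioned when all non-zero times are
  ≲1e-3 time units (ln y / t amplifies rounding); the estimator contract
  covers experimentally meaningful spacings.
* `read_abundance_table` requires an explicit orientation (`taxa_rows` /
  `samples_rows`); silent transposition is the classic table bug, so
  auto-detection is deliberately absent.
* The hmmsearch hit threshold defaults to E ≤ 1e-5 (full-sequence E-value,
  a conservative common choice for presence calls) and is configurable;
  presence is binary, so hit counts and scores beyond the threshold are
  ignored.
* Scores are genus-resolution by construction: strain-level trait
  variation, horizontal transfer and copy number are invisible, and the
  unscored fraction grows in exactly the habitats (underexplored clades)
  where degradation potential is most interesting. Treat potentials as
  comparative, not absolute.

## Problem sizes in tests and the acceptance script

Recovery suites run at 1,000 random genome-trait cases, 100 random
(table, coefficient) pairs, 500 seeded decay replicates per regime, 200
random datasets for Dunn antisymmetry and 100 random tables for
conservation — sizes at which the stochastic assertions (median half-life
within 10%, mean removal within 1%) are stable across seeds while the
whole suite stays interactive.
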