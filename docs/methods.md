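# Methods

This note documents the statistical procedure implemented by
`sigassoc`, the choices made where the design was genuinely open, and
what the simulation-based validation does and does not establish.

## Exposure discretization

The association machinery never regresses on raw exposure weights.
Each signature's per-sample weights are partitioned into three groups
by Lloyd's algorithm on the 1-D vector, with fixed, deterministic
behaviour:

- centroids initialised at the minimum, mean and maximum of the
  observed values (no random restarts, so results are reproducible and
  order-invariant);
- points assigned to the nearest centroid, distance ties broken toward
  the lower centroid — this keeps the many exact zeros of
  zero-inflated exposure vectors in the ZERO cluster;
- clusters that empty out keep their previous centroid rather than
  being reseeded, preserving the zero/high semantics;
- convergence is exact assignment stability, capped at 100 iterations
  (1-D Lloyd converges in a handful of iterations in practice).

A vector with fewer than three distinct values is flagged degenerate
and the signature (or expression feature) is skipped by the
association routines, as is any vector whose converged extreme
clusters are empty. In 1-D the converged assignment is always a
contiguous partition of the sorted values; the test suite checks this,
and checks agreement with the brute-force optimum over all contiguous
3-partitions on well-separated inputs.

## Hypergeometric testing

For binary features the universe is the union of the two extreme
clusters; the mid cluster is deliberately excluded so the test
contrasts tumors where the mutational process is absent with tumors
where it is strong. Both tails are always computed exactly
(`scipy.stats.hypergeom`); reports use the smaller tail with its
direction, because the same machinery must surface both
over-represented features (e.g. a mutation enriched in high-exposure
tumors) and depleted ones. Features without a carrier in the universe
are emitted with p = 1 and flagged uninformative rather than dropped,
so record counts are stable across signatures.

For expression the construction is inverted — expression is clustered,
exposures are binarized — because exposures, unlike expression, have a
natural zero and interpretable absolute scale. The binarization is
strictly greater than the threshold; four thresholds
(0.05, 0.1, 0.2, 0.5) are used and the feature-level statistic is the
minimum tail across them. Taking a minimum inflates raw significance;
this is deliberate and is calibrated by the permutation machinery,
which replicates the identical min-taking procedure under the null.

## Permutation FDR

The null is generated by independently shuffling each signature's
exposure vector over samples, which breaks the exposure-feature joint
distribution while preserving both marginals; the complete procedure
(clustering, counting, both tails, threshold minimum) is re-run on
each of 10 shuffles (configurable upward for smoother estimates).
p-values are pooled per data layer across signatures, mirroring how
operating cutoffs are chosen per layer; per-signature curves are
available by calling the estimator on a subset. The estimator is

    fdr(θ) = A(θ) / max(A(θ), O(θ)),   fdr := 0 when A = 0,

with O the observed and A the mean permuted count of p-values ≤ θ.
It is intentionally conservative (never exceeds 1, honest under
discreteness of the hypergeometric support where uniform-null methods
are not). Default operating cutoffs are raw p < 3e-4 for mutation/CNA/
clinical layers and p < 1e-5 for expression; both are configuration
fields, and the FDR curve at those cutoffs is written with every run.
Count-sparse regimes (few tests, or thresholds far in the tail) make
the estimate noisy — with O and A of order one, a single chance
discovery moves it a lot; pooling across a full signature catalog is
what stabilises it in practice.

## Preprocessing

- **Hypermutation**: samples with more than 500 distinct nonsilently
  mutated genes are removed (strictly more; 500 is retained).
- **Mutation features**: carrier = at least one nonsilent mutation;
  genes carried by fewer than 3 samples, or with only silent events,
  are dropped. The MAF `Variant_Classification` partition is a
  documented lookup: Silent, Intron, UTR/Flank, IGR and RNA classes are
  silent; every coding-changing class is nonsilent.
- **Copy number**: coordinates are 1-based inclusive (the common SEG
  dialect). Region atoms are delimited by the union of all samples'
  breakpoints per chromosome; a sample's value in an atom is the
  covering segment mean, overlaps resolved by maximum magnitude.
  Calls are inclusive at |mean| ≥ 0.5; amplifications and deletions
  are separate matrices; atoms with fewer than 3 carriers are dropped.
  Neighbouring same-chromosome regions whose carrier sets have
  symmetric difference ≤ 1 are merged (carriers OR-ed, spans unioned),
  iterated to a fixpoint, which makes the operation idempotent. The
  symmetric-difference reading is the only one that makes OR-merging
  well-defined in both directions of difference.
- **Expression**: quantile normalization maps every column onto the
  across-column mean of sorted values; ties within a column receive
  the mean of their tied reference values, so equal inputs stay equal.
- **Clinical**: strata become dummies (age strictly above its 50%/75%
  quantiles, one dummy per HER2 IHC level 0–3, nodes none / 1–4 / >4,
  receptor and margin/menopause positivity, four race levels); missing
  values contribute 0 and are logged; carrier-less dummies are dropped.
- **Sample universe**: samples present in the mutation, copy-number
  and mRNA layers with at least one non-missing signature estimate;
  miRNA and protein layers are optional and never restrict the
  universe. TCGA-style barcodes are truncated to a 12-character prefix
  for joining (configurable).

## Comutation

Pairs of genes are scored by the Pearson chi-square statistic on the
2×2 carrier table *without* continuity correction: calibration is
empirical, not asymptotic, so the correction would only blunt the
statistic. Every gene's carrier labels are shuffled independently in
each of 100 dataset randomizations — per-gene carrier counts are
preserved, pairwise structure is destroyed — and all randomized
pairwise p-values are aggregated into one null distribution. The
significance rule is raw p < 0.001; each run logs the fraction of the
null below the rule as an empirical check (about 0.2–0.4% on null
data, consistent with type-I control). Degenerate genes (carried by
none or all samples) get p = 1. The exclusivity summary
(samples covered by ≥ 1 gene vs overlapping in ≥ 2) is descriptive
only; no exclusivity p-value is computed here.

## Simulation model

A scenario plants G features per class — mutated genes, copy-number
regions (alternating amplification/deletion sign), over-expressed and
under-expressed genes — and builds the exposure of subject *j* as

    w_j = clip( Σ_c weight_c · I_c(j) + ε_j, 0, 1 )

where I_c(j) indicates carrying *any* planted feature of class c (for
expression: lying in the top/bottom T% of any planted gene's realised
values) and ε ~ U(0, noise_scale). Defaults, chosen once as a
realistic tumor-cohort scale and recorded here: 800 subjects, planted
alteration prevalence 0.05, background alteration rate 0.02, 500
background features per layer, equal component weights 0.25, noise
scale 0.1, standard-normal expression, grid G ∈ {5,10,20},
T ∈ {5,10,20}%. All are `SimulationScenario` fields. All randomness
flows from one integer seed through `numpy` generators; the grid
runner derives one child seed per replicate so tables are reproducible.

The generator emits exactly the dialects the readers consume (MAF
subset, SEG, exposure and expression TSVs), so a simulated dataset
exercises the full pipeline including parsing. Copy-number segments
are emitted for altered sample-region pairs only (a sparse SEG);
a real SNP6 SEG tiles the whole genome, but the breakpoint-union
atomization makes the two representations equivalent for calling.

Sensitivity is the fraction of the 4G planted features whose records
clear the default cutoffs; a planted region counts as recovered when
any significant region feature of the matching class overlaps it,
since merging may have absorbed it into a wider span. The acceptance
script runs the full grid at 20 replicates per scenario (180 simulated
cohorts, a few minutes on one CPU); the per-scenario spread at that
replicate count is a few percentage points.

**What the simulations do not show.** The additive model plants clean,
independent Bernoulli features and iid normal expression; real cohorts
have correlated alterations, batch structure, subtype confounding and
exposure estimation error, none of which are emulated. Sensitivity
figures therefore characterise the procedure's statistical power under
ideal signal, not its accuracy on any real cohort. Notably, scenarios
with many planted features per class saturate: with G = 20 the
probability that a subject carries *some* planted feature of a class
approaches 1 - 0.95^20 ≈ 0.64 per component, exposures pile up near
the top of the scale, the high cluster absorbs over half the cohort,
and the hypergeometric floor (n/N)^K for an individual feature's
geometry rises above the operating cutoff — per-feature sensitivity
collapses even though the composite signal is strong. This saturation
is a property of the class-indicator additive model itself, and it is
why mean sensitivity over the default grid spans from near zero
(saturated cells) to about 50% (sparse cells).

## Known limitations

- Associations are marginal: no covariate adjustment, no subtype
  stratification, no multi-signature joint models.
- The k-means discretization is scale-dependent by design; exposures
  and expression are assumed comparable across samples (expression via
  quantile normalization).
- The FDR estimator's variance grows in count-sparse regimes (see
  above); increase permutations when operating far in the tail.
- Region features are breakpoint atoms, not gene-annotated loci; no
  liftover or gene-model mapping is performed.
- The fixture generators used for calibration checks draw each
  signature independently and do not enforce the per-sample
  sum-to-at-most-one constraint of real weight tables; the
  per-signature discretization never observes the sum.
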