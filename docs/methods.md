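# Methods

## Scope and model chain

`drugprox` implements a five-stage analysis: (i) per-protein ratio
quantification from 8-plex isobaric reporter intensities, (ii) a Cauchy
noise model for ratio significance, (iii) annotation-based restriction and
summarisation of the dysregulated set, (iv) node2vec-style embedding of a
protein-interaction graph, and (v) co-citation-weighted cosine proximity
scoring of chemicals and diseases against the restricted set, with a final
two-stage ranking.  A synthetic-data module generates every input with
planted truth, which is what all statistical tests run against.

## Quantification and the Cauchy null

Peptide log-ratios `x_i = log10(i_c / i_113)` are computed per treatment
channel against the reference channel 113 (untreated, normoxia); rows
with non-positive or missing intensities are dropped for the affected
channel pair rather than imputed.  Channel medians are equalised first
(`normalize_channels`, multiplicative median matching), which removes any
pure per-channel loading/labelling bias exactly.

Aggregation to protein level offers three modes.  The default is the
**unweighted mean** of peptide log-ratios: the mean of iid Cauchy
variables is Cauchy with the *same* location and scale (stability), so
when peptide ratio noise is heavy-tailed the protein-level null is exactly
the fitted Cauchy and the test is exactly calibrated — the null up+down
call rate at α = 0.05 is 0.05 to within sampling error, which the
acceptance suite verifies on 14,000 null tests.  The intensity-weighted
mean (`w_i = i_c + i_113`) is provided for compatibility with common
practice, but note that its weights are correlated with the noise (a
peptide whose treatment intensity is inflated by a large positive ratio
error also gets a large weight, while a deflated one is diluted); in our
simulations this skews the null call rate upward to ≈ 0.065.  The median
mode under-rejects (≈ 0.035) because the median of n ≥ 3 Cauchy draws is
lighter-tailed than the Cauchy the p-value assumes.  These calibration
numbers are reproduced by the test suite's simulations, not assumed.

The null is fitted on the pooled protein log-ratios of all non-reference
channels (a per-channel restriction is available): location = median,
scale = half the interquartile range, which is the closed-form consistent
estimator for a Cauchy and robust to a planted-effect contamination of the
pool.  A maximum-likelihood fit is available behind `method="mle"`.  At
least 10 observations are required; identical observations raise a
degenerate-fit error.  P-values are two-sided,
`p = 1 − 2·arctan(|x − µ|/s)/π`, and calls require ratio > 1 (up) or < 1
(down) together with p ≤ α = 0.05; a ratio of exactly 1 is never called.
No multiple-testing correction is applied to the per-protein calls.

**Sensitivity caveat.**  The two-sided Cauchy test at α = 0.05 rejects
only beyond |x − µ| ≥ tan(0.475π)·s ≈ 12.7 scale units.  With a fitted
scale of ~0.05 the detection boundary sits at ~0.64 log10 units — beyond a
4-fold change.  Moderate fold changes (e.g. 2-fold) are therefore rarely
significant under this model regardless of peptide counts; this is an
inherent property of the heavy-tailed null, and the planted-recovery
acceptance check documents the measured sensitivity rather than hiding it.

## Annotation restriction

Annotations are flat protein → term sets in two namespaces (GO biological
process, PIR-style keywords); no ontology ancestor propagation is
performed.  The metabolic restriction takes the union over the five fixed
GO processes (ATP metabolic process, oxidation–reduction, carbohydrate,
lipid, and cellular protein metabolic process), overridable in config.
Tallies report `100·count/denominator` with an explicit denominator
argument (defaulting to the selected set) because the appropriate
denominator — dysregulated vs all quantified — is a reporting choice, not
a modelling one.  Over-representation is a one-sided hypergeometric
`P(X ≥ k)` with optional Benjamini–Hochberg q-values (off by default).

## Embedding

Walks: second-order biased random walks with return parameter p and
in–out parameter q (defaults p = q = 1, 10 walks of length 80 per node),
sampled by direct categorical draws over the neighbour set; with
p = q = 1 the kernel reduces analytically to the first-order weighted
walk, which the tests verify by enumeration and χ².

Training: skip-gram with negative sampling written directly in numpy.
Pairs use the classic reduced-window rule (per-centre window uniform on
1..window, default window 10); negatives (default 5) come from the
unigram^0.75 distribution; SGD runs in minibatches (default 2048 pairs)
with learning rate decaying linearly 0.025 → 1e-4.  Minibatching delays
the saturation feedback a strictly sequential SGD would give, which on
small dense corpora can let vector norms run away; rows are therefore
re-projected to a maximum norm of 10 after each batch.  Training is
single-threaded and bit-reproducible given the seed.  Default dimension
128.  Isolated nodes (never producing a walk of length ≥ 2) receive no
vector — a zero vector would poison cosine similarity — and are recorded
in a skipped list; scoring omits them but counts the omissions.

Quality gate (verified in the acceptance suite): on a two-block
stochastic block model (2 × 50 nodes, p_in = 0.3, p_out = 0.02) the mean
intra-block cosine exceeds the inter-block mean by ≥ 0.2 and 2-means
clustering of the vectors recovers the blocks at ≥ 95% accuracy in at
least 4 of 5 seeds (measured: margins ≈ 0.35–0.38, accuracy 100%).

## Proximity score and ranking

The score sums cosine similarities over all query × profile protein
pairs, keeping pairs with cosine ≥ τ = 0.5 and weighting each by the
profile protein's co-citation count (raw counts by default; a
normalised-weights mode divides by the profile's total count, making
scores comparable across profiles of different literature coverage).
Cosine **similarity** is used, and high-similarity pairs are *kept*: a
higher score means the chemical's co-cited proteins sit closer to the
query network, which is the reading consistent with ranking candidates by
how strongly they target the network.  Query proteins are unweighted —
only the entity side carries literature counts.  All-pairs scoring (not a
single weighted-centroid comparison) is the primary definition because
the score is defined over the full cosine matrix of the two groups.

Ranking is two-stage: all chemicals sorted by descending network score
(ties lexicographic by entity id), then — within the top `top_n` — re-sorted
by descending proximity of each chemical's protein support to the disease
profile, metabolites dropped, and the first `top_k` reported.  Chemicals
whose profile has no embedded protein are listed as unscorable with a
reason rather than silently dropped.

## Synthetic study conditions

The quant generator defaults emulate the scale of the motivating
experiment: 834 proteins, 3.25 peptides/protein (shifted Poisson,
support ≥ 1), base peptide intensity lognormal(ln 1e5, 0.5), per-channel
multiplicative bias uniform in [0.5, 2], 20% of proteins regulated per
treatment channel with 2-fold effects in a random direction (50/50
up/down), and peptide log10-ratio noise of scale 0.05.  Noise is placed
on the treatment channel's log-ratio (the reference channel carries none)
so the configured noise law *is* the peptide ratio distribution;
`cauchy_logratio` is the default because it matches the distributional
assumption of the significance model, with `lognormal` (Gaussian
log-ratios) as the light-tailed alternative.  Cauchy draws are clipped at
±8 decades to keep intensities finite; the clip lies two orders of
magnitude beyond the α = 0.05 decision boundary and is statistically
invisible there.  Count-valued draws use a shifted Poisson
`1 + Poisson(mean − 1)` so the configured mean is exact and counts are
≥ 1.

The interaction graph is a stochastic block model; co-citation profiles
hit a planted target block at rate 0.8 and everything else at 0.05 with
counts ≥ 1 (mean 3); annotations are independent Bernoulli per
protein × term (metabolic GO terms at 0.15 each, so roughly 56% of
proteins carry at least one; PIR keywords acetylation/phosphoprotein at
0.65/0.60, echoing the 60–70% prevalence such keyword tallies typically
show among dysregulated sets).

The end-to-end planted benchmark (`demo_config`) uses 200 proteins in two
blocks of 100, regulation planted only within block 0, 20 chemicals with
CHEM0001 targeting block 0 and the rest background-only, and one disease
profile anchored on block 0.  Embedding parameters are scaled to the
200-node graph (dimension 64, 10 walks of length 40, window 5, 3 epochs)
— ample for a two-block structure and fast enough to repeat across many
seeds.  Because of the Cauchy sensitivity caveat above, the query set in
this benchmark consists partly of false-positive calls spread over both
blocks; recovery of the planted chemical at the top of the ranking
therefore genuinely tests the proximity score's ability to pick out the
concentrated, high-count profile rather than relying on a clean query.

What the generators do **not** emulate: spectra and m/z values,
identification FDR, isotope-impurity correction, shared peptides between
proteins, intensity-dependent (heteroskedastic) ratio noise, degree
heterogeneity and hub structure of real interaction networks, and
literature-bias structure of real co-citation counts.  Passing tests
demonstrate internal correctness and recoverability under these idealised
conditions, not performance on real data.

## Numerical and reproducibility choices

All randomness flows through `numpy.random.default_rng` with explicit
seeds; the pipeline derives per-stage seeds from one master seed by
hashing the stage name (blake2s, reduced below 2^31).  Two runs with the
same config and seed produce byte-identical artifacts; the run report
excludes wall-clock time and absolute paths for that reason.  TSV floats
are written at 10 significant digits.  Ties in rankings and tallies break
lexicographically; sorting uses stable mergesort.  Degenerate inputs
(empty tables, zero-spread fits, zero-norm vectors, τ outside [−1, 1],
empty groups after embedding restriction) raise informative errors rather
than propagating NaNs.

## Limitations

* The quantification stage tests each protein ratio against a global
  Cauchy null; it does not decompose spectrum-level vs biological
  variance, nor shrink the scale with peptide count, so its power at
  moderate fold changes is low by construction (see the sensitivity
  caveat).
* The SGNS implementation is deliberately compact (single-threaded,
  minibatched); it is not a performance replacement for large-graph
  embedding tools and has been validated on graphs up to a few hundred
  nodes.
* The hypergeometric over-representation test is a plain stand-in for
  richer annotation-enrichment tooling (no EASE-style jackknife, no
  annotation clustering).
* Real co-citation databases and curated interaction networks are out of
  scope; users supply their own tables in the documented TSV/GMT formats.
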