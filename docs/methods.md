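# Methods

This note documents the models, null models, defaults and numerical choices
behind `microassembly`, and what the synthetic generators do and do not
emulate.

## Data model

Counts are kept as non-negative integers (reads) throughout; every analysis
normalizes on demand (relative abundances for Bray–Curtis and the neutral
model, per-taxon habitat-use distributions for niche indices, presence/
absence for Jaccard). No rarefaction is applied by default because the
stages disagree about the right normalization; `rarefy()` (subsampling
without replacement to the minimum depth, seeded) is available for users who
want even depths. Metadata requires sample id, coordinates and region; all
covariates may be missing. A region label inconsistent with the aridity
index (arid ⇔ 0.03 < AI < 0.2, humid ⇔ AI > 0.65) is a warning, not an
error, since the label may encode a design decision rather than the raster
value. Replicates are kept as samples everywhere; no site-level pooling.

## Synthetic generators

The generators exist so that each inference stage can be tested against a
planted truth, at the scale of the field design they emulate (47 sites × 3
replicates = 141 samples, two regions).

**Neutral** (`simulate_neutral`): each taxon's latent relative abundance in
each sample is drawn from the Sloan stationary marginal
Beta(*N m p*, *N m*(1 − *p*)), the latent vector is renormalized across taxa
and *N* reads drawn multinomially. This gives exact target marginals at
O(taxa) cost per sample instead of an individual-based birth–death loop, and
is fully seedable. The metacommunity defaults to a lognormal(0, 1)
rank-abundance vector on the simplex.

**Niche** (`simulate_niche`): expected abundance of taxon *i* in sample *s*
is *p*ᵢ exp(−(*e*ₛ − μᵢ)² / 2σᵢ²) along an environmental gradient
(unit-scaled aridity index in the study-like design), counts multinomial.
Defaults: gradient on [0, 1], optima uniform over it, a single width
σ = 0.08 — a strongly selective regime in which a taxon spans < 10 % of the
gradient. σ is the knob that moves the community between regimes; the
community breadth *B*com decreases monotonically as σ shrinks.

**Planted networks** (`plant_network`): taxa in a block share a
standard-normal latent factor with loadings ±s (negative blocks alternate
signs, so they contain anti-correlated pairs); latent Gaussians are
exponentiated to log-normal abundances and scaled to multinomial counts. All
within-block pairs with their expected correlation signs are recorded as the
planted edge list. Compositional closure attenuates correlations when block
taxa dominate the taxon budget, so recovery tests embed blocks among a
larger pool of independent noise taxa — which is also the realistic
situation.

**Study-like** (`make_study_like`): coordinates on a rough latitudinal
transect with the humid sites placed coastally; aridity index drawn inside
each region's class window; covariates (MAT, MAP, pH, TC, TN, DOC, DON,
NO₃, NH₄) normal with region-specific means and spreads patterned on the
sampled climate (MAP ~264–565 mm arid vs ~856–1769 mm humid; MAT warmer,
pH higher and carbon pools lower in the arid region). The bacteria-like
table is neutral (*m* = 0.1, 300 taxa), the fungi-like table
gradient-filtered (150 taxa, σ = 0.08) over the same samples. Reads per
sample default to 10 000, a typical post-QC amplicon depth.

What the generators do **not** emulate: sequencing error and chimeras,
taxon-specific depth biases, spatial autocorrelation beyond the single
transect gradient, phylogenetic structure, and real covariate
distributions — the covariate effect sizes are calibration placeholders,
not estimates of any real sites. Passing recovery tests therefore shows the
estimators are correct for their generating models, not that real
communities follow those models.

## Neutral community model

The fit follows the occurrence-frequency formulation: with mean depth *N*,
mean relative abundance *p*ᵢ and occurrence frequency *f*ᵢ per taxon, the
model predicts *f* = 1 − BetaCDF(*d*; *Nm p*, *Nm*(1 − *p*)). *Nm* is the
single free parameter, found by bounded scalar least squares on log₁₀ *Nm*
over [10⁻³, 10⁷] (an estimate at a bound raises a warning and is flagged in
the results); *m* = *Nm*/*N*. R² = 1 − SSres/SStot about the mean of *f*;
the 95 % envelope is the Wilson score interval of the predicted frequency
at *n* = number of samples, and taxa are reported as above/within/below it.

The detection limit *d* deserves care. Under binomial read sampling a taxon
at latent abundance *x* is observed with probability 1 − (1 − *x*)ᴺ ≈
1 − e^(−*Nx*), a smooth curve, while the model uses the hard threshold
*x* > *d*. The conventional one-read rule *d* = 1/*N* puts the threshold
where the smooth curve is already at 1 − e⁻¹ ≈ 0.63, ignoring the mass
detected below it, and inflates fitted *Nm* by ~25–30 % on count data. The
`auto` default is therefore *d* = ln 2/*N*, the abundance at which the
detection probability crosses ½, which centres the hard threshold on the
smooth curve; recovery of a planted *m* = 0.1 is then unbiased to within a
few percent. Any explicit value (including 1/*N*) can be passed instead.

## Normalized stochasticity ratio

For each within-group sample pair, observed dissimilarity *D* is compared
with the mean dissimilarity *D̄* over null communities; selection strength
is ESS = (*D̄* − *D*)/*D̄* if *D* ≤ *D̄*, else (*D* − *D̄*)/(1 − *D̄*), and
NST = 1 − ESS, averaged over pairs and reported in percent, with 50 % as the
stochastic/deterministic boundary. Pairs with degenerate null means (0 or 1)
are excluded with a warning.

The null model (PF) preserves each sample's richness exactly, draws its taxa
without replacement with probability proportional to occurrence frequency,
and reassigns the sample's observed non-zero counts to the drawn taxa
uniformly at random. Because this null preserves *occupancy* structure but
scrambles *abundance* structure, the dissimilarity metric must be matched to
it: with Bray–Curtis the null is far more dissimilar than any real
community (the abundance hierarchy is destroyed), and even perfectly neutral
data scores as strongly "deterministic". The default metric is therefore
Jaccard on presence/absence, under which neutral communities score NST ≈
75–85 % and strongly filtered communities ≈ 40 %, reproducing the intended
qualitative contrast; Bray–Curtis remains available via `metric=`. Null
count defaults to 1000 (seeded); calibration tests use 100.

## Networks

All unordered taxon pairs (after an optional prevalence filter, default 1/3
of the region's samples when run through the pipeline) are scored by
Spearman ρ with mid-rank ties; two-sided p-values use the t approximation
(exact permutation enumeration for ≤ 9 samples, though network construction
itself requires ≥ 10); Benjamini–Hochberg correction runs across all tested
pairs. An edge needs *q* < 0.01 and |ρ| > 0.6. The strength threshold is
applied to |ρ| because negative links are an explicit output of the
stability analysis and a one-sided ρ > 0.6 rule would forbid them;
`use_absolute_rho=False` gives the literal one-sided reading. Constant taxa
are skipped with a warning (ρ undefined).

Topology is computed on the unweighted, sign-blind graph: harmonic
closeness (mean inverse shortest-path length) rather than classic closeness
because co-occurrence networks are routinely disconnected; modularity from
greedy agglomerative (CNM) optimization with nodes and edges inserted in
sorted order so ties break deterministically.

Robustness: per repetition, ⌊*f n*⌋ nodes are removed uniformly at random
(*f* = 0.5, 100 repetitions by default) and the outcome is the fraction of
the *original* n nodes that survive with at least one remaining link, so
values are comparable across networks; two robustness distributions are
compared by a two-sided rank-sum test. The Monte-Carlo mean is validated
against exhaustive enumeration over all removal sets on small graphs.

## Driver ranking

Composition is regressed on covariates with a bootstrap ensemble of
regression trees (500 by default, each split drawn from ⌈p/3⌉ candidate
predictors); importance is the mean increase in out-of-bag MSE when a
predictor's values are permuted, computed with one seeded permutation
stream per predictor so rankings do not depend on column order. Optional
significance comes from refitting to permuted responses (off by default —
99 permutations × 500 trees is expensive; the calibration test uses smaller
ensembles, and the proper null for "is the best predictor real?" is the
permutation distribution of the *maximum* importance).

Encoding "composition" as a single response is a genuine design choice. The
first PCoA axis (`composition_response`) is the simplest encoding, but when
between-region turnover saturates Bray–Curtis it degenerates into a binary
region indicator, and any covariate separating the regions explains it as
well as the true gradient driver — the importance ranking among collinear
covariates becomes a lottery. The pipeline therefore defaults to the
multivariate encoding (`rf_importance_multiaxis`): one ensemble per
retained PCoA axis, importances summed across axes. Axis-k scores carry
variance proportional to their eigenvalue, so the plain sum is an
eigenvalue-weighted aggregate — the increase in squared reconstruction
error of the whole embedding. This keeps within-region compositional signal
that only the true driver explains; on study-like data it identifies the
aridity index as the top fungal driver essentially always, where the
axis-1 encoding succeeds only ~two-thirds of the time. `drivers_response:
axis1` in the pipeline config restores the single-axis behaviour.

## Numerical and procedural details

* PERMANOVA: pseudo-F from the squared-distance partition; p-value
  (1 + #{F_perm ≥ F_obs})/(1 + n_perm) under seeded label permutation —
  bit-reproducible, and the statistic matches scikit-bio's implementation
  to machine precision (cross-checked in tests).
* Distance–decay p-values treat pairs as independent, which they are not;
  the result object carries an explicit anti-conservatism caveat.
* Rank-sum comparisons use exact enumeration of the midrank permutation
  distribution when C(n₁+n₂, n₁) ≤ 2·10⁵, otherwise the normal
  approximation with tie correction.
* Shannon entropy uses natural log so Pielou's J = H/ln S is exact at 1 for
  uniform communities.
* Levins breadth normalizes within taxon across samples (samples as
  resource states), the only convention under which B ∈ [1, n_samples];
  *B*com averages taxa present in ≥ 5 samples by default (variance control
  for rare taxa; overridable, and set to 0 in width-response tests so the
  filter cannot mask the effect).
* The overlap network's edge threshold defaults to the 90th percentile of
  off-diagonal overlaps (no principled absolute threshold exists);
  an edge exists if either directed overlap reaches it.
* Per-stage pipeline seeds are substreams of the master seed derived via
  CRC32 of the stage name, so stages can be re-run in isolation and runs
  are reproducible from the manifest alone.
* Scaled problem sizes: calibration and recovery tests use 100-null NST,
  100–200-tree ensembles and 20–60-taxon toys; these sizes were chosen so
  the full verification cycle completes in minutes while keeping the Monte-
  Carlo error well inside the asserted margins.

## Known limitations

* The NCM fit assumes a single metacommunity and equal depths; strongly
  uneven depths distort both *p* and *f*.
* NST magnitudes depend on the null algorithm, metric and group sizes;
  only the position relative to the 50 % boundary and paired contrasts are
  interpretable, not absolute percentages.
* Spearman-threshold networks inherit compositional biases of relative
  abundance data; no compositionality correction (e.g. CLR) is applied.
* The robustness protocol (uniform removal, degree-0 extinction rule) is
  one of several in use; absolute robustness values are protocol-specific.
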