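# Methods

`odorkin` analyzes wide GC–MS peak tables (samples × compounds, arbitrary
area units) together with per-individual metadata (sex, social group, age,
standardized rank) and a pedigree. It asks two complementary questions:
do whole chemical profiles cluster by attribute (similarity branch), and
which compounds carry each attribute's signal (composition branch).

## Compound retention

Two rules are applied to the raw peak table before any statistics:

1. **Blank rule.** A compound is exogenous (contaminant, swab- or
   solvent-derived) if its mean area in blank controls is similar to or
   higher than in the animal samples. "Similar or higher" is
   operationalized as `blank_mean >= blank_ratio * sample_mean` with
   `blank_ratio = 1.0` by default and exposed as a parameter, where the
   sample mean is taken over samples in which the compound is present.
   The blank rule is evaluated first.
2. **Rarity rule.** A compound quantifiable (area > 0) in fewer than
   `min_samples = 3` samples is discarded as having no general relevance.

Filtering is idempotent and reported per compound
(`retained / excluded_blank / excluded_rare`, with the means and counts
that drove the decision).

## Transformations

Retained areas are standardized per sample to percent of the sample's
total retained area (rows sum to 100; zeros stay zero). Two chains then
diverge:

* **Similarity chain**: natural `log(x + 1)` of the percentages. This
  compresses dominance by abundant compounds while preserving
  presence/absence contrast, and feeds Bray–Curtis.
* **Model chain**: `log(arcsin(sqrt(x/100)) + 0.01)`. The
  arcsine-square-root stabilizes the variance of proportions; the shifted
  log symmetrizes the heavy zero class (a zero maps to `log(0.01) ≈
  −4.605`, full dominance to `log(π/2 + 0.01) ≈ 0.459`). The composition
  order of the two steps is genuinely ambiguous in practice; both orders
  are monotone and finite on [0, 100], the default is
  arcsine-then-log (which keeps the arcsine argument in [0, 1] naturally),
  and the alternative order is selectable and recorded in the run
  manifest.

Age is z-transformed (sample SD, ddof = 1) over the model rows' sample
vector; rank is mean-centered. Both aid optimizer conditioning without
changing the tests.

## Similarity branch

Pairwise Bray–Curtis dissimilarity, `D(x,y) = Σ|x−y| / Σ(x+y)`, is
computed between transformed sample profiles (and, for Mantel tests,
between transformed individual-mean profiles; means are taken on the
percent scale before the log transform, so they remain row-stochastic).

**ANOSIM.** All M = n(n−1)/2 pairwise dissimilarities are ranked
(average ranks on ties); `R = (mean_rank_between − mean_rank_within) /
(M/2)`. Because individuals contribute one to five samples, samples are
not exchangeable under the null; the permutation scheme therefore
shuffles the multiset of group labels across individuals (blocks), each
sample inheriting its individual's new label. The literal reading
"permute samples within the individual" would leave every label
unchanged, so block-level exchangeability is the implemented
interpretation, and the scheme name is recorded in every result. A free
(sample-level) scheme exists for comparison and is demonstrably
anticonservative on blocked data (see the type-I validation test).
P-values are one-sided upper with the +1 correction:
`p = (1 + #{R_perm ≥ R_obs}) / (1 + n_perm)`; default `n_perm = 999`.

**Kin ANOSIM.** For one parental line, within-pairs are the
cross-individual sample pairs of half-sibling dyads of that line;
between-pairs are sample pairs of distantly related or unrelated dyads
(no shared parent, r < 0.25). Same-individual pairs, pairs of the other
half-sib line, and close-kin pairs are excluded from the ranking, which
runs over included pairs only. The null permutes sibship membership
across individuals, preserving the sibship-size multiset; the fixed
exclusion set is kept anchored to the real pedigree so the comparison
set stays commensurate across draws. When every included dissimilarity
is tied, R is reported as 0 with a degenerate-ties flag.

**Mantel.** Pearson correlation of the two upper-triangle vectors;
the null relabels the second matrix's rows and columns simultaneously.
One-sided upper by default, two-sided available.

## Pedigree relatedness

Relatedness is pure path counting on a pedigree truncated at the
grandparental generation: `r = Σ (1/2)^L` over connecting paths through
parents and grandparents whose up- and down-legs meet only at the common
ancestor. Shared parent contributes 0.25 per parent; a shared
grandparent without a shared parent contributes 0.0625 per grandparent.
Deeper known ancestry is ignored by design — this matches the working
definition of "unrelated" as sharing no ancestor up to and including
grandparents, under uneven pedigree depth. Missing parents are unique
unrelated founders. Dyad categories: maternal/paternal half-sib (exactly
one shared parent), `excluded_close` (full sibs, parent–offspring,
grandparent–grandchild — flagged, not dropped), `distant`
(0.0625 ≤ r < 0.25 without a shared parent), `unrelated` (r < 0.0625).
A dyad that is half-sib through one line and shares a grandparent on the
other side is categorized by the closer tie while r sums all paths.

## Composition branch: vectorized random-slopes mixed model

The samples × compounds matrix of model-transformed abundances is
vectorized into a single Gaussian response (one row per sample ×
compound). Fixed effects: sex (coded +1/2 female, −1/2 male, so the
fixed effect and slopes read as the female-minus-male difference), social
group (treatment-coded), z-age, and rank on the female subset. Random
intercepts: sample and compound (the matrix rows and columns, absorbing
the pseudo-replication created by vectorizing), individual, mother and
father. The test predictors are per-compound random slopes of every
fixed effect within compound: a predictor matters when compounds differ
in their response to it.

Parameterization: one variance component per random term; slopes are
independent of each other and of the compound intercept (no covariance
parameters). The categorical group slope uses an orthonormal
sum-to-zero basis over group levels within each compound (exchangeable
level deviations, one shared variance), which also makes the
"largest difference between groups" summary invariant to the reference
level. The simplest convergent covariance structure was chosen because
richer structures (correlated slopes) cannot be identified reliably at
these dimensions; the choice is recorded in the run manifest.

Estimation is maximum likelihood (not REML) so LRTs between nested
models are coherent. The implementation profiles out the fixed effects
and the residual variance analytically and optimizes the log variance
ratios `γ_r = σ_r²/σ²` by L-BFGS-B with an analytic gradient, using the
Woodbury identity so each objective evaluation costs O(q³) in the total
random-effect dimension q (≈ 440 at study dimensions) rather than in the
number of rows. Bounds of [e⁻¹⁴, e⁸] on the ratios keep boundary
components finite; convergence failures trigger up to five jittered
restarts under a derived seed and are flagged, never silent. Conditional
(BLUP) effects are recovered as `b = Γ²Zᵀ W⁻¹ (y − Xβ̂)`.

**Tests.** The omnibus LRT compares the full model against the model
without any random slopes; per-predictor LRTs drop only that predictor's
slopes. `χ² = 2Δlogℓ` (clipped at 0; inversions beyond optimizer noise
warn), df = parameter-count difference, p from the naive χ²(df)
reference. Testing variance components on the boundary makes this
reference conservative; that is documented rather than corrected (no
mixture-χ²), matching common `anova`-style practice.

**Slope table.** Per compound, the sex/age/rank slope is the fixed
effect plus the compound's conditional slope deviation; the group value
is the largest pairwise difference among the compound's group-level
effects. The strongest-effect rule selects compounds whose absolute
slope is at least one sample SD above the mean absolute slope for that
predictor; when the SD is zero the rule is vacuous and selects nothing
(with a warning).

## Synthetic data generator

The generator emulates a cross-sectional swab study of a provisioned
colony: 60 adults (52 F : 8 M), five social groups, female ages 6–21 and
male ages 6–11 (uniform), standardized female ranks uniform on [0, 1],
one to five samples per individual with probabilities
(0.20, 0.50, 0.20, 0.05, 0.05) (mean 2.25, ≈ 132 samples), 21 endogenous
compounds plus 10 contaminants, five blanks, and a pedigree planted with
exactly 6 maternal half-sib dyads (two-offspring mothers) and 26
paternal dyads (sibships up to size six), all other parents unique.

Abundances are log-normal with detection censoring: latent
log-abundance = compound baseline (N(0.9, 1.5²)) + compound-specific
sex, group and maternal-family effects + compound-specific age and rank
slopes + individual deviation + residual; `area = exp(latent)`, zeroed
below the detection threshold (1.0). These defaults give ≈ 13.5 of 21
compounds per sample, the zero-inflation regime of real swab profiles.
Contaminants are i.i.d. log-normal in samples and appear in blanks at a
log-scale +1 shift (similar-or-higher concentration), so the blank rule
has an unambiguous planted truth. The maternal-family effect attaches to
the mother id, deliberately conflating shared genes and shared
environment the way maternal-kin resemblance does in a female-philopatric
species; there is no separate additive-genetic term. All randomness
derives from one master seed through named substreams.

What the generator does **not** emulate: chromatographic drift,
co-elution, batch effects, microbiome dynamics, compositional error
structure of real integrators. Passing tests therefore demonstrate the
statistical machinery's calibration and power under the assumed
generative model, not field validity of any biological conclusion.

## Validation experiments and problem sizes

* ANOSIM R is checked exactly against a brute-force rank implementation,
  and the sampled blocked-permutation p against exhaustive enumeration
  on designs of ≤ 8 samples (tolerance 2/√n_perm, n_perm = 999).
* Type-I calibration: 1000 replicates of 16 individuals × 3 samples with
  strong within-individual correlation and no group effect, 99
  permutations each; blocked rejection at α = 0.05 must stay inside the
  95% binomial band while free permutation must exceed it.
* Power monotonicity: rejection rate non-decreasing over planted sex
  effects of {0, 0.5, 1, 2} × residual SD, 100 replicates per level with
  common random numbers across levels.
* Pedigree oracle: path-counting relatedness equals an independent
  brute-force enumeration on 1000 random three-generation pedigrees.
* Mixed-model recovery: 100 data sets at study dimensions with three
  compounds carrying a sex slope of 1.0 and residual SD 0.3, planted
  directly on the response scale (the scale on which those parameters
  are defined; routed through the compositional pipeline the same latent
  effect is distorted by standardization and censoring, which a separate
  end-to-end test covers with a looser criterion). The strongest-effect
  rule must recover the planted set as the top three |slopes| in ≥ 90%
  of runs and the omnibus LRT must reject in ≥ 95%; on 100 null data
  sets the omnibus rejection must not exceed the nominal 5% beyond
  binomial noise.

## Numerical conventions

Distances and result tables serialize at 12 significant digits; write →
read round-trips are exact at that precision. Ties in dissimilarities
take average ranks. Permutation p-values always carry the +1 correction
and can never be 0. Degenerate inputs fail loudly with the offending
identifiers named: all-zero samples cannot be standardized, constant
attribute vectors cannot be z-transformed or Mantel-tested, labels with
fewer than two samples have no within-pairs.

## Known limitations

* The LRT reference is conservative at variance boundaries (see above).
* Per-compound slope shrinkage depends on the estimated slope variance;
  rankings are stable but absolute slope magnitudes are not comparable
  across fits with different covariance structures or transform orders.
* The kin ANOSIM's sibship-permutation null keeps the exclusion set
  anchored to the observed pedigree; alternative restrictions would
  change p-values (not R).
* Blank filtering compares means only; a compound genuinely present in
  animals but also abundant in blanks is discarded (conservative by
  design).
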