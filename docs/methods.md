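# Methods

This note documents the statistical conventions, default parameters,
generator design and known limitations of `magdyn`. Nothing stated here
goes beyond what the test suite and `scripts/acceptance.py` themselves
compute.

## Inputs and quality screening

The pipeline consumes a sample × MAG integer read-count table (TSV), a
MAG quality table (genome length, completeness, contamination; percent
columns are converted to fractions on read), per-MAG gene annotations, a
rooted Newick phylogeny over the MAGs with branch lengths, a JSON pathway
database and a sample-metadata table (individual, cage, species,
treatment, time index; individuals nest in cages, cages in species, and
each (individual, time) pair is unique).

MAGs are retained when completeness ≥ 0.70 **and** contamination < 0.10
(the completeness bound is inclusive, the contamination bound strict).
Counts are normalised for genome length and depth: per sample,
`vᵢ = countᵢ / lengthᵢ` rescaled so each row sums to 10⁶ ("reads per
million"). The quality filter is applied before normalisation; the order
is configurable. All-zero samples are kept in tables but excluded from
diversity computations with a warning.

## Trait distillation

A pathway is an ordered list of steps; each step carries one or more
alternative identifier combinations, each combination a set of jointly
required gene identifiers. The step score is the best fraction-present
over its alternatives — a generalisation of the two-identifier
complete/half-complete/empty rule to arbitrary combination sizes, to
which it reduces exactly. The pathway score (GIFT) is the arithmetic mean
of step scores; function-level MCIs are means of GIFTs within each
function category (14 by default).

Genome incompleteness biases raw GIFTs downward. Under uniformly random
gene loss at rate `1 − c` the expected observed score is `c` times the
true score, so the default adjustment is `min(1, GIFT / c)` — unbiased in
expectation under that model, capped at the scale maximum. The
adjustment is a pluggable strategy (`distill_genome(..., adjustment=...)`)
because other conventions exist.

## Diversity

All diversities are Hill numbers, computed for any order q but analysed
at q = 1 by default (the q → 1 limit is evaluated analytically, never by
numerical perturbation).

* **Neutral**: `exp(−Σ pᵢ ln pᵢ)`.
* **Phylogenetic**: branch-level formulation; with `a_b` the summed
  relative abundance under branch `b`, `L_b` its length and
  `T = Σ L_b a_b` the abundance-weighted mean depth, the q = 1 value is
  `exp(−Σ (L_b/T) a_b ln a_b)`. This is the *normalised* variant (an
  effective number of lineages); the un-normalised effective branch
  length (× T) is exposed via `normalized=False`. On a star tree with
  equal branch lengths it reduces exactly to the neutral value.
* **Functional**: attribute diversity on the Gower distance `d` over the
  MCI trait table (traits scaled by their range; constant traits are
  excluded; all-constant input is an error). With
  `Q = Σ d_ij p_i p_j`, the q = 1 effective number of equally distinct
  MAGs is `exp(−½ Σ (d_ij/Q) p_i p_j ln(p_i p_j))`.

Partitioning uses equal sample weights: gamma from the pooled mean
abundance vector, alpha as the within-sample Hill average (exponential of
mean Shannon for neutral/phylogenetic; for the functional component the
total attribute diversity with the pooled-assemblage Q), and
`β = γ/ᾱ ∈ [1, N]` for neutral/phylogenetic, `[1, N²]` for functional.
Sørensen-type turnover rescales β to [0, 1] by `(β−1)/(N−1)` or
`(β−1)/(N²−1)` respectively. Because reference implementations differ on
the functional normalisation, the `N−1` variant is also available
(`functional_normalization="linear"`); the `N²−1` variant is the default
since functional β genuinely ranges to N². Within-individual series
report both consecutive-pair turnovers and the overall N-sample turnover
(the N-sample partition is the default "overall" statistic; the mean of
pairwise values is reported alongside).

## Redundancy

Per sample: Rao quadratic entropy `Q`, Gini–Simpson `D`, uniqueness
`U* = Q/D` and redundancy `R* = 1 − U*`. With Gower distances bounded in
[0, 1], `U* ∈ [0, 1]`; clipping guards only floating-point overshoot, and
a genuine `Q > D` raises an assertion rather than being clipped.
Single-MAG samples (D = 0) are flagged undefined and excluded from
summaries. The diversity–redundancy relation reports Pearson and
Spearman correlations between `log` neutral diversity and `R*` with
permutation p-values (999 label permutations, seeded, observed labelling
included in the reference set).

## PERMANOVA and CAP

PERMANOVA operates on the Gower-centered matrix `G = −½ J D² J`:
`SS_total = tr(G)`, among-group SS from the group-membership projection,
pseudo-F with (a−1, N−a) degrees of freedom, and the **unadjusted**
`R² = SS_among/SS_total` as effect size. Restricted permutations
honour the repeated-measures design: treatment labels are freely
re-permuted *within each individual's samples*, sampled with replacement
from the within-block permutation group, with the observed labelling
always part of the reference set, so
`p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)` and `p ≥ 1/(n_perm+1)`.
Blocks with a single sample contribute no permutation (warned). With a
single all-encompassing block the procedure equals unrestricted
PERMANOVA exactly. Only the single fixed-effect design is implemented.

CAP performs principal-coordinate decomposition of `G`, drops
negative-eigenvalue axes with a warning (turnover dissimilarities are
generally non-Euclidean), and runs linear discriminant analysis of group
membership on the first m coordinates. When m is not supplied it is the
smallest value maximising leave-one-out allocation success. Canonical
axes are capped at (number of groups − 1).

## CWM trajectories

MAGs failing a 0.1% maximum-relative-abundance prevalence filter are
removed and rows re-closed. Per sample, `CWM_f = Σ pᵢ·MCI(i, f)`. Per
(function, treatment), the point estimate is the mean of per-individual
means and the interval a percentile bootstrap (default 2000 draws, level
0.90) resampling **individuals** with replacement — the individual, not
the sample, is the exchangeable unit; cage-level resampling is available
via `resample_unit="cage_id"` for cage-clustered designs. Non-overlapping
intervals between consecutive treatments are flagged as shifts with the
sign of the mean difference. This is a frequentist stand-in for a
posterior-interval rule: the estimand (community-weighted mean capacity)
and the decision rule (interval overlap) are retained, while hierarchical
Bayesian machinery is out of scope.

## Synthetic study generator

Defaults model a two-species captivity experiment at desk scale: a
high-richness archetype (60 MAGs) and a low-richness one (15 MAGs) —
scaled down from the hundreds-versus-dozens contrast of real
genome-resolved datasets to keep full-pipeline runs in seconds — with 12
individuals in 4 cages per species and five treatments sampled once per
individual in fixed order (Acclimation, Heat, Cold, Diet, Return).

* **Phylogeny**: Yule (pure-birth) trees, exponential waiting times; the
  two species' trees are joined at a common root for a single tip set.
* **Pathway DB**: 56 pathways in 14 functions (scaled down from a
  251-pathway/14-function reference layout), 2–6 steps, 1–3 alternatives,
  1–2 identifiers per combination, identifiers unique per combination.
* **Gene content**: per-gene two-state Markov evolution along the tree
  with switch rate `1/signal` (default signal 2.0, i.e. clade-conserved
  blocks); whole pathway blocks shared across all MAGs with probability
  `redundancy_level` (default 0.25). Completeness ~ U[0.7, 1.0]; observed
  gene sets are true sets thinned at rate (1 − completeness), exercising
  the completeness adjustment. Contamination ~ U[0, 0.05].
* **Abundances**: per-MAG baseline log abundances N(0, 1.5²), MAG-specific
  cage (σ = 0.2) and individual (σ = 0.3) random intercepts, per-sample
  log-normal noise (σ = 0.4), multinomial read sampling at depths
  U[50 000, 150 000]. Treatment effects are multiplicative on the latent
  scale so relative-abundance directionality is depth-invariant.
* **Injected signal**: the low-richness species carries a dominant
  responder MAG with coherent log-scale effects (+1.5 Heat, −2.5 Cold,
  +1.2 Diet) whose genome is completed for three injected functions while
  its neighbours are depleted in those genes, so community capacity
  tracks the responder. The high-richness species receives small
  *incoherent* per-individual effects (σ = 0.25) — compositional wobble
  with no directional mean. A null mode removes all effects. Ground truth
  (responder, effects, injected functions) is emitted for recovery tests.

Identical configuration and seed give a byte-identical bundle; all
randomness flows through spawned child generators of one seed.

What the generator does *not* emulate: zero-inflation beyond sampling
zeros (the analyses under test are abundance-weighted at q = 1 and
insensitive to rare-taxon handling), strain-level variation, read-level
artefacts, uneven cage sizes, and compositional covariance between
non-responder MAGs. Passing recovery tests therefore demonstrate that
the pipeline detects the modelled class of directional signals, not that
it is robust to every feature of real sequencing data.

## Calibration experiments

The test suite calibrates the two stochastic procedures:

* **Restricted-permutation PERMANOVA**: 500 null datasets (iid bivariate
  normal points, 10 individuals × 5 treatments, labels permuted within
  individuals, 199 permutations each); the rejection rate at α = 0.05
  must fall inside the 95% binomial envelope around 0.05.
* **Bootstrap CWM intervals**: 500 replicate studies of a single null
  low-richness species with a *fixed* baseline abundance profile, 24
  individuals (a complete five-point cohort at realistic field scale)
  and exchangeable individuals (no cage variance), against a
  1000-individual Monte-Carlo truth at the same profile; empirical
  coverage of the nominal 90% intervals must lie in [0.86, 0.94]
  (measured: ≈ 0.87).

The exchangeable design matches the interval's own assumption that
individuals are the iid resampling unit. This is a known limitation, not
a hidden one: when a cage-level variance component is present and
individuals are resampled ignoring it, the intervals undercover
(≈ 0.72–0.82 in the same experiment with cage σ = 0.2 over 4–8 cages);
`resample_unit="cage_id"` is the appropriate choice for such designs.
Percentile intervals at n = 24 also retain the usual slight small-sample
anticonservatism, which the band accommodates.

## Numerical conventions

`0·ln 0 = 0` throughout; zero-abundance MAGs are dropped per computation,
never globally. Beta values are validated against their theoretical
ranges with a 10⁻⁶ relative guard and clipped only within it. Distance
matrices must be symmetric to 10⁻¹⁰. Tie-breaks: CAP's m prefers the
smallest maximiser; permutation p-values use a 10⁻¹² tolerance when
comparing permuted statistics to the observed one so exact ties count in
favour of the null. Degenerate inputs (all-zero vectors, functionally
uniform communities, single-sample strata, single-individual treatments)
raise errors or warnings as documented in the respective docstrings
rather than returning silent NaNs.
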