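# Methods

This note documents the models, estimators, parameter choices and numerical
conventions behind `beaknest`, and states precisely what the synthetic-data
generator does and does not emulate.

## 1. Material coding

Descriptors are matched against a term → category lexicon
(`src/beaknest/data/material_lexicon.csv`) after normalization (lower-case,
whitespace collapsed). Matching is exact by design: fuzzy matching would make
coding irreproducible and misses unauditable. Unmapped terms are logged and
returned as *unknown*; they never contribute to a profile.

Per source, the primary-material candidate follows a fixed precedence: the
emphasized ("most commonly used") descriptor's category, else the single
category if only one is represented, else the category of the first
categorizable descriptor. Across sources, the primary is the unanimous
candidate or the sentinel `mixed`. The used set is the union of mapped
categories over all sources, so the binary use variables pool evidence even
when sources disagree about the primary. A species with no categorizable
descriptor in any source raises an explicit "omit" error at the
single-species level and is collected into an omission list at the corpus
level — never silently dropped. Cross-source ties among first-listed
materials are resolved by the same unanimity rule (any disagreement ⇒
`mixed`); this is one plausible convention, and it is applied uniformly.

## 2. Trait-evolution models

**Covariance construction.** For a rooted tree with branch lengths, the
Brownian-motion covariance `C[i,j]` is the root-to-MRCA path length of tips
i and j. A root (stem) edge, when present, is shared history and is added as
a constant to the whole matrix. The construction works on polytomies
directly (every cross-child tip pair at a node shares that node as MRCA), so
polytomies need no explicit zero-length resolution — the result is identical.

**Brownian motion.** ML estimates are closed-form GLS:
`z0 = (1'C⁻¹x)/(1'C⁻¹1)`, `σ² = (x−z0)'C⁻¹(x−z0)/n` (ML, not REML,
the common default of comparative-methods software). Cholesky factorization
with a scaled diagonal jitter (`1e-10 · mean diag`, applied only on
failure) handles the near-singular matrices produced by very short sister
branches; truly singular cases raise. A constant trait returns σ² = 0 with
infinite log-likelihood (the degenerate supremum).

**Equal-rates Mk.** One transition rate q over k states. The transition
probability has the Jukes–Cantor-like closed form
`P(stay) = 1/k + (k−1)/k·e^(−kqt)`, `P(to a specific other state) =
(1−e^(−kqt))/k`, so no matrix exponentials are needed. The likelihood is
computed by Felsenstein pruning with per-node rescaling and a uniform
(stationary) root prior; q is optimized on the log scale by bounded Brent
search over `[1e-8/h, 1e3/h]` (h = tree height), tolerance 1e-8. A single
observed state yields q = 0 with a warning. The level set can be declared
explicitly so states unobserved on a given tree keep their dimension.

**Pruning.** `prune_to_taxa` preserves all pairwise path lengths, and — via
the retained stem edge — the full covariance of the retained tips, hence the
trait-model likelihood. Without the stem correction, restricting to a
subclade would discard the shared root-to-MRCA depth and change BM
likelihoods.

**MCC consensus.** The consensus of a tree sample is the sample member
maximizing the product of its clades' sample frequencies (summed logs), with
each branch length replaced by the median length of the matching clade over
the trees containing it. Ties keep the earliest sample member. This is the
TreeAnnotator-style summary; by construction the consensus topology is
always a member of the sample.

## 3. Random forests and out-of-bag accuracy

The ensemble is scikit-learn's `RandomForestClassifier` with bootstrap
aggregation, `floor(sqrt(p))` features per split after one-hot encoding of
the categorical predictors (every declared level gets a column, so encodings
are stable across subsamples), and a config-supplied seed. 5000 trees is the
study-scale default; desk-scale runs pass 150–300.

Accuracy is out-of-bag: each species is predicted by majority vote of the
trees whose bootstrap excluded it. Species without any out-of-bag vote
(possible in tiny ensembles) are excluded from accuracy with a warning. The
report stores the observed-by-predicted confusion matrix; the overall
accuracy is exactly `100·trace/total` and per-class accuracies are row
proportions.

Contribution analysis refits the model once per predictor twice over
(leave-one-out → marginal contribution; single-predictor → independent
contribution) under the same seed, and reports the majority-class frequency
as the chance baseline. With correlated predictors, marginal contributions
of redundant variables are ≈ 0 while their independent contributions stay
high — both columns are needed to read importance correctly.

## 4. Bias controls

**Phylogenetic-simulation null.** Per topology: refit BM to each continuous
predictor and equal-rates Mk to each categorical predictor *on that
topology*, simulate one full replacement predictor set, refit the forest
against the observed labels, record out-of-bag accuracy. Labels are never
simulated. Predictors are simulated independently of one another (no
cross-predictor covariance); parameters are refitted per topology. Columns
that come out constant (e.g. σ² fitted as 0) are dropped with a warning
before the refit. The distribution over topologies is summarized by median
and IQR; the median was chosen for symmetry with the downsampling summary.
When several model families are evaluated, one simulated predictor set per
topology is shared across all of them, exactly as re-running every model on
one simulated dataset. Passing the observed predictors through unsimulated
reproduces the observed accuracy exactly — a no-op identity used as a
machinery test.

**Downsampling null.** Per replicate, every class is subsampled without
replacement to the smallest class size and the forest refitted; retained
rows are untouched. Already-balanced data short-circuits to the full model.
Requires the smallest class to have ≥ 2 members. Summary: median and IQR
over replicates (100 at study scale).

Both nulls derive replicate seeds from a spawned `SeedSequence`, so results
are reproducible per (seed, replicate-index).

## 5. Confirmatory phylogenetic logistic regression

Continuous inputs are standardized to mean 0, variance 1 with the sample
(ddof = 1) convention. The beak-morphospace PCA runs on the correlation
matrix by default (the five inputs mix millimetres and grams; the choice is
recorded in the result and togglable), with the deterministic sign
convention that each component's largest-magnitude loading is positive.

The phylogenetic logistic regression follows the estimating-equation
(Ives–Garland-style) formulation: marginally `logit P(y=1) = Xβ`, with
working residual correlation `R(α) = exp(−α·d_ij)` in patristic distance —
the stationary correlation of an Ornstein–Uhlenbeck process with attraction
α (large α ⇒ phylogenetic independence). β solves the logistic GEE by Fisher
scoring; α is profiled on the log scale by the Gaussian pseudo-likelihood of
the Pearson residuals, `½log|R| + (n/2)·log(e'R⁻¹e/n)`, over a range from
near-full correlation at the maximal distance to numerically zero
correlation at the minimal distance. A 1e-6 nugget keeps R invertible when
tips sit at near-zero distances. When the selected α leaves all residual
correlations below 1e-6 the fit is redone under the exact identity, so on a
star phylogeny the estimator coincides with ordinary logistic regression to
machine precision. Diverging linear predictors (|η| > 40) raise an explicit
separation error rather than returning silently inflated coefficients.

The reported log-likelihood is the Bernoulli likelihood at the fitted
probabilities and `AIC = 2k − 2ℓ` with k = coefficients + 1 for α; this is a
working-independence information criterion (the GEE has no true likelihood),
adequate for ranking nested candidate sets, and it is invariant to affine
rescaling of predictors because the fitted probabilities are. Model
selection reports ΔAIC against the best candidate and flags competitors with
ΔAIC > 2 as distinguishable; candidates within 2 units are reported as
statistically indistinguishable and never silently resolved. The candidate
list is configuration, not code (default: intercept-only, PC1, PC2,
PC1+PC2).

The companion simulator draws binary responses with exactly logistic
marginals coupled by a Gaussian copula with correlation `R(α)` — the model
class the estimator assumes — and is used for coefficient-recovery checks
(median estimates within 15% of truth at n = 500 over 50 replicates).

## 6. The synthetic world

`simulate_tree` draws pure-birth (Yule) trees conditioned on n extant tips.
The underlying simulator stops at the instant of the n-th speciation, which
leaves the newest sister pair at patristic distance exactly zero; the
generator therefore extends all tip branches by the memoryless waiting time
to the next speciation, giving a proper n-tip Yule sample that stays
ultrametric and has no duplicate tips.

`generate_dataset` builds, per configuration:

- **Continuous predictors**: `signal_mix·BM + (1−signal_mix)·noise` on the
  first tree, standardized, then mapped to positive measurement scales by a
  lognormal transform (bill lengths ~20–30 mm, body mass ~50 g median with
  broad spread — a realistic passerine-dominated spectrum). `signal_mix`
  defaults to 0.7, the moderately strong phylogenetic signal typical of
  avian morphometrics.
- **Categorical predictors**: equal-rates Mk on the same tree with rate
  `1.5/(k·height)`, i.e. a moderate expected amount of change per root-to-tip
  path regardless of the state count.
- **Labels**: multinomial-logit scores = effect_matrix × standardized
  predictors + class_bias + phylo_effect_sd × standardized latent BM traits
  (one per category) + Gumbel noise; primary = argmax. Extra used categories
  join the set with probability `0.5·0.4^rank` down the score ranking, so
  specialists and generalists both occur. The default class_bias reproduces
  the strong imbalance of real per-material sample sizes (fibre and grass
  abundant; mineral and binder rare, at roughly 1:20 relative frequency).

The latent phylogenetic effect enters the *scores*, not the predictors, so
ecological signal (effect_matrix), predictor phylogenetic signal
(signal_mix), and label phylogenetic signal (phylo_effect_sd) are
independently dialable — the property the null-calibration tests rely on.

What the generator does **not** emulate: the empirical covariance structure
among real beak dimensions (they are generated independently before the
logit), real trait–diet correlations, literature-sourcing noise (each
synthetic species gets one internally consistent source), and `mixed`
primaries (cross-source disagreement is never generated). Consequently, a
green test establishes that the estimators and nulls behave correctly in a
world with known structure — not that the package reproduces any real-data
accuracy value.

One calibration note: with labels driven by iid predictors through a
multinomial logit over several predictors, a random forest at n ≈ 500–600
tops out near 80–88% because the induced decision boundaries cut across
many dimensions. The "ecology-only" calibration world therefore uses a
single-predictor fan (category c scores `s·(a_c·x − a_c²/2)` with the a_c at
equal-mass quantiles), whose equal-frequency interval labels a forest learns
almost perfectly (>96% observed) while phylogenetic simulations on a star
tree stay at chance.

## 7. Pipeline conventions

Every stage failure aborts with the stage name and a nonzero exit status.
All randomness derives from the single run seed through spawned
`SeedSequence`s; reruns with the same config and seed produce byte-identical
CSV tables (the manifest records seed, config, package and Python versions,
and a config hash). Desk-scale defaults (200 forest trees, 20 topologies,
20 downsampling replicates) keep a 300-species end-to-end run to a few
minutes on one CPU; study-scale values (5000/100/100) are one flag away.

## 8. Known limitations

- The Mk rate is a single equal-rates parameter; ordered or asymmetric
  transition models are out of scope.
- No OU/EB or rate-heterogeneous continuous models; no divergence-time
  estimation.
- The GEE AIC is a quasi-criterion; absolute values are not comparable
  across response variables, only across candidate predictor sets for one
  response.
- The phylogenetic null simulates predictors independently; if real
  predictors co-vary strongly along the tree, the null may understate the
  accuracy attributable to phylogeny.
- `phylo_logistic` estimates α by a profile pseudo-likelihood; its α is a
  working parameter for the correlation structure, not a calibrated
  evolutionary rate, and frequently sits at the independence bound on data
  with weak signal (reported via `alpha_at_bound`).
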