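# beaknest

Phylogenetic comparative tools for asking whether avian **beak morphology
predicts nest-material use** — and how much of that predictive success is an
artifact of shared evolutionary history or of class-frequency imbalance.

The package is aimed at comparative biologists working with species-level
trait tables (beak measurements, body mass, hand-wing index, diet and habitat
categories), literature-derived nest-material descriptions, and posterior
samples of time-calibrated phylogenies.

## What it does

1. **Material coding** (`beaknest.materials`). Free-text material descriptors
   are mapped through an auditable lexicon onto seven categories — *binder,
   fibre, grass, leaf, mineral, silk, twig*. Each species gets the set of
   categories it uses, a single *primary* material (per-source precedence:
   the descriptor flagged as most commonly used ≻ the only category reported
   ≻ the first categorizable descriptor; cross-source disagreement ⇒
   *mixed*), and a *specialist* flag (exactly one used category).

2. **Random-forest models** (`beaknest.forest`). Three families over 12
   morpho-ecological predictors: one binary model per material, a multiclass
   primary-material model (with or without *mixed*), and a specialist-only
   model. Accuracy is always **out-of-bag**: each species is predicted by the
   trees whose bootstrap excluded it, so `accuracy = 100·tr(confusion)/n`
   needs no test split. Per-predictor *marginal* (full minus leave-one-out
   accuracy) and *independent* (single-predictor accuracy) contributions are
   reported against the majority-class chance baseline.

3. **Bias controls** (`beaknest.nulls`).
   - *Phylogenetic-simulation null*: per topology from a tree sample, each
     continuous predictor is refitted under Brownian motion
     (tip values ~ MVN(z₀·1, σ²C), C the shared-path-length matrix) and each
     categorical predictor under the equal-rates Mk model
     (P(stay) = 1/k + (k−1)/k·e^(−kqt)); a full replacement predictor set is
     simulated and the forest refitted against the *observed* labels.
     Simulated accuracy ≈ observed accuracy ⇒ the model's success is carried
     by phylogenetic signal alone.
   - *Downsampling null*: every class is subsampled to the smallest class
     size and the forest refitted; the median over replicates shows how much
     accuracy rests on majority guessing.

4. **Confirmatory phylogenetic GLMs** (`beaknest.pgls`). PCA of the four
   beak variables + body mass (PC1 ≈ size, PC2 ≈ width/depth-to-length
   shape), then phylogenetic logistic regression of binary material use on a
   maximum-clade-credibility consensus tree: logit E[y] = Xβ with residual
   working correlation exp(−α·d_ij) (the stationary Ornstein–Uhlenbeck
   correlation in patristic distance d_ij; larger α ⇒ weaker signal),
   estimated by generalized estimating equations. Candidate predictor sets
   are ranked by AIC with ΔAIC > 2 treated as a meaningful difference.

5. **Synthetic worlds** (`beaknest.synth`). Yule trees, predictors with
   tunable phylogenetic signal (BM/noise blend, Mk categoricals), and
   7-category labels from a multinomial logit with separately dialable
   ecological effects, latent phylogenetic effect, and class imbalance —
   so every claim above is testable without external databases.

## Worked example

```python
import numpy as np
from beaknest import synth, forest, nulls, pgls, phylo

ds = synth.generate_dataset(synth.SynthConfig(n_species=300, n_trees=20, seed=42))
rf = forest.RFConfig(n_trees=200, seed=42)

rep = forest.run_primary_model(ds.profiles, ds.predictors, rf)
print("primary OOB accuracy: %.1f%%" % rep.overall_accuracy)

y = ds.primary_labels
pn = nulls.phylo_null(y, ds.predictors, ds.trees[:20], rf, seed=42)
dn = nulls.downsample_null(y, ds.predictors, rf, n_reps=20, seed=42)
print("phylo null median: %.1f%%  downsample median: %.1f%%" % (pn.median, dn.median))
```

prints

```
primary OOB accuracy: 45.7%
phylo null median: 30.2%  downsample median: 23.4%
```

Read: the forest predicts the primary material of 45.7% of species from their
morphology and ecology (chance would be the largest class, grass, at ~26%).
Replacing the predictors with Brownian-motion/Mk simulations on the same
trees still yields 30.2% — a sizeable share of the success reflects
phylogenetic signal rather than ecology. Balancing the seven classes drops
accuracy to 23.4%, so part of the headline number is majority guessing.

The confirmatory track on the same data:

```python
from beaknest.predictors import BEAK_PREDICTORS

pca = pgls.beak_pca(ds.predictors[list(BEAK_PREDICTORS)])
design = pca.scores[["PC1", "PC2"]]
cons = phylo.prune_to_taxa(phylo.consensus_tree(ds.trees), set(design.index))
yb = forest.binary_labels(ds.profiles, "fibre").map({"used": 1, "not_used": 0})
print(pgls.select_model({"intercept_only": [], "size": ["PC1"],
                         "shape": ["PC2"], "size+shape": ["PC1", "PC2"]},
                        yb, design, cons)[["model", "aic", "delta_aic"]])
```

ranks `size` best (AIC 379.4) with `size+shape` indistinguishable
(ΔAIC 0.5 ≤ 2) and the intercept-only model decisively worse (ΔAIC 25.0):
beak size carries real information about fibre use in this synthetic world.

A full result bundle (Table-1-style five-column summary, confusion heat maps,
contribution tables, per-material model-selection tables, run manifest):

```bash
beaknest run-all --outdir results/demo --synthetic --n-species 300 --seed 42
```

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the complete pipeline from scratch on a reduced-scale synthetic world
derived from the seed — generation, material coding, all three forest
families, both nulls, contributions, and the phylogenetic GLM track — and
writes its JSON summary to `--out`.
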