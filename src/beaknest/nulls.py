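"""Bias-quantification nulls for the random-forest models.

Two procedures bound how much of a model's out-of-bag accuracy is explained by
confounds rather than by a predictor-response relationship:

* **Phylogenetic-simulation null** — per tree topology, Brownian-motion
  parameters are fitted to each continuous predictor and an equal-rates Mk
  rate to each categorical predictor; a full replacement predictor set is then
  simulated on that topology and the forest is refitted against the *observed*
  labels.  Simulated accuracy close to observed accuracy indicates that
  phylogenetic signal alone reproduces the predictive success; simulated
  accuracy near chance indicates shared history plays little role.  Labels
  are never simulated.

* **Downsampling null** — species from more frequent response classes are
  dropped at random until every class has the size of the smallest one, and
  the model is refitted; the median over replicates measures how much accuracy
  rests on class-frequency bias (majority guessing).

Both nulls summarize replicate accuracies by median and interquartile range
and are reproducible under (seed, replicate-index) pairs.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from beaknest.forest import RFConfig, fit_forest, report
from beaknest.phylo import (
    Phylogeny,
    TreeError,
    fit_bm,
    fit_mk,
    prune_to_taxa,
    simulate_bm,
    simulate_mk,
    tip_labels,
)
from beaknest.predictors import CATEGORICAL_LEVELS

logger = logging.getLogger(__name__)


@dataclass
class NullReport:
    """Replicate accuracies (percent) under one null, with median and IQR."""

    null_kind: str  # "phylogenetic" or "downsampled"
    accuracies: list[float]
    median: float
    iqr: tuple[float, float]
    n_replicates: int

    @classmethod
    def from_accuracies(cls, kind: str, accs: Sequence[float]) -> "NullReport":
        arr = np.asarray(list(accs), dtype=float)
        return cls(
            null_kind=kind,
            accuracies=arr.tolist(),
            median=float(np.median(arr)),
            iqr=(float(np.percentile(arr, 25)), float(np.percentile(arr, 75))),
            n_replicates=len(arr),
        )


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_predictor_set(
    predictors: pd.DataFrame,
    tree: Phylogeny,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """One replacement predictor table simulated on ``tree``.

    Each continuous column gets BM parameters refitted on this topology and a
    fresh BM draw; each categorical column gets a refitted equal-rates Mk rate
    and a fresh Mk draw over its declared level set.  Columns that come out
    constant (e.g. sigma2 fitted as 0) are still returned; downstream model
    code is expected to drop them.
    """
    rng = np.random.default_rng(seed)
    species = list(predictors.index)
    sim: dict[str, pd.Series] = {}
    for col in predictors.columns:
        obs = predictors[col]
        if col in CATEGORICAL_LEVELS:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mk = fit_mk(tree, obs, levels=CATEGORICAL_LEVELS[col])
            sim[col] = simulate_mk(tree, mk, n_reps=1, seed=rng)["rep0"].loc[species]
        else:
            bm = fit_bm(tree, obs.astype(float))
            sim[col] = simulate_bm(tree, bm, n_reps=1, seed=rng)["rep0"].loc[species]
    return pd.DataFrame(sim, index=species)


def _drop_constant(X: pd.DataFrame) -> pd.DataFrame:
    constant = [c for c in X.columns if X[c].nunique(dropna=False) <= 1]
    if constant:
        warnings.warn(f"dropping constant simulated predictors: {constant}")
        X = X.drop(columns=constant)
    return X


def phylo_null(
    labels: pd.Series,
    predictors: pd.DataFrame,
    trees: Sequence[Phylogeny],
    config: RFConfig = RFConfig(),
    seed: int | None = 0,
    simulate: bool = True,
) -> NullReport:
    """Phylogenetic-simulation null over a sample of topologies.

    Every species in the predictor table must be a tip of every tree (trees
    with extra tips are pruned).  ``simulate=False`` passes the observed
    predictors through unchanged — a no-op wrapper that reproduces the
    observed accuracy exactly, useful for validating the machinery.
    """
    species = set(predictors.index)
    root_ss = np.random.SeedSequence(seed)
    accs = []
    for i, (tree, ss) in enumerate(zip(trees, root_ss.spawn(len(trees)))):
        tips = set(tip_labels(tree))
        missing = species - tips
        if missing:
            raise TreeError(
                f"tree {i}: species missing from tips: {sorted(missing)[:5]}"
            )
        if tips != species:
            tree = prune_to_taxa(tree, species)
        if simulate:
            X = simulate_predictor_set(predictors, tree, seed=_child_seed(ss))
            X = _drop_constant(X)
        else:
            X = predictors
        fitted = fit_forest(X, labels, config)
        accs.append(report(fitted).overall_accuracy)
        logger.debug("phylo_null topology %d: %.2f%%", i, accs[-1])
    return NullReport.from_accuracies("phylogenetic", accs)


def phylo_null_multi(
    label_sets: dict[str, pd.Series],
    predictors: pd.DataFrame,
    trees: Sequence[Phylogeny],
    config: RFConfig = RFConfig(),
    seed: int | None = 0,
) -> dict[str, NullReport]:
    """Phylogenetic null for several model families at once.

    The per-topology predictor simulation depends only on the predictors and
    the tree, so one simulated predictor set per topology is shared by every
    label set (binary, primary, specialist ...), exactly as re-running all the
    forest models on one simulated dataset.
    """
    species = set(predictors.index)
    root_ss = np.random.SeedSequence(seed)
    accs: dict[str, list[float]] = {name: [] for name in label_sets}
    for i, (tree, ss) in enumerate(zip(trees, root_ss.spawn(len(trees)))):
        tips = set(tip_labels(tree))
        missing = species - tips
        if missing:
            raise TreeError(
                f"tree {i}: species missing from tips: {sorted(missing)[:5]}"
            )
        if tips != species:
            tree = prune_to_taxa(tree, species)
        X = _drop_constant(simulate_predictor_set(predictors, tree, seed=_child_seed(ss)))
        for name, labels in label_sets.items():
            fitted = fit_forest(X.loc[X.index.intersection(labels.index)], labels, config)
            accs[name].append(report(fitted).overall_accuracy)
    return {
        name: NullReport.from_accuracies("phylogenetic", a) for name, a in accs.items()
    }


def balanced_subsample(labels: pd.Series, seed) -> pd.Index:
    """Index of one class-balanced subsample: exactly min-class-size species
    drawn without replacement from every class."""
    counts = labels.value_counts()
    m = int(counts.min())
    rng = np.random.default_rng(seed)
    parts = []
    for cls in sorted(counts.index):
        members = labels.index[labels == cls].to_numpy()
        parts.append(rng.choice(members, size=m, replace=False))
    return pd.Index(np.concatenate(parts))


def downsample_null(
    labels: pd.Series,
    predictors: pd.DataFrame,
    config: RFConfig = RFConfig(),
    n_reps: int = 100,
    seed: int | None = 0,
) -> NullReport:
    """Class-balanced downsampling null.

    Per replicate, ``m`` species (the smallest class size) are sampled without
    replacement from every class and the forest is refitted on that balanced
    subset; retained rows are untouched.  Raises when the smallest class has
    fewer than two members.  When classes are already balanced every replicate
    uses the full data.
    """
    labels = labels.loc[labels.index.intersection(predictors.index)]
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("downsampling needs >= 2 classes")
    m = int(counts.min())
    if m < 2:
        raise ValueError(f"smallest class has {m} member(s); need >= 2")
    balanced = counts.nunique() == 1
    root_ss = np.random.SeedSequence(seed)
    accs = []
    for ss in root_ss.spawn(n_reps):
        keep = labels.index if balanced else balanced_subsample(labels, ss)
        fitted = fit_forest(predictors.loc[keep], labels.loc[keep], config)
        accs.append(report(fitted).overall_accuracy)
    return NullReport.from_accuracies("downsampled", accs)
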