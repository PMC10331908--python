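"""Random-forest models of nest-material use and their accuracy reports.

Three model families mirror the analysis design: one binary model per material
category (uses / does not use), a multiclass model of the primary material
(optionally including the ``mixed`` class), and the primary-material model
restricted to specialists.  Accuracy is always out-of-bag (OOB) accuracy: each
species is predicted by majority vote over the ensemble members whose
bootstrap did not contain it, so no separate test split is needed.

The ensemble is scikit-learn's :class:`RandomForestClassifier`; categorical
predictors are one-hot encoded (the encoding is recorded in the report), with
``floor(sqrt(p))`` features tried per split.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from beaknest.materials import CATEGORIES, MIXED, MaterialProfile
from beaknest.predictors import (
    ALL_PREDICTORS,
    drop_incomplete,
    encode_predictors,
    validate_predictor_frame,
)

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised for label/predictor configurations that cannot be modelled."""


@dataclass(frozen=True)
class RFConfig:
    """Forest settings: 5000 trees by default (desk-scale runs pass fewer),
    sqrt-of-encoded-features per split, explicit seed."""

    n_trees: int = 5000
    max_features: str | int | float = "sqrt"
    seed: int = 0
    predictor_subset: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")


@dataclass
class FittedForest:
    """A fitted ensemble with its out-of-bag predictions."""

    model: RandomForestClassifier = field(repr=False)
    species: list[str]
    observed: np.ndarray
    oob_predicted: np.ndarray  # dtype=object; None where no OOB vote exists
    classes: list[str]
    encoded_columns: list[str]
    n_dropped_missing: int
    config: RFConfig


@dataclass
class ClassifierReport:
    """OOB accuracy, per-class accuracy and confusion matrix for one model."""

    overall_accuracy: float  # percent
    per_class_accuracy: dict[str, float]  # percent, keyed by observed class
    confusion: pd.DataFrame  # counts; rows = observed, columns = predicted
    confusion_normalized: pd.DataFrame  # rows sum to 1
    n_per_class: dict[str, int]
    n_total: int
    n_without_oob: int
    encoding: str = "one-hot"


def _select_predictors(predictors: pd.DataFrame, config: RFConfig) -> pd.DataFrame:
    if config.predictor_subset is None:
        return predictors
    missing = set(config.predictor_subset) - set(predictors.columns)
    if missing:
        raise ModelError(f"predictor subset not in table: {sorted(missing)}")
    return predictors[list(config.predictor_subset)]


def fit_forest(
    predictors: pd.DataFrame,
    labels: pd.Series | Mapping[str, str],
    config: RFConfig = RFConfig(),
) -> FittedForest:
    """Fit a bootstrap-aggregated classification forest with OOB predictions.

    Species with missing predictor values are dropped (logged).  Raises
    :class:`ModelError` when fewer than two classes remain; warns when a class
    has fewer than two members.  Reproducible under ``config.seed``.
    """
    if not isinstance(labels, pd.Series):
        labels = pd.Series(dict(labels))
    predictors = _select_predictors(predictors, config)
    common = predictors.index.intersection(labels.index)
    if len(common) == 0:
        raise ModelError("predictors and labels share no species")
    X_raw = drop_incomplete(predictors.loc[common])
    n_dropped = len(common) - len(X_raw)
    y = labels.loc[X_raw.index].astype(str)

    counts = y.value_counts()
    if len(counts) < 2:
        raise ModelError(f"labels contain a single class: {counts.index.tolist()}")
    small = counts[counts < 2]
    if len(small):
        warnings.warn(f"classes with < 2 members: {small.index.tolist()}")

    X = encode_predictors(X_raw)
    rf = RandomForestClassifier(
        n_estimators=config.n_trees,
        max_features=config.max_features,
        oob_score=True,
        bootstrap=True,
        random_state=config.seed,
        n_jobs=1,
    )
    with warnings.catch_warnings():
        # small ensembles legitimately leave some rows without OOB votes;
        # those rows are handled explicitly below
        warnings.filterwarnings(
            "ignore", message="Some inputs do not have OOB scores"
        )
        warnings.filterwarnings("ignore", message="invalid value encountered")
        rf.fit(X.to_numpy(), y.to_numpy())

    votes = rf.oob_decision_function_
    has_oob = np.nan_to_num(votes).sum(axis=1) > 0
    pred = np.empty(len(y), dtype=object)
    pred[:] = None
    if has_oob.any():
        pred[has_oob] = rf.classes_[np.nan_to_num(votes[has_oob]).argmax(axis=1)]
    n_no_oob = int((~has_oob).sum())
    if n_no_oob:
        warnings.warn(
            f"{n_no_oob} species lack an out-of-bag prediction and are "
            "excluded from accuracy"
        )
    return FittedForest(
        model=rf,
        species=list(X_raw.index),
        observed=y.to_numpy(),
        oob_predicted=pred,
        classes=list(rf.classes_),
        encoded_columns=list(X.columns),
        n_dropped_missing=n_dropped,
        config=config,
    )


def report(fitted: FittedForest) -> ClassifierReport:
    """Summarize a fitted forest: OOB accuracy and confusion matrix.

    ``overall_accuracy = 100 * trace(confusion) / total``; the normalized
    confusion divides each row by the observed class sample size.
    """
    mask = np.array([p is not None for p in fitted.oob_predicted])
    obs = fitted.observed[mask]
    pred = fitted.oob_predicted[mask].astype(str)
    classes = fitted.classes
    conf = pd.DataFrame(0, index=classes, columns=classes, dtype=int)
    for o, p in zip(obs, pred):
        conf.loc[o, p] += 1
    total = int(conf.to_numpy().sum())
    trace = int(np.trace(conf.to_numpy()))
    overall = 100.0 * trace / total if total else float("nan")
    row_sums = conf.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = conf.div(row_sums.replace(0, np.nan), axis=0)
    per_class = {
        c: (100.0 * conf.loc[c, c] / row_sums[c]) if row_sums[c] else float("nan")
        for c in classes
    }
    return ClassifierReport(
        overall_accuracy=overall,
        per_class_accuracy=per_class,
        confusion=conf,
        confusion_normalized=norm,
        n_per_class={c: int(row_sums[c]) for c in classes},
        n_total=total,
        n_without_oob=int((~mask).sum()),
    )


def oob_accuracy(
    predictors: pd.DataFrame, labels: pd.Series, config: RFConfig
) -> float:
    """Convenience: fit and return percent OOB accuracy."""
    return report(fit_forest(predictors, labels, config)).overall_accuracy


# ---------------------------------------------------------------------------
# Label constructions for the three model families


def binary_labels(profiles: Sequence[MaterialProfile], category) -> pd.Series:
    return pd.Series(
        {p.species_id: "used" if category in p.used else "not_used" for p in profiles},
        name=f"uses_{category.value if hasattr(category, 'value') else category}",
    )


def primary_labels(
    profiles: Sequence[MaterialProfile], include_mixed: bool = True
) -> pd.Series:
    lab = {p.species_id: str(p.primary) for p in profiles}
    if not include_mixed:
        lab = {s: v for s, v in lab.items() if v != MIXED}
    return pd.Series(lab, name="primary")


def specialist_labels(profiles: Sequence[MaterialProfile]) -> pd.Series:
    return pd.Series(
        {p.species_id: str(p.primary) for p in profiles if p.specialist},
        name="primary",
    )


def run_binary_models(
    profiles: Sequence[MaterialProfile],
    predictors: pd.DataFrame,
    config: RFConfig = RFConfig(),
) -> dict[str, ClassifierReport]:
    """One two-class model per material category over all species.

    Categories used by no species or by every species cannot be modelled and
    are skipped with a warning.
    """
    predictors = validate_predictor_frame(predictors)
    reports: dict[str, ClassifierReport] = {}
    for cat in CATEGORIES:
        y = binary_labels(profiles, cat)
        n_used = (y == "used").sum()
        if n_used == 0 or n_used == len(y):
            warnings.warn(f"{cat.value}: used by {n_used}/{len(y)} species; skipped")
            continue
        reports[cat.value] = report(fit_forest(predictors, y, config))
    return reports


def run_primary_model(
    profiles: Sequence[MaterialProfile],
    predictors: pd.DataFrame,
    config: RFConfig = RFConfig(),
    include_mixed: bool = True,
) -> ClassifierReport:
    """Multiclass model of the primary material (7 classes, or 8 with mixed)."""
    predictors = validate_predictor_frame(predictors)
    y = primary_labels(profiles, include_mixed=include_mixed)
    return report(fit_forest(predictors, y, config))


def run_specialist_model(
    profiles: Sequence[MaterialProfile],
    predictors: pd.DataFrame,
    config: RFConfig = RFConfig(),
) -> ClassifierReport:
    """Primary-material model restricted to single-material specialists."""
    predictors = validate_predictor_frame(predictors)
    y = specialist_labels(profiles)
    counts = y.value_counts()
    if (counts >= 2).sum() < 2:
        raise ModelError(
            "specialist model needs >= 2 specialist classes with >= 2 members; "
            f"got {counts.to_dict()}"
        )
    return report(fit_forest(predictors, y, config))


def _labels_for_family(
    profiles: Sequence[MaterialProfile], model_family: str
) -> pd.Series:
    if model_family == "primary":
        return primary_labels(profiles)
    if model_family == "primary_no_mixed":
        return primary_labels(profiles, include_mixed=False)
    if model_family == "specialist":
        return specialist_labels(profiles)
    if model_family.startswith("binary:"):
        cat = model_family.split(":", 1)[1]
        return binary_labels(profiles, cat)
    raise ModelError(f"unknown model family: {model_family!r}")


def contribution_analysis(
    profiles: Sequence[MaterialProfile],
    predictors: pd.DataFrame,
    config: RFConfig = RFConfig(),
    model_family: str = "primary",
) -> pd.DataFrame:
    """Marginal and independent accuracy contribution of each predictor.

    For each of the 12 predictors: *marginal* = full-model accuracy minus the
    accuracy of the model refitted without that predictor; *independent* = the
    accuracy of a model containing only that predictor.  The majority-class
    frequency is reported alongside as the chance baseline.  All refits reuse
    ``config.seed``.
    """
    predictors = validate_predictor_frame(predictors)
    subset = list(config.predictor_subset or ALL_PREDICTORS)
    predictors = predictors[subset]
    config = RFConfig(
        n_trees=config.n_trees, max_features=config.max_features, seed=config.seed
    )
    y = _labels_for_family(profiles, model_family)
    full_acc = oob_accuracy(predictors, y, config)
    chance = 100.0 * y.value_counts(normalize=True).max()
    rows = []
    for pred in subset:
        without = [c for c in subset if c != pred]
        acc_without = oob_accuracy(predictors[without], y, config)
        acc_only = oob_accuracy(predictors[[pred]], y, config)
        rows.append(
            {
                "predictor": pred,
                "full_accuracy": full_acc,
                "marginal_contribution": full_acc - acc_without,
                "independent_accuracy": acc_only,
                "chance_accuracy": chance,
            }
        )
    return pd.DataFrame(rows).set_index("predictor")
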