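"""The 12-predictor schema shared by the models and the data generator.

Six continuous predictors (four beak measurements, body mass, hand-wing index)
and six categorical predictors (trophic level, trophic niche, trophic
lifestyle, habitat density, habitat, migration) with fixed level sets.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Continuous predictors and their units.
CONTINUOUS_PREDICTORS: tuple[str, ...] = (
    "bill_length_total_mm",
    "bill_length_nares_mm",
    "bill_width_nares_mm",
    "bill_depth_nares_mm",
    "body_mass_g",
    "hand_wing_index",
)

#: The four beak measurements plus body mass: the "naive" morphology subset
#: and the input of the beak-morphospace PCA.
BEAK_PREDICTORS: tuple[str, ...] = CONTINUOUS_PREDICTORS[:5]

#: Categorical predictors with their declared level sets.
CATEGORICAL_LEVELS: dict[str, tuple[str, ...]] = {
    "trophic_level": ("carnivore", "herbivore", "scavenger", "omnivore"),
    "trophic_niche": (
        "invertivore", "frugivore", "granivore", "nectarivore", "omnivore",
        "aquatic_predator", "aquatic_herbivore", "terrestrial_herbivore",
        "vertivore", "scavenger",
    ),
    "trophic_lifestyle": ("aerial", "aquatic", "generalist", "insessorial", "terrestrial"),
    "habitat_density": ("dense", "semi_open", "open"),
    "habitat": (
        "forest", "woodland", "shrubland", "grassland", "wetland", "marine",
        "coastal", "riverine", "desert", "rock", "human_modified",
    ),
    "migration": ("sedentary", "partial", "migratory"),
}

CATEGORICAL_PREDICTORS: tuple[str, ...] = tuple(CATEGORICAL_LEVELS)

ALL_PREDICTORS: tuple[str, ...] = CONTINUOUS_PREDICTORS + CATEGORICAL_PREDICTORS


class PredictorError(ValueError):
    """Raised for malformed predictor tables."""


def validate_predictor_frame(df: pd.DataFrame, strict_positive: bool = True) -> pd.DataFrame:
    """Validate a predictor table against the 12-predictor schema.

    Checks column presence, finiteness/positivity of masses and lengths, and
    that categorical values come from the declared level sets.  Returns the
    frame with columns in canonical order.
    """
    missing = set(ALL_PREDICTORS) - set(df.columns)
    if missing:
        raise PredictorError(f"missing predictor columns: {sorted(missing)}")
    out = df[list(ALL_PREDICTORS)].copy()
    cont = out[list(CONTINUOUS_PREDICTORS)].to_numpy(dtype=float)
    finite = np.isfinite(cont)
    if strict_positive and not (cont[finite] > 0).all():
        raise PredictorError("continuous predictors must be > 0 (lengths, mass)")
    for col, levels in CATEGORICAL_LEVELS.items():
        bad = set(out[col].dropna()) - set(levels)
        if bad:
            raise PredictorError(f"{col}: values outside declared levels: {sorted(bad)}")
    return out


def encode_predictors(df: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode the categorical predictors for a numeric-matrix model.

    Every declared level gets a column (even if unobserved), so encodings are
    stable across subsamples of the same table.
    """
    parts = []
    for col in df.columns:
        if col in CATEGORICAL_LEVELS:
            cat = pd.Categorical(df[col], categories=CATEGORICAL_LEVELS[col])
            dummies = pd.get_dummies(cat, prefix=col, dtype=float)
            dummies.index = df.index
            parts.append(dummies)
        else:
            parts.append(df[[col]].astype(float))
    return pd.concat(parts, axis=1)


def drop_incomplete(df: pd.DataFrame) -> pd.DataFrame:
    """Drop species with any missing predictor value, logging the count."""
    complete = df.dropna()
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.warning("dropped %d species with missing predictor values", n_dropped)
    return complete
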