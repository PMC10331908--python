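"""Synthetic trees, predictors and material labels for end-to-end testing.

The generator emulates the statistical structure the analysis assumes, at a
configurable scale, so that every downstream stage (random forests, the
phylogenetic-simulation null, the downsampling null, phylogenetic logistic
regression) can be exercised without any external database:

* a sample of pure-birth (Yule) ultrametric trees;
* six continuous predictors, each a ``signal_mix``-weighted blend of a
  Brownian-motion trait on the first tree and independent Gaussian noise,
  mapped onto positive measurement scales (mm, g) via a lognormal transform;
* six categorical predictors evolved under the equal-rates Mk model;
* seven-category material labels from a multinomial logit: per-category scores
  are a linear map of the standardized predictors (``effect_matrix``) plus
  per-category intercepts (``class_bias``, controlling frequency imbalance)
  plus a latent Brownian-motion effect (``phylo_effect_sd``) plus Gumbel
  noise; the primary material is the argmax, and extra used categories are
  drawn with probability decaying in score rank so both specialists and
  generalists occur.

The latent phylogenetic effect enters the category scores rather than the
predictors, so "accuracy driven by phylogeny" and "accuracy driven by
ecology" can be dialed independently.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from dendropy.simulate import treesim

from beaknest.materials import CATEGORIES, MaterialCategory, MaterialProfile
from beaknest.phylo import BMParams, MkParams, Phylogeny, simulate_bm, simulate_mk
from beaknest.predictors import (
    ALL_PREDICTORS,
    CATEGORICAL_LEVELS,
    CONTINUOUS_PREDICTORS,
    validate_predictor_frame,
)

N_CATEGORIES = len(CATEGORIES)

#: Lognormal location/scale used to map standardized traits onto measurement
#: units (typical small-to-mid-sized bird: ~30 mm bill, ~50 g body mass).
_MEASUREMENT_SCALES: dict[str, tuple[float, float]] = {
    "bill_length_total_mm": (3.4, 0.5),
    "bill_length_nares_mm": (3.0, 0.5),
    "bill_width_nares_mm": (1.9, 0.4),
    "bill_depth_nares_mm": (2.0, 0.4),
    "body_mass_g": (3.9, 1.0),
    "hand_wing_index": (3.2, 0.4),
}


def _default_effect_matrix() -> np.ndarray:
    """Each category loads on one continuous predictor (category i on
    predictor i mod 6), giving the forest learnable but non-trivial
    structure."""
    E = np.zeros((N_CATEGORIES, len(ALL_PREDICTORS)))
    for c in range(N_CATEGORIES):
        E[c, c % len(CONTINUOUS_PREDICTORS)] = 1.5
    return E


def _default_class_bias() -> np.ndarray:
    """Intercepts giving a strongly imbalanced category spectrum, shaped like
    the per-material sample sizes of a global nest-material database (rare
    mineral/binder use, abundant fibre/grass use)."""
    counts = np.array([409.0, 3989.0, 3661.0, 2185.0, 186.0, 991.0, 2776.0])
    bias = np.log(counts / counts.sum())
    return bias - bias.mean()


@dataclass
class SynthConfig:
    """Configuration of the synthetic world.

    Defaults give a 500-species sample with moderately strong phylogenetic
    signal in the predictors, an ecological effect on material choice, a
    latent phylogenetic effect of comparable magnitude, and class imbalance
    mirroring real per-material sample sizes.
    """

    n_species: int = 500
    n_trees: int = 100
    birth_rate: float = 1.0
    signal_mix: float | Mapping[str, float] = 0.7
    effect_matrix: np.ndarray | None = None
    phylo_effect_sd: float = 1.0
    class_bias: np.ndarray | None = None
    mk_rate_scale: float = 1.5
    extra_material_p: float = 0.5
    extra_material_decay: float = 0.4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise ValueError("n_species must be >= 3")
        if self.n_trees < 1 or self.birth_rate <= 0:
            raise ValueError("n_trees >= 1 and birth_rate > 0 required")
        if self.phylo_effect_sd < 0 or self.mk_rate_scale < 0:
            raise ValueError("rates and standard deviations must be >= 0")
        if self.effect_matrix is not None:
            self.effect_matrix = np.asarray(self.effect_matrix, dtype=float)
            if self.effect_matrix.shape != (N_CATEGORIES, len(ALL_PREDICTORS)):
                raise ValueError(
                    f"effect_matrix must be {N_CATEGORIES} x {len(ALL_PREDICTORS)}"
                )
        if self.class_bias is not None:
            self.class_bias = np.asarray(self.class_bias, dtype=float)
            if self.class_bias.shape != (N_CATEGORIES,):
                raise ValueError(f"class_bias must have {N_CATEGORIES} entries")
        for w in self._signal_weights().values():
            if not 0.0 <= w <= 1.0:
                raise ValueError("signal_mix weights must lie in [0, 1]")

    def _signal_weights(self) -> dict[str, float]:
        if isinstance(self.signal_mix, Mapping):
            return {c: float(self.signal_mix.get(c, 0.0)) for c in CONTINUOUS_PREDICTORS}
        return {c: float(self.signal_mix) for c in CONTINUOUS_PREDICTORS}

    def resolved_effect_matrix(self) -> np.ndarray:
        return self.effect_matrix if self.effect_matrix is not None else _default_effect_matrix()

    def resolved_class_bias(self) -> np.ndarray:
        return self.class_bias if self.class_bias is not None else _default_class_bias()

    def to_yaml(self, path) -> None:
        d = {
            "n_species": self.n_species, "n_trees": self.n_trees,
            "birth_rate": self.birth_rate,
            "signal_mix": dict(self.signal_mix) if isinstance(self.signal_mix, Mapping)
            else self.signal_mix,
            "effect_matrix": None if self.effect_matrix is None
            else self.effect_matrix.tolist(),
            "phylo_effect_sd": self.phylo_effect_sd,
            "class_bias": None if self.class_bias is None else self.class_bias.tolist(),
            "mk_rate_scale": self.mk_rate_scale,
            "extra_material_p": self.extra_material_p,
            "extra_material_decay": self.extra_material_decay,
            "seed": self.seed,
        }
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SynthConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        return cls(**d)


@dataclass
class SynthDataset:
    """A generated world: trees, predictor table, material profiles."""

    trees: list[Phylogeny]
    predictors: pd.DataFrame
    profiles: list[MaterialProfile]
    scores: pd.DataFrame = field(repr=False, default=None)

    def __iter__(self):
        return iter((self.trees, self.predictors, self.profiles))

    @property
    def primary_labels(self) -> pd.Series:
        return pd.Series(
            {p.species_id: str(p.primary) for p in self.profiles}, name="primary"
        ).loc[self.predictors.index]


def _child_seed(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def simulate_tree(n_species: int, birth_rate: float = 1.0, seed: int | None = None) -> Phylogeny:
    """Simulate a pure-birth (Yule) ultrametric tree with exactly
    ``n_species`` extant tips, labelled sp0001..spN."""
    if n_species < 3:
        raise ValueError("n_species must be >= 3")
    rng = random.Random(seed)
    tree = treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0,
        num_extant_tips=n_species, rng=rng,
    )
    # the simulator stops at the instant of the n-th speciation, leaving the
    # newest sister pair at patristic distance zero; grow all tips by the
    # (memoryless) waiting time to the next speciation so the sample is a
    # proper n-tip Yule tree and remains ultrametric
    extra = rng.expovariate(n_species * birth_rate)
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    width = max(4, len(str(n_species)))
    for i, leaf in enumerate(tree.leaf_node_iter(), start=1):
        leaf.taxon.label = f"sp{i:0{width}d}"
    return tree


def _tree_height(tree: Phylogeny) -> float:
    tree.calc_node_root_distances(return_leaf_distances_only=False)
    return max(lf.root_distance for lf in tree.leaf_node_iter())


def generate_dataset(config: SynthConfig) -> SynthDataset:
    """Generate (trees, predictors, material profiles) under ``config``.

    Bit-reproducible for a fixed config: every random stream derives from
    ``config.seed`` through a spawned seed sequence.
    """
    root_ss = np.random.SeedSequence(config.seed)
    ss_trees, ss_cont, ss_cat, ss_latent, ss_labels, ss_extra = root_ss.spawn(6)

    trees = [
        simulate_tree(config.n_species, config.birth_rate, seed=_child_seed(ss))
        for ss in ss_trees.spawn(config.n_trees)
    ]
    tree = trees[0]
    species = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
    n = len(species)
    height = _tree_height(tree)

    # continuous predictors: signal_mix * BM + (1 - signal_mix) * iid noise,
    # standardized, then mapped to a positive measurement scale
    rng_cont = np.random.default_rng(ss_cont)
    weights = config._signal_weights()
    bm_unit = BMParams(sigma2=1.0 / height, z0=0.0)  # unit-variance tip traits
    z_cont = {}
    data = {}
    for col in CONTINUOUS_PREDICTORS:
        b = simulate_bm(tree, bm_unit, n_reps=1, seed=rng_cont)["rep0"].loc[species]
        b = (b - b.mean()) / b.std(ddof=0)
        e = pd.Series(rng_cont.normal(size=n), index=species)
        w = weights[col]
        raw = w * b + (1.0 - w) * e
        z = (raw - raw.mean()) / raw.std(ddof=0)
        z_cont[col] = z
        mu, s = _MEASUREMENT_SCALES[col]
        data[col] = np.exp(mu + s * z)

    # categorical predictors under equal-rates Mk; rate scaled so the expected
    # amount of change per root-to-tip path is moderate for every state count
    rng_cat = np.random.default_rng(ss_cat)
    z_cat = {}
    for col, levels in CATEGORICAL_LEVELS.items():
        k = len(levels)
        q = config.mk_rate_scale / (k * height)
        params = MkParams(k=k, q=q, levels=tuple(levels))
        states = simulate_mk(tree, params, n_reps=1, seed=rng_cat)["rep0"].loc[species]
        data[col] = states
        codes = states.map({lv: i for i, lv in enumerate(levels)}).astype(float)
        sd = codes.std(ddof=0)
        z_cat[col] = (codes - codes.mean()) / sd if sd > 0 else codes * 0.0

    predictors = validate_predictor_frame(pd.DataFrame(data, index=species))

    # category scores: ecological effect + intercepts + latent BM + Gumbel
    Z = pd.DataFrame({**z_cont, **z_cat})[list(ALL_PREDICTORS)].to_numpy()
    E = config.resolved_effect_matrix()
    bias = config.resolved_class_bias()
    scores = Z @ E.T + bias[None, :]
    if config.phylo_effect_sd > 0:
        rng_latent = np.random.default_rng(ss_latent)
        for c in range(N_CATEGORIES):
            b = simulate_bm(tree, bm_unit, n_reps=1, seed=rng_latent)["rep0"].loc[species]
            b = (b - b.mean()) / b.std(ddof=0)
            scores[:, c] += config.phylo_effect_sd * b.to_numpy()

    rng_labels = np.random.default_rng(ss_labels)
    gumbel = rng_labels.gumbel(size=scores.shape)
    noisy = scores + gumbel
    primary_idx = noisy.argmax(axis=1)

    # used set: primary plus extras with probability decaying in score rank
    rng_extra = np.random.default_rng(ss_extra)
    profiles = []
    for i, sp in enumerate(species):
        order = np.argsort(-noisy[i])
        used = {CATEGORIES[primary_idx[i]]}
        rank = 0
        for c in order:
            if c == primary_idx[i]:
                continue
            p_inc = config.extra_material_p * config.extra_material_decay**rank
            if rng_extra.random() < p_inc:
                used.add(CATEGORIES[c])
            rank += 1
        profiles.append(
            MaterialProfile(
                species_id=sp,
                used=frozenset(used),
                primary=CATEGORIES[primary_idx[i]],
                specialist=len(used) == 1,
            )
        )

    score_df = pd.DataFrame(scores, index=species, columns=[c.value for c in CATEGORIES])
    return SynthDataset(trees=trees, predictors=predictors, profiles=profiles, scores=score_df)


#: Canonical descriptor term used when writing a synthetic source table.
_CATEGORY_TERMS: dict[MaterialCategory, str] = {
    MaterialCategory.BINDER: "mud",
    MaterialCategory.FIBRE: "feathers",
    MaterialCategory.GRASS: "grass",
    MaterialCategory.LEAF: "leaves",
    MaterialCategory.MINERAL: "pebbles",
    MaterialCategory.SILK: "spider silk",
    MaterialCategory.TWIG: "twigs",
}


def profiles_to_source_table(profiles: Sequence[MaterialProfile]) -> pd.DataFrame:
    """Render profiles as a synthetic literature-source table.

    One source per species; descriptors are canonical lexicon terms for the
    used categories with the primary's term listed first and emphasized, so
    material coding round-trips the profiles exactly.
    """
    rows = []
    for p in profiles:
        ordered = [p.primary] + sorted(
            (c for c in p.used if c != p.primary), key=lambda c: c.value
        )
        terms = [_CATEGORY_TERMS[c] for c in ordered]
        rows.append(
            {
                "species_id": p.species_id,
                "source_id": "synthetic",
                "descriptors": ";".join(terms),
                "emphasized": terms[0],
            }
        )
    return pd.DataFrame(rows)


def write_dataset(ds: SynthDataset, outdir) -> dict[str, str]:
    """Write the dataset in the same formats the real-data entry point
    consumes: traits CSV, materials source CSV, multi-tree Newick."""
    from pathlib import Path

    from beaknest.phylo import write_newick_trees

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "traits": str(outdir / "traits.csv"),
        "materials": str(outdir / "materials.csv"),
        "trees": str(outdir / "trees.nwk"),
    }
    ds.predictors.rename_axis("species_id").to_csv(paths["traits"])
    profiles_to_source_table(ds.profiles).to_csv(paths["materials"], index=False)
    write_newick_trees(ds.trees, paths["trees"])
    return paths
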