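"""Coding of nest-material descriptions into seven material categories.

Free-text material descriptors (e.g. "mud", "spider silk", "twigs") are mapped
through an editable lexicon onto seven categories: binder (adhesive matrix such
as mud or saliva), fibre (soft strands such as feathers, fur, moss), grass
(filamentous grass-like material including seaweed and algae), leaf, mineral
(hard inorganic items), silk and twig (woody elements).  Each species is then
assigned the set of categories it is known to use, a single "primary" material
(or ``mixed`` when literature sources disagree), and a specialist flag (exactly
one used category).

Matching is exact on normalized tokens (lower-cased, whitespace-collapsed); no
fuzzy matching is attempted, so every miss is auditable.  Terms that fail to
map are logged and reported as unknown, never guessed.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel primary value for species whose sources disagree.
MIXED = "mixed"


class MaterialCategory(str, Enum):
    """The seven nest-material categories."""

    BINDER = "binder"
    FIBRE = "fibre"
    GRASS = "grass"
    LEAF = "leaf"
    MINERAL = "mineral"
    SILK = "silk"
    TWIG = "twig"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES: tuple[MaterialCategory, ...] = tuple(MaterialCategory)


class MaterialCodingError(ValueError):
    """Raised for invalid material-coding inputs."""


class NoScorableRecordsError(MaterialCodingError):
    """No source record for the species contains a categorizable descriptor.

    Mirrors the study design of omitting species with ambiguous or missing
    material descriptions from all downstream models; callers must handle the
    omission explicitly rather than dropping the species silently.
    """


def normalize_term(term: str) -> str:
    """Lower-case and collapse internal whitespace."""
    return " ".join(term.strip().lower().split())


def load_lexicon(path=None) -> dict[str, MaterialCategory]:
    """Load a term -> category lexicon from a two-column CSV.

    With no ``path``, the packaged default lexicon is used.  It is seeded with
    the exemplar terms of each category definition (mud, sand, saliva, peat,
    droppings -> binder; feathers, fur, hair, plant down, moss, fern, fungi,
    rootlets -> fibre; ...) plus obvious singular/plural variants.
    """
    if path is None:
        ref = resources.files("beaknest").joinpath("data/material_lexicon.csv")
        with ref.open("r", encoding="utf-8") as fh:
            return _parse_lexicon(fh)
    with open(path, "r", encoding="utf-8") as fh:
        return _parse_lexicon(fh)


def _parse_lexicon(fh) -> dict[str, MaterialCategory]:
    reader = csv.DictReader(fh)
    lex: dict[str, MaterialCategory] = {}
    for row in reader:
        term = normalize_term(row["term"])
        cat = MaterialCategory(row["category"].strip().lower())
        if term in lex and lex[term] is not cat:
            raise MaterialCodingError(
                f"lexicon maps {term!r} to both {lex[term]} and {cat}"
            )
        lex[term] = cat
    return lex


def categorize_material(
    descriptor: str, lexicon: Mapping[str, MaterialCategory]
) -> MaterialCategory | None:
    """Map one free-text descriptor to a material category.

    Returns ``None`` (unknown) for terms absent from the lexicon; unknown
    descriptors are logged so coding gaps can be audited.  Empty descriptors
    are an input error.
    """
    term = normalize_term(descriptor)
    if not term:
        raise MaterialCodingError("empty material descriptor")
    cat = lexicon.get(term)
    if cat is None:
        logger.warning("unmapped material descriptor: %r", descriptor)
    return cat


@dataclass(frozen=True)
class SourceDescription:
    """One literature source's material description for one species."""

    species_id: str
    source_id: str
    descriptors: tuple[str, ...]
    emphasized_descriptor: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "descriptors", tuple(self.descriptors))
        if not self.descriptors:
            raise MaterialCodingError(
                f"{self.species_id}/{self.source_id}: no descriptors"
            )
        if self.emphasized_descriptor is not None:
            norm = [normalize_term(d) for d in self.descriptors]
            if normalize_term(self.emphasized_descriptor) not in norm:
                raise MaterialCodingError(
                    f"{self.species_id}/{self.source_id}: emphasized descriptor "
                    f"{self.emphasized_descriptor!r} not among descriptors"
                )


@dataclass(frozen=True)
class MaterialProfile:
    """Resolved material use for one species."""

    species_id: str
    used: frozenset[MaterialCategory]
    primary: MaterialCategory | str  # a category, or the MIXED sentinel
    specialist: bool = field(default=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "used", frozenset(self.used))
        if not self.used:
            raise MaterialCodingError(f"{self.species_id}: empty used set")
        if self.primary != MIXED and self.primary not in self.used:
            raise MaterialCodingError(
                f"{self.species_id}: primary {self.primary} not in used set"
            )
        if self.specialist != (len(self.used) == 1):
            raise MaterialCodingError(
                f"{self.species_id}: specialist flag inconsistent with used set"
            )


def _source_candidate(
    record: SourceDescription, lexicon: Mapping[str, MaterialCategory]
) -> tuple[MaterialCategory | None, list[MaterialCategory]]:
    """Per-source primary candidate and the list of mapped categories.

    The candidate is, in order of precedence: the category of the descriptor
    the source flags as most commonly used; the single category if only one is
    represented; otherwise the category of the first categorizable descriptor.
    """
    cats = [
        c for d in record.descriptors if (c := categorize_material(d, lexicon))
    ]
    if not cats:
        return None, []
    if record.emphasized_descriptor is not None:
        emph = categorize_material(record.emphasized_descriptor, lexicon)
        if emph is not None:
            return emph, cats
    if len(set(cats)) == 1:
        return cats[0], cats
    return cats[0], cats


def resolve_primary(
    records: Sequence[SourceDescription],
    lexicon: Mapping[str, MaterialCategory],
) -> MaterialProfile:
    """Resolve one species' material profile from its source records.

    The used set is the union of mapped categories over all sources.  The
    primary material is the per-source candidate if all sources agree, and the
    ``mixed`` sentinel otherwise.  Raises :class:`NoScorableRecordsError` when
    no source yields a single categorizable descriptor ("omit" species).
    """
    if not records:
        raise MaterialCodingError("no source records supplied")
    species = {r.species_id for r in records}
    if len(species) != 1:
        raise MaterialCodingError(f"records span multiple species: {sorted(species)}")
    species_id = records[0].species_id

    candidates: list[MaterialCategory] = []
    used: set[MaterialCategory] = set()
    for rec in records:
        cand, cats = _source_candidate(rec, lexicon)
        if cand is None:
            continue
        candidates.append(cand)
        used.update(cats)
    if not candidates:
        raise NoScorableRecordsError(
            f"{species_id}: no categorizable material descriptor in any source"
        )
    primary: MaterialCategory | str
    primary = candidates[0] if len(set(candidates)) == 1 else MIXED
    return MaterialProfile(
        species_id=species_id,
        used=frozenset(used),
        primary=primary,
        specialist=len(used) == 1,
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def read_source_table(path) -> list[SourceDescription]:
    """Read source descriptions from a delimited file.

    Expected columns: ``species_id``, ``source_id``, ``descriptors``
    (semicolon-separated terms) and optionally ``emphasized`` (a term from the
    descriptor list, blank if the source flags none).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"species_id", "source_id", "descriptors"}
    missing = required - set(df.columns)
    if missing:
        raise MaterialCodingError(f"source table missing columns: {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        terms = tuple(t for t in (s.strip() for s in row.descriptors.split(";")) if t)
        emph = getattr(row, "emphasized", "") or None
        records.append(
            SourceDescription(
                species_id=row.species_id,
                source_id=row.source_id,
                descriptors=terms,
                emphasized_descriptor=emph,
            )
        )
    return records


def code_materials(
    records: Iterable[SourceDescription],
    lexicon: Mapping[str, MaterialCategory] | None = None,
) -> tuple[list[MaterialProfile], list[str]]:
    """Code a whole corpus, grouping records by species.

    Returns the resolved profiles plus the list of omitted species (those with
    no categorizable descriptor in any source).
    """
    if lexicon is None:
        lexicon = load_lexicon()
    by_species: dict[str, list[SourceDescription]] = {}
    for rec in records:
        by_species.setdefault(rec.species_id, []).append(rec)
    profiles, omitted = [], []
    for species_id, recs in by_species.items():
        try:
            profiles.append(resolve_primary(recs, lexicon))
        except NoScorableRecordsError:
            logger.warning("omitting species with no scorable material: %s", species_id)
            omitted.append(species_id)
    return profiles, omitted


def profiles_to_frame(profiles: Sequence[MaterialProfile]) -> pd.DataFrame:
    """Tabulate profiles: 7 binary used-category columns, primary, specialist."""
    rows = []
    for p in profiles:
        row: dict[str, object] = {"species_id": p.species_id}
        for cat in CATEGORIES:
            row[f"used_{cat.value}"] = int(cat in p.used)
        row["primary"] = str(p.primary)
        row["specialist"] = p.specialist
        rows.append(row)
    return pd.DataFrame(rows).set_index("species_id").sort_index()
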