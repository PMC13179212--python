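"""Fuzzy (multi-category) trait coding for species-by-trait tables.

Reef-fish trait compilations assign each species one *or more* categories
per categorical trait (e.g. a barracuda occupies near-surface, mid-water
and near-bottom positions).  For multivariate analyses each trait is
spread into one binary column per category, and every column is weighted
by the inverse of the number of categories in its trait so that traits
with many categories do not dominate distance computations.  Species
sharing an identical binary signature collapse into a single *functional
entity*, the unit of functional richness and redundancy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TraitTable",
    "BinaryTraitMatrix",
    "FunctionalEntity",
    "expand_traits",
    "derive_entities",
    "entity_redundancy",
]


def _canon(label: str) -> str:
    """Canonical form used for matching labels: trimmed and case-folded."""
    return label.strip().casefold()


@dataclass
class TraitTable:
    """Species × categorical-trait table with multi-valued cells.

    Parameters
    ----------
    schema :
        Mapping trait name -> ordered sequence of category labels.  The
        declaration order fixes the column order of any derived binary
        matrix.
    assignments :
        Mapping species id -> {trait name -> set of category labels}.
        Every set must be non-empty and drawn from the trait's declared
        categories.
    taxonomy :
        Optional mapping species id -> (genus, family).
    """

    schema: dict[str, tuple[str, ...]]
    assignments: dict[str, dict[str, frozenset[str]]]
    taxonomy: dict[str, tuple[str, str]] | None = None

    # canonical label -> declared label, per trait (built on init)
    _canon_maps: dict[str, dict[str, str]] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.schema = {t: tuple(cats) for t, cats in self.schema.items()}
        self._canon_maps = {
            t: {_canon(c): c for c in cats} for t, cats in self.schema.items()
        }
        clean: dict[str, dict[str, frozenset[str]]] = {}
        for sp, traits in self.assignments.items():
            row: dict[str, frozenset[str]] = {}
            for trait, cats in traits.items():
                if trait not in self.schema:
                    raise ValueError(f"species {sp!r}: unknown trait {trait!r}")
                resolved = []
                for c in cats:
                    key = _canon(c)
                    if key not in self._canon_maps[trait]:
                        raise ValueError(
                            f"species {sp!r}, trait {trait!r}: unknown "
                            f"category label {c!r}"
                        )
                    resolved.append(self._canon_maps[trait][key])
                row[trait] = frozenset(resolved)
            clean[sp] = row
        self.assignments = clean

    @property
    def species(self) -> list[str]:
        return list(self.assignments)

    @property
    def traits(self) -> list[str]:
        return list(self.schema)

    def genus(self, species: str) -> str | None:
        if self.taxonomy is None or species not in self.taxonomy:
            return None
        return self.taxonomy[species][0]

    def family(self, species: str) -> str | None:
        if self.taxonomy is None or species not in self.taxonomy:
            return None
        return self.taxonomy[species][1]


@dataclass
class BinaryTraitMatrix:
    """Species × (trait, category) indicator matrix with column weights.

    ``data`` has a two-level column index (trait, category); ``weights``
    is aligned with the columns and equals 1 / (number of categories in
    the column's trait), so the weights of one trait's block sum to 1.
    """

    data: pd.DataFrame
    weights: pd.Series

    def __post_init__(self) -> None:
        if not self.data.columns.equals(self.weights.index):
            raise ValueError("weights must be indexed by the data columns")
        if (self.weights <= 0).any():
            raise ValueError("column weights must be positive")

    @property
    def species(self) -> list[str]:
        return list(self.data.index)

    @property
    def traits(self) -> list[str]:
        return list(dict.fromkeys(self.data.columns.get_level_values(0)))

    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def row_signature(self, species: str) -> tuple[int, ...]:
        return tuple(int(v) for v in self.data.loc[species])

    def subset(self, species: Sequence[str]) -> "BinaryTraitMatrix":
        return BinaryTraitMatrix(self.data.loc[list(species)], self.weights)

    def to_table(self, taxonomy: dict[str, tuple[str, str]] | None = None) -> TraitTable:
        """Collapse the binary coding back to a categorical trait table."""
        schema: dict[str, tuple[str, ...]] = {}
        for trait, cat in self.data.columns:
            schema.setdefault(trait, ())
            schema[trait] = schema[trait] + (cat,)
        assignments = {}
        for sp in self.data.index:
            row = self.data.loc[sp]
            assignments[sp] = {
                trait: frozenset(
                    cat for (t, cat) in self.data.columns if t == trait and row[(t, cat)]
                )
                for trait in schema
            }
        return TraitTable(schema=schema, assignments=assignments, taxonomy=taxonomy)


@dataclass(frozen=True)
class FunctionalEntity:
    """A unique binary trait signature and the species carrying it."""

    entity_id: str
    signature: tuple[int, ...]
    members: frozenset[str]


def expand_traits(
    table: TraitTable, traits_to_use: Sequence[str] | None = None
) -> BinaryTraitMatrix:
    """Spread categorical traits into weighted binary indicator columns.

    Column order is deterministic: traits in the order requested (or
    declared), categories in declaration order.  Each column's weight is
    the inverse of the number of categories in its trait; excluding a
    trait simply removes its columns.

    Raises
    ------
    ValueError
        If a species lacks any category for a requested trait, or if a
        requested trait is not in the schema.
    """
    traits = list(traits_to_use) if traits_to_use is not None else list(table.schema)
    for t in traits:
        if t not in table.schema:
            raise ValueError(f"trait {t!r} not declared in the table schema")

    columns = pd.MultiIndex.from_tuples(
        [(t, c) for t in traits for c in table.schema[t]],
        names=["trait", "category"],
    )
    rows = np.zeros((len(table.species), len(columns)), dtype=np.int8)
    col_pos = {tc: i for i, tc in enumerate(columns)}
    for i, sp in enumerate(table.species):
        for t in traits:
            cats = table.assignments[sp].get(t, frozenset())
            if not cats:
                raise ValueError(
                    f"species {sp!r} has no category for requested trait {t!r}"
                )
            for c in cats:
                rows[i, col_pos[(t, c)]] = 1

    data = pd.DataFrame(rows, index=pd.Index(table.species, name="species"),
                        columns=columns)
    weights = pd.Series(
        [1.0 / len(table.schema[t]) for t, _ in columns], index=columns, name="weight"
    )
    return BinaryTraitMatrix(data=data, weights=weights)


def derive_entities(matrix: BinaryTraitMatrix) -> list[FunctionalEntity]:
    """Partition species into functional entities by identical binary rows.

    Entity ids are stable across runs and row orderings: signatures are
    sorted lexicographically and numbered ``FE001``, ``FE002``, ...
    """
    groups: dict[tuple[int, ...], set[str]] = {}
    for sp in matrix.species:
        groups.setdefault(matrix.row_signature(sp), set()).add(sp)
    width = max(3, len(str(len(groups))))
    entities = [
        FunctionalEntity(
            entity_id=f"FE{i + 1:0{width}d}",
            signature=sig,
            members=frozenset(members),
        )
        for i, (sig, members) in enumerate(sorted(groups.items()))
    ]
    return entities


def entity_redundancy(
    entities: Iterable[FunctionalEntity],
    taxonomy: Mapping[str, tuple[str, str]] | None,
) -> pd.DataFrame:
    """Count species, genera and families per functional entity.

    Returns a frame indexed by entity id with columns ``n_species``,
    ``n_genera``, ``n_families``, sorted by decreasing species count with
    alphabetical entity-id tie-break.  If taxonomy is missing for any
    member the genus/family counts are reported as missing with a warning.
    """
    records = []
    for e in entities:
        rec: dict[str, object] = {"entity_id": e.entity_id, "n_species": len(e.members)}
        have_tax = taxonomy is not None and all(sp in taxonomy for sp in e.members)
        if have_tax:
            assert taxonomy is not None
            rec["n_genera"] = len({taxonomy[sp][0] for sp in e.members})
            rec["n_families"] = len({taxonomy[sp][1] for sp in e.members})
        else:
            warnings.warn(
                f"entity {e.entity_id}: taxonomy missing for some members; "
                "counting species only",
                stacklevel=2,
            )
            rec["n_genera"] = np.nan
            rec["n_families"] = np.nan
        records.append(rec)
    out = pd.DataFrame.from_records(records).set_index("entity_id")
    return out.sort_values(
        ["n_species", "entity_id"], ascending=[False, True], kind="mergesort"
    )
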