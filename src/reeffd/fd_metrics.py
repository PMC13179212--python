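"""Community-level functional-diversity metrics.

For a community (one site x 10-m depth bin) with transect-normalized
abundances, this module computes:

* CWM — community-weighted mean of each binary trait category, i.e. the
  (square-root-)abundance-weighted proportion of the community carrying
  the category;
* FRic — convex-hull area of the community's species on two ordination
  axes (abundance-independent);
* FEve — regularity of abundance along the minimum spanning tree linking
  the community's species in trait space;
* FDis — abundance-weighted mean distance to the community centroid;
* Rao's quadratic entropy Q, Simpson diversity D, and functional
  redundancy R = D - Q (which is non-negative whenever distances lie in
  [0, 1], i.e. for uncorrected Gower dissimilarities);
* sample-based rarefaction of species or functional-entity richness.

Abundances are square-root transformed before weighting by default,
which damps the influence of very abundant species without
over-weighting rare ones; the raw scale is available via
``sqrt_transform=False``.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix, TraitSpace
from .trait_coding import BinaryTraitMatrix, FunctionalEntity

__all__ = [
    "Community",
    "cwm",
    "functional_richness",
    "functional_evenness",
    "functional_dispersion",
    "rao_simpson_redundancy",
    "rarefaction",
    "community_metrics",
    "entity_lookup",
]


@dataclass
class Community:
    """Abundances of one site x depth-bin community.

    ``abundances`` maps species id to a non-negative density (counts per
    metre of transect, normalized upstream); at least one value must be
    positive.
    """

    site: str
    depth_bin: float  # lower edge of the 10-m bin, metres
    abundances: dict[str, float]

    def __post_init__(self) -> None:
        if not self.abundances or not any(a > 0 for a in self.abundances.values()):
            raise ValueError("community must contain at least one positive abundance")
        if any(a < 0 for a in self.abundances.values()):
            raise ValueError("abundances must be non-negative")
        self.abundances = {s: float(a) for s, a in self.abundances.items() if a > 0}

    @property
    def community_id(self) -> str:
        return f"{self.site}:{self.depth_bin:g}"

    @property
    def species(self) -> list[str]:
        return list(self.abundances)


def _weights(community: Community, species: Sequence[str], sqrt_transform: bool) -> np.ndarray:
    a = np.array([community.abundances[s] for s in species], dtype=float)
    w = np.sqrt(a) if sqrt_transform else a
    return w / w.sum()


def cwm(
    community: Community,
    matrix: BinaryTraitMatrix,
    sqrt_transform: bool = True,
) -> pd.Series:
    """Community-weighted mean of every binary trait category.

    ``CWM_k = sum_s sqrt(a_s) x_sk / sum_s sqrt(a_s)`` — the weighted
    proportion of community abundance carrying category k, in [0, 1].
    """
    species = [s for s in community.species if s in matrix.data.index]
    if not species:
        raise ValueError("no community species present in the trait matrix")
    w = _weights(community, species, sqrt_transform)
    X = matrix.data.loc[species].to_numpy(dtype=float)
    return pd.Series(w @ X, index=matrix.data.columns, name=community.community_id)


def _hull_area(points: np.ndarray) -> float:
    pts = np.unique(points, axis=0)
    if len(pts) < 3:
        return 0.0
    try:
        return float(ConvexHull(pts).volume)  # 2-D "volume" is the area
    except QhullError:
        return 0.0  # collinear / degenerate


def functional_richness(
    space: TraitSpace,
    community: Community | Sequence[str],
    axes: tuple[int, int] = (1, 2),
) -> float:
    """Convex-hull area of the community on two ordination axes.

    Abundance-independent; returns 0 (with a warning) for degenerate
    communities with fewer than three distinct points or collinear ones.
    """
    species = community.species if isinstance(community, Community) else list(community)
    pts = space.axes(which=axes, labels=species)
    area = _hull_area(pts)
    if area == 0.0:
        warnings.warn(
            "degenerate community (fewer than 3 distinct/non-collinear points); "
            "functional richness set to 0",
            stacklevel=2,
        )
    return area


def functional_evenness(
    space: TraitSpace,
    community: Community,
    axes: tuple[int, ...] | None = None,
    sqrt_transform: bool = True,
) -> float:
    """Regularity of abundance along the minimum spanning tree (FEve).

    Each MST edge between species i and j gets an abundance-scaled
    length ``EW = d(i, j) / (w_i + w_j)``; FEve measures how evenly the
    normalized EW values are distributed, reaching 1 for perfectly
    regular spacing.  Undefined for fewer than 3 species (returns NaN
    with a warning).
    """
    species = community.species
    S = len(species)
    if S < 3:
        warnings.warn("FEve undefined for fewer than 3 species", stacklevel=2)
        return float("nan")
    X = space.axes(which=axes, labels=species)
    w = _weights(community, species, sqrt_transform)
    D = squareform(pdist(X), checks=False)
    mst = minimum_spanning_tree(D).tocoo()
    ew = np.array([D[i, j] / (w[i] + w[j]) for i, j in zip(mst.row, mst.col)])
    total = ew.sum()
    if total == 0.0:
        return 1.0  # all species coincident: perfectly regular
    pew = ew / total
    thr = 1.0 / (S - 1)
    return float((np.minimum(pew, thr).sum() - thr) / (1.0 - thr))


def functional_dispersion(
    space: TraitSpace,
    community: Community,
    axes: tuple[int, ...] | None = None,
    sqrt_transform: bool = True,
) -> float:
    """Abundance-weighted mean distance to the community centroid (FDis)."""
    species = community.species
    X = space.axes(which=axes, labels=species)
    w = _weights(community, species, sqrt_transform)
    centroid = w @ X
    return float(w @ np.linalg.norm(X - centroid, axis=1))


def rao_simpson_redundancy(
    d: DistanceMatrix,
    community: Community,
    sqrt_transform: bool = True,
) -> tuple[float, float, float]:
    """Rao's quadratic entropy, Simpson diversity and their difference.

    ``Q = sum_ij d_ij p_i p_j``, ``D = 1 - sum_i p_i**2`` and redundancy
    ``R = D - Q``, which is non-negative whenever all pairwise distances
    lie in [0, 1] (uncorrected Gower).  Distances outside [0, 1] raise,
    since the redundancy identity is undefined there.
    """
    if d.values.max(initial=0.0) > 1.0 + 1e-12:
        raise ValueError("redundancy requires distances in [0, 1] (uncorrected Gower)")
    species = community.species
    sub = d.subset(species)
    p = _weights(community, species, sqrt_transform)
    Q = float(p @ sub.values @ p)
    simpson = float(1.0 - (p**2).sum())
    return Q, simpson, simpson - Q


def entity_lookup(entities: Iterable[FunctionalEntity]) -> dict[str, str]:
    """Map each species id to its functional-entity id."""
    return {sp: e.entity_id for e in entities for sp in e.members}


def rarefaction(
    communities: Sequence[Community | Mapping[str, float] | set],
    unit: str = "species",
    n_draws: int = 200,
    seed: int = 0,
    entity_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Sample-based rarefaction of species or functional-entity richness.

    Each community (or bare species set) is one sampling unit.  For every
    subset size m the expected richness is estimated as the mean pooled
    richness over ``n_draws`` random subsets of m units (Monte Carlo,
    seeded).  Returns a frame with columns ``size``, ``mean``, ``sd``.
    """
    if unit not in ("species", "entity"):
        raise ValueError("unit must be 'species' or 'entity'")
    if unit == "entity" and entity_of is None:
        raise ValueError("entity rarefaction requires an entity_of mapping")

    sets: list[frozenset[str]] = []
    for c in communities:
        if isinstance(c, Community):
            sp = set(c.species)
        elif isinstance(c, Mapping):
            sp = {s for s, a in c.items() if a > 0}
        else:
            sp = set(c)
        if unit == "entity":
            assert entity_of is not None
            sp = {entity_of[s] for s in sp if s in entity_of}
        sets.append(frozenset(sp))

    rng = np.random.default_rng(seed)
    n = len(sets)
    rows = []
    for m in range(1, n + 1):
        if m == n:
            richness = np.array([len(frozenset().union(*sets))], dtype=float)
        else:
            richness = np.empty(n_draws)
            for k in range(n_draws):
                idx = rng.choice(n, size=m, replace=False)
                richness[k] = len(frozenset().union(*(sets[i] for i in idx)))
        rows.append(
            {"size": m, "mean": float(richness.mean()),
             "sd": float(richness.std(ddof=1)) if richness.size > 1 else 0.0}
        )
    return pd.DataFrame(rows)


def community_metrics(
    communities: Sequence[Community],
    matrix: BinaryTraitMatrix,
    space: TraitSpace,
    gower_d: DistanceMatrix,
    entity_of: Mapping[str, str] | None = None,
    fric_axes: tuple[int, int] = (1, 2),
    sqrt_transform: bool = True,
) -> pd.DataFrame:
    """Tidy per-community metrics table (one row per site x depth bin)."""
    rows = []
    for c in communities:
        present = [s for s in c.species if s in space._label_pos]
        if not present:
            continue
        sub = Community(site=c.site, depth_bin=c.depth_bin,
                        abundances={s: c.abundances[s] for s in present})
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fric = functional_richness(space, sub, axes=fric_axes)
            feve = functional_evenness(space, sub, sqrt_transform=sqrt_transform)
        fdis = functional_dispersion(space, sub, sqrt_transform=sqrt_transform)
        q, simpson, red = rao_simpson_redundancy(gower_d, sub, sqrt_transform=sqrt_transform)
        rows.append(
            {
                "site": c.site,
                "depth_bin": c.depth_bin,
                "species_richness": len(present),
                "entity_richness": (
                    len({entity_of[s] for s in present}) if entity_of else math.nan
                ),
                "FRic": fric,
                "FEve": feve,
                "FDis": fdis,
                "RaoQ": q,
                "Simpson": simpson,
                "redundancy": red,
            }
        )
    return pd.DataFrame(rows)
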