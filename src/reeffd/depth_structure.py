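"""Depth binning, depth zones, and the 75% depth-affinity classifier.

Reef-fish communities are analysed in 10-m depth bins nested in broader,
site-specific depth zones (altiphotic, upper/lower mesophotic,
upper/lower rariphotic, below rariphotic).  A species' *depth affinity*
is the shortest contiguous run of zones capturing at least 75% of its
abundance: one zone makes a zone specialist, two adjacent zones a
hyphenated generalist (e.g. "altiphotic-upper_mesophotic"), three or
more a flagged multi-zone generalist.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

from .distances import TraitSpace
from .fd_metrics import Community, _hull_area, _weights

__all__ = [
    "DEFAULT_ZONE_LIMITS",
    "DepthZoneScheme",
    "bin_depths",
    "species_zone_profiles",
    "assign_affinity",
    "zone_trait_summary",
    "affinity_trait_summary",
]

#: Default zone limits in metres (half-open [lo, hi) intervals), consistent
#: with the community breaks observed near 130, 200 and 300 m.
DEFAULT_ZONE_LIMITS: dict[str, tuple[float, float]] = {
    "altiphotic": (0.0, 40.0),
    "upper_mesophotic": (40.0, 90.0),
    "lower_mesophotic": (90.0, 130.0),
    "upper_rariphotic": (130.0, 200.0),
    "lower_rariphotic": (200.0, 300.0),
    "below_rariphotic": (300.0, float("inf")),
}


@dataclass
class DepthZoneScheme:
    """Ordered, contiguous depth zones with optional site-specific limits."""

    default_limits: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_ZONE_LIMITS)
    )
    site_limits: dict[str, dict[str, tuple[float, float]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, limits in [("default", self.default_limits)] + list(
            self.site_limits.items()
        ):
            zones = list(limits.items())
            for (z1, (lo1, hi1)), (z2, (lo2, hi2)) in zip(zones, zones[1:]):
                if hi1 != lo2:
                    raise ValueError(
                        f"{name}: zones {z1!r} and {z2!r} are not contiguous"
                    )
                if lo1 >= hi1 or lo2 >= hi2:
                    raise ValueError(f"{name}: empty zone interval")

    @property
    def zone_order(self) -> list[str]:
        return list(self.default_limits)

    def limits_for(self, site: str) -> dict[str, tuple[float, float]]:
        return self.site_limits.get(site, self.default_limits)

    def zone_of(self, site: str, depth: float) -> str:
        for zone, (lo, hi) in self.limits_for(site).items():
            if lo <= depth < hi:
                return zone
        raise ValueError(f"depth {depth} m outside the zone scheme for site {site!r}")


def bin_depths(
    observations: pd.DataFrame, width: float = 10.0
) -> list[Community]:
    """Pool observations into site x depth-bin communities.

    ``observations`` needs columns ``site``, ``depth``, ``transect_id``,
    ``transect_length``, ``species``, ``count``.  Depths fall in half-open
    bins [d, d + width); within a bin, counts are summed over transects
    and divided by the summed length of the distinct transects present,
    yielding densities per metre of transect.  Empty bins are absent.
    """
    required = {"site", "depth", "transect_id", "transect_length", "species", "count"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations missing columns: {sorted(missing)}")
    if (observations["depth"] < 0).any():
        raise ValueError("negative depths are not allowed")

    obs = observations.copy()
    obs["depth_bin"] = (obs["depth"] // width) * width
    communities: list[Community] = []
    for (site, bin_low), grp in obs.groupby(["site", "depth_bin"], sort=True):
        total_length = (
            grp.drop_duplicates("transect_id")["transect_length"].astype(float).sum()
        )
        counts = grp.groupby("species")["count"].sum()
        abundances = {
            str(sp): float(c) / total_length for sp, c in counts.items() if c > 0
        }
        if abundances:
            communities.append(
                Community(site=str(site), depth_bin=float(bin_low), abundances=abundances)
            )
    return communities


def species_zone_profiles(
    communities: Sequence[Community],
    scheme: DepthZoneScheme,
    mode: str = "mean_density",
) -> pd.DataFrame:
    """Per-species abundance share across depth zones.

    With ``mode='mean_density'`` (default) the weight of a zone is the
    species' mean density over the bins of that zone where it occurs,
    so that wide zones do not dominate purely by containing more bins;
    ``mode='sum'`` uses raw summed densities instead.  Rows are
    normalized to sum to 1.
    """
    if mode not in ("mean_density", "sum"):
        raise ValueError("mode must be 'mean_density' or 'sum'")
    zones = scheme.zone_order
    acc: dict[str, dict[str, list[float]]] = {}
    for c in communities:
        zone = scheme.zone_of(c.site, c.depth_bin)
        for sp, a in c.abundances.items():
            acc.setdefault(sp, {z: [] for z in zones})[zone].append(a)
    rows = {}
    for sp, by_zone in acc.items():
        vals = np.array(
            [
                (np.mean(by_zone[z]) if mode == "mean_density" else np.sum(by_zone[z]))
                if by_zone[z]
                else 0.0
                for z in zones
            ]
        )
        rows[sp] = vals / vals.sum()
    return pd.DataFrame.from_dict(rows, orient="index", columns=zones).sort_index()


def assign_affinity(
    zone_shares: Mapping[str, float],
    zone_order: Sequence[str],
    threshold: float = 0.75,
) -> str:
    """Label a species by the zones holding >= 75% of its abundance.

    Chooses the shortest contiguous run of zones whose summed share
    reaches the threshold; ties go to the run with the higher total
    share, then to the shallower run.  A single-zone run returns the
    zone name, two zones a hyphenated label, three or more
    ``"generalist"``.
    """
    if not zone_shares:
        raise ValueError("empty zone profile")
    shares = np.array([float(zone_shares.get(z, 0.0)) for z in zone_order])
    total = shares.sum()
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"zone shares must sum to 1 (got {total:.6g})")
    n = len(shares)
    best: tuple[int, float, int] | None = None  # (length, -share, start)
    for length in range(1, n + 1):
        for start in range(0, n - length + 1):
            s = shares[start : start + length].sum()
            if s >= threshold - 1e-12:
                key = (length, -s, start)
                if best is None or key < best:
                    best = key
        if best is not None:
            break
    assert best is not None  # a full run always sums to 1 >= threshold
    length, _, start = best
    run = list(zone_order[start : start + length])
    if length == 1:
        return run[0]
    if length == 2:
        return f"{run[0]}-{run[1]}"
    return "generalist"


def _pooled_abundance(communities: Sequence[Community]) -> dict[str, float]:
    pooled: dict[str, float] = {}
    for c in communities:
        for sp, a in c.abundances.items():
            pooled[sp] = pooled.get(sp, 0.0) + a
    return pooled


def _hull_and_centroid(
    space: TraitSpace,
    abundances: Mapping[str, float],
    axes: tuple[int, int],
    sqrt_transform: bool = True,
) -> tuple[float, np.ndarray | None, np.ndarray]:
    species = [s for s in abundances if s in space._label_pos]
    pts = space.axes(which=axes, labels=species)
    area = _hull_area(pts)
    vertices = None
    uniq = np.unique(pts, axis=0)
    if len(uniq) >= 3:
        try:
            hull = ConvexHull(uniq)
            vertices = uniq[hull.vertices]
        except QhullError:
            pass
    comm = Community(site="pooled", depth_bin=0.0, abundances=dict(abundances))
    w = _weights(comm, comm.species, sqrt_transform)
    pts_w = space.axes(which=axes, labels=comm.species)
    centroid = w @ pts_w
    return area, vertices, centroid


def _points_in_hull(points: np.ndarray, hull_vertices: np.ndarray, tol: float = 1e-9) -> bool:
    if len(hull_vertices) < 3:
        return False
    hull = ConvexHull(hull_vertices)
    eq = hull.equations  # normal . x + offset <= 0 inside
    return bool(np.all(points @ eq[:, :-1].T + eq[:, -1] <= tol))


def zone_trait_summary(
    space: TraitSpace,
    communities: Sequence[Community],
    scheme: DepthZoneScheme,
    axes: tuple[int, int] = (1, 2),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Hull area, pooled-hull fraction and weighted centroid per depth zone.

    Returns a per-zone summary frame and a dict of hull-vertex arrays
    (absent for degenerate zones, whose area is 0 but whose centroid is
    still defined).
    """
    pooled = _pooled_abundance(list(communities))
    pooled_area, _, _ = _hull_and_centroid(space, pooled, axes)
    rows = []
    polygons: dict[str, np.ndarray] = {}
    by_zone: dict[str, list[Community]] = {}
    for c in communities:
        by_zone.setdefault(scheme.zone_of(c.site, c.depth_bin), []).append(c)
    for zone in scheme.zone_order:
        if zone not in by_zone:
            continue
        ab = _pooled_abundance(by_zone[zone])
        area, vertices, centroid = _hull_and_centroid(space, ab, axes)
        if vertices is not None:
            polygons[zone] = vertices
        rows.append(
            {
                "zone": zone,
                "n_species": len([s for s in ab if s in space._label_pos]),
                "hull_area": area,
                "hull_fraction": area / pooled_area if pooled_area > 0 else np.nan,
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
            }
        )
    return pd.DataFrame(rows).set_index("zone"), polygons


def affinity_trait_summary(
    space: TraitSpace,
    affinities: Mapping[str, str],
    communities: Sequence[Community],
    scheme: DepthZoneScheme,
    axes: tuple[int, int] = (1, 2),
) -> tuple[pd.DataFrame, dict[str, np.ndarray]]:
    """Hulls and centroids per depth-affinity group, with zone containment.

    Each affinity group's hull is compared against the hull of the
    community observed in its constituent zone(s): ``contained`` reports
    whether every group member lies inside that zone hull.
    """
    pooled = _pooled_abundance(list(communities))
    zone_species: dict[str, set[str]] = {}
    by_zone: dict[str, list[Community]] = {}
    for c in communities:
        z = scheme.zone_of(c.site, c.depth_bin)
        by_zone.setdefault(z, []).append(c)
        zone_species.setdefault(z, set()).update(c.species)

    rows = []
    polygons: dict[str, np.ndarray] = {}
    for label in sorted(set(affinities.values())):
        members = [
            s for s, l in affinities.items() if l == label and s in space._label_pos
        ]
        if not members:
            continue
        ab = {s: pooled.get(s, 1.0) for s in members}
        area, vertices, centroid = _hull_and_centroid(space, ab, axes)
        if vertices is not None:
            polygons[label] = vertices

        run = label.split("-") if label != "generalist" else scheme.zone_order
        zone_members = set().union(*(zone_species.get(z, set()) for z in run))
        zone_members &= set(space._label_pos)
        contained: bool | float = np.nan
        if zone_members:
            zpts = np.unique(space.axes(which=axes, labels=sorted(zone_members)), axis=0)
            mpts = space.axes(which=axes, labels=members)
            if len(zpts) >= 3:
                try:
                    contained = _points_in_hull(mpts, zpts)
                except QhullError:
                    contained = np.nan
        rows.append(
            {
                "affinity": label,
                "n_species": len(members),
                "hull_area": area,
                "centroid_x": centroid[0],
                "centroid_y": centroid[1],
                "contained_in_zone_hull": contained,
            }
        )
    return pd.DataFrame(rows).set_index("affinity"), polygons
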