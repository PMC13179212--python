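"""Synthetic depth-structured reef-fish communities with known ground truth.

The generator emulates a multi-island submersible/SCUBA survey: ~250
species observed along 10-m depth bins from the surface to 450 m at
four sites, with six categorical traits (32 categories in total).  Each
species has a unimodal (Gaussian) depth response with peak depth mu,
breadth sigma and log-normal peak density, a species pool defined by
configurable community-break depths (the pool turns over at each
break), and trait-dependent environmental filtering: depth-restricted
trait categories (e.g. herbivory, mid-water position, schooling) are
only assigned to species whose peak lies inside the category's depth
window, and abundance is attenuated exponentially outside it.  Counts
are Poisson draws of expected density x transect length with log-normal
site effects and a per-species detection probability; a noiseless mode
returns the expected densities exactly.

Ground truth records the break depths, the depth-affinity label implied
by each species' expected response curve, the expected per-bin trait-
category frequencies, and all species parameters, so every downstream
stage (binning, affinity classification, clustering, trend fitting) can
be validated against the generating process.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .depth_structure import DepthZoneScheme, assign_affinity, species_zone_profiles
from .fd_metrics import Community
from .trait_coding import TraitTable, expand_traits

__all__ = [
    "DEFAULT_TRAIT_SCHEMA",
    "DEFAULT_CATEGORY_WINDOWS",
    "SyntheticConfig",
    "GroundTruth",
    "generate",
    "fixture_small",
]

#: Six categorical traits, 32 categories in total, mirroring the structure
#: of reef-fish trait compilations (size, diet, water-column position,
#: gregariousness, mobility, reproduction).
DEFAULT_TRAIT_SCHEMA: dict[str, tuple[str, ...]] = {
    "size": ("very_small", "small", "medium", "large", "very_large"),
    "diet": (
        "planktivore",
        "sessile_invertivore",
        "mobile_invertivore",
        "piscivore",
        "macroalgae_herbivore",
        "microalgae_herbivore",
        "corallivore",
        "detritivore",
        "ectoparasite_cleaner",
    ),
    "position": ("bottom", "near_bottom", "mid_water", "near_surface"),
    "gregariousness": ("solitary", "paired", "small_school", "medium_school", "large_school"),
    "mobility": ("sedentary", "reef_mobile", "between_reef", "vertically_mobile"),
    "reproduction": ("pelagic_eggs", "benthic_eggs", "brooder", "livebearer", "egg_guarder"),
}

_INF = float("inf")

#: Depth windows (m) outside which a category is environmentally filtered.
#: Unlisted categories are unrestricted.  Windows encode the familiar
#: depth gradients: herbivores, corallivores, detritivores and cleaners
#: vanish below the mesophotic, mid-water and schooling strategies thin
#: out with depth, and high mobility is absent below the rariphotic.
DEFAULT_CATEGORY_WINDOWS: dict[tuple[str, str], tuple[float, float]] = {
    ("diet", "macroalgae_herbivore"): (0.0, 130.0),
    ("diet", "microalgae_herbivore"): (0.0, 130.0),
    ("diet", "corallivore"): (0.0, 120.0),
    ("diet", "detritivore"): (0.0, 120.0),
    ("diet", "ectoparasite_cleaner"): (0.0, 100.0),
    ("position", "near_surface"): (0.0, 100.0),
    ("position", "mid_water"): (0.0, 200.0),
    ("gregariousness", "large_school"): (0.0, 200.0),
    ("mobility", "between_reef"): (0.0, 300.0),
    ("mobility", "vertically_mobile"): (0.0, 300.0),
}


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic survey and community model."""

    n_sites: int = 4
    depth_min: float = 0.0
    depth_max: float = 450.0
    bin_width: float = 10.0
    #: per-site surveyed range; by default the first site spans the full
    #: gradient and the remaining sites cover 40-300 m, as in mixed
    #: submersible/SCUBA campaigns.
    site_depth_ranges: tuple[tuple[float, float], ...] | None = None
    n_species: int = 250
    trait_schema: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: {t: tuple(c) for t, c in DEFAULT_TRAIT_SCHEMA.items()}
    )
    category_windows: dict[tuple[str, str], tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_CATEGORY_WINDOWS)
    )
    filter_decay: float = 0.1  # 1/m attenuation outside a category window
    #: multiplier on the attenuation decay: 0 disables abundance
    #: filtering (windows still constrain trait assignment), larger
    #: values suppress out-of-window occurrences more sharply
    filter_strength: float = 1.0
    break_depths: tuple[float, ...] = (200.0,)
    soft_break_scale: float | None = None  # None = hard pool turnover
    peak_breadth_mean: float = 25.0  # m, log-normal median of sigma_s
    peak_breadth_sigma: float = 0.4
    amplitude_median: float = 0.4  # fish per m of transect at the peak
    amplitude_sigma: float = 0.9
    site_effect_sigma: float = 0.3
    detection_prob: float = 0.9
    multi_category_prob: float = 0.1
    #: Dirichlet concentration of within-trait category frequencies; small
    #: values skew frequencies so binary signatures collide and species
    #: share functional entities at realistic rates (~2/3 as many
    #: entities as species).
    category_concentration: float = 0.2
    n_transects_per_bin: int = 2
    transect_length: float = 120.0
    noise: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.site_depth_ranges is None:
            full = (self.depth_min, self.depth_max)
            partial = (max(40.0, self.depth_min), min(300.0, self.depth_max))
            self.site_depth_ranges = (full,) + (partial,) * (self.n_sites - 1)
        if len(self.site_depth_ranges) != self.n_sites:
            raise ValueError("site_depth_ranges must have one entry per site")
        for lo, hi in self.category_windows.values():
            if lo < self.depth_min or lo >= hi:
                raise ValueError("category windows must be valid intervals in range")
        for b in self.break_depths:
            if not (self.depth_min < b < self.depth_max):
                raise ValueError("break depths must lie inside the depth range")

    def category_window(self, trait: str, cat: str) -> tuple[float, float]:
        """Allowed depth window of a category (unrestricted if unlisted)."""
        return self.category_windows.get((trait, cat), (self.depth_min, _INF))


@dataclass
class GroundTruth:
    """Generating-process truth for validating downstream analyses."""

    break_depths: tuple[float, ...]
    affinities: dict[str, str]
    species_params: pd.DataFrame  # mu, sigma, amplitude, pool
    bin_category_frequencies: pd.DataFrame
    zone_scheme: DepthZoneScheme

    def to_json(self, path) -> None:
        payload = {
            "break_depths": list(self.break_depths),
            "affinities": self.affinities,
            "species_params": self.species_params.to_dict(orient="index"),
            "bin_category_frequencies": {
                str(k): {f"{t}:{c}": x for (t, c), x in v.items()}
                for k, v in self.bin_category_frequencies.to_dict(orient="index").items()
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)


def _pool_bounds(config: SyntheticConfig, mu: float) -> tuple[float, float]:
    edges = [config.depth_min, *sorted(config.break_depths), config.depth_max]
    for lo, hi in zip(edges, edges[1:]):
        if lo <= mu < hi or (hi == edges[-1] and mu == hi):
            return lo, hi
    raise ValueError(f"peak depth {mu} outside depth range")


def _expected_density(
    config: SyntheticConfig,
    d: float,
    mu: float,
    sigma: float,
    amp: float,
    window: tuple[float, float],
) -> float:
    dens = amp * math.exp(-((d - mu) ** 2) / (2.0 * sigma**2))
    lo, hi = _pool_bounds(config, mu)
    if not (lo <= d < hi or (d == hi == config.depth_max)):
        if config.soft_break_scale is None:
            return 0.0
        gap = lo - d if d < lo else d - hi
        dens *= math.exp(-gap / config.soft_break_scale)
    wlo, whi = window
    decay = config.filter_decay * config.filter_strength
    if d < wlo:
        dens *= math.exp(-decay * (wlo - d))
    elif d > whi:
        dens *= math.exp(-decay * (d - whi))
    return dens


def _draw_traits(
    config: SyntheticConfig, mu: np.ndarray, rng: np.random.Generator
) -> tuple[dict[str, dict[str, frozenset[str]]], list[str]]:
    """Sample category sets per species subject to the depth filters.

    Category frequencies within each trait are skewed (Dirichlet-drawn),
    so binary signatures collide and functional entities hold several
    species, as in real trait compilations.  Frequencies are drawn
    independently for every species pool (the depth intervals between
    community breaks): a break is a turnover in trait composition, not
    merely in species identity.
    """
    species_ids = [f"sp{i + 1:03d}" for i in range(config.n_species)]
    edges = [config.depth_min, *sorted(config.break_depths), config.depth_max]
    n_pools = len(edges) - 1
    cat_probs = {
        (pool, trait): rng.dirichlet(
            np.full(len(cats), config.category_concentration)
        )
        for pool in range(n_pools)
        for trait, cats in config.trait_schema.items()
    }
    pool_of = np.minimum(np.searchsorted(edges, mu, side="right") - 1, n_pools - 1)
    assignments: dict[str, dict[str, frozenset[str]]] = {}
    conflicts: list[str] = []
    for i, sp in enumerate(species_ids):
        row: dict[str, frozenset[str]] = {}
        for trait, cats in config.trait_schema.items():
            allowed_mask = np.array(
                [
                    config.category_window(trait, c)[0]
                    <= mu[i]
                    <= config.category_window(trait, c)[1]
                    for c in cats
                ]
            )
            if not allowed_mask.any():
                conflicts.append(
                    f"species {sp} (peak {mu[i]:.0f} m): no feasible category for {trait}"
                )
                continue
            probs = cat_probs[(int(pool_of[i]), trait)] * allowed_mask
            probs = probs / probs.sum() if probs.sum() > 0 else allowed_mask / allowed_mask.sum()
            allowed = [c for c, ok in zip(cats, allowed_mask) if ok]
            n_cat = 1
            while n_cat < min(3, len(allowed)) and rng.random() < config.multi_category_prob:
                n_cat += 1
            chosen = rng.choice(len(cats), size=n_cat, replace=False, p=probs)
            row[trait] = frozenset(cats[j] for j in chosen)
        assignments[sp] = row
    if conflicts:
        raise ValueError("infeasible filter combinations:\n" + "\n".join(conflicts))
    return assignments, species_ids


def generate(
    config: SyntheticConfig, zone_scheme: DepthZoneScheme | None = None
) -> tuple[TraitTable, pd.DataFrame, GroundTruth]:
    """Generate a trait table, long-format observations, and ground truth.

    Deterministic for a fixed config (the seed lives in the config): the
    same config yields byte-identical outputs.
    """
    rng = np.random.default_rng(config.seed)
    zone_scheme = zone_scheme or DepthZoneScheme()

    mu = rng.uniform(config.depth_min, config.depth_max, size=config.n_species)
    sigma = np.exp(
        rng.normal(math.log(config.peak_breadth_mean), config.peak_breadth_sigma,
                   size=config.n_species)
    )
    amp = np.exp(
        rng.normal(math.log(config.amplitude_median), config.amplitude_sigma,
                   size=config.n_species)
    )

    assignments, species_ids = _draw_traits(config, mu, rng)

    # taxonomy: ~2.5 species per genus, ~3 genera per family
    n_genera = max(1, int(config.n_species / 2.5))
    genus_idx = rng.integers(0, n_genera, size=config.n_species)
    taxonomy = {
        sp: (f"Genus{g + 1:03d}", f"Family{g // 3 + 1:03d}")
        for sp, g in zip(species_ids, genus_idx)
    }
    table = TraitTable(
        schema=config.trait_schema, assignments=assignments, taxonomy=taxonomy
    )

    # effective filter window per species: intersection over carried categories
    windows = []
    for i, sp in enumerate(species_ids):
        lo, hi = config.depth_min, _INF
        for trait, cats in assignments[sp].items():
            for c in cats:
                wlo, whi = config.category_window(trait, c)
                lo, hi = max(lo, wlo), min(hi, whi)
        windows.append((lo, hi))

    site_effect = (
        np.exp(rng.normal(0.0, config.site_effect_sigma,
                          size=(config.n_sites, config.n_species)))
        if config.noise
        else np.ones((config.n_sites, config.n_species))
    )
    detection = config.detection_prob if config.noise else 1.0

    records: list[tuple] = []
    for s in range(config.n_sites):
        site = f"site{s + 1}"
        lo_site, hi_site = config.site_depth_ranges[s]
        bins = np.arange(lo_site, hi_site, config.bin_width)
        for b in bins:
            d = b + config.bin_width / 2.0
            for t in range(config.n_transects_per_bin):
                tid = f"{site}-d{b:g}-t{t + 1}"
                for i, sp in enumerate(species_ids):
                    dens = _expected_density(config, d, mu[i], sigma[i], amp[i], windows[i])
                    if dens <= 1e-12:  # below detectability
                        continue
                    lam = dens * site_effect[s, i] * detection * config.transect_length
                    count = rng.poisson(lam) if config.noise else lam
                    if count > 0:
                        records.append(
                            (site, d, tid, config.transect_length, sp, count)
                        )
    observations = pd.DataFrame(
        records,
        columns=["site", "depth", "transect_id", "transect_length", "species", "count"],
    )

    truth = _ground_truth(config, zone_scheme, table, species_ids, mu, sigma, amp, windows)
    return table, observations, truth


def _ground_truth(
    config: SyntheticConfig,
    zone_scheme: DepthZoneScheme,
    table: TraitTable,
    species_ids: list[str],
    mu: np.ndarray,
    sigma: np.ndarray,
    amp: np.ndarray,
    windows: list[tuple[float, float]],
) -> GroundTruth:
    # expected (noise-free, site-effect-free) communities mirroring the
    # per-site survey coverage, so the noiseless observation path
    # reproduces the ground truth exactly
    assert config.site_depth_ranges is not None
    expected: list[Community] = []
    bin_densities: dict[float, dict[str, float]] = {}
    for s in range(config.n_sites):
        lo_site, hi_site = config.site_depth_ranges[s]
        for b in np.arange(lo_site, hi_site, config.bin_width):
            b = float(b)
            if b not in bin_densities:
                d = b + config.bin_width / 2.0
                ab = {}
                for i, sp in enumerate(species_ids):
                    dens = _expected_density(config, d, mu[i], sigma[i], amp[i], windows[i])
                    if dens > 1e-12:
                        ab[sp] = dens
                bin_densities[b] = ab
            if bin_densities[b]:
                expected.append(
                    Community(site=f"site{s + 1}", depth_bin=b,
                              abundances=dict(bin_densities[b]))
                )

    bm = expand_traits(table)
    X = bm.data
    freq_rows = {}
    for b in sorted(bin_densities):
        ab = bin_densities[b]
        if not ab:
            continue
        sp_list = list(ab)
        a = np.array([ab[s] for s in sp_list])
        freq_rows[b] = (a @ X.loc[sp_list].to_numpy(dtype=float)) / a.sum()

    profiles = species_zone_profiles(expected, zone_scheme)
    affinities = {
        sp: assign_affinity(profiles.loc[sp].to_dict(), zone_scheme.zone_order)
        for sp in profiles.index
    }
    params = pd.DataFrame(
        {
            "mu": mu,
            "sigma": sigma,
            "amplitude": amp,
            "pool": [f"{_pool_bounds(config, m)[0]:g}-{_pool_bounds(config, m)[1]:g}" for m in mu],
        },
        index=pd.Index(species_ids, name="species"),
    )
    freq = pd.DataFrame.from_dict(freq_rows, orient="index", columns=bm.data.columns)
    freq.index.name = "depth_bin"
    return GroundTruth(
        break_depths=tuple(config.break_depths),
        affinities=affinities,
        species_params=params,
        bin_category_frequencies=freq,
        zone_scheme=zone_scheme,
    )


def fixture_small() -> tuple[TraitTable, pd.DataFrame, dict]:
    """Tiny deterministic dataset: 8 species, 2 traits, 3 depth bins.

    Counts are small integers on single 10-m transects so every
    downstream quantity is hand-checkable; the returned dict freezes a
    few of those hand-derived values (per-bin densities and the Gower
    distance of the first species pair).
    """
    schema = {
        "diet": ("plankton", "invertebrates", "fish"),
        "position": ("bottom", "midwater"),
    }
    assignments = {
        "sp1": {"diet": frozenset(["plankton"]), "position": frozenset(["midwater"])},
        "sp2": {"diet": frozenset(["plankton"]), "position": frozenset(["bottom"])},
        "sp3": {"diet": frozenset(["invertebrates"]), "position": frozenset(["bottom"])},
        "sp4": {"diet": frozenset(["invertebrates", "fish"]), "position": frozenset(["bottom"])},
        "sp5": {"diet": frozenset(["fish"]), "position": frozenset(["bottom", "midwater"])},
        "sp6": {"diet": frozenset(["fish"]), "position": frozenset(["bottom", "midwater"])},
        "sp7": {"diet": frozenset(["plankton", "invertebrates"]), "position": frozenset(["midwater"])},
        "sp8": {"diet": frozenset(["invertebrates"]), "position": frozenset(["bottom"])},
    }
    taxonomy = {
        "sp1": ("GenusA", "Fam1"), "sp2": ("GenusA", "Fam1"),
        "sp3": ("GenusB", "Fam1"), "sp4": ("GenusB", "Fam1"),
        "sp5": ("GenusC", "Fam2"), "sp6": ("GenusC", "Fam2"),
        "sp7": ("GenusD", "Fam2"), "sp8": ("GenusE", "Fam3"),
    }
    table = TraitTable(schema=schema, assignments=assignments, taxonomy=taxonomy)

    rows = []
    counts = {
        0.0: {"sp1": 8, "sp2": 4, "sp3": 2, "sp7": 1},
        10.0: {"sp2": 2, "sp3": 4, "sp4": 4, "sp5": 1, "sp8": 1},
        20.0: {"sp5": 3, "sp6": 3, "sp8": 6},
    }
    for b, by_sp in counts.items():
        for sp, c in by_sp.items():
            rows.append(("siteA", b + 5.0, f"siteA-d{b:g}-t1", 10.0, sp, c))
    observations = pd.DataFrame(
        rows, columns=["site", "depth", "transect_id", "transect_length", "species", "count"]
    )
    expected = {
        # densities = count / 10 m transect
        "density_bin0_sp1": 0.8,
        "density_bin10_sp4": 0.4,
        # Gower(sp1, sp2): diet identical, position fully mismatched on
        # both of 2 columns with weight 1/2 each -> (0 + 1) / 2 = 0.5
        "gower_sp1_sp2": 0.5,
        "n_entities": 6,  # sp5/sp6 and sp3/sp8 each share a signature
    }
    return table, observations, expected
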