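"""Trait-profile clustering across depth: Bray-Curtis, Ward, SIMPROF, PERMANOVA.

Depth bins are described by the abundance-weighted frequency of each
trait category among all individuals in the bin (a "trait-frequency
profile", 32 columns for the full six-trait schema).  Profiles are
compared with Bray-Curtis dissimilarity, clustered with Ward's
minimum-variance linkage, and the dendrogram is pruned by similarity
profile analysis (SIMPROF): descending from the root, each node is
tested against a null obtained by independently permuting every trait
category across the node's bins, and descent stops where the observed
similarity profile is indistinguishable from the permuted one.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree

from .distances import DistanceMatrix
from .fd_metrics import Community
from .trait_coding import BinaryTraitMatrix

__all__ = [
    "ClusterResult",
    "trait_frequency_profiles",
    "bray_curtis",
    "ward_dendrogram",
    "simprof",
    "permanova",
    "primary_split_depth",
]


def trait_frequency_profiles(
    communities: list[Community],
    matrix: BinaryTraitMatrix,
    pool_sites: bool = True,
) -> pd.DataFrame:
    """Abundance-weighted trait-category frequencies per depth bin.

    Frequency of category k in bin b is ``sum_s a_sb x_sk / sum_s a_sb``
    over raw (untransformed) abundances — the share of individuals in
    the bin carrying the category.  With ``pool_sites`` (default) sites
    are pooled per bin, giving one row per 10-m bin indexed by the bin's
    lower edge; otherwise rows are (site, bin) pairs.
    """
    if not communities:
        raise ValueError("no communities given")
    pooled: dict[object, dict[str, float]] = {}
    for c in communities:
        key = c.depth_bin if pool_sites else (c.site, c.depth_bin)
        acc = pooled.setdefault(key, {})
        for sp, a in c.abundances.items():
            if sp in matrix.data.index:
                acc[sp] = acc.get(sp, 0.0) + a
    rows = {}
    for key in sorted(pooled):
        ab = pooled[key]
        if not ab:
            continue
        species = list(ab)
        a = np.array([ab[s] for s in species])
        X = matrix.data.loc[species].to_numpy(dtype=float)
        rows[key] = (a @ X) / a.sum()
    index = pd.Index(list(rows), name="depth_bin" if pool_sites else ("site", "depth_bin"))
    return pd.DataFrame(list(rows.values()), index=index, columns=matrix.data.columns)


def _bc_condensed(X: np.ndarray) -> np.ndarray:
    iu, ju = np.triu_indices(len(X), 1)
    num = np.abs(X[iu] - X[ju]).sum(axis=1)
    den = (X[iu] + X[ju]).sum(axis=1)
    with np.errstate(invalid="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    return d


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between profile rows (in [0, 1])."""
    X = profiles.to_numpy(dtype=float)
    if (X.sum(axis=1) == 0).any():
        raise ValueError("all-zero profile row: Bray-Curtis undefined")
    from scipy.spatial.distance import squareform

    d = squareform(_bc_condensed(X), checks=False)
    return DistanceMatrix(labels=[str(l) for l in profiles.index], values=d)


def ward_dendrogram(d: DistanceMatrix) -> np.ndarray:
    """Ward minimum-variance linkage matrix for a dissimilarity matrix.

    Uses the Lance-Williams recursion on the given dissimilarities (the
    common practice for Bray-Curtis input); the nearest-neighbor-chain
    agglomeration is deterministic, with ties resolved toward the
    lowest-index pair.
    """
    return linkage(d.condensed(), method="ward")


# ---------------------------------------------------------------------------
# SIMPROF


@dataclass
class ClusterResult:
    """SIMPROF-pruned partition of a Ward dendrogram."""

    labels: list[object]
    linkage: np.ndarray
    clusters: list[list[object]]
    assignments: dict[object, int]
    tests: pd.DataFrame  # one row per tested node: size, pi, p, significant


def _sorted_sim_profiles(X: np.ndarray, max_elems: float = 2e7) -> np.ndarray:
    """Sorted Bray-Curtis *similarity* profiles for a batch of matrices.

    ``X`` has shape (P, m, k); returns (P, m*(m-1)/2) with each row's
    similarities (1 - dissimilarity) in ascending order.  Chunked over P
    to bound the memory of the pairwise broadcast.
    """
    X = np.asarray(X, dtype=np.float32)  # bandwidth-bound; 1e-7 relative
    # error is far below the permutation noise of the pi statistic
    P, m, k = X.shape
    iu, ju = np.triu_indices(m, 1)
    npairs = len(iu)
    rowsum = X.sum(axis=2)
    den = rowsum[:, iu] + rowsum[:, ju]  # BC denominator needs only row sums
    out = np.empty((P, npairs), dtype=np.float32)
    chunk = max(1, int(max_elems / max(npairs * k, 1)))
    for start in range(0, P, chunk):
        sl = X[start : start + chunk]
        diff = sl[:, iu, :] - sl[:, ju, :]
        np.abs(diff, out=diff)
        out[start : start + chunk] = diff.sum(axis=2)
    with np.errstate(invalid="ignore"):
        np.divide(out, den, out=out, where=den > 0)
        out[den <= 0] = 0.0
    out = 1.0 - out
    out.sort(axis=1)
    return out


def simprof_test(
    X: np.ndarray,
    n_expected: int = 1000,
    n_null: int = 999,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """One similarity-profile homogeneity test on the rows of ``X``.

    The observed statistic is ``pi = sum_r |s_(r) - sbar_(r)|`` where
    ``s_(r)`` are the ordered Bray-Curtis similarities between rows and
    ``sbar_(r)`` the rank-wise mean over ``n_expected`` matrices with
    every column independently permuted across rows.  The p-value counts
    how many of ``n_null`` further permuted matrices reach a pi at least
    as large: ``p = (1 + #{pi_null >= pi_obs}) / (1 + n_null)``.
    """
    rng = np.random.default_rng() if rng is None else rng
    obs = _sorted_sim_profiles(X[None, :, :])[0].astype(np.float64)
    perms = np.tile(X, (n_expected + n_null, 1, 1))
    perms = rng.permuted(perms, axis=1)
    profiles = _sorted_sim_profiles(perms).astype(np.float64)
    expected = profiles[:n_expected].mean(axis=0)
    pi_obs = float(np.abs(obs - expected).sum())
    pi_null = np.abs(profiles[n_expected:] - expected).sum(axis=1)
    p = (1.0 + int((pi_null >= pi_obs - 1e-12).sum())) / (1.0 + n_null)
    return pi_obs, p


def _is_significant(p: float, alpha: float, n_null: int) -> bool:
    # alpha smaller than the permutation resolution 1/(1+n_null) cannot be
    # reached by counting; it then behaves like the resolution limit
    # (reject only when no null statistic matches the observed one).
    resolution = 1.0 / (1.0 + n_null)
    if alpha <= resolution:
        return p <= resolution + 1e-12
    return p < alpha


def simprof(
    profiles: pd.DataFrame,
    linkage_matrix: np.ndarray | None = None,
    alpha: float = 1e-7,
    n_expected: int = 1000,
    n_null: int = 999,
    seed: int = 0,
) -> ClusterResult:
    """Top-down SIMPROF pruning of a Ward dendrogram of trait profiles.

    Starting at the root, each internal node with at least three objects
    is tested for internal structure; significant nodes are split along
    the dendrogram and their children tested in turn, while
    non-significant (homogeneous) nodes become terminal clusters.
    Clusters are numbered in leaf order of the dendrogram.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    labels = list(profiles.index)
    X = profiles.to_numpy(dtype=float)
    if linkage_matrix is None:
        linkage_matrix = ward_dendrogram(bray_curtis(profiles))
    rng = np.random.default_rng(seed)
    root = to_tree(linkage_matrix)

    clusters: list[list[object]] = []
    test_rows: list[dict[str, object]] = []

    def visit(node) -> None:
        leaves = node.pre_order(lambda l: l.id)
        if node.is_leaf() or len(leaves) <= 2:
            clusters.append([labels[i] for i in sorted(leaves)])
            return
        pi, p = simprof_test(X[sorted(leaves)], n_expected, n_null, rng)
        significant = _is_significant(p, alpha, n_null)
        test_rows.append(
            {
                "node_size": len(leaves),
                "height": float(node.dist),
                "pi": pi,
                "p": p,
                "significant": significant,
            }
        )
        if significant:
            visit(node.left)
            visit(node.right)
        else:
            clusters.append([labels[i] for i in sorted(leaves)])

    visit(root)
    # number clusters by the depth order of their first member
    clusters.sort(key=lambda c: labels.index(c[0]))
    assignments = {l: i for i, c in enumerate(clusters) for l in c}
    tests = pd.DataFrame(
        test_rows, columns=["node_size", "height", "pi", "p", "significant"]
    )
    return ClusterResult(
        labels=labels,
        linkage=linkage_matrix,
        clusters=clusters,
        assignments=assignments,
        tests=tests,
    )


def primary_split_depth(result: ClusterResult) -> float | None:
    """Depth boundary implied by the root split of a depth-bin dendrogram.

    Requires labels to be numeric bin lower edges.  If the root test was
    significant, the two root branches are reduced to the cut depth that
    best separates them (fewest bins on the wrong side); ties go to the
    shallowest such cut.  Returns None when the root was homogeneous.
    """
    if result.tests.empty or not bool(result.tests.iloc[0]["significant"]):
        return None
    root = to_tree(result.linkage)
    left = set(root.left.pre_order(lambda l: l.id))
    depths = np.array([float(l) for l in result.labels])
    width = np.diff(np.unique(depths)).min() if len(depths) > 1 else 10.0
    in_left = np.array([i in left for i in range(len(depths))])
    candidates = np.unique(np.concatenate([depths, depths + width]))
    best_cut, best_err = None, None
    for cut in candidates:
        below = depths < cut
        err = min((below ^ in_left).sum(), (below ^ ~in_left).sum())
        if best_err is None or err < best_err:
            best_cut, best_err = float(cut), int(err)
    return best_cut


# ---------------------------------------------------------------------------
# PERMANOVA


def permanova(
    d: DistanceMatrix,
    grouping: list | np.ndarray | pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> dict[str, float]:
    """One-way permutational multivariate analysis of variance.

    Partitions the total sum of squared dissimilarities into between- and
    within-group components; the pseudo-F statistic is referenced to a
    null distribution of free row permutations.  Returns a dict with
    ``F``, ``R2``, ``p``, ``df_between`` and ``df_within``.
    """
    groups = np.asarray(pd.Series(list(grouping)).astype("category").cat.codes)
    n = len(d)
    if len(groups) != n:
        raise ValueError("grouping length must match the distance matrix")
    counts = np.bincount(groups)
    if (counts == 1).any():
        warnings.warn("a factor level has a single member", stacklevel=2)
    a = len(counts)
    D2 = d.values**2

    def f_stat(g: np.ndarray) -> tuple[float, float, float]:
        ss_total = D2.sum() / (2.0 * n)
        ss_within = 0.0
        for lvl in range(a):
            idx = np.flatnonzero(g == lvl)
            if len(idx) > 1:
                ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
        ss_between = ss_total - ss_within
        F = (ss_between / (a - 1)) / (ss_within / (n - a))
        return F, ss_between / ss_total, ss_total

    F_obs, r2, _ = f_stat(groups)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        F_perm, _, _ = f_stat(rng.permutation(groups))
        if F_perm >= F_obs - 1e-12:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return {
        "F": float(F_obs),
        "R2": float(r2),
        "p": float(p),
        "df_between": float(a - 1),
        "df_within": float(n - a),
    }
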