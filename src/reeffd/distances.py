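"""Weighted Gower dissimilarity, Cailliez correction and PCoA embedding.

The trait space is built in three steps: (1) a weighted Gower
dissimilarity between binary trait signatures, which lives in [0, 1];
(2) the Cailliez additive correction — the smallest constant added to all
off-diagonal dissimilarities that makes the matrix embeddable in
Euclidean space; (3) principal-coordinates analysis of the corrected
matrix, yielding species coordinates whose Euclidean distances reproduce
the corrected dissimilarities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .trait_coding import BinaryTraitMatrix

__all__ = ["DistanceMatrix", "TraitSpace", "gower", "cailliez", "pcoa", "trait_space"]

_SYM_TOL = 1e-12
_EIG_REL_TOL = 1e-8


@dataclass
class DistanceMatrix:
    """Labeled symmetric dissimilarity matrix with zero diagonal."""

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = list(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] != len(self.labels):
            raise ValueError("values must be square and match the labels")
        if np.abs(v - v.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("distance matrix is not symmetric")
        if (v < 0).any():
            raise ValueError("distances must be non-negative")
        v = (v + v.T) / 2.0
        np.fill_diagonal(v, 0.0)
        self.values = v

    def __len__(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def subset(self, labels: list[str]) -> "DistanceMatrix":
        pos = {l: i for i, l in enumerate(self.labels)}
        idx = np.array([pos[l] for l in labels])
        return DistanceMatrix(labels=list(labels), values=self.values[np.ix_(idx, idx)])


@dataclass
class TraitSpace:
    """PCoA embedding of a (corrected) species dissimilarity matrix.

    ``coordinates`` holds one column per retained axis (positive
    eigenvalues only), ordered by decreasing eigenvalue and scaled so
    that Euclidean distances across all axes reproduce the corrected
    dissimilarities.  ``variance_fractions`` are eigenvalue shares of the
    positive spectrum.
    """

    coordinates: pd.DataFrame
    eigenvalues: np.ndarray
    variance_fractions: np.ndarray
    cailliez_constant: float = 0.0
    _label_pos: dict[str, int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._label_pos = {l: i for i, l in enumerate(self.coordinates.index)}

    @property
    def labels(self) -> list[str]:
        return list(self.coordinates.index)

    @property
    def n_axes(self) -> int:
        return self.coordinates.shape[1]

    def axes(self, which: tuple[int, ...] | None = None, labels=None) -> np.ndarray:
        """Coordinate block for 1-based axis numbers (default: all axes)."""
        coords = self.coordinates if labels is None else self.coordinates.loc[list(labels)]
        if which is None:
            return coords.to_numpy()
        return coords.to_numpy()[:, [a - 1 for a in which]]


def gower(matrix: BinaryTraitMatrix) -> DistanceMatrix:
    """Weighted Gower dissimilarity between binary trait rows.

    ``d(i, j) = sum_k w_k |x_ik - x_jk| / sum_k w_k`` with w_k the inverse
    category count of column k's trait; values lie in [0, 1].
    """
    X = matrix.values()
    if X.shape[1] == 0:
        raise ValueError("binary matrix has no columns")
    w = matrix.weights.to_numpy(dtype=float)
    wn = w / w.sum()
    d = squareform(pdist(X, metric="cityblock", w=wn), checks=False)
    d = np.clip(d, 0.0, 1.0)
    return DistanceMatrix(labels=matrix.species, values=d)


def _centering(n: int) -> np.ndarray:
    return np.eye(n) - np.full((n, n), 1.0 / n)


def cailliez(d: DistanceMatrix) -> tuple[DistanceMatrix, float]:
    """Smallest additive constant making a dissimilarity matrix Euclidean.

    The constant is the largest real eigenvalue of the 2n x 2n block
    matrix ``[[0, 2*D1], [-I, -4*D2]]`` where D1 and D2 are the
    double-centered forms of ``-D**2 / 2`` and ``-D / 2``.  The constant
    is added to every off-diagonal dissimilarity; an already-Euclidean
    input yields a constant of zero.
    """
    D = d.values
    n = len(d)
    J = _centering(n)
    delta1 = J @ (-0.5 * D**2) @ J
    # already-Euclidean input needs no constant: detect it directly from
    # the spectrum of the double-centered matrix (more robust than the
    # near-zero eigenvalue of the block matrix below)
    lam = np.linalg.eigvalsh((delta1 + delta1.T) / 2.0)
    if lam.min() >= -1e-9 * max(lam.max(), 1.0):
        return DistanceMatrix(labels=d.labels, values=D.copy()), 0.0
    delta2 = J @ (-0.5 * D) @ J
    upper = np.hstack([np.zeros((n, n)), 2.0 * delta1])
    lower = np.hstack([-np.eye(n), -4.0 * delta2])
    special = np.vstack([upper, lower])
    eigvals = np.linalg.eigvals(special)
    real = eigvals.real[np.abs(eigvals.imag) < 1e-8 * (1 + np.abs(eigvals.real))]
    c = float(real.max()) if real.size else 0.0
    if c < 1e-10:
        c = 0.0
    corrected = D + c
    np.fill_diagonal(corrected, 0.0)
    return DistanceMatrix(labels=d.labels, values=corrected), c


def pcoa(d: DistanceMatrix, cailliez_constant: float = 0.0) -> TraitSpace:
    """Principal-coordinates analysis of a Euclidean dissimilarity matrix.

    Double-centers ``-D**2 / 2``, eigendecomposes, and keeps axes with
    eigenvalues above ``1e-8 * max(eigenvalue)``.  Coordinates on axis a
    are ``eigenvector_a * sqrt(lambda_a)``.  Each eigenvector's sign is
    fixed so its largest-magnitude loading is positive, making axes
    reproducible across linear-algebra backends.

    Raises
    ------
    ValueError
        For fewer than 3 objects, or a fully degenerate (all points
        identical) configuration.
    """
    n = len(d)
    if n < 3:
        raise ValueError("PCoA needs at least 3 objects to define a 2-D space")
    J = _centering(n)
    B = J @ (-0.5 * d.values**2) @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]

    tol = _EIG_REL_TOL * max(eigvals.max(initial=0.0), 0.0)
    keep = eigvals > max(tol, 0.0)
    if not keep.any():
        raise ValueError("all eigenvalues are zero: points are coincident")
    lam = eigvals[keep]
    vec = eigvecs[:, keep]
    # reproducible sign: largest-|loading| positive on every axis
    flip = vec[np.abs(vec).argmax(axis=0), np.arange(vec.shape[1])] < 0
    vec[:, flip] *= -1.0
    coords = vec * np.sqrt(lam)

    fractions = lam / lam.sum()
    frame = pd.DataFrame(
        coords,
        index=pd.Index(d.labels, name="species"),
        columns=[f"PCoA{i + 1}" for i in range(coords.shape[1])],
    )
    return TraitSpace(
        coordinates=frame,
        eigenvalues=eigvals,
        variance_fractions=fractions,
        cailliez_constant=cailliez_constant,
    )


def trait_space(matrix: BinaryTraitMatrix) -> TraitSpace:
    """Gower -> Cailliez -> PCoA convenience chain for a binary trait matrix."""
    d = gower(matrix)
    corrected, c = cailliez(d)
    return pcoa(corrected, cailliez_constant=c)
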