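"""Normalized Hamming distances, similarity matrices and ordination.

The ordination used for vertical placement is a PCA of the n x n similarity
matrix (one minus normalized Hamming distance) treated as an observations x
features table: columns are mean-centered and components come from an SVD.
Classical principal-coordinates analysis of the distance matrix is available
as an alternative mode.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .io import PhenotypeMatrix

__all__ = [
    "DistanceMatrix",
    "SimilarityMatrix",
    "OrdinationResult",
    "hamming_distance_matrix",
    "similarity_matrix",
    "pca_on_similarity",
    "pcoa_on_distance",
]


@dataclass(frozen=True)
class DistanceMatrix:
    """Square symmetric matrix of normalized distances in [0, 1]."""

    names: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        n = len(self.names)
        if values.shape != (n, n):
            raise ValueError(f"distance matrix shape {values.shape} does not match {n} names")
        if not np.allclose(values, values.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(values), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (values < -1e-12).any() or (values > 1 + 1e-12).any():
            raise ValueError("distances must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.names)

    def upper_triangle(self) -> np.ndarray:
        """Strict upper triangle, vectorized row-major (i < j)."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def write_csv(self, path: str | Path, sep: str = ",") -> None:
        with Path(path).open("w", newline="", encoding="utf-8") as fh:
            w = csv.writer(fh, delimiter=sep)
            w.writerow([""] + list(self.names))
            for name, row in zip(self.names, self.values):
                w.writerow([name] + [repr(float(v)) for v in row])


@dataclass(frozen=True)
class SimilarityMatrix:
    """One minus a distance matrix: entries in [0, 1], unit diagonal."""

    names: tuple[str, ...]
    values: np.ndarray


@dataclass(frozen=True)
class OrdinationResult:
    """Per-entity coordinates on principal components plus variance fractions."""

    names: tuple[str, ...]
    coordinates: np.ndarray  # entities x components
    variance_explained: np.ndarray  # non-increasing fractions, sum <= 1

    def component(self, k: int = 1) -> np.ndarray:
        """Coordinates on the k-th component (1-based)."""
        return self.coordinates[:, k - 1]


def hamming_distance_matrix(m: PhenotypeMatrix, axis: str = "strains") -> DistanceMatrix:
    """Pairwise normalized Hamming distances between rows or columns of ``m``.

    ``d(i, j)`` is the number of differing positions divided by the profile
    length.
    """
    if axis == "strains":
        names, profiles = m.strain_names, m.values
    elif axis == "resources":
        names, profiles = m.resource_names, m.values.T
    else:
        raise ValueError(f"axis must be 'strains' or 'resources', got {axis!r}")
    if len(names) == 1:
        return DistanceMatrix(names, np.zeros((1, 1)))
    d = squareform(pdist(profiles.astype(float), metric="hamming"))
    return DistanceMatrix(names, d)


def similarity_matrix(d: DistanceMatrix) -> SimilarityMatrix:
    """Entry-wise ``1 - d``; diagonal becomes all ones."""
    return SimilarityMatrix(d.names, 1.0 - d.values)


def pca_on_similarity(s: SimilarityMatrix) -> OrdinationResult:
    """PCA of the similarity matrix read as observations x features.

    Columns are mean-centered; scores and variance fractions come from the
    SVD of the centered matrix (fraction k = s_k^2 / sum s^2, the n-1
    covariance divisor cancels).  Each component's sign is fixed so the first
    entity with a non-zero coordinate (in input order) is positive.

    Raises ``ValueError`` for n < 2; an all-identical input (zero variance)
    yields zero coordinates and zero fractions with a warning.
    """
    values = np.asarray(s.values, dtype=float)
    n = len(s.names)
    if n < 2:
        raise ValueError("ordination undefined for fewer than 2 entities")
    if values.shape != (n, n) or not np.allclose(values, values.T, atol=1e-10):
        raise ValueError("similarity matrix must be square and symmetric")

    centered = values - values.mean(axis=0, keepdims=True)
    if np.allclose(centered, 0.0, atol=1e-14):
        warnings.warn("zero total variance: all profiles identical, coordinates set to 0")
        return OrdinationResult(s.names, np.zeros((n, n)), np.zeros(n))

    u, sv, _ = np.linalg.svd(centered, full_matrices=False)
    coords = u * sv  # scores: centered @ V
    fractions = sv**2 / np.sum(sv**2)
    _fix_signs(coords)
    return OrdinationResult(s.names, coords, fractions)


def pcoa_on_distance(d: DistanceMatrix) -> OrdinationResult:
    """Classical PCoA (Torgerson scaling) of a distance matrix.

    Alternative ordination mode; negative eigenvalues are dropped and the
    variance fractions are taken over the positive spectrum.
    """
    n = d.n
    if n < 2:
        raise ValueError("ordination undefined for fewer than 2 entities")
    d2 = d.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ d2 @ j
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    pos = eigvals > max(1e-12, 1e-10 * abs(eigvals[0]))
    if not pos.any():
        warnings.warn("zero total variance: all profiles identical, coordinates set to 0")
        return OrdinationResult(d.names, np.zeros((n, n)), np.zeros(n))
    eigvals, eigvecs = eigvals[pos], eigvecs[:, pos]
    coords = eigvecs * np.sqrt(eigvals)
    fractions = eigvals / eigvals.sum()
    _fix_signs(coords)
    return OrdinationResult(d.names, coords, fractions)


def _fix_signs(coords: np.ndarray, tol: float = 1e-12) -> None:
    """Flip each component so the first non-zero coordinate in input order is >= 0."""
    for k in range(coords.shape[1]):
        col = coords[:, k]
        nz = np.flatnonzero(np.abs(col) > tol)
        if nz.size and col[nz[0]] < 0:
            coords[:, k] = -col
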