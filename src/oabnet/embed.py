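"""Two-component PCA of the score matrix for cluster visualization.

Coordinates are the centered data projected on the top-2 eigenvectors
of the covariance matrix.  Eigenvector sign is arbitrary, so a fixed
convention is applied: the largest-magnitude loading of each component
is made positive, keeping plots and regression tests stable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .errors import ValidationError
from .preprocess import ScoreMatrix


@dataclass
class Embedding2D:
    coords: np.ndarray  # (n, 2), unitless principal-component scores
    explained_variance_ratio: np.ndarray  # (2,), non-increasing
    loadings: np.ndarray  # (5, 2), orthonormal columns
    total_variance: float  # sum over all 5 components, for conservation checks
    patient_ids: list[str] | None = None


def pca_2d(matrix: ScoreMatrix) -> Embedding2D:
    """Project onto the first two principal components."""
    values = np.asarray(matrix.values, dtype=float)
    n, p = values.shape
    if n < 3 or p < 2:
        raise ValidationError("PCA requires at least 3 rows and 2 columns")

    full = PCA(n_components=min(n, p))
    full.fit(values)
    total_variance = float(full.explained_variance_.sum())

    pca = PCA(n_components=2)
    coords = pca.fit_transform(values)
    loadings = pca.components_.T.copy()  # (p, 2)
    evr = pca.explained_variance_ratio_.copy()

    if pca.explained_variance_[1] <= 1e-12 * max(pca.explained_variance_[0], 1.0):
        warnings.warn(
            "input is rank-deficient; second component has zero variance",
            stacklevel=2,
        )

    # deterministic sign: largest-magnitude loading of each component positive
    for j in range(2):
        idx = int(np.argmax(np.abs(loadings[:, j])))
        if loadings[idx, j] < 0:
            loadings[:, j] *= -1.0
            coords[:, j] *= -1.0

    return Embedding2D(
        coords=coords,
        explained_variance_ratio=evr,
        loadings=loadings,
        total_variance=total_variance,
        patient_ids=list(matrix.patient_ids),
    )
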