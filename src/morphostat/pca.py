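"""Covariance-matrix PCA and the degenerated morphospace.

The Z-value matrix (samples x parameters, typically ~120 x 501) is
column-centered and decomposed by PCA of the sample variance-covariance
matrix (n-1 denominator).  Because rows << columns the decomposition runs
through the thin SVD of the centered data, which is algebraically
identical to eigendecomposing the covariance matrix.  The *degenerated*
space keeps the smallest number of leading components whose cumulative
explained-variance ratio reaches a threshold (0.90 in the study: 44 PCs
for the full sample-level matrix, 8 for the strain-mean matrix).

Loading signs are fixed deterministically: each loading vector is flipped
so its largest-magnitude entry is positive, making results reproducible
across linear-algebra backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Union

import numpy as np
import pandas as pd

from .glm import ZMatrix


class PCAError(ValueError):
    pass


@dataclass
class PCSpace:
    """A fitted PCA: orthonormal loadings, scores, and variance shares.

    ``n_selected`` is the smallest k whose cumulative explained-variance
    ratio reaches ``threshold``.
    """

    loadings: pd.DataFrame            # parameters x components
    scores: pd.DataFrame              # rows x components
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    n_selected: int
    threshold: float
    centering_means: pd.Series

    @property
    def component_names(self) -> list[str]:
        return list(self.loadings.columns)

    def transform(self, data: pd.DataFrame) -> pd.DataFrame:
        """Project new rows (same parameters) into this space."""
        centered = data[self.centering_means.index] - self.centering_means
        return centered @ self.loadings

    def reconstruct(self, k: int | None = None) -> pd.DataFrame:
        k = k if k is not None else len(self.component_names)
        L = self.loadings.iloc[:, :k]
        return self.scores.iloc[:, :k] @ L.T + self.centering_means


def pca_covariance(z: Union[ZMatrix, pd.DataFrame], threshold: float = 0.90
                   ) -> PCSpace:
    """PCA of the sample covariance matrix of ``z`` (rows are observations).

    Columns are mean-centered first.  Zero-variance columns must be
    excluded upstream; they are rejected here because they would silently
    distort the variance ratios.
    """
    X = z.usable() if isinstance(z, ZMatrix) else z
    if X.isna().any().any():
        raise PCAError("missing values present; exclude incomplete columns first")
    n, p = X.shape
    if n < 2:
        raise PCAError("need >= 2 rows for PCA")
    if not 0.0 < threshold <= 1.0:
        raise PCAError("threshold must be in (0, 1]")
    variances = X.var(axis=0, ddof=1)
    zero = variances.index[variances == 0.0]
    if len(zero):
        raise PCAError(f"zero-variance columns present: {list(zero[:5])}")

    means = X.mean(axis=0)
    C = (X - means).to_numpy(dtype=float)
    # rows << columns: thin SVD of the centered data == covariance eigen
    U, s, Vt = np.linalg.svd(C, full_matrices=False)
    eig = s**2 / (n - 1)
    # deterministic sign: largest-|.| loading entry positive
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.argmax(np.abs(Vt), axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    scores = C @ Vt.T

    total = eig.sum()
    ratio = eig / total if total > 0 else np.zeros_like(eig)
    names = [f"PC{i + 1}" for i in range(len(eig))]
    loadings = pd.DataFrame(Vt.T, index=X.columns, columns=names)
    scores_df = pd.DataFrame(scores, index=X.index, columns=names)
    space = PCSpace(loadings, scores_df, eig, ratio, 0, threshold, means)
    space.n_selected = select_pcs(space, threshold)
    return space


def select_pcs(space: Union[PCSpace, np.ndarray], threshold: float) -> int:
    """Smallest k with cumulative explained-variance ratio >= threshold."""
    if not 0.0 < threshold <= 1.0:
        raise PCAError("threshold must be in (0, 1]")
    ratio = (
        space.explained_variance_ratio
        if isinstance(space, PCSpace)
        else np.asarray(space, dtype=float)
    )
    cum = np.cumsum(ratio)
    # tolerate float roundoff at the boundary (e.g. 10 equal eigenvalues)
    hit = np.nonzero(cum >= threshold - 1e-12)[0]
    return int(hit[0]) + 1 if len(hit) else len(ratio)
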