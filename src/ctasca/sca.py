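"""Simultaneous component analysis of effect matrices: centered SVD-PCA.

Scores and loadings follow the standardisation T = sqrt(n-1) * U_A and
P = V_A S_A / sqrt(n-1), so that T P' reproduces the rank-A SVD truncation of
the centered matrix and every score column has unit sample variance.  The
sign of each component is fixed so the largest-magnitude loading entry is
positive, making runs reproducible.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DatasetDims
from .effects import reshape_individual

logger = logging.getLogger(__name__)

GEOMETRIES = ("trajectory", "individual")


def center_columns(M: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Remove column means; return (centered matrix, means)."""
    M = np.asarray(M, dtype=float)
    if M.shape[0] < 2:
        raise ValueError("need at least 2 rows to center")
    means = M.mean(axis=0)
    return M - means, means


@dataclass
class SCAResult:
    """Scores, loadings and explained variance of one effect-matrix PCA."""

    scores: np.ndarray  # n x A, unit sample variance per column
    loadings: np.ndarray  # m x A
    singular_values: np.ndarray  # (A,)
    explained_variance: np.ndarray  # (A,) fractions of total variance
    column_means: np.ndarray  # (m,)
    geometry: str = "trajectory"
    row_labels: pd.DataFrame | None = None
    col_labels: list[str] | None = None

    @property
    def A(self) -> int:
        return self.scores.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Rank-A reconstruction of the centered matrix (T P')."""
        return self.scores @ self.loadings.T

    def scores_frame(self) -> pd.DataFrame:
        out = self.row_labels.copy() if self.row_labels is not None else pd.DataFrame(
            index=range(len(self.scores))
        )
        for a in range(self.A):
            out[f"PC{a + 1}"] = self.scores[:, a]
        return out

    def loadings_frame(self) -> pd.DataFrame:
        labels = self.col_labels or [f"v{i}" for i in range(len(self.loadings))]
        out = pd.DataFrame({"variable": labels})
        for a in range(self.A):
            out[f"PC{a + 1}"] = self.loadings[:, a]
        return out


def effective_components(M: np.ndarray, A: int, geometry: str, dims: DatasetDims) -> int:
    """Clip a requested component count to the matrix's centered rank."""
    M = np.asarray(M, dtype=float)
    if geometry == "individual":
        M = reshape_individual(M, dims)
    Mc = M - M.mean(axis=0)
    s = np.linalg.svd(Mc, compute_uv=False)
    tol = max(Mc.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    return int(min(A, np.sum(s > tol)))


def pca_svd(Mc: np.ndarray, A: int) -> SCAResult:
    """PCA of a column-centered matrix via SVD with the score standardisation.

    ``A`` may not exceed the numerical rank of ``Mc``.  Explained variance
    fractions are singular values squared over their total.
    """
    Mc = np.asarray(Mc, dtype=float)
    n = Mc.shape[0]
    U, s, Vt = np.linalg.svd(Mc, full_matrices=False)
    tol = max(Mc.shape) * np.finfo(float).eps * (s[0] if len(s) else 0.0)
    rank = int(np.sum(s > tol))
    if A > rank:
        raise ValueError(f"A={A} exceeds the numerical rank {rank} of the matrix")
    if A < 1:
        raise ValueError("A must be >= 1")
    s_total2 = float(np.sum(s**2))
    U, s, Vt = U[:, :A], s[:A], Vt[:A]
    # deterministic sign: largest-|loading| entry positive per component
    P_unsigned = Vt.T * s
    flip = np.sign(P_unsigned[np.argmax(np.abs(P_unsigned), axis=0), np.arange(A)])
    flip[flip == 0] = 1.0
    U = U * flip
    Vt = Vt * flip[:, None]
    scale = np.sqrt(n - 1)
    T = scale * U
    P = Vt.T * (s / scale)
    return SCAResult(
        scores=T,
        loadings=P,
        singular_values=s,
        explained_variance=s**2 / s_total2,
        column_means=Mc.mean(axis=0),
    )


def analyse_effect(
    M: np.ndarray,
    geometry: str,
    A: int,
    dims: DatasetDims,
    row_labels: pd.DataFrame | None = None,
    col_labels: list[str] | None = None,
) -> SCAResult | None:
    """Center and PCA one effect matrix in the requested geometry.

    ``trajectory`` analyses the IHK x J matrix directly: score rows carry
    (subject, treatment, time) labels and loadings the J response labels.
    ``individual`` reshapes to I x HKJ first: one score row per subject.
    A zero matrix has no principal components; ``None`` is returned with a
    warning.
    """
    if geometry not in GEOMETRIES:
        raise ValueError(f"geometry must be one of {GEOMETRIES}")
    M = np.asarray(M, dtype=float)
    if geometry == "individual":
        M = reshape_individual(M, dims)
        if row_labels is not None:
            subjects = row_labels["subject"].astype(str).unique()
            row_labels = pd.DataFrame({"subject": subjects})
        if col_labels is not None:
            col_labels = [
                f"{h}:{t}:{j}"
                for h, t in row_labels_cells(dims)
                for j in col_labels
            ]
    Mc, means = center_columns(M)
    if not np.any(np.abs(Mc) > 1e-300):
        warnings.warn("effect matrix is zero after centering; no components to extract")
        return None
    res = pca_svd(Mc, A)
    res.geometry = geometry
    res.row_labels = row_labels.reset_index(drop=True) if row_labels is not None else None
    res.col_labels = col_labels
    res.column_means = means
    return res


def row_labels_cells(dims: DatasetDims) -> list[tuple[str, str]]:
    """(treatment, time) cell labels in canonical order, as generic indices."""
    return [(f"h{h + 1}", f"k{k + 1}") for h in range(dims.H) for k in range(dims.K)]
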