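"""Decomposition of the response matrix into additive effect matrices.

The fitted model splits Y (IHK x J) into six named effect matrices plus a
residual:

    Y = M0f + MTf + MTGf + M0r + MTr + MTGr + E

where M0*, MT*, MTG* collect the intercept, time and time-treatment
interaction columns of the design, the ``f``/``r`` superscripts distinguish
fixed-effect from random-effect (BLUP) contributions, and E holds residuals
(missing where the observation is missing).  Every effect matrix is populated
on all design rows — model predictions fill cells whose observation is
missing — so the matrices stay rectangular for the PCA step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import DatasetDims, LongDataset
from .lmm import MultivariateFit

GROUPS = ("baseline", "time", "time_treatment")
_GROUP_TO_COLS = {"baseline": "intercept", "time": "time", "time_treatment": "time_treatment"}

#: canonical effect-matrix names in summation order
EFFECT_NAMES = ("M0f", "MTf", "MTGf", "M0r", "MTr", "MTGr")

_NAME_TO_PARTS = {
    "M0f": ("baseline", "fixed"),
    "MTf": ("time", "fixed"),
    "MTGf": ("time_treatment", "fixed"),
    "M0r": ("baseline", "random"),
    "MTr": ("time", "random"),
    "MTGr": ("time_treatment", "random"),
}


def effect_matrix(fit: MultivariateFit, group: str, kind: str) -> np.ndarray:
    """One IHK x J effect matrix.

    ``group`` selects the design columns (``baseline`` / ``time`` /
    ``time_treatment``); ``kind`` selects fixed effects (X columns times the
    matching rows of B) or random effects (the analogous per-subject product
    with the BLUPs).
    """
    if group not in _GROUP_TO_COLS:
        raise ValueError(f"unknown effect group {group!r}; expected one of {GROUPS}")
    if kind not in ("fixed", "random"):
        raise ValueError(f"kind must be 'fixed' or 'random', got {kind!r}")
    design = fit.design
    cols = design.column_groups[_GROUP_TO_COLS[group]]
    if kind == "fixed":
        return design.X[:, cols] @ fit.B[cols, :]
    # random: columns of Z belonging to this group, per subject block
    slots = np.flatnonzero(np.isin(design.random_cols, cols))
    n, J = len(design.X), fit.J
    if len(slots) == 0:
        return np.zeros((n, J))
    gamma = fit.gamma_tensor()  # I x q x J
    Zg = design.Z[:, slots]  # n x s
    return np.einsum("ns,nsj->nj", Zg, gamma[design.subject_index][:, slots, :])


def combine(matrices: list[np.ndarray]) -> np.ndarray:
    """Elementwise sum of same-shape effect matrices."""
    if not matrices:
        raise ValueError("need at least one matrix")
    shape = matrices[0].shape
    for M in matrices[1:]:
        if M.shape != shape:
            raise ValueError(f"shape mismatch: {M.shape} vs {shape}")
    return np.sum(matrices, axis=0)


@dataclass
class EffectMatrices:
    """The six named effect matrices plus residuals for one fitted model."""

    M0f: np.ndarray
    MTf: np.ndarray
    MTGf: np.ndarray
    M0r: np.ndarray
    MTr: np.ndarray
    MTGr: np.ndarray
    E: np.ndarray  # NaN where the observation is missing
    row_labels: pd.DataFrame
    response_cols: list[str]
    dims: DatasetDims

    def __getitem__(self, name: str) -> np.ndarray:
        if name not in EFFECT_NAMES and name != "E":
            raise KeyError(name)
        return getattr(self, name)

    def get(self, expression: str) -> np.ndarray:
        """Resolve an effect expression such as ``"MTf"`` or ``"MTf+MTGf"``."""
        names = [s.strip() for s in expression.split("+")]
        for nm in names:
            if nm not in EFFECT_NAMES:
                raise ValueError(f"unknown effect name {nm!r}; expected ones of {EFFECT_NAMES}")
        return combine([self[nm] for nm in names])

    def model_sum(self) -> np.ndarray:
        return combine([self[nm] for nm in EFFECT_NAMES])

    def to_frame(self, name: str) -> pd.DataFrame:
        out = self.row_labels.copy()
        out[self.response_cols] = self[name]
        return out


def decompose(fit: MultivariateFit, data: LongDataset) -> EffectMatrices:
    """Compute all six effect matrices and the residuals for a fitted model."""
    parts = {nm: effect_matrix(fit, *_NAME_TO_PARTS[nm]) for nm in EFFECT_NAMES}
    Y = data.Y
    E = Y - combine(list(parts.values()))  # NaN propagates to unobserved cells
    return EffectMatrices(
        **parts,
        E=E,
        row_labels=data.row_labels,
        response_cols=list(data.response_cols),
        dims=data.dims,
    )


def reshape_individual(M: np.ndarray, dims: DatasetDims) -> np.ndarray:
    """Reshape an IHK x J effect matrix to I x HKJ (one row per subject).

    Row ``i`` concatenates the subject's (treatment, time) rows in canonical
    order with the J response entries as the fastest-varying axis per cell,
    i.e. element order (h, k, j).
    """
    M = np.asarray(M)
    if M.shape[0] != dims.n_rows:
        raise ValueError(f"expected {dims.n_rows} rows (IHK), got {M.shape[0]}")
    if M.shape[1] != dims.J:
        raise ValueError(f"expected {dims.J} columns (J), got {M.shape[1]}")
    return M.reshape(dims.I, dims.H * dims.K * dims.J)


def inverse_reshape_individual(M: np.ndarray, dims: DatasetDims) -> np.ndarray:
    """Inverse of :func:`reshape_individual`."""
    M = np.asarray(M)
    if M.shape != (dims.I, dims.H * dims.K * dims.J):
        raise ValueError(f"expected shape {(dims.I, dims.H * dims.K * dims.J)}, got {M.shape}")
    return M.reshape(dims.n_rows, dims.J)
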