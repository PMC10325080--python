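"""Time-basis expansions, sum-coded treatment contrasts and design matrices.

The fixed design for one subject takes the form ``[1 | f(t) | f(t) * g]``
where ``f`` is a polynomial or natural-cubic-spline basis of the numeric time
variable and ``g`` is the sum-coded treatment contrast.  There is no
treatment main-effect column: the model assumes treatments do not differ at
the time origin, so the interaction columns must vanish there.  The random
design mirrors the fixed design per subject (or is reduced to a random
intercept) and is stored implicitly via a subject index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SUBJECT, TIME, TREATMENT, LongDataset


def polynomial_basis(t: np.ndarray, degree: int) -> np.ndarray:
    """Raw polynomial basis ``[t, t^2, ..., t^degree]`` (no intercept column)."""
    if degree < 1:
        raise ValueError(f"degree must be >= 1, got {degree}")
    t = np.asarray(t, dtype=float)
    return np.column_stack([t**m for m in range(1, degree + 1)])


def natural_spline_basis(
    t: np.ndarray,
    df: int,
    boundary_knots: tuple[float, float] | None = None,
    interior_knots: np.ndarray | None = None,
) -> np.ndarray:
    """Natural cubic spline basis with ``df`` columns (no intercept column).

    Uses the truncated-power construction of the natural cubic spline space:
    with knots ``xi_1 < ... < xi_m`` (boundary knots included) the non-constant
    part of the space is spanned by ``t`` together with the ``m - 2``
    functions ``d_k(t) - d_{m-1}(t)`` where

        d_k(t) = [ (t - xi_k)_+^3 - (t - xi_m)_+^3 ] / (xi_m - xi_k).

    Each basis function is C^2 everywhere and exactly linear outside the
    boundary knots.  The basis is anchored to equal 0 at the lower boundary
    knot so the intercept keeps its time-origin meaning and interaction
    columns vanish at baseline.

    When ``interior_knots`` is omitted, ``df - 1`` interior knots are placed
    at equally spaced quantiles of ``t``; boundary knots default to
    ``(min(t), max(t))``.
    """
    if df < 1:
        raise ValueError(f"df must be >= 1, got {df}")
    t = np.asarray(t, dtype=float)
    distinct = np.unique(t)
    if df > len(distinct):
        raise ValueError(f"df={df} exceeds the number of distinct time values ({len(distinct)})")
    if boundary_knots is None:
        boundary_knots = (float(distinct.min()), float(distinct.max()))
    lo, hi = map(float, boundary_knots)
    if not lo < hi:
        raise ValueError(f"boundary knots must be strictly ordered, got ({lo}, {hi})")
    if interior_knots is None:
        probs = np.arange(1, df) / df
        interior_knots = np.quantile(distinct, probs)
    interior_knots = np.asarray(interior_knots, dtype=float)
    if len(interior_knots) != df - 1:
        raise ValueError(f"need {df - 1} interior knots for df={df}, got {len(interior_knots)}")
    if len(interior_knots) and not (
        (interior_knots > lo).all() and (interior_knots < hi).all()
    ):
        raise ValueError("interior knots must lie strictly inside the boundary knots")

    knots = np.concatenate([[lo], np.sort(interior_knots), [hi]])

    def _columns(x: np.ndarray) -> np.ndarray:
        def d(k: int) -> np.ndarray:
            return (
                np.maximum(x - knots[k], 0.0) ** 3 - np.maximum(x - knots[-1], 0.0) ** 3
            ) / (knots[-1] - knots[k])

        cols = [x]
        d_last = d(len(knots) - 2)
        for k in range(len(knots) - 2):
            cols.append(d(k) - d_last)
        return np.column_stack(cols)

    B = _columns(t) - _columns(np.array([lo]))  # anchor: 0 at the lower boundary knot
    return B


@dataclass(frozen=True)
class TimeBasis:
    """Specification of the time-basis expansion.

    ``degree_or_df`` is the polynomial degree or the spline degrees of
    freedom.  Spline knots may be left unset and are then resolved from the
    observed times when the basis is evaluated.
    """

    kind: str  # "polynomial" | "natural_spline"
    degree_or_df: int
    boundary_knots: tuple[float, float] | None = None
    interior_knots: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("polynomial", "natural_spline"):
            raise ValueError(f"unknown basis kind {self.kind!r}")
        if self.degree_or_df < 1:
            raise ValueError("degree_or_df must be >= 1")
        if self.kind == "polynomial" and (self.boundary_knots or self.interior_knots):
            raise ValueError("polynomial basis takes no knots")

    @property
    def n_columns(self) -> int:
        return self.degree_or_df

    def resolve(self, t: np.ndarray) -> "TimeBasis":
        """Fill in default knots from the observed times (spline only)."""
        if self.kind == "polynomial":
            return self
        distinct = np.unique(np.asarray(t, dtype=float))
        bk = self.boundary_knots or (float(distinct.min()), float(distinct.max()))
        ik = self.interior_knots
        if ik is None:
            probs = np.arange(1, self.degree_or_df) / self.degree_or_df
            ik = tuple(float(v) for v in np.quantile(distinct, probs))
        return TimeBasis(self.kind, self.degree_or_df, tuple(bk), tuple(ik))

    def evaluate(self, t: np.ndarray) -> np.ndarray:
        if self.kind == "polynomial":
            return polynomial_basis(t, self.degree_or_df)
        resolved = self.resolve(t)
        return natural_spline_basis(
            t,
            resolved.degree_or_df,
            boundary_knots=resolved.boundary_knots,
            interior_knots=np.asarray(resolved.interior_knots),
        )


@dataclass(frozen=True)
class TreatmentCoding:
    """Sum coding of the treatment factor.

    For ``H`` levels the contrast matrix has ``H - 1`` columns, each summing
    to zero over the levels.  For the two-level case the first level in
    sorted order codes as +1 and the second as -1.
    """

    levels: tuple[str, ...]
    contrasts: np.ndarray  # H x (H-1)

    @property
    def codes(self) -> dict[str, float]:
        """Level -> contrast value (two-level designs only)."""
        if len(self.levels) != 2:
            raise ValueError("scalar codes are only defined for H=2")
        return {lvl: float(self.contrasts[i, 0]) for i, lvl in enumerate(self.levels)}

    def row(self, level: str) -> np.ndarray:
        return self.contrasts[self.levels.index(level)]


def sum_code(levels) -> TreatmentCoding:
    """Build the sum-coded contrast for the given treatment labels."""
    levels = tuple(sorted(str(v) for v in dict.fromkeys(levels)))
    H = len(levels)
    if H < 2:
        raise ValueError(f"need at least 2 treatment levels, got {levels}")
    C = np.zeros((H, H - 1))
    C[: H - 1, :] = np.eye(H - 1)
    C[H - 1, :] = -1.0
    return TreatmentCoding(levels=levels, contrasts=C)


@dataclass
class DesignBundle:
    """Stacked fixed/random design matrices plus the column bookkeeping.

    ``X`` is the IHK x p fixed design; the random design is block-diagonal
    with per-subject blocks ``Z_i = X_i[:, random_cols]`` and is never stored
    densely.  ``column_groups`` partitions the p columns into the named
    groups ``intercept`` / ``time`` / ``time_treatment``.
    """

    X: np.ndarray
    column_groups: dict[str, np.ndarray]
    column_names: list[str]
    subject_index: np.ndarray  # row -> subject position (0..I-1), canonical order
    subjects: np.ndarray
    random_cols: np.ndarray  # X columns mirrored into Z_i
    basis: TimeBasis
    coding: TreatmentCoding
    row_labels: pd.DataFrame

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def q(self) -> int:
        return len(self.random_cols)

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def Z(self) -> np.ndarray:
        """Rows of the per-subject random design (IHK x q); block alignment
        is given by ``subject_index``."""
        return self.X[:, self.random_cols]


RANDOM_STRUCTURES = ("mirror_fixed", "intercept_only", "none")


def build_design(
    data: LongDataset,
    basis: TimeBasis,
    random_structure: str = "mirror_fixed",
) -> DesignBundle:
    """Construct the stacked design matrices for a dataset in canonical order.

    Fixed columns are ``[1 | basis(t) | basis(t) x contrast]`` — no treatment
    main effect, so at the time origin the fixed predictor is identical
    across treatments.
    """
    if random_structure not in RANDOM_STRUCTURES:
        raise ValueError(f"random_structure must be one of {RANDOM_STRUCTURES}")
    t = data.df[TIME].to_numpy(dtype=float)
    basis = basis.resolve(data.times)
    B = basis.evaluate(t)
    nb = B.shape[1]
    coding = sum_code(data.treatments)
    G = np.vstack([coding.row(str(v)) for v in data.df[TREATMENT].astype(str)])  # n x (H-1)

    blocks = [np.ones((len(t), 1)), B]
    names = ["intercept"] + [f"t{m}" for m in range(1, nb + 1)]
    for c in range(G.shape[1]):
        blocks.append(B * G[:, [c]])
        suffix = "" if G.shape[1] == 1 else f".{c + 1}"
        names += [f"t{m}:g{suffix}" for m in range(1, nb + 1)]
    X = np.hstack(blocks)

    groups = {
        "intercept": np.array([0]),
        "time": np.arange(1, 1 + nb),
        "time_treatment": np.arange(1 + nb, X.shape[1]),
    }

    subjects = data.subjects
    pos = {s: i for i, s in enumerate(subjects)}
    subject_index = np.array([pos[s] for s in data.df[SUBJECT].astype(str)])

    if random_structure == "mirror_fixed":
        random_cols = np.arange(X.shape[1])
    elif random_structure == "intercept_only":
        random_cols = np.array([0])
    else:
        random_cols = np.array([], dtype=int)

    return DesignBundle(
        X=X,
        column_groups=groups,
        column_names=names,
        subject_index=subject_index,
        subjects=subjects,
        random_cols=random_cols,
        basis=basis,
        coding=coding,
        row_labels=data.row_labels,
    )
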