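"""Long-format dataset contract, CSV I/O and preprocessing.

A :class:`LongDataset` holds tidy longitudinal observations: one row per
(subject, treatment, time) cell of a complete cross-over grid, with ``J``
numeric response columns.  Rows are kept in a canonical order — subject-major,
then treatment, then ascending time — which every downstream reshape relies
on.  Missing response values are represented as NaN cells; rows are never
dropped, so the design grid stays rectangular.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SUBJECT = "subject"
TREATMENT = "treatment"
TIME = "time"
INDEX_COLS = (SUBJECT, TREATMENT, TIME)

#: default suffix marking a below-detection-limit flag column in CSV files
LOD_SUFFIX = "_lod"


@dataclass(frozen=True)
class DatasetDims:
    """Grid dimensions of a complete long-format dataset."""

    I: int  # subjects
    H: int  # treatments
    K: int  # time points
    J: int  # responses

    def __post_init__(self) -> None:
        for name in ("I", "H", "K", "J"):
            if getattr(self, name) < 1:
                raise ValueError(f"dimension {name} must be >= 1, got {getattr(self, name)}")

    @property
    def n_rows(self) -> int:
        return self.I * self.H * self.K


class LongDataset:
    """Tidy longitudinal observations on a complete (subject, treatment, time) grid.

    Parameters
    ----------
    df
        Data frame with columns ``subject``, ``treatment``, ``time`` plus the
        response columns.  Any row order is accepted; rows are sorted into
        canonical order on construction.
    response_cols
        Names of the response columns, in a fixed order.
    lod
        Optional boolean frame (same index/columns as the responses) flagging
        below-detection-limit cells.
    """

    def __init__(
        self,
        df: pd.DataFrame,
        response_cols: list[str],
        lod: pd.DataFrame | None = None,
    ) -> None:
        missing = [c for c in (*INDEX_COLS, *response_cols) if c not in df.columns]
        if missing:
            raise ValueError(f"missing required columns: {missing}")
        if not response_cols:
            raise ValueError("at least one response column is required")
        df = df.copy()
        if not np.issubdtype(np.asarray(df[TIME]).dtype, np.number):
            try:
                df[TIME] = pd.to_numeric(df[TIME])
            except (ValueError, TypeError) as exc:
                raise ValueError("time column must be numeric") from exc
        dup = df.duplicated(subset=list(INDEX_COLS), keep=False)
        if dup.any():
            triple = df.loc[dup.idxmax(), list(INDEX_COLS)].tolist()
            raise ValueError(f"duplicate (subject, treatment, time) triple: {tuple(triple)}")

        order = np.lexsort(
            (df[TIME].to_numpy(), df[TREATMENT].astype(str).to_numpy(), df[SUBJECT].astype(str).to_numpy())
        )
        df = df.iloc[order].reset_index(drop=True)
        for col in response_cols:
            df[col] = pd.to_numeric(df[col], errors="coerce")
            if np.isinf(df[col].to_numpy(dtype=float, na_value=np.nan)).any():
                raise ValueError(f"response {col!r} contains non-finite values")
        self.df = df
        self.response_cols = list(response_cols)
        if lod is not None:
            lod = lod.iloc[order].reset_index(drop=True).astype(bool)
            if list(lod.columns) != self.response_cols or len(lod) != len(df):
                raise ValueError("lod frame must match the response columns and row count")
        self.lod = lod
        self._validate_grid()

    def _validate_grid(self) -> None:
        subjects = self.subjects
        treatments = self.treatments
        times = self.times
        expected = len(subjects) * len(treatments) * len(times)
        if len(self.df) != expected:
            raise ValueError(
                f"incomplete design grid: {len(self.df)} rows, expected "
                f"{len(subjects)}x{len(treatments)}x{len(times)} = {expected}"
            )
        # canonical order implies the grid is the cartesian product in order
        tiled_t = np.tile(times, len(subjects) * len(treatments))
        if not np.allclose(self.df[TIME].to_numpy(dtype=float), tiled_t):
            raise ValueError("rows do not form a complete subject x treatment x time grid")

    # ------------------------------------------------------------------ views
    @property
    def subjects(self) -> np.ndarray:
        return np.unique(self.df[SUBJECT].astype(str).to_numpy())

    @property
    def treatments(self) -> np.ndarray:
        return np.unique(self.df[TREATMENT].astype(str).to_numpy())

    @property
    def times(self) -> np.ndarray:
        return np.unique(self.df[TIME].to_numpy(dtype=float))

    @property
    def dims(self) -> DatasetDims:
        return DatasetDims(
            I=len(self.subjects), H=len(self.treatments), K=len(self.times), J=len(self.response_cols)
        )

    @property
    def Y(self) -> np.ndarray:
        """Response matrix, IHK x J, NaN where missing."""
        return self.df[self.response_cols].to_numpy(dtype=float)

    @property
    def row_labels(self) -> pd.DataFrame:
        return self.df[list(INDEX_COLS)].copy()

    def replace_responses(self, Y: np.ndarray) -> "LongDataset":
        df = self.df.copy()
        df[self.response_cols] = np.asarray(Y, dtype=float)
        return LongDataset(df, self.response_cols, lod=self.lod)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        d = self.dims
        return f"LongDataset(I={d.I}, H={d.H}, K={d.K}, J={d.J})"


# ---------------------------------------------------------------------- I/O

def read_long_csv(
    path,
    column_map: dict | None = None,
) -> LongDataset:
    """Read a long-format CSV into a :class:`LongDataset`.

    ``column_map`` may remap the index columns and select responses::

        {"subject": "ID", "treatment": "arm", "time": "minutes",
         "responses": ["glc", "lac"], "lod_suffix": "_lod"}

    When ``responses`` is omitted, every column other than the index columns
    (and any LOD-flag columns) is treated as a response.  Unparseable response
    cells become missing, with a logged count.
    """
    column_map = dict(column_map or {})
    raw = pd.read_csv(path, float_precision="round_trip")
    rename = {}
    for key in INDEX_COLS:
        src = column_map.get(key, key)
        if src not in raw.columns:
            raise ValueError(f"column {src!r} (mapped to {key!r}) not found in {path}")
        rename[src] = key
    raw = raw.rename(columns=rename)
    lod_suffix = column_map.get("lod_suffix", LOD_SUFFIX)
    responses = column_map.get("responses")
    if responses is None:
        responses = [
            c for c in raw.columns if c not in INDEX_COLS and not c.endswith(lod_suffix)
        ]
    lod_cols = {r: r + lod_suffix for r in responses if r + lod_suffix in raw.columns}
    lod = None
    if lod_cols:
        lod = pd.DataFrame(False, index=raw.index, columns=list(responses))
        for r, c in lod_cols.items():
            lod[r] = raw[c].fillna(0).astype(bool)
    coerced = raw[list(responses)].apply(pd.to_numeric, errors="coerce")
    n_bad = int((coerced.isna() & raw[list(responses)].notna()).sum().sum())
    if n_bad:
        logger.warning("%d unparseable response cells set to missing", n_bad)
    raw[list(responses)] = coerced
    data = LongDataset(raw[[*INDEX_COLS, *responses]], list(responses), lod=lod)
    d = data.dims
    logger.info("read %s: I=%d H=%d K=%d J=%d", path, d.I, d.H, d.K, d.J)
    return data


def write_long_csv(data: LongDataset, path) -> None:
    """Write a dataset back to CSV in canonical row order."""
    out = data.df.copy()
    if data.lod is not None:
        for r in data.response_cols:
            out[r + LOD_SUFFIX] = data.lod[r].astype(int)
    out.to_csv(path, index=False)


# -------------------------------------------------------------- preprocessing

def drop_below_lod(data: LongDataset) -> LongDataset:
    """Set below-detection-limit cells to missing.

    The design grid is preserved: flagged cells become NaN, rows are never
    deleted.  A response whose cells are all flagged is an error.
    """
    if data.lod is None:
        return data
    Y = data.Y
    flags = data.lod.to_numpy(dtype=bool)
    all_flagged = flags.all(axis=0)
    if all_flagged.any():
        bad = data.response_cols[int(np.argmax(all_flagged))]
        raise ValueError(f"response {bad!r} has every measurement below the detection limit")
    per_response = flags.sum(axis=0)
    for name, n in zip(data.response_cols, per_response):
        if n:
            logger.info("below-LOD removal: %s: %d cells set to missing", name, int(n))
    Y = Y.copy()
    Y[flags] = np.nan
    out = data.replace_responses(Y)
    out.lod = None
    return out


def baseline_sd(data: LongDataset, baseline_time: float = 0.0) -> pd.Series:
    """Sample SD (ddof=1) of the baseline observations per response.

    Pooled over subjects and treatment occasions, under the assumption that
    there is no treatment difference at baseline.
    """
    mask = np.isclose(data.df[TIME].to_numpy(dtype=float), baseline_time)
    if not mask.any():
        raise ValueError(f"no observations at baseline time {baseline_time}")
    base = data.df.loc[mask, data.response_cols]
    n = base.notna().sum()
    if (n < 2).any():
        bad = n.index[n < 2].tolist()
        raise ValueError(f"fewer than 2 baseline observations for responses: {bad}")
    return base.std(ddof=1)


def baseline_sd_scale(data: LongDataset, baseline_time: float = 0.0) -> LongDataset:
    """Divide each response by its baseline-time sample SD.

    After scaling, the baseline SD of every response equals 1.  A zero or
    undefined baseline SD is an error (naming the response).
    """
    sd = baseline_sd(data, baseline_time)
    bad = sd.index[~(sd > 0) | ~np.isfinite(sd)].tolist()
    if bad:
        raise ValueError(f"zero or undefined baseline SD for responses: {bad}")
    Y = data.Y / sd.to_numpy()[None, :]
    return data.replace_responses(Y)
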