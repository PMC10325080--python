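"""Bootstrap confidence intervals for scores and loadings.

Subjects are resampled with replacement (each drawn subject carries its whole
cross-over series); the model is re-estimated on every replicate, replicate
loadings are rotated towards the reference loadings by orthogonal Procrustes
analysis, scores are rotated with the same rotation, and elementwise
percentile bounds are taken over the aligned replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datamodel import SUBJECT, TIME, TREATMENT, LongDataset
from .design import TimeBasis, build_design
from .effects import decompose
from .lmm import fit_all
from .sca import SCAResult, analyse_effect

logger = logging.getLogger(__name__)


def bootstrap_subjects(data: LongDataset, n_boot: int, seed: int) -> list[LongDataset]:
    """Subject-level bootstrap replicates of a dataset.

    Each replicate draws I subjects with replacement; a drawn subject keeps
    all of its rows across treatments and times.  Duplicated subjects are
    given fresh unique ids so the mixed model treats them as distinct
    grouping units.  Reproducible from ``seed``.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    subjects = data.subjects
    I = len(subjects)
    blocks = {s: g for s, g in data.df.groupby(data.df[SUBJECT].astype(str), sort=False)}
    seeds = np.random.SeedSequence(seed).spawn(n_boot)
    out = []
    for r in range(n_boot):
        rng = np.random.default_rng(seeds[r])
        draw = rng.choice(subjects, size=I, replace=True)
        frames = []
        for slot, s in enumerate(draw):
            g = blocks[s].copy()
            g[SUBJECT] = f"b{slot:03d}:{s}"
            frames.append(g)
        df = pd.concat(frames, ignore_index=True)
        out.append(LongDataset(df, data.response_cols))
    return out


def procrustes_align(
    P_boot: np.ndarray, P_ref: np.ndarray, T_boot: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Rotate replicate loadings (and scores) towards the reference loadings.

    The rotation R minimises ||P_boot R - P_ref||_F over orthogonal matrices;
    closed form R = W V' from the SVD  P_boot' P_ref = W Sigma V'.
    Returns (P_boot R, T_boot R, R).
    """
    P_boot = np.asarray(P_boot, dtype=float)
    P_ref = np.asarray(P_ref, dtype=float)
    if P_boot.shape != P_ref.shape:
        raise ValueError(f"loading shape mismatch: {P_boot.shape} vs {P_ref.shape}")
    W, _, Vt = np.linalg.svd(P_boot.T @ P_ref)
    R = W @ Vt
    T_rot = None if T_boot is None else np.asarray(T_boot) @ R
    return P_boot @ R, T_rot, R


def percentile_ci(stack: np.ndarray, level: float = 0.95) -> tuple[np.ndarray, np.ndarray]:
    """Elementwise percentile bounds over replicates (axis 0)."""
    stack = np.asarray(stack, dtype=float)
    if stack.shape[0] < 2:
        raise ValueError("need at least 2 replicates for percentile bounds")
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    alpha = (1.0 - level) / 2.0
    # order-statistic (conservative) percentiles: with 2 replicates the
    # bounds collapse to the elementwise min/max
    lower = np.percentile(stack, 100 * alpha, axis=0, method="lower")
    upper = np.percentile(stack, 100 * (1 - alpha), axis=0, method="higher")
    return lower, upper


@dataclass
class BootstrapResult:
    """Percentile bounds aligned to a reference SCA result.

    Score bounds are keyed by (treatment, time, component) — fixed-effect
    trajectory scores are constant across subjects, so the unique
    (treatment, time) cells identify them across replicates.  Loading bounds
    are keyed by (variable, component).
    """

    n_boot: int
    level: float
    reference: SCAResult
    score_table: pd.DataFrame  # treatment, time, component, value, lower, upper
    loading_table: pd.DataFrame  # variable, component, value, lower, upper
    replicate_failures: int

    @property
    def score_bounds(self) -> np.ndarray:
        return self.score_table[["lower", "upper"]].to_numpy()

    @property
    def loading_bounds(self) -> np.ndarray:
        return self.loading_table[["lower", "upper"]].to_numpy()


def _cell_scores(scores: np.ndarray, row_labels: pd.DataFrame) -> pd.DataFrame:
    """Collapse trajectory scores to unique (treatment, time) cells.

    Valid for fixed-effect matrices, whose rows repeat across subjects; the
    mean over subjects is taken (a no-op up to floating noise).
    """
    df = row_labels[[TREATMENT, TIME]].copy()
    for a in range(scores.shape[1]):
        df[f"PC{a + 1}"] = scores[:, a]
    return df.groupby([TREATMENT, TIME], sort=True).mean().reset_index()


def bootstrap_pipeline(
    data: LongDataset,
    basis: TimeBasis,
    effect: str,
    A: int,
    n_boot: int = 100,
    level: float = 0.95,
    seed: int = 0,
    random_structure: str = "mirror_fixed",
    backend: str = "profiled",
) -> BootstrapResult:
    """End-to-end bootstrap CIs for a fixed-effect trajectory analysis.

    ``effect`` names a fixed-effect matrix or a sum of them (``"MTf"``,
    ``"MTf+MTGf"``, ...).  The reference model is fitted on the full data;
    every replicate is refitted, Procrustes-aligned to the reference via its
    loadings, and the percentile bounds of the aligned scores (per
    treatment-time cell) and loadings are collected.  Replicates whose fits
    fail are dropped and counted; more than 50% failures is an error.
    """
    names = [s.strip() for s in effect.split("+")]
    if any(not nm.endswith("f") for nm in names):
        raise ValueError(
            "bootstrap CIs are only defined for fixed-effect matrices: their "
            "trajectory scores are identified by (treatment, time) across replicates"
        )
    design = build_design(data, basis, random_structure)
    fit = fit_all(data, design, backend=backend)
    em = decompose(fit, data)
    ref = analyse_effect(
        em.get(effect), "trajectory", A, data.dims,
        row_labels=data.row_labels, col_labels=data.response_cols,
    )
    if ref is None:
        raise ValueError(f"effect {effect!r} is zero; nothing to bootstrap")
    ref_cells = _cell_scores(ref.scores, data.row_labels)

    score_reps, loading_reps = [], []
    failures = 0
    for rep_data in bootstrap_subjects(data, n_boot, seed):
        try:
            rep_design = build_design(rep_data, basis, random_structure)
            warm = fit if backend == "profiled" else None
            rep_fit = fit_all(rep_data, rep_design, backend=backend, warm_from=warm)
            rep_em = decompose(rep_fit, rep_data)
            rep = analyse_effect(
                rep_em.get(effect), "trajectory", A, rep_data.dims,
                row_labels=rep_data.row_labels, col_labels=rep_data.response_cols,
            )
            if rep is None or any(not f.converged for f in rep_fit.per_variable):
                raise RuntimeError("replicate fit did not converge")
        except Exception as exc:
            failures += 1
            logger.warning("bootstrap replicate dropped: %s", exc)
            continue
        P_rot, T_rot, _ = procrustes_align(rep.loadings, ref.loadings, rep.scores)
        cells = _cell_scores(T_rot, rep_data.row_labels)
        score_reps.append(cells[[f"PC{a + 1}" for a in range(A)]].to_numpy())
        loading_reps.append(P_rot)
    if failures > n_boot / 2:
        raise RuntimeError(
            f"unstable model: {failures}/{n_boot} bootstrap replicates failed"
        )
    if len(score_reps) < 2:
        raise RuntimeError("fewer than 2 successful bootstrap replicates")

    s_lo, s_hi = percentile_ci(np.stack(score_reps), level)
    l_lo, l_hi = percentile_ci(np.stack(loading_reps), level)

    score_rows = []
    for a in range(A):
        for c in range(len(ref_cells)):
            score_rows.append(
                {
                    TREATMENT: ref_cells[TREATMENT].iloc[c],
                    TIME: ref_cells[TIME].iloc[c],
                    "component": a + 1,
                    "value": ref_cells[f"PC{a + 1}"].iloc[c],
                    "lower": s_lo[c, a],
                    "upper": s_hi[c, a],
                }
            )
    loading_rows = []
    for a in range(A):
        for m, name in enumerate(data.response_cols):
            loading_rows.append(
                {
                    "variable": name,
                    "component": a + 1,
                    "value": ref.loadings[m, a],
                    "lower": l_lo[m, a],
                    "upper": l_hi[m, a],
                }
            )
    return BootstrapResult(
        n_boot=n_boot,
        level=level,
        reference=ref,
        score_table=pd.DataFrame(score_rows),
        loading_table=pd.DataFrame(loading_rows),
        replicate_failures=failures,
    )
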