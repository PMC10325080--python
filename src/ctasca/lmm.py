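"""Per-variable linear mixed models and the multivariate coefficient assembly.

Each response column is modelled as

    y_i = X_i beta + Z_i gamma_i + eps_i,     gamma_i ~ N(0, D),  eps ~ N(0, s2 I)

with an unstructured random-effects covariance ``D`` estimated by REML.  The
default solver profiles out ``beta`` and the residual variance and optimises
the REML criterion over the Cholesky factor of ``D / s2``; subjects sharing a
missingness pattern share one small covariance factorisation, which makes the
balanced cross-over case (all subjects observed on the same grid) essentially
a single 2K x 2K factorisation per objective evaluation.  A statsmodels
``MixedLM`` backend is kept as a cross-check and fallback.

Fits across columns are fully independent; the coefficients are collected in
``B`` (p x J) and the predicted random effects (BLUPs) in ``Gamma`` (Iq x J).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .datamodel import LongDataset
from .design import DesignBundle

logger = logging.getLogger(__name__)

_SINGULAR_TOL = 1e-6


@dataclass
class UnivariateFit:
    """REML fit of one response column."""

    beta: np.ndarray  # (p,)
    gamma: np.ndarray  # (I, q) BLUPs, subjects in canonical order
    D_hat: np.ndarray  # (q, q)
    sigma2_eps: float
    converged: bool
    singular: bool
    loglik: float  # REML log-likelihood
    method: str = "profiled_reml"
    theta: np.ndarray | None = None  # packed variance parameters (warm starts)

    @property
    def q(self) -> int:
        return self.gamma.shape[1]


@dataclass
class MultivariateFit:
    """Column-wise assembly of the univariate fits."""

    B: np.ndarray  # p x J
    Gamma: np.ndarray  # Iq x J, subject-major blocks of length q
    per_variable: list[UnivariateFit]
    design: DesignBundle
    response_cols: list[str]

    @property
    def J(self) -> int:
        return self.B.shape[1]

    def gamma_tensor(self) -> np.ndarray:
        """Gamma reshaped to (I, q, J)."""
        I = self.design.n_subjects
        q = self.design.q
        return self.Gamma.reshape(I, q, self.J)

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "variable": name,
                "converged": f.converged,
                "singular": f.singular,
                "sigma2_eps": f.sigma2_eps,
                "loglik_reml": f.loglik,
                "method": f.method,
            }
            for name, f in zip(self.response_cols, self.per_variable)
        ]
        return pd.DataFrame(rows)


# ------------------------------------------------------------------ internals


def _pack_chol(L: np.ndarray) -> np.ndarray:
    q = L.shape[0]
    return L[np.tril_indices(q)]


def _unpack_chol(theta: np.ndarray, q: int) -> np.ndarray:
    L = np.zeros((q, q))
    L[np.tril_indices(q)] = theta
    return L


class _PatternStats:
    """Sufficient statistics for subjects sharing one missingness pattern.

    With W = I + Z Lam Z' the Woodbury identity gives, per subject,

        W^-1   = I - Z Lam M^-1 Z',      M = I_q + (Z'Z) Lam
        log|W| = log|M|

    so the profiled REML criterion only needs the cross-products below and
    never touches an n x n matrix during optimisation.
    """

    def __init__(self, X: np.ndarray, Z: np.ndarray, Y: np.ndarray, subject_pos: np.ndarray):
        self.m = Y.shape[1]  # subjects in this pattern
        self.subject_pos = subject_pos
        self.ZtZ = Z.T @ Z
        self.ZtX = Z.T @ X
        self.XtX = X.T @ X
        self.ZtY = Z.T @ Y  # q x m
        self.Xty = X.T @ Y.sum(axis=1)
        self.yty = np.einsum("nm,nm->m", Y, Y)  # per-member y'y


def _group_patterns(y, X, Z, subject_index, I):
    """Split the data by subject and group subjects with equal missingness."""
    patterns: dict[bytes, list[int]] = {}
    masks = []
    for i in range(I):
        rows = subject_index == i
        mask = rows & np.isfinite(y)
        if not mask.any():
            raise ValueError(f"subject at position {i} has no observed values")
        masks.append(mask)
        key = mask[rows].tobytes()
        patterns.setdefault(key, []).append(i)
    out = []
    for members in patterns.values():
        mask = masks[members[0]]
        Xp = X[mask]
        Zp = Z[mask]
        Yp = np.column_stack([y[masks[i]] for i in members])
        out.append(_PatternStats(Xp, Zp, Yp, np.array(members)))
    return out


def _assemble(theta, patterns, p, q):
    """Accumulate log|W|, A = X'W^-1X, b = X'W^-1y, c = sum y'W^-1y."""
    L = _unpack_chol(theta, q)
    Lam = L @ L.T
    logdetW = 0.0
    A = np.zeros((p, p))
    b = np.zeros(p)
    c = 0.0
    cache = []
    for pat in patterns:
        M = np.eye(q) + pat.ZtZ @ Lam
        sign, logdetM = np.linalg.slogdet(M)
        if sign <= 0:
            return None
        Minv = np.linalg.inv(M)
        LamMi = Lam @ Minv
        logdetW += pat.m * logdetM
        A += pat.m * (pat.XtX - pat.ZtX.T @ LamMi @ pat.ZtX)
        u = pat.ZtY.sum(axis=1)
        b += pat.Xty - pat.ZtX.T @ (LamMi @ u)
        c += float(pat.yty.sum() - np.einsum("qm,qm->", pat.ZtY, LamMi @ pat.ZtY))
        cache.append((pat, Minv, LamMi))
    return L, Lam, logdetW, A, b, c, cache


def _profiled_criterion(theta, patterns, p, q, N):
    """-2 * profiled REML log-likelihood, up to an additive constant."""
    out = _assemble(theta, patterns, p, q)
    if out is None:
        return np.inf
    _, _, logdetW, A, b, c, _ = out
    sA, logdetA = np.linalg.slogdet(A)
    if sA <= 0:
        return np.inf
    beta = np.linalg.solve(A, b)
    rWr = c - float(b @ beta)
    if rWr <= 0:
        return np.inf
    return logdetW + logdetA + (N - p) * np.log(rWr)


_BIG = 1e10


def _criterion_and_grad(theta, patterns, p, q, N):
    """Criterion plus its analytic gradient w.r.t. the packed Cholesky factor.

    With M = I + Z'Z Lam the directional derivative of each term in the
    criterion reduces to a trace against dLam:

        d log|W|        =  tr(Z'Z M^-T  dLam)            (per subject)
        d log|A|        = -tr(M^-1 S A^-1 S' M^-T dLam),  S = Z'X
        d r'W^-1 r      = -sum_i s_i' dLam s_i,           s_i = M^-1 Z' r_i

    (the last uses that beta-hat minimises the weighted RSS, so its own
    derivative drops out).  For Lam = L L' the chain rule gives
    df/dL = (G + G') L with G the accumulated trace matrix.
    """
    out = _assemble(theta, patterns, p, q)
    if out is None:
        return _BIG, np.zeros_like(theta)
    L, Lam, logdetW, A, b, c, cache = out
    sA, logdetA = np.linalg.slogdet(A)
    if sA <= 0:
        return _BIG, np.zeros_like(theta)
    Ainv = np.linalg.inv(A)
    beta = Ainv @ b
    rWr = c - float(b @ beta)
    if rWr <= 0:
        return _BIG, np.zeros_like(theta)
    f = logdetW + logdetA + (N - p) * np.log(rWr)

    G = np.zeros((q, q))
    for pat, Minv, _ in cache:
        MinvT = Minv.T
        G += pat.m * (pat.ZtZ @ MinvT)
        MS = Minv @ pat.ZtX  # q x p
        G -= pat.m * (MS @ Ainv @ MS.T)
        Ztr = pat.ZtY - (pat.ZtX @ beta)[:, None]
        sM = Minv @ Ztr  # q x m
        G -= ((N - p) / rWr) * (sM @ sM.T)
    dL = (G + G.T) @ L
    return f, dL[np.tril_indices(q)]


def _solution_at(theta, patterns, p, q, N, I):
    """Recompute beta, sigma2, D, BLUPs and the REML loglik at theta."""
    _, Lam, logdetW, A, b, c, cache = _assemble(theta, patterns, p, q)
    _, logdetA = np.linalg.slogdet(A)
    beta = np.linalg.solve(A, b)
    rWr = c - float(b @ beta)
    sigma2 = max(rWr, 0.0) / (N - p)
    if sigma2 > 0:
        loglik = -0.5 * (
            (N - p) * np.log(2.0 * np.pi * sigma2) + logdetW + logdetA + (N - p)
        )
    else:  # degenerate (noise-free) fit
        loglik = np.nan
    gamma = np.zeros((I, q))
    for pat, _, LamMi in cache:
        # Z'W^-1 r_i = (I - Z'Z Lam M^-1)(Z'y_i - Z'X beta)
        Ztr = pat.ZtY - (pat.ZtX @ beta)[:, None]  # q x m
        g = Lam @ (Ztr - pat.ZtZ @ (LamMi @ Ztr))
        gamma[pat.subject_pos] = g.T
    D_hat = sigma2 * Lam
    return beta, gamma, D_hat, sigma2, loglik


def _fit_profiled(y, X, Z, subject_index, I, start_theta=None) -> UnivariateFit:
    obs = np.isfinite(y)
    N = int(obs.sum())
    p = X.shape[1]
    q = Z.shape[1]

    # column scaling of Z for conditioning; Lam is estimated on the scaled
    # design and mapped back afterwards
    scale = np.maximum(np.abs(Z).max(axis=0), 1e-12)
    patterns = _group_patterns(y, X, Z / scale, subject_index, I)

    # degenerate noise-free data: the profiled criterion is undefined at
    # zero residual variance, but the fit is plain least squares
    beta_ols, _, _, _ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    rss = float(np.sum((y[obs] - X[obs] @ beta_ols) ** 2))
    if rss <= 1e-20 * max(float(y[obs] @ y[obs]), 1.0):
        return UnivariateFit(
            beta=beta_ols,
            gamma=np.zeros((I, q)),
            D_hat=np.zeros((q, q)),
            sigma2_eps=rss / max(N - p, 1),
            converged=True,
            singular=True,
            loglik=np.nan,
            method="profiled_reml",
            theta=_pack_chol(np.zeros((q, q))),
        )

    starts: list[np.ndarray] = []
    if start_theta is not None:
        starts.append(np.asarray(start_theta, dtype=float))
    starts += [_pack_chol(np.eye(q) * d) for d in (0.3, 1.0, 0.03)]
    best = None
    for theta0 in starts:
        res = optimize.minimize(
            _criterion_and_grad,
            theta0,
            args=(patterns, p, q, N),
            jac=True,
            method="L-BFGS-B",
            options={"maxiter": 1000, "ftol": 1e-12, "gtol": 1e-8},
        )
        if best is None or res.fun < best.fun - 1e-9:
            best = res
        if best.success and np.isfinite(best.fun):
            break
    converged = bool(best.success and np.isfinite(best.fun))
    if not converged and np.isfinite(best.fun):
        # L-BFGS line-search failures near the optimum: polish derivative-free
        polish = optimize.minimize(
            _profiled_criterion,
            best.x,
            args=(patterns, p, q, N),
            method="Nelder-Mead",
            options={"maxfev": 5000, "xatol": 1e-8, "fatol": 1e-10},
        )
        improved_little = polish.fun >= best.fun - 1e-6 * max(abs(best.fun), 1.0)
        if polish.fun < best.fun:
            best = polish
        converged = bool(polish.success or improved_little)
    beta, gamma_s, D_s, sigma2, loglik = _solution_at(best.x, patterns, p, q, N, I)
    # undo the Z column scaling: Z Lam Z' = Zs (S Lam S) Zs'  with S = diag(scale)
    D_hat = D_s / np.outer(scale, scale)
    gamma = gamma_s / scale[None, :]
    eig = np.linalg.eigvalsh(D_hat)
    singular = bool(eig.min() < _SINGULAR_TOL * max(eig.max(), 1e-12))
    if not converged:
        logger.warning("profiled REML did not converge (criterion %.6g)", best.fun)
    return UnivariateFit(
        beta=beta,
        gamma=gamma,
        D_hat=D_hat,
        sigma2_eps=float(sigma2),
        converged=converged,
        singular=singular,
        loglik=float(loglik),
        method="profiled_reml",
        theta=best.x,
    )


def _fit_statsmodels(y, X, Z, subject_index, I) -> UnivariateFit:
    import statsmodels.api as sm

    obs = np.isfinite(y)
    scale = np.maximum(np.abs(Z).max(axis=0), 1e-12)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(
            y[obs], X[obs], groups=subject_index[obs], exog_re=Z[obs] / scale
        )
        res = model.fit(reml=True, method="lbfgs")
    q = Z.shape[1]
    gamma = np.zeros((I, q))
    for grp, vals in res.random_effects.items():
        gamma[int(grp)] = np.asarray(vals) / scale
    D_hat = np.asarray(res.cov_re) / np.outer(scale, scale)
    eig = np.linalg.eigvalsh(D_hat)
    singular = bool(eig.min() < _SINGULAR_TOL * max(eig.max(), 1e-12))
    return UnivariateFit(
        beta=np.asarray(res.fe_params),
        gamma=gamma,
        D_hat=D_hat,
        sigma2_eps=float(res.scale),
        converged=bool(res.converged),
        singular=singular,
        loglik=float(res.llf),
        method="statsmodels",
    )


def _fit_ols(y, X, I) -> UnivariateFit:
    obs = np.isfinite(y)
    beta, _, _, _ = np.linalg.lstsq(X[obs], y[obs], rcond=None)
    resid = y[obs] - X[obs] @ beta
    dof = max(obs.sum() - X.shape[1], 1)
    return UnivariateFit(
        beta=beta,
        gamma=np.zeros((I, 0)),
        D_hat=np.zeros((0, 0)),
        sigma2_eps=float(resid @ resid / dof),
        converged=True,
        singular=False,
        loglik=np.nan,
        method="ols",
    )


# ----------------------------------------------------------------- public API


def fit_univariate(
    y: np.ndarray,
    design: DesignBundle,
    backend: str = "profiled",
    start_theta: np.ndarray | None = None,
) -> UnivariateFit:
    """REML fit of a single response vector against the shared design.

    Rows with missing ``y`` are excluded from the fit; every subject must
    contribute at least one observed value.  ``backend`` selects the solver:
    ``"profiled"`` (default, fast profiled REML) or ``"statsmodels"``
    (MixedLM cross-check).  ``start_theta`` warm-starts the profiled solver
    (e.g. from a previous fit of the same variable).  With an empty random
    structure the fit reduces to ordinary least squares.
    """
    y = np.asarray(y, dtype=float)
    if len(y) != len(design.X):
        raise ValueError("response length does not match the design")
    if not np.isfinite(y).any():
        raise ValueError("response is entirely missing")
    I = design.n_subjects
    if design.q == 0:
        return _fit_ols(y, design.X, I)
    Z = design.Z
    if backend == "profiled":
        return _fit_profiled(y, design.X, Z, design.subject_index, I, start_theta)
    if backend == "statsmodels":
        return _fit_statsmodels(y, design.X, Z, design.subject_index, I)
    raise ValueError(f"unknown backend {backend!r}")


def fit_all(
    data: LongDataset,
    design: DesignBundle,
    backend: str = "profiled",
    warm_from: "MultivariateFit | None" = None,
) -> MultivariateFit:
    """Fit every response column independently and assemble B and Gamma.

    ``warm_from`` supplies per-variable starting values from a previous fit
    of the same responses (used to speed up bootstrap refits).
    """
    Y = data.Y
    fits = []
    for j, name in enumerate(data.response_cols):
        start = None
        if warm_from is not None and j < len(warm_from.per_variable):
            start = warm_from.per_variable[j].theta
        try:
            fits.append(fit_univariate(Y[:, j], design, backend=backend, start_theta=start))
        except Exception as exc:
            raise RuntimeError(f"fit failed for response {name!r}: {exc}") from exc
    B = np.column_stack([f.beta for f in fits])
    I, q = design.n_subjects, design.q
    Gamma = np.zeros((I * q, len(fits)))
    for j, f in enumerate(fits):
        Gamma[:, j] = f.gamma.reshape(-1)
    n_bad = sum(not f.converged for f in fits)
    n_sing = sum(f.singular for f in fits)
    logger.info(
        "fit_all: %d responses, %d non-converged, %d singular", len(fits), n_bad, n_sing
    )
    return MultivariateFit(
        B=B, Gamma=Gamma, per_variable=fits, design=design, response_cols=list(data.response_cols)
    )
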