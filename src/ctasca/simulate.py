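"""Synthetic cross-over datasets with known encoded effects.

Responses are generated from the same model family the estimator assumes:
population-level polynomial time curves plus sum-coded time-treatment
interactions (fixed part), correlated per-subject random deviations of every
coefficient (drawn once per subject and shared across treatment occasions),
and iid Gaussian noise.  The exact draws are returned so the ground-truth
effect-matrix decomposition can be built for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import SUBJECT, TIME, TREATMENT, DatasetDims, LongDataset
from .design import DesignBundle, TimeBasis, build_design
from .effects import EFFECT_NAMES, EffectMatrices, effect_matrix
from .lmm import MultivariateFit, UnivariateFit


@dataclass
class SimulationSpec:
    """Generating model for one synthetic cross-over study.

    ``beta_tilde`` holds the generating fixed effects, one row per response
    (J x p with p = 1 + 2 * degree).  ``D_tilde`` (q x q, q = p) is the
    covariance of the per-subject random coefficients; random effects are
    drawn independently per (subject, response).  ``sigma_eps`` is the SD of
    the added measurement noise.
    """

    beta_tilde: np.ndarray
    D_tilde: np.ndarray
    sigma_eps: float
    t: np.ndarray = field(default_factory=lambda: np.arange(11.0))
    treatments: tuple[str, ...] = ("A", "B")
    n_subjects: int = 40
    degree: int = 2
    seed: int = 0
    response_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.beta_tilde = np.atleast_2d(np.asarray(self.beta_tilde, dtype=float))
        self.D_tilde = np.asarray(self.D_tilde, dtype=float)
        self.t = np.asarray(self.t, dtype=float)
        p = 1 + self.degree * len(self.treatments[1:]) + self.degree
        if self.beta_tilde.shape[1] != p:
            raise ValueError(
                f"beta_tilde must have p={p} columns for degree {self.degree} "
                f"and H={len(self.treatments)}, got {self.beta_tilde.shape[1]}"
            )
        if self.D_tilde.shape != (p, p):
            raise ValueError(f"D_tilde must be {p}x{p}, got {self.D_tilde.shape}")
        if not np.allclose(self.D_tilde, self.D_tilde.T):
            raise ValueError("D_tilde must be symmetric")
        eig = np.linalg.eigvalsh(self.D_tilde)
        if eig.min() < -1e-10 * max(abs(eig.max()), 1.0):
            raise ValueError("D_tilde must be positive semidefinite")
        if not np.all(np.diff(self.t) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.beta_tilde)):
            raise ValueError("beta_tilde must be finite")
        if self.response_names is None:
            self.response_names = [f"m{j + 1:02d}" for j in range(self.J)]

    @property
    def p(self) -> int:
        return self.beta_tilde.shape[1]

    @property
    def J(self) -> int:
        return self.beta_tilde.shape[0]

    @property
    def dims(self) -> DatasetDims:
        return DatasetDims(
            I=self.n_subjects, H=len(self.treatments), K=len(self.t), J=self.J
        )

    def design_for(self) -> tuple[LongDataset, DesignBundle]:
        """Empty dataset on the spec's grid plus its design bundle."""
        rows = []
        for i in range(self.n_subjects):
            for h in self.treatments:
                for tk in self.t:
                    rows.append({SUBJECT: f"s{i + 1:03d}", TREATMENT: h, TIME: tk})
        df = pd.DataFrame(rows)
        for name in self.response_names:
            df[name] = 0.0
        data = LongDataset(df, list(self.response_names))
        design = build_design(data, TimeBasis("polynomial", self.degree), "mirror_fixed")
        return data, design


def simulate_dataset(spec: SimulationSpec) -> tuple[LongDataset, np.ndarray]:
    """Generate a dataset from the spec; returns (data, gamma_draws).

    ``gamma_draws`` has shape (I, q, J): the per-subject random coefficients
    actually drawn, needed by :func:`encode_ground_truth`.
    """
    rng = np.random.default_rng(spec.seed)
    data, design = spec.design_for()
    X = design.X
    # population curves
    fixed = X @ spec.beta_tilde.T  # n x J
    # subject deviations: one draw per (subject, response), shared across
    # treatment occasions
    I, q, J = spec.n_subjects, spec.p, spec.J
    # eigen-based factor: exact for singular (including zero) covariances
    evals, evecs = np.linalg.eigh(spec.D_tilde)
    L = evecs * np.sqrt(np.clip(evals, 0.0, None))
    gamma = np.einsum("pq,iqj->ipj", L, rng.standard_normal((I, q, J)))  # I x q x J
    random_part = np.einsum("np,npj->nj", X, gamma[design.subject_index])
    noise = spec.sigma_eps * rng.standard_normal((len(X), J))
    Y = fixed + random_part + noise
    return data.replace_responses(Y), gamma


def encode_ground_truth(spec: SimulationSpec, gamma: np.ndarray) -> EffectMatrices:
    """Exact effect-matrix decomposition of the noise-free simulated signal.

    Built with the same design products the estimator uses, but from the
    generating coefficients and the actually drawn random effects; the sum of
    the six matrices equals the simulated responses minus their noise term.
    """
    gamma = np.asarray(gamma, dtype=float)
    I, q, J = spec.n_subjects, spec.p, spec.J
    if gamma.shape != (I, q, J):
        raise ValueError(f"gamma draws must have shape {(I, q, J)}, got {gamma.shape}")
    data, design = spec.design_for()
    per_variable = [
        UnivariateFit(
            beta=spec.beta_tilde[j],
            gamma=gamma[:, :, j],
            D_hat=spec.D_tilde,
            sigma2_eps=spec.sigma_eps**2,
            converged=True,
            singular=False,
            loglik=np.nan,
            method="encoded",
        )
        for j in range(J)
    ]
    truth = MultivariateFit(
        B=spec.beta_tilde.T,
        Gamma=gamma.reshape(I * q, J),
        per_variable=per_variable,
        design=design,
        response_cols=list(spec.response_names),
    )
    parts = {
        "M0f": effect_matrix(truth, "baseline", "fixed"),
        "MTf": effect_matrix(truth, "time", "fixed"),
        "MTGf": effect_matrix(truth, "time_treatment", "fixed"),
        "M0r": effect_matrix(truth, "baseline", "random"),
        "MTr": effect_matrix(truth, "time", "random"),
        "MTGr": effect_matrix(truth, "time_treatment", "random"),
    }
    return EffectMatrices(
        **parts,
        E=np.zeros((design.X.shape[0], J)),
        row_labels=data.row_labels,
        response_cols=list(spec.response_names),
        dims=spec.dims,
    )


def reference_scenario(seed: int = 0, n_subjects: int = 40) -> SimulationSpec:
    """Default simulation scenario: 40 x 2 x 11 grid, 25 responses.

    The generating fixed effects encode two orthogonal population patterns in
    time — a slow linear increase and a parabolic excursion — and two
    diverging time-treatment interaction patterns, each loading on a
    different block of the 25 responses.  Random effects of all five
    coefficients are correlated (off-diagonal 0.3 in correlation) so subject
    curves covary in level and shape.  The exact coefficient values below
    are this package's own documented choices.
    """
    J = 25
    j = np.arange(J)
    t = np.arange(11.0)
    # orthogonal loading patterns over responses (disjoint supports)
    lin_pat = np.where(j < 13, 1.0, 0.0) * np.linspace(1.0, 0.4, J)
    par_pat = np.where(j >= 13, 1.0, 0.0) * np.linspace(0.4, 1.0, J)
    div_a = np.where(j % 2 == 0, 1.0, 0.0) * np.linspace(0.9, 0.5, J)
    div_b = -np.where(j % 2 == 1, 1.0, 0.0) * np.linspace(0.5, 0.9, J)

    # Temporal profiles are chosen orthogonal under the inner product the PCA
    # step actually sees.  The time effect is column-centered, so a slow
    # linear increase (t) and the hump 10t - t^2 are orthogonal after
    # centering on this grid.  Interaction columns already have zero mean
    # over the +-1 treatment blocks, so the second diverging profile is the
    # raw-orthogonalised quadratic t^2 - c t with c = sum(t^3) / sum(t^2).
    c = float(np.sum(t**3) / np.sum(t**2))
    # coefficient vectors (b1, b2) for each profile, amplitudes balanced so
    # the paired components carry comparable variance
    time_p1 = 0.35 * np.array([1.0, 0.0])  # slow increase
    time_p2 = 0.125 * np.array([10.0, -1.0])  # parabolic hump
    int_p1 = 0.15 * np.array([1.0, 0.0])  # steady divergence
    int_p2 = 0.075 * np.array([-c, 1.0])  # late-crossing divergence

    beta = np.zeros((J, 5))
    beta[:, 0] = 5.0 + 0.1 * j  # baselines
    beta[:, 1:3] = np.outer(lin_pat, time_p1) + np.outer(par_pat, time_p2)
    beta[:, 3:5] = np.outer(div_a, int_p1) + np.outer(div_b, int_p2)

    sd = np.array([0.40, 0.060, 0.008, 0.040, 0.006])
    corr = 0.3 * np.ones((5, 5)) + 0.7 * np.eye(5)
    D = corr * np.outer(sd, sd)
    return SimulationSpec(
        beta_tilde=beta,
        D_tilde=D,
        sigma_eps=0.25,
        t=np.arange(11.0),
        treatments=("A", "B"),
        n_subjects=n_subjects,
        degree=2,
        seed=seed,
    )
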