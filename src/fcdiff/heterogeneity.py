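"""Between-subject heterogeneity and edge-effect estimation.

Each subject's edge vector is modelled as ``Y_n ~ MVN(X_n' beta, Sigma + psi)``
with independent subjects, where ``Sigma`` is the topology-structured edge
covariance (plugged in from the Dirichlet-process estimator) and ``psi``
captures between-subject variability.  Two low-parameter structures are
supported:

* ``scaled_identity``:    psi = sigma^2 I
* ``compound_symmetry``:  psi_ii = sigma^2, psi_ij = b (i != j)

Because the same ``E x E`` weight applies to every subject, generalised
least squares for ``beta`` collapses to ordinary least squares,
``beta_hat = (X'X)^{-1} X'Y``, while the weight survives in the variance
``var(beta_hat) = (X'X)^{-1} (Sigma + psi)`` (intercept-only:
``(Sigma + psi) / N``).  ``sigma^2`` and ``b`` are moment estimators from
the residual covariance ``Omega_hat = mean_n r_n r_n'``: the average
diagonal and average off-diagonal of ``Omega_hat - Sigma``, clamped so
``psi`` stays positive semidefinite.  ``beta`` and ``psi`` are refined
alternately until the heterogeneity parameters stop moving.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SCALED_IDENTITY",
    "COMPOUND_SYMMETRY",
    "PsiModel",
    "GroupFit",
    "estimate_beta",
    "estimate_psi",
    "fit_group",
]

SCALED_IDENTITY = "scaled_identity"
COMPOUND_SYMMETRY = "compound_symmetry"

_ALIASES = {
    "scaled_identity": SCALED_IDENTITY,
    "scaled": SCALED_IDENTITY,
    "identity_scaled": SCALED_IDENTITY,
    "compound_symmetry": COMPOUND_SYMMETRY,
    "cs": COMPOUND_SYMMETRY,
}

_PSD_EPS = 1e-10


def normalize_structure(structure: str) -> str:
    try:
        return _ALIASES[structure.strip().lower()]
    except KeyError:
        raise ValueError(
            f"unknown psi structure {structure!r}; expected one of {sorted(set(_ALIASES))}"
        ) from None


@dataclass
class PsiModel:
    """Between-subject covariance: diagonal ``sigma_sq``, off-diagonal ``b``."""

    structure: str
    sigma_sq: float = 0.0
    b: float = 0.0

    def __post_init__(self):
        self.structure = normalize_structure(self.structure)
        if self.structure == SCALED_IDENTITY:
            self.b = 0.0

    def matrix(self, E: int) -> np.ndarray:
        psi = np.full((E, E), self.b)
        np.fill_diagonal(psi, self.sigma_sq)
        return psi

    def add_to(self, Sigma: np.ndarray) -> np.ndarray:
        """``Sigma + psi`` without materialising psi separately."""
        out = Sigma + self.b
        np.fill_diagonal(out, np.diag(Sigma) + self.sigma_sq)
        return out


@dataclass
class GroupFit:
    """Edge effects and heterogeneity for one group.

    ``beta_hat`` is the length-``E`` effect vector (intercept-only design)
    and ``var_beta = (Sigma + psi) / N`` its ``E x E`` covariance.
    """

    beta_hat: np.ndarray
    var_beta: np.ndarray
    psi: PsiModel
    n_iterations: int
    converged: bool
    n_subjects: int
    Omega_hat: np.ndarray | None = None

    @property
    def E(self) -> int:
        return self.beta_hat.shape[-1]


def _design(Y: np.ndarray, X) -> np.ndarray:
    if X is None:
        return np.ones((Y.shape[0], 1))
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    if X.shape[0] != Y.shape[0]:
        raise ValueError("design matrix rows must match subjects")
    return X


def estimate_beta(Y: np.ndarray, X, Sigma: np.ndarray, psi: PsiModel):
    """GLS effect estimate and its variance.

    Because every subject shares the weight ``(Sigma + psi)^{-1}``, the
    weight cancels and ``beta_hat = (X'X)^{-1} X'Y`` exactly; the variance
    of each row of ``beta_hat`` is ``(X'X)^{-1}_{jj} (Sigma + psi)``.
    Returns ``(beta, var_beta)`` with ``beta`` of shape ``(p, E)`` and,
    for the single-column designs used throughout, ``var_beta`` the
    ``E x E`` matrix ``(X'X)^{-1}_{00} (Sigma + psi)``.
    """
    Y = np.asarray(Y, dtype=float)
    X = _design(Y, X)
    xtx = X.T @ X
    if np.linalg.matrix_rank(xtx) < xtx.shape[0]:
        raise ValueError("singular design matrix X'X")
    beta = np.linalg.solve(xtx, X.T @ Y)
    if X.shape[1] != 1:
        raise NotImplementedError(
            "variance of beta is only provided for single-column designs"
        )
    xtx_inv = 1.0 / float(xtx[0, 0])
    var_beta = xtx_inv * psi.add_to(np.asarray(Sigma, dtype=float))
    return beta, var_beta


def estimate_psi(residuals: np.ndarray, Sigma: np.ndarray, structure: str,
                 keep_omega: bool = False) -> PsiModel | tuple[PsiModel, np.ndarray]:
    """Moment estimate of the heterogeneity parameters from residuals.

    ``sigma^2`` is the average diagonal of ``Omega_hat - Sigma`` (floored
    at 0) and, under compound symmetry, ``b`` the average off-diagonal
    (clipped into ``[-sigma^2/(E-1) + eps, sigma^2]`` so psi is PSD).
    Both averages are computed without materialising ``Omega_hat``; pass
    ``keep_omega=True`` to also receive the dense residual covariance.
    """
    R = np.asarray(residuals, dtype=float)
    if R.ndim != 2 or R.shape[0] < 2:
        raise ValueError("need at least 2 subjects of residuals")
    N, E = R.shape
    Sigma = np.asarray(Sigma, dtype=float)
    structure = normalize_structure(structure)

    sq_total = float(np.sum(R * R))
    omega_diag_mean = sq_total / (N * E)
    sigma_diag_mean = float(np.trace(Sigma)) / E
    sigma_sq = max(omega_diag_mean - sigma_diag_mean, 0.0)

    b = 0.0
    if structure == COMPOUND_SYMMETRY and E > 1:
        row_sums = R.sum(axis=1)
        omega_off_mean = (float(np.sum(row_sums**2)) - sq_total) / (N * E * (E - 1))
        sigma_off_mean = (float(Sigma.sum()) - float(np.trace(Sigma))) / (E * (E - 1))
        b_raw = omega_off_mean - sigma_off_mean
        if sigma_sq > 0:
            lo = -sigma_sq / (E - 1) + _PSD_EPS
            b = float(np.clip(b_raw, lo, sigma_sq))
    psi = PsiModel(structure=structure, sigma_sq=sigma_sq, b=b)
    if keep_omega:
        return psi, R.T @ R / N
    return psi


def fit_group(Y: np.ndarray, Sigma: np.ndarray, structure: str, X=None,
              tol: float = 1e-6, max_iter: int = 100,
              keep_omega: bool = False) -> GroupFit:
    """Alternate ``beta`` and ``psi`` estimation until convergence.

    Starts from ``psi = 0``; declares convergence when the largest change
    in ``(sigma^2, b)`` falls below ``tol``.  With an intercept-only
    design ``beta_hat`` does not depend on ``psi``, so the loop reaches a
    fixed point on the second iteration.  Non-convergence at ``max_iter``
    is flagged, not raised.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.shape[0] < 2:
        raise ValueError("need at least 2 subjects per group")
    Sigma = np.asarray(Sigma, dtype=float)
    structure = normalize_structure(structure)
    X = _design(Y, X)

    psi = PsiModel(structure=structure, sigma_sq=0.0, b=0.0)
    converged = False
    n_iterations = 0
    beta = None
    Omega_hat = None
    xtx = X.T @ X
    for _ in range(max_iter):
        n_iterations += 1
        # GLS beta with a shared subject weight reduces to OLS; see estimate_beta
        beta = np.linalg.solve(xtx, X.T @ Y)
        residuals = Y - X @ beta
        if keep_omega:
            new_psi, Omega_hat = estimate_psi(residuals, Sigma, structure, keep_omega=True)
        else:
            new_psi = estimate_psi(residuals, Sigma, structure)
        delta = max(abs(new_psi.sigma_sq - psi.sigma_sq), abs(new_psi.b - psi.b))
        psi = new_psi
        if delta < tol:
            converged = True
            break

    # clamps guarantee a PSD psi, hence var_beta inherits Sigma's definiteness
    assert psi.sigma_sq >= 0.0
    if Y.shape[1] > 1:
        assert -psi.sigma_sq / (Y.shape[1] - 1) - 1e-12 <= psi.b <= psi.sigma_sq + 1e-12

    _, var_beta = estimate_beta(Y, X, Sigma, psi)
    return GroupFit(
        beta_hat=beta[0] if beta.shape[0] == 1 else beta,
        var_beta=var_beta,
        psi=psi,
        n_iterations=n_iterations,
        converged=converged,
        n_subjects=Y.shape[0],
        Omega_hat=Omega_hat,
    )
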