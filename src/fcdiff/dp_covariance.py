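"""Dirichlet-process estimation of the edge-by-edge covariance matrix.

The dependence between connectivity edges follows the latent community
structure of the region graph: two edges are strongly correlated when all
four of their endpoint regions fall in the same cluster, and weakly
(baseline) correlated otherwise.  Writing ``omega_i = C_k`` for the
cluster label of region ``i``, the E x E edge correlation matrix is

    Lambda[e_ij, e_i'j'] = rho_k   if omega_i = omega_j = omega_i' = omega_j' = C_k
                           rho_0   otherwise

with unit diagonal.  A Dirichlet process with concentration ``alpha``
provides the prior over the unknown partition, and independent normal
priors are placed on the baseline correlation ``rho_0`` and the
within-cluster factors ``rho_k``.  Given centred residual vectors
``R_n ~ MVN(0, Lambda)`` the posterior kernel is

    exp{ -N/2 (log|Lambda| + tr(H Lambda^{-1})) } p(partition) p(rho)

where ``H`` is the correlation-standardised residual cross-product.  The
sampler alternates a collapsed Gibbs scan over region labels (Chinese
restaurant process conditionals; a fresh ``rho`` is drawn from its prior
when a new cluster is proposed) with Metropolis-Hastings random-walk
updates of the correlation factors.

All likelihood evaluations exploit the structure of ``Lambda``: it is a
block equicorrelation matrix plus the rank-one baseline term
``rho_0 * 11'``, so inverses, determinants and traces come from per-block
closed forms and the Sherman-Morrison identity rather than dense
factorisations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import log

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .connectivity import EdgeIndexMap, region_count_for_edges

logger = logging.getLogger(__name__)

__all__ = [
    "DPHyperparameters",
    "ClusterAssignment",
    "CorrelationFactors",
    "ResidualSummary",
    "PosteriorCovariance",
    "NotPositiveDefiniteError",
    "DegenerateEdgeError",
    "build_lambda",
    "structured_inverse_and_logdet",
    "compute_residual_summary",
    "log_posterior_kernel",
    "log_crp_prior",
    "DPCovarianceSampler",
    "estimate_edge_covariance",
]

_EPS = 1e-12


class NotPositiveDefiniteError(ValueError):
    """A (partition, rho) state does not yield a positive-definite Lambda."""


class DegenerateEdgeError(ValueError):
    """An edge has zero residual variance and cannot be standardised."""


# ---------------------------------------------------------------------------
# configuration and state containers


@dataclass
class DPHyperparameters:
    """Priors and chain settings for the Dirichlet-process sampler.

    Parameters
    ----------
    alpha : float
        DP concentration; larger values favour more clusters.
    mu0, tau0_sq : float
        Normal prior mean / variance of the baseline correlation ``rho_0``.
    muk, tauk_sq : float
        Normal prior mean / variance of each within-cluster ``rho_k``.
    n_iter, n_burn : int
        Total sweeps and discarded burn-in sweeps.
    proposal_sd : float
        Random-walk standard deviation of the Metropolis updates.
    seed : int
        Seed of the single generator driving the whole chain.
    """

    alpha: float = 1.0
    mu0: float = 0.0
    tau0_sq: float = 0.25
    muk: float = 0.0
    tauk_sq: float = 0.25
    n_iter: int = 2000
    n_burn: int = 1000
    proposal_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.alpha <= 0:
            raise ValueError("alpha must be > 0")
        if self.tau0_sq <= 0 or self.tauk_sq <= 0:
            raise ValueError("prior variances must be > 0")
        if not (self.n_iter > self.n_burn >= 0):
            raise ValueError("need n_iter > n_burn >= 0")
        if self.proposal_sd <= 0:
            raise ValueError("proposal_sd must be > 0")


def canonicalize_labels(omega) -> tuple[np.ndarray, np.ndarray]:
    """Relabel clusters by first occurrence; returns (labels, old-label order)."""
    omega = np.asarray(omega)
    seen: dict = {}
    out = np.empty(len(omega), dtype=np.intp)
    order = []
    for idx, lab in enumerate(omega):
        lab = int(lab)
        if lab not in seen:
            seen[lab] = len(order)
            order.append(lab)
        out[idx] = seen[lab]
    return out, np.asarray(order, dtype=np.intp)


@dataclass(frozen=True)
class ClusterAssignment:
    """Partition of the ``V`` regions into ``K`` occupied clusters."""

    omega: np.ndarray  # (V,) contiguous 0-based labels

    def __post_init__(self):
        omega = np.asarray(self.omega, dtype=np.intp)
        if omega.ndim != 1 or omega.size == 0:
            raise ValueError("omega must be a non-empty 1-D label vector")
        canon, _ = canonicalize_labels(omega)
        if not np.array_equal(canon, omega):
            omega = canon
        object.__setattr__(self, "omega", omega)

    @property
    def V(self) -> int:
        return self.omega.size

    @property
    def K(self) -> int:
        return int(self.omega.max()) + 1

    @property
    def sizes(self) -> np.ndarray:
        return np.bincount(self.omega, minlength=self.K)


@dataclass(frozen=True)
class CorrelationFactors:
    """Baseline correlation ``rho_0`` and per-cluster factors ``rho_k``."""

    rho0: float
    rho_k: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "rho_k", np.atleast_1d(np.asarray(self.rho_k, dtype=float)))


def _as_omega(omega) -> np.ndarray:
    """Label vector as given; labels index ``rho_k`` so they are NOT
    relabelled here (gaps are allowed, negative labels are not)."""
    if isinstance(omega, ClusterAssignment):
        return omega.omega
    omega = np.asarray(omega, dtype=np.intp)
    if omega.size and omega.min() < 0:
        raise ValueError("cluster labels must be non-negative")
    return omega


def _as_rho(rho) -> tuple[float, np.ndarray]:
    if isinstance(rho, CorrelationFactors):
        return float(rho.rho0), np.asarray(rho.rho_k, dtype=float)
    rho0, rho_k = rho
    return float(rho0), np.atleast_1d(np.asarray(rho_k, dtype=float))


# ---------------------------------------------------------------------------
# Lambda construction and structured linear algebra


def edge_cluster_groups(omega, edge_map: EdgeIndexMap) -> np.ndarray:
    """Per-edge cluster membership: ``k`` when both endpoints sit in cluster
    ``k``, ``-1`` for edges straddling clusters."""
    omega = _as_omega(omega)
    if omega.size != edge_map.V:
        raise ValueError(f"omega has {omega.size} labels for V={edge_map.V}")
    wi = omega[edge_map.i]
    wj = omega[edge_map.j]
    return np.where(wi == wj, wi, -1)


def build_lambda(omega, rho, edge_map: EdgeIndexMap) -> np.ndarray:
    """Dense E x E edge correlation matrix for a partition and factors."""
    omega = _as_omega(omega)
    rho0, rho_k = _as_rho(rho)
    K = int(omega.max()) + 1
    if rho_k.size < K:
        raise ValueError(
            f"partition has {K} occupied clusters but only {rho_k.size} rho_k factors"
        )
    g = edge_cluster_groups(omega, edge_map)
    E = edge_map.E
    L = np.full((E, E), rho0)
    for k in range(K):
        idx = np.flatnonzero(g == k)
        if idx.size:
            L[np.ix_(idx, idx)] = rho_k[k]
    np.fill_diagonal(L, 1.0)
    return L


def _structure_terms(rho0: float, c: np.ndarray, n_blocks: np.ndarray, n_free: float):
    """Positive-definiteness check plus shared scalars of the structured form.

    ``Lambda = A + rho0 * 11'`` where ``A`` is block diagonal: per-cluster
    equicorrelation blocks of ``n_blocks[k]`` edges with diagonal
    ``a = 1 - rho0`` and off-diagonal ``c[k] = rho_k - rho0``, plus
    ``n_free`` decoupled edges with diagonal ``a``.

    Returns ``None`` when the state is not positive definite, otherwise a
    dict with ``a``, per-block column sums ``denom = a + (n-1) c``, the
    Sherman-Morrison scalars ``s = 1' A^{-1} 1`` and ``t = 1 + rho0 * s``,
    and ``logdet`` of Lambda.
    """
    a = 1.0 - rho0
    if a <= _EPS:
        return None
    n = np.asarray(n_blocks, dtype=float)
    c = np.asarray(c, dtype=float)
    occupied = n >= 1
    multi = n >= 2
    denom = a + (n - 1.0) * c
    if np.any(multi & ((a - c <= _EPS) | (denom <= _EPS))):
        return None
    # u value (entries of A^{-1} 1) per block; blocks of one edge behave
    # like free edges because a 1x1 block has no off-diagonal.
    u = np.where(occupied, 1.0 / np.where(occupied, denom, 1.0), 1.0 / a)
    u = np.where(multi, u, 1.0 / a)
    s = float(np.sum(n * u)) + n_free / a
    t = 1.0 + rho0 * s
    if t <= _EPS:
        return None
    logdet = float(np.log(t)) + n_free * np.log(a)
    if np.any(multi):
        logdet += float(np.sum(np.log(denom[multi])))
        logdet += float(np.sum((n[multi] - 1.0) * np.log(a - c[multi])))
    logdet += float(np.sum(occupied & ~multi)) * np.log(a)  # single-edge blocks
    return {"a": a, "c": c, "n": n, "denom": denom, "u": u, "s": s, "t": t,
            "logdet": logdet, "multi": multi, "occupied": occupied}


def _loglik_terms(N: int, rho0: float, c, n_g, D_g, T) -> float:
    """Gaussian log-likelihood term ``-N/2 (log|Lambda| + tr(H Lambda^{-1}))``.

    ``n_g``, ``D_g`` are group sizes and diagonal sums with index 0 the
    free (between-cluster) edges and index ``k+1`` cluster ``k``; ``T`` is
    the symmetric matrix of block sums of ``H`` over those groups.
    Returns ``-inf`` for non-positive-definite states.

    Scalar arithmetic throughout: the group count is tiny, and this runs
    once per Gibbs candidate, so numpy dispatch would dominate.
    """
    a = 1.0 - rho0
    if a <= _EPS:
        return -np.inf
    K = len(c)
    inv_a = 1.0 / a
    log_a = log(a)
    s = n_g[0] * inv_a
    logdet = n_g[0] * log_a
    tr_A = D_g[0] * inv_a
    u = [inv_a] * (K + 1)
    for k in range(K):
        nk = n_g[k + 1]
        if nk == 0:
            continue
        ck = c[k]
        if nk >= 2:
            gap = a - ck
            denom = a + (nk - 1.0) * ck
            if gap <= _EPS or denom <= _EPS:
                return -np.inf
            uk = 1.0 / denom
            logdet += log(denom) + (nk - 1.0) * log(gap)
            tr_A += (D_g[k + 1] - (ck * uk) * T[k + 1, k + 1]) / gap
        else:  # a single-edge block has no off-diagonal: behaves like free
            uk = inv_a
            logdet += log_a
            tr_A += D_g[k + 1] * inv_a
        u[k + 1] = uk
        s += nk * uk
    t = 1.0 + rho0 * s
    if t <= _EPS:
        return -np.inf
    logdet += log(t)
    uv = np.asarray(u)
    q = float(uv @ T @ uv)
    trace = tr_A - rho0 * q / t
    return -0.5 * N * (logdet + trace)


def structured_inverse_and_logdet(omega, rho, edge_map: EdgeIndexMap):
    """Closed-form ``(Lambda^{-1}, log|Lambda|)`` via block equicorrelation
    inverses and one Sherman-Morrison step for the rank-one baseline term.

    Raises :class:`NotPositiveDefiniteError` for invalid states.
    """
    omega = _as_omega(omega)
    rho0, rho_k = _as_rho(rho)
    g = edge_cluster_groups(omega, edge_map)
    K = int(omega.max()) + 1
    if rho_k.size < K:
        raise ValueError("missing rho_k for an occupied cluster")
    E = edge_map.E
    n_blocks = np.array([np.sum(g == k) for k in range(K)], dtype=float)
    n_free = float(np.sum(g == -1))
    c = rho_k[:K] - rho0
    st = _structure_terms(rho0, c, n_blocks, n_free)
    if st is None:
        raise NotPositiveDefiniteError(
            f"state rho0={rho0}, rho_k={rho_k[:K]} gives a non-PD Lambda"
        )
    a = st["a"]
    A_inv = np.zeros((E, E))
    free_idx = np.flatnonzero(g == -1)
    A_inv[free_idx, free_idx] = 1.0 / a
    for k in range(K):
        idx = np.flatnonzero(g == k)
        m = idx.size
        if m == 0:
            continue
        if m == 1:
            A_inv[idx, idx] = 1.0 / a
            continue
        ck = c[k]
        block = np.full((m, m), -ck / ((a - ck) * st["denom"][k]))
        np.fill_diagonal(block, 1.0 / (a - ck) - ck / ((a - ck) * st["denom"][k]))
        A_inv[np.ix_(idx, idx)] = block
    u_vec = A_inv.sum(axis=1)  # A^{-1} 1
    L_inv = A_inv - (rho0 / st["t"]) * np.outer(u_vec, u_vec)
    return L_inv, st["logdet"]


# ---------------------------------------------------------------------------
# residual summary and posterior kernel


@dataclass(frozen=True)
class ResidualSummary:
    """Residual cross-products feeding the covariance sampler.

    ``H0 = R'R / (N - p)`` and ``H`` its correlation standardisation
    ``Diag(H0)^{-1/2} H0 Diag(H0)^{-1/2}`` (unit diagonal).
    """

    H0: np.ndarray
    H: np.ndarray
    N: int
    p: int


def compute_residual_summary(R: np.ndarray, p: int) -> ResidualSummary:
    """Cross-product summary of an ``N x E`` residual matrix."""
    R = np.asarray(R, dtype=float)
    if R.ndim != 2:
        raise ValueError("residual matrix must be 2-D")
    N, E = R.shape
    if N <= p:
        raise ValueError(f"need N > p, got N={N}, p={p}")
    H0 = R.T @ R / (N - p)
    d = np.diag(H0)
    bad = np.flatnonzero(d <= 0)
    if bad.size:
        raise DegenerateEdgeError(
            f"edge {int(bad[0])} has zero residual variance; cannot standardise"
        )
    inv_sd = 1.0 / np.sqrt(d)
    H = H0 * np.outer(inv_sd, inv_sd)
    np.fill_diagonal(H, 1.0)
    return ResidualSummary(H0=H0, H=H, N=N, p=p)


def log_crp_prior(omega, alpha: float) -> float:
    """Log Chinese-restaurant-process probability of a partition."""
    omega = _as_omega(omega)
    V = omega.size
    sizes = np.bincount(omega)
    sizes = sizes[sizes > 0]
    K = sizes.size
    return (K * np.log(alpha) + float(np.sum(gammaln(sizes)))
            + gammaln(alpha) - gammaln(alpha + V))


def _normal_logpdf(x: float, mu: float, var: float) -> float:
    return -0.5 * (np.log(2 * np.pi * var) + (x - mu) ** 2 / var)


def _group_aggregates(H: np.ndarray, diagH: np.ndarray, g: np.ndarray, K: int):
    """Counts, diagonal sums and block sums of ``H`` over edge groups.

    Index 0 is the free group, ``k + 1`` cluster ``k``.
    """
    gi = g + 1
    K1 = K + 1
    E = g.size
    G = np.zeros((E, K1))
    G[np.arange(E), gi] = 1.0
    T = G.T @ (H @ G)
    n = np.bincount(gi, minlength=K1).astype(float)
    D = np.bincount(gi, weights=diagH, minlength=K1)
    return n, D, T, G


def log_posterior_kernel(summary: ResidualSummary, omega, rho,
                         hyper: DPHyperparameters,
                         edge_map: EdgeIndexMap | None = None) -> float:
    """Log posterior kernel (likelihood + CRP prior + normal rho priors).

    Returns ``-inf`` for states whose Lambda is not positive definite.
    """
    omega = _as_omega(omega)
    rho0, rho_k = _as_rho(rho)
    edge_map = edge_map or EdgeIndexMap(omega.size)
    K = int(omega.max()) + 1
    if rho_k.size < K:
        raise ValueError("missing rho_k for an occupied cluster")
    g = edge_cluster_groups(omega, edge_map)
    n, D, T, _ = _group_aggregates(summary.H, np.diag(summary.H), g, K)
    ll = _loglik_terms(summary.N, rho0, rho_k[:K] - rho0, n, D, T)
    if not np.isfinite(ll):
        return -np.inf
    lp = log_crp_prior(omega, hyper.alpha)
    lp += _normal_logpdf(rho0, hyper.mu0, hyper.tau0_sq)
    lp += float(np.sum([_normal_logpdf(r, hyper.muk, hyper.tauk_sq) for r in rho_k[:K]]))
    return ll + lp


# ---------------------------------------------------------------------------
# sampler


class DPCovarianceSampler:
    """MCMC over (partition, correlation factors) given a residual summary.

    One *sweep* is a Gibbs scan of all region labels in ascending index
    order followed by one Metropolis-Hastings step per correlation factor.
    The generator passed at construction drives every random choice, so a
    chain is a pure function of its seed.
    """

    def __init__(self, summary: ResidualSummary, edge_map: EdgeIndexMap,
                 hyper: DPHyperparameters, rng: np.random.Generator | None = None):
        if edge_map.E != summary.H.shape[0]:
            raise ValueError("edge map does not match residual summary size")
        self.summary = summary
        self.H = summary.H
        self.diagH = np.diag(summary.H).copy()
        self.N = summary.N
        self.edge_map = edge_map
        self.V = edge_map.V
        self.hyper = hyper
        self.rng = rng if rng is not None else np.random.default_rng(hyper.seed)
        # per-region incident edges and the far-end region of each
        self._inc = [edge_map.incident(i) for i in range(self.V)]
        self._other = [np.where(edge_map.i[self._inc[i]] == i,
                                edge_map.j[self._inc[i]],
                                edge_map.i[self._inc[i]]) for i in range(self.V)]
        # initial state: one cluster, factors at the prior means
        self.omega = np.zeros(self.V, dtype=np.intp)
        self.rho0 = float(hyper.mu0)
        self.rho = np.array([float(hyper.muk)])
        self.accept_rho0 = 0
        self.prop_rho0 = 0
        self.accept_rhok = 0
        self.prop_rhok = 0

    # -- likelihood plumbing ------------------------------------------------

    @property
    def K(self) -> int:
        return int(self.omega.max()) + 1

    def _edge_groups(self, omega) -> np.ndarray:
        wi = omega[self.edge_map.i]
        wj = omega[self.edge_map.j]
        return np.where((wi == wj) & (wi >= 0), wi, -1)

    def _loglik(self, n, D, T, rho0, rho_k) -> float:
        return _loglik_terms(self.N, rho0, rho_k - rho0, n, D, T)

    def _candidate_logliks(self, i: int):
        """Likelihood of every reassignment of region ``i``.

        Returns ``(cand_clusters, logliks, base_ll, rho_new)`` where
        ``cand_clusters`` are the occupied clusters once ``i`` is held
        out, ``base_ll`` the likelihood with ``i`` as a lone singleton
        (which is the new-cluster candidate's likelihood) and ``rho_new``
        the fresh prior draw attached to the new-cluster candidate.
        """
        omega = self.omega
        K = self.K
        held = omega.copy()
        held[i] = -1
        m_minus = np.bincount(held[held >= 0], minlength=K)
        g_base = self._edge_groups(held)
        n, D, T, G = _group_aggregates(self.H, self.diagH, g_base, K)
        base_ll = self._loglik(n, D, T, self.rho0, self.rho[:K])
        rho_new = float(self.rng.normal(self.hyper.muk, np.sqrt(self.hyper.tauk_sq)))

        inc = self._inc[i]
        other = self._other[i]
        other_lab = omega[other]
        cands = [k for k in range(K) if m_minus[k] > 0]
        logliks = []
        for k in cands:
            A = inc[other_lab == k]
            # move edge set A from the free group into cluster k's block
            rows = self.H[A]
            v = (rows @ G).sum(axis=0)
            w = float(rows[:, A].sum())
            dD = float(self.diagH[A].sum())
            kh = k + 1
            T2 = T.copy()
            T2[kh, kh] += 2.0 * v[kh] + w
            T2[0, 0] += -2.0 * v[0] + w
            delta_0k = v[0] - v[kh] - w
            T2[0, kh] += delta_0k
            T2[kh, 0] += delta_0k
            for h in range(K + 1):
                if h in (0, kh):
                    continue
                T2[kh, h] += v[h]
                T2[h, kh] += v[h]
                T2[0, h] -= v[h]
                T2[h, 0] -= v[h]
            n2 = n.copy()
            n2[0] -= A.size
            n2[kh] += A.size
            D2 = D.copy()
            D2[0] -= dD
            D2[kh] += dD
            logliks.append(self._loglik(n2, D2, T2, self.rho0, self.rho[:K]))
        return cands, np.asarray(logliks, dtype=float), base_ll, rho_new, m_minus

    # -- updates ------------------------------------------------------------

    def update_node(self, i: int) -> None:
        """Gibbs update of region ``i``'s cluster label (CRP conditional)."""
        cands, logliks, base_ll, rho_new, m_minus = self._candidate_logliks(i)
        logw = np.concatenate([
            logliks + np.log(m_minus[cands]),
            [base_ll + np.log(self.hyper.alpha)],
        ])
        finite = np.isfinite(logw)
        if not np.any(finite):
            logger.warning("all candidate states for region %d are non-PD; keeping label", i)
            return
        logw = logw - logw[finite].max()
        w = np.where(finite, np.exp(logw), 0.0)
        cdf = np.cumsum(w)
        choice = int(np.searchsorted(cdf, self.rng.random() * cdf[-1], side="right"))
        choice = min(choice, w.size - 1)

        old = int(self.omega[i])
        rho = self.rho[: self.K].copy()
        if choice < len(cands):
            self.omega[i] = cands[choice]
        else:  # open a new cluster
            self.omega[i] = self.K
            rho = np.append(rho, rho_new)
        if m_minus[old] == 0 and self.omega[i] != old:
            # the old cluster emptied: drop it and its factor
            rho = np.delete(rho, old)
            self.omega[self.omega > old] -= 1
        self.omega, order = canonicalize_labels(self.omega)
        self.rho = rho[order]

    def sweep_omega(self) -> None:
        for i in range(self.V):
            self.update_node(i)

    def sweep_rho(self) -> None:
        """One Metropolis-Hastings step per correlation factor."""
        K = self.K
        g = self._edge_groups(self.omega)
        n, D, T, _ = _group_aggregates(self.H, self.diagH, g, K)
        hy = self.hyper
        cur_ll = self._loglik(n, D, T, self.rho0, self.rho[:K])
        # baseline rho0
        prop = self.rho0 + self.rng.normal(0.0, hy.proposal_sd)
        self.prop_rho0 += 1
        ll_prop = self._loglik(n, D, T, prop, self.rho[:K])
        if np.isfinite(ll_prop):
            logr = (ll_prop - cur_ll
                    + _normal_logpdf(prop, hy.mu0, hy.tau0_sq)
                    - _normal_logpdf(self.rho0, hy.mu0, hy.tau0_sq))
            if np.log(self.rng.uniform()) < logr:
                self.rho0 = float(prop)
                cur_ll = ll_prop
                self.accept_rho0 += 1
        # within-cluster factors
        for k in range(K):
            prop_k = self.rho.copy()
            prop_k[k] = self.rho[k] + self.rng.normal(0.0, hy.proposal_sd)
            self.prop_rhok += 1
            ll_prop = self._loglik(n, D, T, self.rho0, prop_k[:K])
            if np.isfinite(ll_prop):
                logr = (ll_prop - cur_ll
                        + _normal_logpdf(prop_k[k], hy.muk, hy.tauk_sq)
                        - _normal_logpdf(self.rho[k], hy.muk, hy.tauk_sq))
                if np.log(self.rng.uniform()) < logr:
                    self.rho = prop_k
                    cur_ll = ll_prop
                    self.accept_rhok += 1

    def sweep(self) -> None:
        self.sweep_omega()
        self.sweep_rho()

    def log_posterior(self) -> float:
        return log_posterior_kernel(
            self.summary, self.omega, (self.rho0, self.rho), self.hyper, self.edge_map
        )

    @property
    def acceptance_rates(self) -> dict:
        return {
            "rho0": self.accept_rho0 / max(self.prop_rho0, 1),
            "rho_k": self.accept_rhok / max(self.prop_rhok, 1),
        }


# ---------------------------------------------------------------------------
# point estimation


@dataclass
class PosteriorCovariance:
    """Point estimate of the edge covariance with its MCMC provenance."""

    omega_hat: ClusterAssignment
    rho_hat: CorrelationFactors
    Lambda_hat: np.ndarray
    Sigma_hat: np.ndarray
    samples: list
    diagnostics: pd.DataFrame
    acceptance: dict
    seed: int


def estimate_edge_covariance(R: np.ndarray, p: int, hyper: DPHyperparameters,
                             edge_map: EdgeIndexMap | None = None) -> PosteriorCovariance:
    """Run the sampler on a residual matrix and return the plug-in covariance.

    The point estimate is the retained draw with the highest log posterior
    kernel (ties broken by the earliest draw); the correlation factors are
    averaged over retained draws sharing that partition.  The covariance is
    the correlation structure rescaled by the residual variances,
    ``Sigma_hat = Diag(H0)^{1/2} Lambda_hat Diag(H0)^{1/2}``.
    """
    R = np.asarray(R, dtype=float)
    summary = compute_residual_summary(R, p)
    E = R.shape[1]
    edge_map = edge_map or EdgeIndexMap(region_count_for_edges(E))
    sampler = DPCovarianceSampler(summary, edge_map, hyper)

    retained = []
    diag_rows = []
    for it in range(hyper.n_iter):
        sampler.sweep()
        lp = sampler.log_posterior()
        diag_rows.append((it, lp, sampler.K))
        if it >= hyper.n_burn:
            retained.append({
                "omega": sampler.omega.copy(),
                "rho0": sampler.rho0,
                "rho_k": sampler.rho.copy(),
                "log_posterior": lp,
            })
    finite = [s for s in retained if np.isfinite(s["log_posterior"])]
    if not finite:
        raise NotPositiveDefiniteError("chain produced no valid retained state")

    lps = np.array([s["log_posterior"] for s in finite])
    best = finite[int(np.argmax(lps))]
    key = best["omega"].tobytes()
    matching = [s for s in finite if s["omega"].tobytes() == key]
    rho0_hat = float(np.mean([s["rho0"] for s in matching]))
    rho_k_hat = np.mean([s["rho_k"] for s in matching], axis=0)

    omega_hat = ClusterAssignment(best["omega"])
    rho_hat = CorrelationFactors(rho0_hat, rho_k_hat)
    try:
        _, _ = structured_inverse_and_logdet(omega_hat, rho_hat, edge_map)
    except NotPositiveDefiniteError:
        # averaging rho across draws can, rarely, exit the PD region;
        # fall back to the MAP draw's own factors, which are PD by construction
        rho_hat = CorrelationFactors(best["rho0"], best["rho_k"])
    Lambda_hat = build_lambda(omega_hat, rho_hat, edge_map)
    sd = np.sqrt(np.diag(summary.H0))
    Sigma_hat = Lambda_hat * np.outer(sd, sd)

    diagnostics = pd.DataFrame(diag_rows, columns=["sweep", "log_posterior", "n_clusters"])
    return PosteriorCovariance(
        omega_hat=omega_hat,
        rho_hat=rho_hat,
        Lambda_hat=Lambda_hat,
        Sigma_hat=Sigma_hat,
        samples=retained,
        diagnostics=diagnostics,
        acceptance=sampler.acceptance_rates,
        seed=hyper.seed,
    )
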