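"""Two-group network and edge-wise tests with permutation inference.

The whole-network hypothesis (equality of the two groups' edge-mean
vectors) is tested with the Hotelling-type quadratic form

    T = (beta1 - beta2)' (var(beta1) + var(beta2))^{-1} (beta1 - beta2)

with an identity contrast over all E edges, and each single edge with the
squared two-sample z-score

    t_e = (beta1(e) - beta2(e))^2 / (var(beta1)(e,e) + var(beta2)(e,e)).

Null distributions come from relabelling subjects across groups (group
sizes preserved); the effect and heterogeneity parameters are re-estimated
for every relabelling while each pseudo-group reuses the structured edge
covariance estimated under the observed labels.  Edge-wise permutation
p-values are Benjamini-Hochberg adjusted.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, LinAlgError
from statsmodels.stats.multitest import multipletests

from .connectivity import ConnectivityDataset
from .heterogeneity import GroupFit, fit_group, normalize_structure

logger = logging.getLogger(__name__)

__all__ = [
    "PermutationPlan",
    "NetworkTestResult",
    "network_statistic",
    "edge_statistic",
    "edge_statistics",
    "fdr_adjust",
    "permutation_test",
]


class DegenerateEdgeError(ValueError):
    """An edge has zero variance under both groups."""


@dataclass
class PermutationPlan:
    """Permutation-test settings.

    ``B`` random relabellings are drawn from ``seed``; with
    ``exhaustive=True`` every group-size-preserving assignment is
    enumerated instead (the observed labelling included) and ``B`` is
    ignored.
    """

    B: int = 500
    seed: int = 0
    alpha: float = 0.05
    exhaustive: bool = False

    def __post_init__(self):
        if not self.exhaustive and self.B < 1:
            raise ValueError("need at least B = 1 permutation")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")


@dataclass
class NetworkTestResult:
    """Whole-network statistic with its permutation p-value."""

    statistic: float
    p_value: float
    n_permutations: int
    alpha: float
    exhaustive: bool = False

    @property
    def reject(self) -> bool:
        return self.p_value <= self.alpha


def _solve_spd(M: np.ndarray, d: np.ndarray) -> np.ndarray:
    try:
        return cho_solve(cho_factor(M, lower=True, check_finite=False), d,
                         check_finite=False)
    except (LinAlgError, np.linalg.LinAlgError):
        ridge = 1e-8 * float(np.trace(M)) / M.shape[0]
        logger.warning("variance sum numerically singular; adding ridge %.3e", ridge)
        return cho_solve(
            cho_factor(M + ridge * np.eye(M.shape[0]), lower=True, check_finite=False),
            d, check_finite=False)


def network_statistic(fit1: GroupFit, fit2: GroupFit) -> float:
    """Hotelling-type quadratic form over the whole edge set."""
    if fit1.E != fit2.E:
        raise ValueError("group fits cover different edge sets")
    d = fit1.beta_hat - fit2.beta_hat
    V = fit1.var_beta + fit2.var_beta
    return float(d @ _solve_spd(V, d))


def edge_statistics(fit1: GroupFit, fit2: GroupFit) -> np.ndarray:
    """Vector of squared two-sample z-scores, one per edge."""
    d = fit1.beta_hat - fit2.beta_hat
    den = np.diag(fit1.var_beta) + np.diag(fit2.var_beta)
    if np.any(den <= 0):
        e = int(np.flatnonzero(den <= 0)[0])
        raise DegenerateEdgeError(f"edge {e} has zero pooled variance")
    return d * d / den


def edge_statistic(fit1: GroupFit, fit2: GroupFit, e: int) -> float:
    """Single-edge squared z-score (0-based edge index)."""
    if not 0 <= e < fit1.E:
        raise IndexError(f"edge index {e} out of range for E={fit1.E}")
    return float(edge_statistics(fit1, fit2)[e])


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a non-empty 1-D sequence")
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _fit_pair(Y, idx1, idx2, Sigma1, Sigma2, structure):
    fit1 = fit_group(Y[idx1], Sigma1, structure)
    fit2 = fit_group(Y[idx2], Sigma2, structure)
    return fit1, fit2


def permutation_test(dataset: ConnectivityDataset, sigma_by_group: dict,
                     structure: str, plan: PermutationPlan):
    """Observed statistics plus permutation p-values for both hypotheses.

    Parameters
    ----------
    dataset : ConnectivityDataset
        Two-group edge data.
    sigma_by_group : dict
        Structured edge covariance per group label, estimated once under
        the observed labels and held fixed across relabellings (the first
        pseudo-group always pairs with the first group's Sigma).
    structure : str
        Heterogeneity structure, ``"scaled_identity"`` or
        ``"compound_symmetry"``.
    plan : PermutationPlan

    Returns
    -------
    (NetworkTestResult, pandas.DataFrame)
        The network test and the per-edge table with columns ``edge``
        (1-based), ``region_i``, ``region_j``, ``beta1``, ``beta2``,
        ``stat``, ``p_perm``, ``p_fdr``.
    """
    structure = normalize_structure(structure)
    labels = dataset.group_labels
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, found {labels}")
    g1, g2 = labels
    idx1 = dataset.indices(g1)
    idx2 = dataset.indices(g2)
    Sigma1 = np.asarray(sigma_by_group[g1], dtype=float)
    Sigma2 = np.asarray(sigma_by_group[g2], dtype=float)
    Y = dataset.Y
    n1, n2 = idx1.size, idx2.size
    N = n1 + n2

    fit1, fit2 = _fit_pair(Y, idx1, idx2, Sigma1, Sigma2, structure)
    obs_net = network_statistic(fit1, fit2)
    obs_edge = edge_statistics(fit1, fit2)

    if plan.exhaustive:
        assignments = [np.asarray(comb, dtype=np.intp)
                       for comb in itertools.combinations(range(N), n1)]
    else:
        assignments = None

    rng = np.random.default_rng(plan.seed)
    all_idx = np.arange(N)
    count_net = 0
    count_edge = np.zeros(obs_edge.size, dtype=np.int64)
    n_perm = len(assignments) if plan.exhaustive else plan.B
    for b in range(n_perm):
        if plan.exhaustive:
            p1 = assignments[b]
            mask = np.zeros(N, dtype=bool)
            mask[p1] = True
            p2 = all_idx[~mask]
        else:
            perm = rng.permutation(N)
            p1, p2 = perm[:n1], perm[n1:]
        f1, f2 = _fit_pair(Y, p1, p2, Sigma1, Sigma2, structure)
        net_b = network_statistic(f1, f2)
        edge_b = edge_statistics(f1, f2)
        count_net += net_b >= obs_net
        count_edge += edge_b >= obs_edge

    if plan.exhaustive:
        p_net = count_net / n_perm
        p_edge = count_edge / n_perm
    else:
        p_net = (1 + count_net) / (n_perm + 1)
        p_edge = (1 + count_edge) / (n_perm + 1)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # multipletests warns on tiny inputs
        p_fdr = fdr_adjust(p_edge)

    emap = dataset.edge_map
    region = dataset.regions.labels
    table = pd.DataFrame({
        "edge": np.arange(1, emap.E + 1),
        "region_i": [region[i] for i in emap.i],
        "region_j": [region[j] for j in emap.j],
        "beta1": fit1.beta_hat,
        "beta2": fit2.beta_hat,
        "stat": obs_edge,
        "p_perm": p_edge,
        "p_fdr": p_fdr,
    })
    net = NetworkTestResult(statistic=obs_net, p_value=float(p_net),
                            n_permutations=n_perm, alpha=plan.alpha,
                            exhaustive=plan.exhaustive)
    return net, table
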