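"""Two-group synthetic connectivity data and power / type-I experiments.

The generator emulates a two-cluster latent network: ``V`` regions split
into two (near-)equal clusters, edge correlation ``rho_within`` for edge
pairs lying fully inside a cluster and ``rho_between`` (default 0)
otherwise, giving the structured correlation matrix ``Lambda_true``.
Per-subject heterogeneity is a scalar ``u_n ~ Uniform(-delta, delta)``
added to every diagonal entry of the edge covariance, and the group
difference is a sparse mean shift: ``d = effect_size`` at
``round(effect_fraction * E)`` randomly chosen edges, added to the
control group.  Setting ``effect_size = 0`` turns the same pipeline into
a type-I-error experiment.

An experiment simulates ``n_reps`` independent replicates, estimates the
edge covariance per group (either by MCMC or, in *oracle* mode, by
injecting ``Lambda_true`` to isolate the inference layer), fits both
groups, runs the permutation network test and reports the rejection
proportion at level ``alpha``.  Every replicate's seed derives
deterministically from the scenario seed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .connectivity import ConnectivityDataset, EdgeIndexMap, RegionSet, edge_count
from .dp_covariance import DPHyperparameters, build_lambda, estimate_edge_covariance
from .heterogeneity import normalize_structure
from .inference import PermutationPlan, permutation_test

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "TrueModel",
    "ExperimentResult",
    "make_true_model",
    "simulate_dataset",
    "run_experiment",
    "summarize_experiments",
    "desk_scale_mcmc",
]

CONTROL = "control"
CASE = "case"


def desk_scale_mcmc(**overrides) -> DPHyperparameters:
    """Chain settings for reduced-replication experiment runs.

    400 sweeps with 200 burn-in: on the simulated two-cluster structures
    the partition mode is typically reached within a few dozen sweeps, so
    this retains ample post-burn-in draws while keeping a full Monte-Carlo
    experiment (two chains per replicate) tractable on one CPU.
    """
    defaults = dict(n_iter=400, n_burn=200)
    defaults.update(overrides)
    return DPHyperparameters(**defaults)


@dataclass
class ScenarioConfig:
    """One cell of the simulation design.

    Defaults mirror the reference study conditions: two latent clusters,
    ``rho_between = 0``, a mean shift of 0.8 at 5% of edges, 100
    replicates and 500 permutations at ``alpha = 0.05``.  ``n_reps``,
    ``n_perms`` and the MCMC settings can be scaled down for desk-scale
    runs; ``oracle_cov=True`` bypasses the MCMC and plugs in the true
    correlation structure.
    """

    V: int = 20
    n_clusters: int = 2
    rho_within: float = 0.3
    rho_between: float = 0.0
    delta: float = 0.15
    n_per_group: int = 25
    effect_size: float = 0.8
    effect_fraction: float = 0.05
    psi_structure: str = "scaled_identity"
    n_reps: int = 100
    n_perms: int = 500
    alpha: float = 0.05
    seed: int = 0
    oracle_cov: bool = False
    mcmc: DPHyperparameters = field(default_factory=DPHyperparameters)

    def __post_init__(self):
        if self.V < 6:
            raise ValueError("need V >= 6 for a meaningful two-cluster design")
        if self.n_clusters < 1 or self.n_clusters > self.V // 2:
            raise ValueError("n_clusters must be in [1, V/2]")
        if not 0 <= self.rho_between < 1:
            raise ValueError("rho_between must lie in [0, 1)")
        if not -1 < self.rho_within < 1:
            raise ValueError("rho_within must lie in (-1, 1)")
        if self.delta < 0 or self.delta >= 1:
            raise ValueError("delta must lie in [0, 1) to keep covariances PD")
        if not 0 < self.effect_fraction < 1:
            raise ValueError("effect_fraction must lie in (0, 1)")
        if self.n_per_group < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.n_reps < 1 or self.n_perms < 1:
            raise ValueError("n_reps and n_perms must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        self.psi_structure = normalize_structure(self.psi_structure)
        if isinstance(self.mcmc, dict):
            self.mcmc = DPHyperparameters(**self.mcmc)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown scenario fields: {sorted(unknown)}")
        return cls(**data)


@dataclass
class TrueModel:
    """Ground truth for one scenario: partition, structure and mean shift."""

    omega_true: np.ndarray
    Lambda_true: np.ndarray
    d_vector: np.ndarray
    edge_map: EdgeIndexMap
    eigvecs: np.ndarray = None
    eigvals: np.ndarray = None

    @property
    def d_support(self) -> np.ndarray:
        return np.flatnonzero(self.d_vector != 0)


def make_true_model(config: ScenarioConfig) -> TrueModel:
    """Build the scenario's true correlation structure and effect vector.

    Regions are split into ``n_clusters`` contiguous, near-equal clusters
    (first cluster gets the remainder for odd ``V``).  The support of the
    mean shift is drawn once per scenario, without replacement, from the
    scenario seed, so every replicate of a cell tests the same
    alternative.
    """
    V = config.V
    E = edge_count(V)
    splits = np.array_split(np.arange(V), config.n_clusters)
    omega = np.empty(V, dtype=np.intp)
    for k, nodes in enumerate(splits):
        omega[nodes] = k
    edge_map = EdgeIndexMap(V)
    rho_k = np.full(config.n_clusters, config.rho_within)
    Lambda = build_lambda(omega, (config.rho_between, rho_k), edge_map)

    vals, vecs = np.linalg.eigh(Lambda)
    if vals.min() <= 0:
        raise ValueError(
            f"scenario correlations rho_within={config.rho_within}, "
            f"rho_between={config.rho_between} give a non-PD structure"
        )

    rng = np.random.default_rng(np.random.SeedSequence([int(config.seed), 0]))
    n_effect = int(round(config.effect_fraction * E))
    support = rng.choice(E, size=n_effect, replace=False)
    d = np.zeros(E)
    d[support] = config.effect_size
    return TrueModel(omega_true=omega, Lambda_true=Lambda, d_vector=d,
                     edge_map=edge_map, eigvecs=vecs, eigvals=vals)


def _sample_group(model: TrueModel, n: int, delta: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Draw ``n`` subjects with per-subject diagonal perturbations.

    Subject ``n`` has covariance ``Lambda_true + u_n I`` with
    ``u_n ~ Uniform(-delta, delta)``; sampling goes through the spectral
    factorisation of ``Lambda_true`` shifted by ``u_n``.
    """
    E = model.edge_map.E
    u = rng.uniform(-delta, delta, size=n)
    z = rng.standard_normal((n, E))
    shifted = model.eigvals[None, :] + u[:, None]
    if shifted.min() < -1e-12:
        raise ValueError(
            "Lambda_true + u I is not positive semidefinite for some subject; "
            "reduce delta or the within-cluster correlation"
        )
    scaled = z * np.sqrt(np.clip(shifted, 0.0, None))
    return scaled @ model.eigvecs.T


def simulate_dataset(model: TrueModel, config: ScenarioConfig,
                     rep_seed) -> ConnectivityDataset:
    """One replicate: control subjects (mean shifted by ``d``) then cases."""
    rng = np.random.default_rng(rep_seed)
    n = config.n_per_group
    Y_control = _sample_group(model, n, config.delta, rng) + model.d_vector
    Y_case = _sample_group(model, n, config.delta, rng)
    Y = np.vstack([Y_control, Y_case])
    groups = np.asarray([CONTROL] * n + [CASE] * n, dtype=object)
    ids = [f"{g}{k + 1:03d}" for g, cnt in ((CONTROL, n), (CASE, n)) for k in range(cnt)]
    return ConnectivityDataset(Y=Y, groups=groups, subject_ids=ids,
                               edge_map=model.edge_map,
                               regions=RegionSet.default(model.edge_map.V))


@dataclass
class ExperimentResult:
    """Rejection proportion over replicates plus per-replicate records."""

    config: ScenarioConfig
    rejection_rate: float
    records: pd.DataFrame
    n_failed: int

    @property
    def n_completed(self) -> int:
        return len(self.records)


def _rep_seeds(config: ScenarioConfig, rep: int) -> list[int]:
    ss = np.random.SeedSequence([int(config.seed), 1, rep])
    return [int(x) for x in ss.generate_state(4)]


def run_experiment(config: ScenarioConfig) -> ExperimentResult:
    """Monte-Carlo power (``effect_size != 0``) or type-I error (``= 0``).

    The type-I and power paths are the same code; only the effect size in
    the config differs.  Replicates are independent given their derived
    seeds, so the result is a pure function of ``config.seed``.
    """
    model = make_true_model(config)
    rows = []
    n_failed = 0
    for rep in range(config.n_reps):
        data_seed, mcmc_seed1, mcmc_seed2, perm_seed = _rep_seeds(config, rep)
        try:
            dataset = simulate_dataset(model, config, data_seed)
            sigma_by_group = {}
            for label, mcmc_seed in ((CONTROL, mcmc_seed1), (CASE, mcmc_seed2)):
                Yg = dataset.group_data(label)
                if config.oracle_cov:
                    sigma_by_group[label] = model.Lambda_true
                else:
                    R = Yg - Yg.mean(axis=0)
                    hyper = dataclasses.replace(config.mcmc, seed=mcmc_seed)
                    est = estimate_edge_covariance(R, p=1, hyper=hyper,
                                                   edge_map=model.edge_map)
                    sigma_by_group[label] = est.Sigma_hat
            plan = PermutationPlan(B=config.n_perms, seed=perm_seed,
                                   alpha=config.alpha)
            net, _ = permutation_test(dataset, sigma_by_group,
                                      config.psi_structure, plan)
            rows.append((rep, net.statistic, net.p_value, net.reject, data_seed))
        except Exception:
            n_failed += 1
            logger.exception("replicate %d failed; excluded from the rate", rep)
    records = pd.DataFrame(rows, columns=["rep", "statistic", "p_value",
                                          "reject", "data_seed"])
    if records.empty:
        raise RuntimeError("every replicate failed; no rejection rate available")
    rate = float(records["reject"].mean())
    return ExperimentResult(config=config, rejection_rate=rate,
                            records=records, n_failed=n_failed)


def summarize_experiments(results: list[ExperimentResult]) -> pd.DataFrame:
    """Long-format summary across scenario cells (one row per experiment)."""
    rows = []
    for res in results:
        cfg = res.config
        rows.append({
            "V": cfg.V,
            "N": cfg.n_per_group,
            "rho_within": cfg.rho_within,
            "delta": cfg.delta,
            "psi_structure": cfg.psi_structure,
            "effect_size": cfg.effect_size,
            "kind": "type_i_error" if cfg.effect_size == 0 else "power",
            "rejection_rate": res.rejection_rate,
            "n_reps": res.n_completed,
            "n_failed": res.n_failed,
        })
    return pd.DataFrame(rows)
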