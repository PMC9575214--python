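"""Edge-level data model for functional-connectivity networks.

A subject's functional connectivity is a symmetric ``V x V`` matrix of
Fisher-z-transformed Pearson correlations between the activity time series
of ``V`` brain regions.  The analysis unit is the *edge*: an unordered
region pair ``(i, j)`` with ``i < j``, of which there are
``E = V(V-1)/2``.  Each subject's matrix is flattened into a length-``E``
edge vector, and a two-group study becomes an ``N x E`` matrix ``Y`` with a
group label per row.

Conventions
-----------
* Edge ordering is lexicographic over ``(i, j)``, ``i < j`` (row-major
  upper triangle), 0-based internally and 1-based in user-facing output.
* The diagonal of a stored connectivity matrix is 0 and is never consumed.
* Matrices asymmetric beyond ``1e-8`` are rejected; smaller asymmetries
  are averaged away.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidRegionCountError",
    "RegionSet",
    "EdgeIndexMap",
    "ConnectivityMatrix",
    "ConnectivityDataset",
    "edge_count",
    "fisher_z",
    "inverse_fisher_z",
    "vectorize",
    "devectorize",
]

#: Largest relative asymmetry tolerated before a matrix is rejected.
ASYMMETRY_TOL = 1e-8


class InvalidRegionCountError(ValueError):
    """Raised when a region count cannot define a connectivity graph."""


def edge_count(V: int) -> int:
    """Number of edges (unordered region pairs) in a ``V``-region network.

    Parameters
    ----------
    V : int
        Number of regions (graph nodes); must be at least 2.

    Returns
    -------
    int
        ``V * (V - 1) // 2``.
    """
    V = int(V)
    if V < 2:
        raise InvalidRegionCountError(
            f"a connectivity graph needs at least 2 regions, got V={V}"
        )
    return V * (V - 1) // 2


def region_count_for_edges(E: int) -> int:
    """Invert :func:`edge_count`, failing if ``E`` is not triangular."""
    V = int(round((1 + np.sqrt(1 + 8 * E)) / 2))
    if edge_count(max(V, 2)) != E:
        raise InvalidRegionCountError(
            f"{E} edges does not correspond to a whole number of regions"
        )
    return V


def fisher_z(r):
    """Fisher z-transform ``arctanh(r)`` of a correlation in ``(-1, 1)``.

    Accepts scalars or arrays; raises ``ValueError`` when any ``|r| >= 1``.
    """
    arr = np.asarray(r, dtype=float)
    if np.any(np.abs(arr) >= 1.0):
        raise ValueError("fisher_z requires |r| < 1")
    out = np.arctanh(arr)
    return float(out) if np.isscalar(r) or out.ndim == 0 else out


def inverse_fisher_z(z):
    """Inverse of :func:`fisher_z` (``tanh``)."""
    out = np.tanh(np.asarray(z, dtype=float))
    return float(out) if np.isscalar(z) or out.ndim == 0 else out


@dataclass(frozen=True)
class RegionSet:
    """Ordered collection of region (node) names."""

    labels: tuple[str, ...]

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        object.__setattr__(self, "labels", labels)
        if len(set(labels)) != len(labels):
            raise ValueError("region labels must be unique")
        if len(labels) < 3:
            raise InvalidRegionCountError(
                f"a region set needs at least 3 regions, got {len(labels)}"
            )

    @classmethod
    def default(cls, V: int) -> "RegionSet":
        """Generic labels ``R1 .. RV``."""
        return cls(tuple(f"R{i + 1}" for i in range(V)))

    @property
    def V(self) -> int:
        return len(self.labels)


class EdgeIndexMap:
    """Bijection between region pairs ``(i, j)``, ``i < j``, and edge indices.

    The ordering is lexicographic in ``(i, j)`` (row-major upper triangle)
    and therefore stable across runs.
    """

    def __init__(self, V: int):
        self.V = int(V)
        self.E = edge_count(self.V)
        iu = np.triu_indices(self.V, k=1)
        #: region index arrays of shape ``(E,)``; ``i < j`` elementwise
        self.i = iu[0].astype(np.intp)
        self.j = iu[1].astype(np.intp)
        self._index = {(int(a), int(b)): e for e, (a, b) in enumerate(zip(self.i, self.j))}

    @property
    def pairs(self) -> list[tuple[int, int]]:
        """Ordered list of 0-based region pairs."""
        return [(int(a), int(b)) for a, b in zip(self.i, self.j)]

    def index_of(self, i: int, j: int) -> int:
        """Edge index of the unordered pair ``{i, j}`` (0-based regions)."""
        if i == j:
            raise KeyError("self-pairs (i, i) are not edges")
        key = (min(i, j), max(i, j))
        return self._index[key]

    def incident(self, i: int) -> np.ndarray:
        """Indices of the ``V - 1`` edges touching region ``i``."""
        return np.flatnonzero((self.i == i) | (self.j == i))

    def __eq__(self, other):
        return isinstance(other, EdgeIndexMap) and other.V == self.V

    def __repr__(self):
        return f"EdgeIndexMap(V={self.V}, E={self.E})"


def _check_symmetric(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[0] != values.shape[1]:
        raise ValueError(f"connectivity matrix must be square, got {values.shape}")
    asym = np.max(np.abs(values - values.T)) if values.size else 0.0
    scale = max(1.0, float(np.max(np.abs(values))) if values.size else 1.0)
    if asym > ASYMMETRY_TOL * scale:
        raise ValueError(
            f"matrix asymmetric beyond tolerance: max |M - M.T| = {asym:.3e}"
        )
    return 0.5 * (values + values.T)


@dataclass
class ConnectivityMatrix:
    """One subject's symmetric matrix of Fisher-z connectivity values."""

    values: np.ndarray
    subject_id: str = ""

    def __post_init__(self):
        sym = _check_symmetric(self.values)
        np.fill_diagonal(sym, 0.0)  # diagonal is a convention, never data
        self.values = sym

    @property
    def V(self) -> int:
        return self.values.shape[0]


def vectorize(matrix, edge_map: EdgeIndexMap) -> np.ndarray:
    """Flatten a symmetric matrix into its length-``E`` edge vector.

    ``matrix`` may be a :class:`ConnectivityMatrix` or a raw square array;
    raw arrays are symmetry-checked (tolerance ``1e-8``) and symmetrized.
    """
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else _check_symmetric(matrix)
    if values.shape[0] != edge_map.V:
        raise ValueError(
            f"matrix has {values.shape[0]} regions but edge map expects {edge_map.V}"
        )
    return values[edge_map.i, edge_map.j].copy()


def devectorize(vec: np.ndarray, edge_map: EdgeIndexMap) -> np.ndarray:
    """Rebuild the symmetric matrix (zero diagonal) from an edge vector."""
    vec = np.asarray(vec, dtype=float)
    if vec.shape != (edge_map.E,):
        raise ValueError(f"expected edge vector of length {edge_map.E}, got {vec.shape}")
    out = np.zeros((edge_map.V, edge_map.V))
    out[edge_map.i, edge_map.j] = vec
    out[edge_map.j, edge_map.i] = vec
    return out


@dataclass
class ConnectivityDataset:
    """Two-group collection of subject edge vectors.

    Attributes
    ----------
    Y : ndarray of shape (N, E)
        One Fisher-z edge vector per subject, columns in
        :class:`EdgeIndexMap` order.
    groups : ndarray of shape (N,)
        Group label per subject (exactly two distinct labels for the
        two-sample analyses; each group needs at least 2 subjects).
    subject_ids : list of str
    edge_map : EdgeIndexMap
    regions : RegionSet
    """

    Y: np.ndarray
    groups: np.ndarray
    subject_ids: list[str]
    edge_map: EdgeIndexMap
    regions: RegionSet = None

    def __post_init__(self):
        self.Y = np.asarray(self.Y, dtype=float)
        self.groups = np.asarray(self.groups, dtype=object)
        if self.Y.ndim != 2:
            raise ValueError("Y must be 2-D (subjects x edges)")
        N, E = self.Y.shape
        if E != self.edge_map.E:
            raise ValueError(f"Y has {E} columns but edge map has {self.edge_map.E} edges")
        if len(self.groups) != N or len(self.subject_ids) != N:
            raise ValueError("groups / subject_ids length must match rows of Y")
        if self.regions is None:
            self.regions = RegionSet.default(self.edge_map.V)
        if self.regions.V != self.edge_map.V:
            raise ValueError("region set size does not match edge map")
        for g in self.group_labels:
            if np.sum(self.groups == g) < 2:
                raise ValueError(f"group {g!r} has fewer than 2 subjects")

    @property
    def n_subjects(self) -> int:
        return self.Y.shape[0]

    @property
    def group_labels(self) -> list:
        """Distinct group labels in order of first appearance."""
        seen: dict = {}
        for g in self.groups:
            seen.setdefault(g, None)
        return list(seen)

    def indices(self, group) -> np.ndarray:
        return np.flatnonzero(self.groups == group)

    def group_data(self, group) -> np.ndarray:
        """Rows of ``Y`` belonging to ``group``."""
        return self.Y[self.indices(group)]

    @classmethod
    def from_matrices(cls, matrices, groups, edge_map=None, regions=None):
        """Assemble from per-subject :class:`ConnectivityMatrix` objects."""
        matrices = list(matrices)
        if not matrices:
            raise ValueError("no connectivity matrices supplied")
        V = matrices[0].V
        edge_map = edge_map or EdgeIndexMap(V)
        Y = np.vstack([vectorize(m, edge_map) for m in matrices])
        ids = [m.subject_id or f"sub{k + 1:03d}" for k, m in enumerate(matrices)]
        return cls(Y=Y, groups=np.asarray(groups, dtype=object), subject_ids=ids,
                   edge_map=edge_map, regions=regions)


def connectivity_from_time_series(series: np.ndarray, subject_id: str = "") -> ConnectivityMatrix:
    """Fisher-z connectivity matrix from a ``regions x time`` table."""
    series = np.asarray(series, dtype=float)
    if series.ndim != 2 or series.shape[1] < 3:
        raise ValueError("time-series table must be regions x time with >= 3 time points")
    corr = np.corrcoef(series)
    off = ~np.eye(corr.shape[0], dtype=bool)
    if np.any(np.abs(corr[off]) >= 1.0):
        raise ValueError("degenerate time series produced |r| >= 1")
    z = np.zeros_like(corr)
    z[off] = np.arctanh(corr[off])
    return ConnectivityMatrix(values=z, subject_id=subject_id)
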