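"""Location adjacency graph and IND/CAR/SAR spatial covariance structures.

Locations (counties or metropolitan areas) form an undirected graph whose
edges join locations sharing a border.  Community-level random effects are
modeled as independent (IND), conditional autoregressive (CAR), or
simultaneous autoregressive (SAR) Gaussian fields on this graph.

With W the 0/1 adjacency, D = diag(neighbor counts), W_+ the row-normalized
adjacency and M = D^{-1}, the covariances are

    IND:  sigma_s^2 I
    CAR:  sigma_s^2 (M^{-1/2} (I - rho M^{-1/2} W_+ M^{1/2}) M^{-1/2})^{-1}
    SAR:  sigma_s^2 ((I - rho M^{-1/2} W_+ M^{1/2}) M^{-1}
                     (I - rho M^{1/2} W_+^T M^{-1/2}))^{-1}

Because M^{-1/2} W_+ M^{1/2} equals the symmetric normalized adjacency
W~ = D^{-1/2} W D^{-1/2}, the precisions simplify to the classical forms

    CAR precision:  (D - rho W) / sigma_s^2
    SAR precision:  (I - rho W~) D (I - rho W~) / sigma_s^2

which are positive definite for |rho| < 1.  Isolated locations (no
neighbors) are treated as independent components with variance sigma_s^2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

STRUCTURES = ("IND", "CAR", "SAR")


class SpatialError(ValueError):
    pass


@dataclass
class LocationGraph:
    """Adjacency structure over an ordered list of locations."""

    locations: list[str]
    W: sparse.csr_matrix  # symmetric 0/1, zero diagonal

    def __post_init__(self) -> None:
        L = len(self.locations)
        if self.W.shape != (L, L):
            raise SpatialError("adjacency shape does not match location count")
        self.neighbor_counts = np.asarray(self.W.sum(axis=1)).ravel()
        self.isolated = self.neighbor_counts == 0
        if self.isolated.any():
            warnings.warn(
                f"{int(self.isolated.sum())} isolated location(s) treated as "
                "independent spatial components",
                stacklevel=2,
            )
        # D with isolates set to 1 so that their precision entry is 1/sigma^2
        self._d_eff = np.where(self.isolated, 1.0, self.neighbor_counts)

    @property
    def L(self) -> int:
        return len(self.locations)

    @property
    def W_plus(self) -> sparse.csr_matrix:
        """Row-normalized adjacency (isolated rows stay zero)."""
        inv = np.where(self.isolated, 0.0, 1.0 / self._d_eff)
        return sparse.diags(inv) @ self.W

    @property
    def M(self) -> np.ndarray:
        """Diagonal of inverse neighbor counts (isolates: 1 by convention)."""
        return 1.0 / self._d_eff

    def normalized_adjacency(self) -> sparse.csr_matrix:
        """W~ = D^{-1/2} W D^{-1/2}, symmetric, spectral radius < 1."""
        s = sparse.diags(1.0 / np.sqrt(self._d_eff))
        return (s @ self.W @ s).tocsr()


@dataclass
class SpatialSpec:
    structure: str
    sigma_s2: float = 1.0
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.structure not in STRUCTURES:
            raise SpatialError(
                f"unknown spatial structure {self.structure!r}; expected {STRUCTURES}"
            )
        if self.sigma_s2 < 0:
            raise SpatialError("sigma_s2 must be >= 0")
        if self.structure != "IND" and not (-1.0 < self.rho < 1.0):
            raise SpatialError(f"rho must lie in (-1, 1), got {self.rho}")


def build_location_graph(
    edges: list[tuple[str, str]], locations: list[str]
) -> LocationGraph:
    """Build the symmetric 0/1 adjacency from an undirected edge list.

    Duplicate and reversed edges are idempotent; self-loops are rejected.
    """
    loc_index = {loc: i for i, loc in enumerate(locations)}
    if len(loc_index) != len(locations):
        raise SpatialError("duplicate location ids")
    L = len(locations)
    rows, cols = [], []
    for a, b in edges:
        if a not in loc_index or b not in loc_index:
            raise SpatialError(f"edge ({a!r}, {b!r}) references unknown location")
        if a == b:
            raise SpatialError(f"self-loop on location {a!r}")
        i, j = loc_index[a], loc_index[b]
        rows += [i, j]
        cols += [j, i]
    W = sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(L, L)
    )
    W.data[:] = 1.0  # collapse duplicate entries
    W.sum_duplicates()
    W.data[:] = 1.0
    return LocationGraph(locations=locations, W=W)


def unit_precision(graph: LocationGraph, structure: str, rho: float) -> sparse.csr_matrix:
    """Precision matrix of the spatial structure at sigma_s^2 = 1.

    CAR: D - rho W;  SAR: (I - rho W~) D (I - rho W~);  IND: I.
    Nonzeros of the CAR precision lie only on the diagonal and graph edges.
    """
    L = graph.L
    if structure == "IND":
        return sparse.identity(L, format="csr")
    if not (-1.0 < rho < 1.0):
        raise SpatialError(f"rho must lie in (-1, 1), got {rho}")
    D = sparse.diags(graph._d_eff)
    if structure == "CAR":
        return (D - rho * graph.W).tocsr()
    if structure == "SAR":
        Wt = graph.normalized_adjacency()
        B = sparse.identity(L) - rho * Wt
        return (B @ D @ B).tocsr()
    raise SpatialError(f"unknown spatial structure {structure!r}")


def spatial_covariance(graph: LocationGraph, spec: SpatialSpec) -> np.ndarray:
    """Dense L x L spatial covariance (symmetric positive definite).

    Intended for moderate graphs (the estimation path never forms this
    densely; it works with the sparse precision instead).
    """
    if spec.structure == "IND":
        return spec.sigma_s2 * np.eye(graph.L)
    P0 = unit_precision(graph, spec.structure, spec.rho).toarray()
    try:
        c = np.linalg.cholesky(P0)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - |rho|<1 guards this
        raise SpatialError(
            f"singular spatial precision (cond={np.linalg.cond(P0):.3g})"
        ) from exc
    inv = np.linalg.inv(c)
    Sigma = spec.sigma_s2 * (inv.T @ inv)
    return 0.5 * (Sigma + Sigma.T)


def gower_factor(Z_s, Sigma_s: np.ndarray) -> float:
    """Average phenotypic variance contributed by the spatial effects.

    Computes tr[Z_s (I - 11^T/N) Sigma_s Z_s^T] / (N - 1), i.e. the mean
    centred variance of the per-individual spatial effect.  CAR/SAR
    covariances have unequal diagonals, so this standardization makes the
    spatial variance comparable across traits and structures.
    """
    Z_s = sparse.csr_matrix(Z_s)
    N = Z_s.shape[0]
    if N < 2:
        raise SpatialError("Gower factor requires at least 2 individuals")
    counts = np.asarray(Z_s.sum(axis=0)).ravel()
    return gower_factor_from_counts(counts, Sigma_s)


def gower_factor_from_counts(counts: np.ndarray, Sigma_s: np.ndarray) -> float:
    """Gower factor from per-location individual counts (same formula)."""
    N = int(counts.sum())
    if N < 2:
        raise SpatialError("Gower factor requires at least 2 individuals")
    diag_term = float(np.dot(counts, np.diag(Sigma_s)))
    mean_term = float(counts @ Sigma_s @ counts) / N
    return (diag_term - mean_term) / (N - 1)
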