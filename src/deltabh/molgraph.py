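"""Molecular graphs from 3D geometries and eigenvalue-fingerprint comparison.

Structures are compared through the sorted eigenvalue spectrum of the
adjacency matrix with atomic numbers on the diagonal: identical spectra
(within tolerance) indicate identical connectivity for the same element
multiset.  A distance-weighted variant of the adjacency matrix extends the
comparison to 3D conformations.  The comparison is permutation-invariant by
construction; it cannot separate cospectral graphs or enantiomers, which is
an accepted limitation of the fingerprint.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CONNECTIVITY_TOL,
    CONFORMATION_TOL,
    COVALENT_RADII,
    DEFAULT_BOND_SCALE,
    MIN_ATOM_DISTANCE,
    SYMBOLS,
)
from .geometry import Geometry, GeometryError


@dataclass(frozen=True)
class MolecularGraph:
    """Unweighted bond graph: 0/1 adjacency plus atomic numbers per node."""

    adjacency: np.ndarray = field(repr=False)
    atomic_numbers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency, dtype=int)
        z = np.asarray(self.atomic_numbers, dtype=int)
        if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
            raise ValueError("adjacency must be square")
        if adj.shape[0] != z.shape[0]:
            raise ValueError("atomic_numbers length must match adjacency size")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if np.any(np.diag(adj) != 0):
            raise ValueError("adjacency diagonal must be zero")
        object.__setattr__(self, "adjacency", adj)
        object.__setattr__(self, "atomic_numbers", z)

    @property
    def n_atoms(self) -> int:
        return self.adjacency.shape[0]

    @property
    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def edges(self) -> list[tuple[int, int]]:
        i, j = np.nonzero(np.triu(self.adjacency))
        return list(zip(i.tolist(), j.tolist()))

    def symbols(self) -> tuple[str, ...]:
        return tuple(SYMBOLS[int(z)] for z in self.atomic_numbers)

    def permuted(self, order: list[int]) -> "MolecularGraph":
        order = np.asarray(order)
        return MolecularGraph(
            self.adjacency[np.ix_(order, order)], self.atomic_numbers[order]
        )


@dataclass(frozen=True)
class WeightedGraph:
    """Distance-weighted bond graph used for conformation comparison."""

    weights: np.ndarray = field(repr=False)
    atomic_numbers: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        z = np.asarray(self.atomic_numbers, dtype=int)
        if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] != z.shape[0]:
            raise ValueError("weights must be square and match atomic_numbers")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if not np.all(np.isfinite(w)) or np.any(w < 0):
            raise ValueError("weights must be finite and nonnegative")
        object.__setattr__(self, "weights", w)
        object.__setattr__(self, "atomic_numbers", z)


def build_graph(geom: Geometry, scale: float = DEFAULT_BOND_SCALE) -> MolecularGraph:
    """Perceive bonds from interatomic distances against covalent-radius sums.

    Atoms i and j are bonded iff d(i,j) <= scale * (r_cov(i) + r_cov(j)).
    """
    if not (1.0 <= scale <= 1.5):
        raise ValueError(f"scale must be in [1.0, 1.5], got {scale}")
    d = geom.distance_matrix()
    n = geom.n_atoms
    off = ~np.eye(n, dtype=bool)
    if n > 1 and d[off].min() < MIN_ATOM_DISTANCE:
        i, j = np.unravel_index(np.argmin(np.where(off, d, np.inf)), d.shape)
        raise GeometryError(
            f"atoms {i} and {j} overlap (d = {d[i, j]:.3f} A < {MIN_ATOM_DISTANCE} A)"
        )
    radii = np.array([COVALENT_RADII[s] for s in geom.symbols])
    cutoff = scale * (radii[:, None] + radii[None, :])
    adjacency = ((d <= cutoff) & off).astype(int)
    return MolecularGraph(adjacency, geom.atomic_numbers)


def spectrum_fingerprint(g: MolecularGraph) -> np.ndarray:
    """Sorted eigenvalues of adjacency + diag(atomic numbers)."""
    m = g.adjacency.astype(float) + np.diag(g.atomic_numbers.astype(float))
    return np.sort(np.linalg.eigvalsh(m))


def weighted_adjacency(geom: Geometry, graph: MolecularGraph) -> WeightedGraph:
    """Weighted bond matrix: w_ij = (r_cov(i)+r_cov(j)) / d_ij on bonded pairs.

    The weight is dimensionless, ~1 at equilibrium bond length and monotone
    in bond compression, so the spectrum is sensitive to conformation.
    """
    radii = np.array([COVALENT_RADII[s] for s in geom.symbols])
    d = geom.distance_matrix()
    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(
            graph.adjacency > 0, (radii[:, None] + radii[None, :]) / np.where(d > 0, d, 1.0), 0.0
        )
    return WeightedGraph(w, graph.atomic_numbers)


def weighted_fingerprint(geom: Geometry, graph: MolecularGraph | None = None) -> np.ndarray:
    """Conformation fingerprint: eigenvalues of an all-pairs distance weighting.

    Every atom pair (bonded or not) carries w_ij = (r_cov(i)+r_cov(j))/d_ij,
    with atomic numbers on the diagonal.  Restricting weights to bonded
    pairs would make the spectrum blind to torsions (rotamers share bond
    lengths), so the conformation comparison deliberately uses all pairs;
    the bonded-only weighting remains available via weighted_adjacency for
    the topological Laplacian.  Invariant under rotation, reflection and
    atom permutation.
    """
    z = geom.atomic_numbers.astype(float)
    radii = np.array([COVALENT_RADII[s] for s in geom.symbols])
    d = geom.distance_matrix()
    np.fill_diagonal(d, 1.0)
    m = (radii[:, None] + radii[None, :]) / d
    np.fill_diagonal(m, z)
    return np.sort(np.linalg.eigvalsh(m))


def same_connectivity(
    a: MolecularGraph, b: MolecularGraph, tol: float = CONNECTIVITY_TOL
) -> bool:
    """True iff the two graphs share atom counts, element multisets, and spectra."""
    if a.n_atoms != b.n_atoms:
        return False
    if not np.array_equal(np.sort(a.atomic_numbers), np.sort(b.atomic_numbers)):
        return False
    return bool(np.max(np.abs(spectrum_fingerprint(a) - spectrum_fingerprint(b))) <= tol)


def same_conformation(
    geom_a: Geometry, geom_b: Geometry, tol: float = CONFORMATION_TOL
) -> bool:
    """True iff the weighted fingerprints agree within ``tol``.

    Callers should establish same_connectivity first; the weighted spectrum
    alone cannot certify connectivity for mismatched graphs.
    """
    if geom_a.n_atoms != geom_b.n_atoms:
        return False
    fa = weighted_fingerprint(geom_a)
    fb = weighted_fingerprint(geom_b)
    return bool(np.max(np.abs(fa - fb)) <= tol)
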