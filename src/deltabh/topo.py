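"""Topological descriptors of transition-state graphs.

Randic connectivity, Estrada and first Zagreb indices are computed on the
unweighted bond graph; the Laplacian spectral gap uses the distance-weighted
bond matrix so that it reflects the 3D tightness of the structure.  A small
registry maps stable column names to descriptor functions so that feature
matrices have reproducible column order.
"""

from __future__ import annotations

from typing import Callable

import numpy as np

from .molgraph import MolecularGraph, WeightedGraph

# Eigenvalues below this are treated as the zero modes of disconnected parts.
_ZERO_EIG_THRESHOLD = 1e-9


def randic_index(g: MolecularGraph) -> float:
    """Sum over edges of (d_i d_j)^(-1/2); 0 for edgeless graphs."""
    deg = g.degrees
    total = 0.0
    for i, j in g.edges():
        total += 1.0 / np.sqrt(deg[i] * deg[j])
    return float(total)


def spectral_gap(g: WeightedGraph | MolecularGraph) -> float:
    """Lowest nonzero eigenvalue of the (weighted) graph Laplacian D - A.

    Degrees are weighted row sums; atomic numbers are not added to the
    Laplacian.  Returns 0.0 when the graph splits into more than one
    component (every eigenvalue beyond the first zero mode still below the
    numerical-zero threshold counts as zero).
    """
    if isinstance(g, MolecularGraph):
        a = g.adjacency.astype(float)
    else:
        a = g.weights
    lap = np.diag(a.sum(axis=1)) - a
    eigs = np.sort(np.linalg.eigvalsh(lap))
    nonzero = eigs[eigs > _ZERO_EIG_THRESHOLD]
    return float(nonzero[0]) if nonzero.size else 0.0


def estrada_index(g: MolecularGraph) -> float:
    """Sum of exp(mu_i) over the plain 0/1 adjacency spectrum."""
    eigs = np.linalg.eigvalsh(g.adjacency.astype(float))
    return float(np.exp(eigs).sum())


def zagreb_index(g: MolecularGraph, second: bool = False) -> float:
    """First Zagreb index sum(d_i^2); second Zagreb sum over edges of d_i*d_j."""
    deg = g.degrees
    if second:
        return float(sum(deg[i] * deg[j] for i, j in g.edges()))
    return float((deg.astype(float) ** 2).sum())


def _mean_degree(g: MolecularGraph) -> float:
    return float(g.degrees.mean())


def _max_degree(g: MolecularGraph) -> float:
    return float(g.degrees.max())


def _edge_count(g: MolecularGraph) -> float:
    return float(g.n_edges)


# name -> (function, needs_weighted). Column order of the topol family.
TOPO_REGISTRY: dict[str, tuple[Callable, bool]] = {
    "randic": (randic_index, False),
    "lambda1": (spectral_gap, True),
    "estrada": (estrada_index, False),
    "zagreb": (zagreb_index, False),
    "mean_degree": (_mean_degree, False),
    "max_degree": (_max_degree, False),
    "n_edges": (_edge_count, False),
}


def topo_features(graph: MolecularGraph, weighted: WeightedGraph | None = None) -> dict[str, float]:
    """Evaluate the registry on a TS graph; weighted matrix feeds lambda1."""
    out: dict[str, float] = {}
    for name, (fn, needs_weighted) in TOPO_REGISTRY.items():
        if needs_weighted:
            out[name] = fn(weighted if weighted is not None else graph)
        else:
            out[name] = fn(graph)
    return out
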