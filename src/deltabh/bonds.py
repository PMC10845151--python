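"""Formed/broken bond counts per element pair between reactant and product.

Atom mapping is positional: curation guarantees the reactant and product of
a record index the same atoms in the same order, as they come from the two
ends of the same intrinsic reaction coordinate.
"""

from __future__ import annotations

import numpy as np

from .constants import SYMBOLS
from .molgraph import MolecularGraph

# Fixed unordered element pairs over {H, C, N, O}; order defines columns.
ELEMENT_PAIRS: tuple[str, ...] = (
    "HH", "CH", "CN", "CO", "HN", "HO", "CC", "NN", "NO", "OO",
)

_PAIR_KEY = {frozenset(p): p for p in ELEMENT_PAIRS}
# single-element pairs like "HH" have a singleton frozenset
for p in ELEMENT_PAIRS:
    _PAIR_KEY.setdefault(frozenset(p), p)

FEATURE_NAMES: tuple[str, ...] = tuple(f"+{p}" for p in ELEMENT_PAIRS) + tuple(
    f"-{p}" for p in ELEMENT_PAIRS
)


class MappingError(ValueError):
    """Reactant/product graphs are not positionally mappable."""


def _pair_name(sym_i: str, sym_j: str) -> str:
    return _PAIR_KEY[frozenset((sym_i, sym_j))]


def bond_changes(reactant: MolecularGraph, product: MolecularGraph) -> dict[str, int]:
    """Count formed (+XY) and broken (-XY) bonds by element pair.

    Formed bonds are edges present in the product only; broken bonds are
    edges present in the reactant only.
    """
    if reactant.n_atoms != product.n_atoms:
        raise MappingError(
            f"atom count mismatch: {reactant.n_atoms} vs {product.n_atoms}"
        )
    if not np.array_equal(reactant.atomic_numbers, product.atomic_numbers):
        raise MappingError("atomic numbers differ in positional order")
    symbols = [SYMBOLS[int(z)] for z in reactant.atomic_numbers]
    counts = {name: 0 for name in FEATURE_NAMES}
    diff = product.adjacency - reactant.adjacency
    formed_i, formed_j = np.nonzero(np.triu(diff > 0))
    broken_i, broken_j = np.nonzero(np.triu(diff < 0))
    for i, j in zip(formed_i, formed_j):
        counts[f"+{_pair_name(symbols[i], symbols[j])}"] += 1
    for i, j in zip(broken_i, broken_j):
        counts[f"-{_pair_name(symbols[i], symbols[j])}"] += 1
    return counts
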