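"""Molecular graphs from 3D structures, and eigenvalue fingerprints.

Builds the bond graph of formaldehyde from raw Cartesian coordinates,
shows the adjacency-eigenvalue fingerprint used to compare connectivity,
and demonstrates that the comparison survives atom reordering but detects
a rewired isomer.
"""

import numpy as np

from deltabh import Geometry, build_graph, same_connectivity, spectrum_fingerprint

h2co = Geometry(
    ("C", "O", "H", "H"),
    np.array([[0.0, 0, 0], [0, 0, 1.21], [0.94, 0, -0.54], [-0.94, 0, -0.54]]),
)
graph = build_graph(h2co)
print("formaldehyde bonds:", [(h2co.symbols[i], h2co.symbols[j]) for i, j in graph.edges()])
print("fingerprint:", np.round(spectrum_fingerprint(graph), 4))
# eigenvalues of adjacency + diag(Z): one value per atom, sorted; identical
# multisets of eigenvalues <=> identical bonding for the same atoms

shuffled = h2co.permuted([3, 1, 0, 2])
print("same connectivity after relabeling atoms:",
      same_connectivity(graph, build_graph(shuffled)))

# hydroxycarbene HCOH: same atoms, different bonding -> different spectrum
hcoh = Geometry(
    ("C", "O", "H", "H"),
    np.array([[0.0, 0, 0], [0, 0, 1.31], [1.04, 0, -0.45], [0.85, 0, 1.75]]),
)
print("formaldehyde vs hydroxycarbene:",
      same_connectivity(graph, build_graph(hcoh)))
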