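"""The four descriptor families for one synthetic reaction.

Generates a single random CHNO reaction and prints a few members of each
feature family: reaction-difference cheminformatics descriptors, topological
indices of the transition-state graph, formed/broken bond counts, and
low-level electronic descriptors (barrier, hardness, imaginary frequency...).
"""

import numpy as np

from deltabh import (
    GeneratorConfig,
    bond_changes,
    build_graph,
    delta_descriptors,
    gen_reaction,
    sqm_features,
)
from deltabh.molgraph import weighted_adjacency
from deltabh.topo import topo_features

record, _, delta_true = gen_reaction(GeneratorConfig(seed=8), np.random.default_rng(8))
print("reaction:", record.smiles_reactant, "->", record.smiles_product)
print("low-level barrier: %.2f kcal/mol, true correction: %.2f kcal/mol"
      % (record.bh_pm7, delta_true))

rk = delta_descriptors(record.smiles_reactant, record.smiles_product)
nonzero = [(n, v) for n, v in zip(rk.names, rk.values) if abs(v) > 1e-9][:5]
print("\nreaction-difference descriptors (first nonzero):")
for name, val in nonzero:
    print(f"  rdkit.{name} = {val:+.3f}")

g_ts = build_graph(record.geom_ts)
topo = topo_features(g_ts, weighted_adjacency(record.geom_ts, g_ts))
print("\ntransition-state topology:")
for name in ("randic", "lambda1", "estrada", "zagreb"):
    print(f"  topol.{name} = {topo[name]:.4f}")
# lambda1 is the lowest nonzero eigenvalue of the distance-weighted graph
# Laplacian: larger means a tighter, more rigidly connected TS

changes = bond_changes(build_graph(record.geom_reactant), build_graph(record.geom_product))
print("\nbond changes:", {k: v for k, v in changes.items() if v})

pm7 = sqm_features(record)
print("\nlow-level electronic descriptors:")
for name in ("bh_pm7", "rate_proxy", "nu1_ts", "eta_ts", "alpha_ts", "de_r"):
    print(f"  pm7.{name} = {pm7[name]:.4f}")
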