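"""Activation Gibbs energies from RRHO thermochemistry.

Takes one synthetic reaction and evaluates the Gibbs energy of activation
G(TS) - G(reactant) at 300, 500 and 1000 K from geometries, harmonic
frequencies (imaginary mode excluded) and electronic energies.
"""

import numpy as np

from deltabh import GeneratorConfig, gen_reaction
from deltabh.thermo import (
    delta_g_activation_profile,
    gibbs,
    thermo_input_from_species,
    zpe,
)

record, _, _ = gen_reaction(GeneratorConfig(seed=6), np.random.default_rng(6))
print("reaction:", record.smiles_reactant, "->", record.smiles_product)
print("barrier (0 K, ZPE-corrected): %.2f kcal/mol" % record.bh_pm7)

reactant = thermo_input_from_species(
    record.geom_reactant, record.reactant.frequencies, record.reactant.energy
)
ts = thermo_input_from_species(record.geom_ts, record.ts.frequencies, record.ts.energy)
print("reactant ZPE: %.2f kcal/mol (sum of hc*nu/2 over %d modes)"
      % (zpe(reactant.frequencies), len(reactant.frequencies)))

profile = delta_g_activation_profile(reactant, ts)
for T, dg in profile.items():
    g_r = gibbs(reactant, T)
    print(f"T = {T:6.0f} K: dG++ = {dg:7.2f} kcal/mol "
          f"(reactant S = {g_r.s_total:.1f} cal/mol/K)")
# dG++ drifts away from the 0 K barrier as -T * (S_TS - S_reactant); the
# entropic term is what makes high-temperature kinetics differ from barrier
# heights alone
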