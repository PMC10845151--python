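"""Standard cheminformatics descriptors in reaction-difference form.

Every registered 2D descriptor is evaluated on the reactant and the product
SMILES and reported as the signed difference (product minus reactant),
except for a declared list of reaction-invariant descriptors (molecular
weight and the like) which are reported as the raw reactant value.  The
registry is the library's full 2D descriptor list minus a few descriptors
that are undefined or overflow-prone on small radical species.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem import Descriptors
from rdkit import RDLogger

RDLogger.DisableLog("rdApp.*")


class SmilesError(ValueError):
    """Raised when an input SMILES string does not parse."""


# Descriptors reported as raw (reactant) values: invariant for the mass- and
# atom-conserving reactions the pipeline targets.
INVARIANT_DESCRIPTORS: tuple[str, ...] = (
    "MolWt",
    "ExactMolWt",
    "HeavyAtomMolWt",
    "HeavyAtomCount",
    "NumValenceElectrons",
)

# Excluded: partial-charge family fails (NaN) on some radicals, BCUT2D needs
# Gasteiger charges, Ipc overflows on dense graphs.
_EXCLUDED_PREFIXES = ("BCUT2D_",)
_EXCLUDED_NAMES = {
    "MaxPartialCharge",
    "MinPartialCharge",
    "MaxAbsPartialCharge",
    "MinAbsPartialCharge",
    "Ipc",
}


def descriptor_registry() -> list[tuple[str, callable]]:
    """Ordered (name, function) list defining the rdkit feature columns."""
    out = []
    for name, fn in Descriptors.descList:
        if name in _EXCLUDED_NAMES or name.startswith(_EXCLUDED_PREFIXES):
            continue
        out.append((name, fn))
    return out


@dataclass
class DeltaDescriptorSet:
    names: list[str]
    values: np.ndarray
    invariant_mask: np.ndarray

    def as_dict(self) -> dict[str, float]:
        return dict(zip(self.names, self.values.tolist()))


def _mol_from_smiles(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise SmilesError(f"could not parse SMILES {smiles!r}")
    return mol


def delta_descriptors(
    smiles_reactant: str,
    smiles_product: str,
    mode: str = "difference",
) -> DeltaDescriptorSet:
    """Product-minus-reactant descriptor differences (raw values where invariant).

    ``mode`` selects the combining rule for non-invariant descriptors:
    "difference" (default, X_P - X_R) or "average" ((X_P + X_R) / 2), kept
    switchable so the choice is auditable.  Multi-fragment species are
    written dot-separated and evaluated as the composite structure.
    """
    if mode not in ("difference", "average"):
        raise ValueError(f"unknown mode {mode!r}")
    mol_r = _mol_from_smiles(smiles_reactant)
    mol_p = _mol_from_smiles(smiles_product)
    registry = descriptor_registry()
    names: list[str] = []
    values = np.empty(len(registry))
    mask = np.zeros(len(registry), dtype=bool)
    for idx, (name, fn) in enumerate(registry):
        names.append(name)
        if name in INVARIANT_DESCRIPTORS:
            mask[idx] = True
            values[idx] = fn(mol_r)
        else:
            vr, vp = fn(mol_r), fn(mol_p)
            values[idx] = vp - vr if mode == "difference" else 0.5 * (vp + vr)
    return DeltaDescriptorSet(names=names, values=values, invariant_mask=mask)
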