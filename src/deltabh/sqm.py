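"""Semiempirical (PM7-style) stationary-point records and derived descriptors.

A :class:`ReactionRecord` bundles reactant, transition state and product at
the low level of theory together with the high-level reference barrier
height.  The regression target of the whole package is the correction

    delta = BH_DFT - BH_PM7

where each barrier height is (E_TS + ZPE_TS) - (E_R + ZPE_R).  The
``pm7`` descriptor family collects the barrier itself, a rate-constant
proxy exp(-BH), the imaginary TS frequency, ZPE differences, bond-order
matrix eigenvalues at the TS, Koopmans hardness/electronegativity, the
self-polarizability difference and the reaction energy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .geometry import Geometry


class RecordError(ValueError):
    """A reaction record violates a structural invariant."""


@dataclass
class SQMSpecies:
    """Low-level scalar results for a single stationary point.

    energy and zpe in kcal/mol; frequencies in cm^-1 with imaginary modes
    stored as negative numbers; homo/lumo in eV; bond_orders is the symmetric
    n x n bond-order matrix; self_polarizability is the atom-summed pi^s.
    """

    energy: float
    zpe: float
    frequencies: np.ndarray
    homo: float
    lumo: float
    bond_orders: np.ndarray = field(repr=False)
    self_polarizability: float

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.bond_orders = np.asarray(self.bond_orders, dtype=float)
        if self.zpe < 0:
            raise RecordError(f"negative ZPE: {self.zpe}")
        if self.bond_orders.size and not np.allclose(
            self.bond_orders, self.bond_orders.T
        ):
            raise RecordError("bond-order matrix must be symmetric")
        if self.lumo < self.homo:
            warnings.warn(
                f"LUMO ({self.lumo} eV) below HOMO ({self.homo} eV)", stacklevel=2
            )

    @property
    def n_imaginary(self) -> int:
        return int((self.frequencies < 0).sum())


@dataclass
class ReactionRecord:
    """One reaction: R/TS/P species and geometries plus the reference barrier."""

    reactant: SQMSpecies
    ts: SQMSpecies
    product: SQMSpecies
    geom_reactant: Geometry
    geom_ts: Geometry
    geom_product: Geometry
    smiles_reactant: str
    smiles_product: str
    bh_dft: float
    record_id: str = ""

    @property
    def bh_pm7(self) -> float:
        return barrier_height(self.reactant, self.ts)

    @property
    def target(self) -> float:
        """The regression target: high-level minus low-level barrier."""
        return self.bh_dft - self.bh_pm7


def barrier_height(reactant: SQMSpecies, ts: SQMSpecies) -> float:
    """ZPE-inclusive barrier: (E_TS + ZPE_TS) - (E_R + ZPE_R), kcal/mol."""
    bh = (ts.energy + ts.zpe) - (reactant.energy + reactant.zpe)
    if bh < 0:
        warnings.warn(f"negative barrier height ({bh:.3f} kcal/mol)", stacklevel=2)
    return bh


def rate_proxy(bh: float) -> float:
    """exp(-BH) on the raw kcal/mol value — a crude rate-constant proxy.

    The exponent carries units by construction; it is a monotone re-coding
    of the barrier, not a physical rate.  Clamped for bh < -50 to avoid
    overflow.
    """
    return float(np.exp(-max(bh, -50.0)))


def koopmans(homo: float, lumo: float) -> tuple[float, float]:
    """Koopmans-theorem hardness and Mulliken electronegativity (eV).

    eta = (e_LUMO - e_HOMO) / 2,  alpha = -(e_LUMO + e_HOMO) / 2.
    """
    eta = (lumo - homo) / 2.0
    alpha = -(lumo + homo) / 2.0
    return eta, alpha


def bond_order_eigenvalues(bond_orders: np.ndarray, k: int = 10) -> np.ndarray:
    """Descending eigenvalues of the bond-order matrix, padded/truncated to k.

    Zero-padding keeps the feature width constant across molecule sizes;
    absent atoms contribute zero bond order.
    """
    bo = np.asarray(bond_orders, dtype=float)
    if bo.size and not np.allclose(bo, bo.T):
        raise RecordError("bond-order matrix must be symmetric")
    eigs = np.sort(np.linalg.eigvalsh(bo))[::-1] if bo.size else np.empty(0)
    out = np.zeros(k)
    out[: min(k, eigs.size)] = eigs[:k]
    return out


# Column order of the pm7 descriptor family (bo_eig columns appended).
SQM_FEATURE_NAMES: tuple[str, ...] = (
    "bh_pm7",
    "rate_proxy",
    "nu1_ts",
    "dzpe_ts_r",
    "dzpe_p_r",
    "dzpe_ts_p",
    "eta_ts",
    "alpha_ts",
    "dpol",
    "de_r",
)


def sqm_features(record: ReactionRecord, n_bo_eigs: int = 10) -> dict[str, float]:
    """Assemble the pm7 descriptor family for one curated record."""
    if record.ts.n_imaginary != 1:
        raise RecordError(
            f"TS must carry exactly one imaginary frequency, found "
            f"{record.ts.n_imaginary} (record {record.record_id!r})"
        )
    bh = record.bh_pm7
    eta, alpha = koopmans(record.ts.homo, record.ts.lumo)
    nu1 = float(abs(record.ts.frequencies[record.ts.frequencies < 0][0]))
    feats: dict[str, float] = {
        "bh_pm7": bh,
        "rate_proxy": rate_proxy(bh),
        "nu1_ts": nu1,
        "dzpe_ts_r": record.ts.zpe - record.reactant.zpe,
        "dzpe_p_r": record.product.zpe - record.reactant.zpe,
        "dzpe_ts_p": record.ts.zpe - record.product.zpe,
        "eta_ts": eta,
        "alpha_ts": alpha,
        "dpol": record.reactant.self_polarizability
        - record.product.self_polarizability,
        "de_r": record.product.energy - record.reactant.energy,
    }
    for i, val in enumerate(bond_order_eigenvalues(record.ts.bond_orders, n_bo_eigs)):
        feats[f"bo_eig{i}"] = float(val)
    return feats


# ---------------------------------------------------------------------------
# JSON record schema
# ---------------------------------------------------------------------------

def _species_to_dict(sp: SQMSpecies) -> dict:
    return {
        "energy": sp.energy,
        "zpe": sp.zpe,
        "frequencies": sp.frequencies.tolist(),
        "homo": sp.homo,
        "lumo": sp.lumo,
        "bond_orders": sp.bond_orders.tolist(),
        "self_polarizability": sp.self_polarizability,
    }


def _species_from_dict(d: dict) -> SQMSpecies:
    return SQMSpecies(
        energy=d["energy"],
        zpe=d["zpe"],
        frequencies=np.array(d["frequencies"]),
        homo=d["homo"],
        lumo=d["lumo"],
        bond_orders=np.array(d["bond_orders"]),
        self_polarizability=d["self_polarizability"],
    )


def _geom_to_dict(g: Geometry) -> dict:
    return {"symbols": list(g.symbols), "coords": g.coords.tolist()}


def _geom_from_dict(d: dict) -> Geometry:
    return Geometry(tuple(d["symbols"]), np.array(d["coords"]))


def record_to_dict(r: ReactionRecord) -> dict:
    return {
        "record_id": r.record_id,
        "reactant": _species_to_dict(r.reactant),
        "ts": _species_to_dict(r.ts),
        "product": _species_to_dict(r.product),
        "geom_reactant": _geom_to_dict(r.geom_reactant),
        "geom_ts": _geom_to_dict(r.geom_ts),
        "geom_product": _geom_to_dict(r.geom_product),
        "smiles_reactant": r.smiles_reactant,
        "smiles_product": r.smiles_product,
        "bh_dft": r.bh_dft,
    }


def record_from_dict(d: dict) -> ReactionRecord:
    return ReactionRecord(
        reactant=_species_from_dict(d["reactant"]),
        ts=_species_from_dict(d["ts"]),
        product=_species_from_dict(d["product"]),
        geom_reactant=_geom_from_dict(d["geom_reactant"]),
        geom_ts=_geom_from_dict(d["geom_ts"]),
        geom_product=_geom_from_dict(d["geom_product"]),
        smiles_reactant=d["smiles_reactant"],
        smiles_product=d["smiles_product"],
        bh_dft=d["bh_dft"],
        record_id=d.get("record_id", ""),
    )


def save_records(path: str | Path, records: list[ReactionRecord]) -> None:
    Path(path).write_text(json.dumps([record_to_dict(r) for r in records]))


def load_records(path: str | Path) -> list[ReactionRecord]:
    return [record_from_dict(d) for d in json.loads(Path(path).read_text())]


# ---------------------------------------------------------------------------
# Optional thin reader for MOPAC-style summary output
# ---------------------------------------------------------------------------

def read_mopac_output(path: str | Path) -> dict:
    """Parse the scalar summary lines of a MOPAC-style output file.

    A best-effort convenience reader for the headline quantities (heat of
    formation, ZPE, HOMO/LUMO, vibrational frequencies); anything absent is
    simply missing from the returned dict.  It does not replace running the
    program or validate the calculation.
    """
    out: dict = {}
    freqs: list[float] = []
    in_freq_block = False
    for line in Path(path).read_text().splitlines():
        upper = line.upper()
        if "FINAL HEAT OF FORMATION" in upper and "KCAL" in upper:
            out["energy"] = float(line.split("=")[1].split()[0])
        elif "ZERO POINT ENERGY" in upper:
            out["zpe"] = float(line.split()[-2])
        elif "HOMO LUMO ENERGIES" in upper:
            parts = line.split("=")[-1].split()
            out["homo"], out["lumo"] = float(parts[0]), float(parts[1])
        elif upper.strip().startswith("FREQ."):
            freqs.extend(float(v) for v in line.split()[1:])
            in_freq_block = True
        elif in_freq_block and not line.strip():
            in_freq_block = False
    if freqs:
        out["frequencies"] = np.array(freqs)
    return out
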