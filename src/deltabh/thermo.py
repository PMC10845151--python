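"""Rigid-rotor/harmonic-oscillator ideal-gas thermochemistry.

Standard closed-form partition-function contributions (translation via
Sackur-Tetrode, rigid-rotor rotation with symmetry number, harmonic
vibrations, electronic spin degeneracy) give H and S corrections on top of
the electronic energy and the ZPE, and from those the Gibbs energy

    G(T) = E_elec + ZPE + H_corr(T) - T * S_total(T)

and the Gibbs energy of activation G(TS) - G(reactant).  Physical constants
are pinned literals so results are bit-reproducible.  No hindered-rotor or
quasi-RRHO damping, no tunneling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import (
    AMU_KG,
    ATM_PA,
    ATOMIC_MASSES,
    BOLTZMANN_K,
    CM1_TO_KCAL,
    PLANCK_H,
    R_CAL,
    R_KCAL,
    SPEED_OF_LIGHT,
)
from .geometry import Geometry

# moments of inertia below this (amu A^2) count as zero (linear/atomic cases)
_INERTIA_ZERO = 1e-6


@dataclass
class ThermoInput:
    """One species for RRHO evaluation; frequencies must all be positive."""

    geometry: Geometry
    frequencies: np.ndarray
    electronic_energy: float  # kcal/mol
    multiplicity: int = 1
    symmetry_number: int = 1

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        if np.any(self.frequencies <= 0):
            raise ValueError(
                "all frequencies must be positive; exclude the imaginary mode"
            )
        if self.multiplicity < 1 or self.symmetry_number < 1:
            raise ValueError("multiplicity and symmetry number must be >= 1")


@dataclass
class GibbsResult:
    T: float
    zpe: float            # kcal/mol
    h_corr: float         # thermal enthalpy correction beyond ZPE, kcal/mol
    s_total: float        # cal/(mol K)
    g: float              # kcal/mol
    components: dict = field(default_factory=dict)


def scale_frequencies(freqs: np.ndarray, factor: float) -> np.ndarray:
    """Multiply harmonic frequencies by an empirical scaling factor.

    Imaginary (negative) entries are scaled too; they never enter thermal
    sums because ThermoInput rejects them.
    """
    if not (0.8 < factor < 1.1):
        raise ValueError(f"scaling factor {factor} outside the sane range (0.8, 1.1)")
    return np.asarray(freqs, dtype=float) * factor


def zpe(freqs: np.ndarray) -> float:
    """Zero-point energy sum(h c nu / 2) in kcal/mol (pinned conversion)."""
    freqs = np.asarray(freqs, dtype=float)
    if freqs.size == 0:
        return 0.0
    if np.any(freqs < 0):
        raise ValueError("negative frequency passed to zpe; exclude imaginary modes")
    return float(0.5 * freqs.sum() * CM1_TO_KCAL)


def _mass_kg(geom: Geometry) -> float:
    return sum(ATOMIC_MASSES[s] for s in geom.symbols) * AMU_KG


def _principal_moments(geom: Geometry) -> np.ndarray:
    """Principal moments of inertia in kg m^2, ascending."""
    masses = np.array([ATOMIC_MASSES[s] for s in geom.symbols]) * AMU_KG
    coords = geom.coords * 1e-10  # Angstrom -> m
    com = (masses[:, None] * coords).sum(axis=0) / masses.sum()
    r = coords - com
    x, y, z = r[:, 0], r[:, 1], r[:, 2]
    ixx = (masses * (y**2 + z**2)).sum()
    iyy = (masses * (x**2 + z**2)).sum()
    izz = (masses * (x**2 + y**2)).sum()
    ixy = -(masses * x * y).sum()
    ixz = -(masses * x * z).sum()
    iyz = -(masses * y * z).sum()
    tensor = np.array([[ixx, ixy, ixz], [ixy, iyy, iyz], [ixz, iyz, izz]])
    return np.sort(np.linalg.eigvalsh(tensor))


def sackur_tetrode_entropy(mass_kg: float, T: float, P_atm: float = 1.0) -> float:
    """Ideal-gas translational entropy, cal/(mol K)."""
    lam = (2.0 * np.pi * mass_kg * BOLTZMANN_K * T / PLANCK_H**2) ** 1.5
    q = lam * BOLTZMANN_K * T / (P_atm * ATM_PA)
    return R_CAL * (np.log(q) + 2.5)


def _rotational(geom: Geometry, T: float, sigma: int) -> tuple[float, float]:
    """(S_rot cal/(mol K), U_rot kcal/mol) for atom/linear/nonlinear cases."""
    moments = _principal_moments(geom)
    zero_scale = _INERTIA_ZERO * AMU_KG * 1e-20
    nonzero = moments[moments > zero_scale]
    if nonzero.size == 0:  # single atom
        return 0.0, 0.0
    if nonzero.size < 3 or moments[0] <= zero_scale:  # linear
        inertia = nonzero[-1]
        q = 8.0 * np.pi**2 * inertia * BOLTZMANN_K * T / (sigma * PLANCK_H**2)
        return R_CAL * (np.log(q) + 1.0), R_KCAL * T
    q = (
        np.sqrt(np.pi)
        / sigma
        * (8.0 * np.pi**2 * BOLTZMANN_K * T / PLANCK_H**2) ** 1.5
        * np.sqrt(np.prod(nonzero))
    )
    return R_CAL * (np.log(q) + 1.5), 1.5 * R_KCAL * T


def _vibrational(freqs: np.ndarray, T: float) -> tuple[float, float]:
    """(S_vib cal/(mol K), thermal U_vib kcal/mol) for harmonic modes."""
    if freqs.size == 0:
        return 0.0, 0.0
    x = freqs * CM1_TO_KCAL / (R_KCAL * T)  # h c nu / k T
    with np.errstate(over="ignore"):  # x/expm1(x) -> 0 cleanly at low T
        expm = np.expm1(x)
        s = R_CAL * (x / expm - np.log1p(-np.exp(-x))).sum()
        u = R_KCAL * T * (x / expm).sum()
    return float(s), float(u)


def gibbs(inp: ThermoInput, T: float, P_atm: float = 1.0) -> GibbsResult:
    """RRHO Gibbs energy at temperature T (K) and pressure P (atm)."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    zpe_val = zpe(inp.frequencies)
    s_trans = sackur_tetrode_entropy(_mass_kg(inp.geometry), T, P_atm)
    s_rot, u_rot = _rotational(inp.geometry, T, inp.symmetry_number)
    s_vib, u_vib = _vibrational(inp.frequencies, T)
    s_el = R_CAL * np.log(inp.multiplicity)
    s_total = s_trans + s_rot + s_vib + s_el
    # H = U + pV = (3/2 RT trans + U_rot + U_vib) + RT
    h_corr = 1.5 * R_KCAL * T + u_rot + u_vib + R_KCAL * T
    g = inp.electronic_energy + zpe_val + h_corr - T * s_total / 1000.0
    return GibbsResult(
        T=T,
        zpe=zpe_val,
        h_corr=h_corr,
        s_total=s_total,
        g=g,
        components={
            "s_trans": s_trans,
            "s_rot": s_rot,
            "s_vib": s_vib,
            "s_el": s_el,
            "u_rot": u_rot,
            "u_vib": u_vib,
        },
    )


def delta_g_activation(reactant: ThermoInput, ts: ThermoInput, T: float) -> float:
    """Gibbs energy of activation G(TS) - G(reactant) at T, kcal/mol."""
    return gibbs(ts, T).g - gibbs(reactant, T).g


def delta_g_activation_profile(
    reactant: ThermoInput,
    ts: ThermoInput,
    temperatures: tuple[float, ...] = (300.0, 500.0, 1000.0),
) -> dict[float, float]:
    """Activation Gibbs energies at a batch of temperatures."""
    return {T: delta_g_activation(reactant, ts, T) for T in temperatures}


def thermo_input_from_species(
    geometry: Geometry,
    frequencies: np.ndarray,
    electronic_energy: float,
    scale_factor: float = 1.0,
    multiplicity: int = 1,
    symmetry_number: int = 1,
) -> ThermoInput:
    """Build a ThermoInput from raw species data, dropping imaginary modes."""
    freqs = scale_frequencies(np.asarray(frequencies, dtype=float), scale_factor)
    return ThermoInput(
        geometry=geometry,
        frequencies=freqs[freqs > 0],
        electronic_energy=electronic_energy,
        multiplicity=multiplicity,
        symmetry_number=symmetry_number,
    )
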