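"""RRHO thermochemistry against closed forms and an independent formulation."""

import numpy as np
import pytest

from deltabh.constants import (
    AMU_KG,
    ATM_PA,
    ATOMIC_MASSES,
    BOLTZMANN_K,
    CM1_TO_KCAL,
    PLANCK_H,
    R_CAL,
    R_KCAL,
)
from deltabh.geometry import Geometry
from deltabh.thermo import (
    GibbsResult,
    ThermoInput,
    delta_g_activation,
    delta_g_activation_profile,
    gibbs,
    sackur_tetrode_entropy,
    scale_frequencies,
    thermo_input_from_species,
    zpe,
)

N2 = ThermoInput(
    Geometry(("N", "N"), np.array([[0.0, 0, 0], [0, 0, 1.098]])),
    np.array([2358.0]),
    electronic_energy=10.0,
    symmetry_number=2,
)

H2CO = ThermoInput(
    Geometry(
        ("C", "O", "H", "H"),
        np.array([[0.0, 0, 0], [0, 0, 1.21], [0.94, 0, -0.54], [-0.94, 0, -0.54]]),
    ),
    np.array([1167.0, 1249.0, 1500.0, 1746.0, 2782.0, 2843.0]),
    electronic_energy=0.0,
    symmetry_number=2,
)


class TestScaling:
    def test_identity_factor(self):
        f = np.array([100.0, 2000.0])
        assert np.allclose(scale_frequencies(f, 1.0), f)

    def test_reference_scaling_factor(self):
        assert scale_frequencies(np.array([1000.0]), 0.9914)[0] == pytest.approx(991.4)

    @pytest.mark.parametrize("factor", [0.0, 0.5, 1.2])
    def test_out_of_range_rejected(self, factor):
        with pytest.raises(ValueError):
            scale_frequencies(np.array([1000.0]), factor)


class TestZPE:
    def test_empty(self):
        assert zpe(np.empty(0)) == 0.0

    def test_single_mode_pinned_constant(self):
        assert zpe(np.array([1000.0])) == pytest.approx(1.42957, abs=1e-5)

    def test_additivity(self):
        a = np.array([500.0, 900.0])
        b = np.array([1500.0, 3000.0])
        assert zpe(np.concatenate([a, b])) == pytest.approx(zpe(a) + zpe(b))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            zpe(np.array([-500.0]))


class TestGibbs:
    def test_monatomic_entropy_is_sackur_tetrode(self):
        atom = ThermoInput(Geometry(("O",), np.zeros((1, 3))), np.empty(0), 0.0)
        g = gibbs(atom, 298.15)
        # independent closed-form evaluation
        m = ATOMIC_MASSES["O"] * AMU_KG
        expected = R_CAL * (
            np.log(
                (2 * np.pi * m * BOLTZMANN_K * 298.15 / PLANCK_H**2) ** 1.5
                * BOLTZMANN_K
                * 298.15
                / ATM_PA
            )
            + 2.5
        )
        assert g.s_total == pytest.approx(expected, abs=1e-9)
        assert g.components["s_rot"] == 0.0 and g.components["s_vib"] == 0.0

    def test_single_oscillator_entropy_closed_form(self):
        g = gibbs(N2, 300.0)
        x = 2358.0 * CM1_TO_KCAL / (R_KCAL * 300.0)
        expected = R_CAL * (x / (np.exp(x) - 1) - np.log(1 - np.exp(-x)))
        assert g.components["s_vib"] == pytest.approx(expected, abs=1e-10)

    def test_low_temperature_limit(self):
        g = gibbs(N2, 1.0)
        assert abs(g.g - (N2.electronic_energy + g.zpe)) < 1e-3
        g001 = gibbs(N2, 0.01)
        assert abs(g001.g - (N2.electronic_energy + g001.zpe)) < 1e-3

    def test_matches_independent_free_energy_formulation(self):
        # oracle: G = E + ZPE - RT ln(q_trans q_rot q_vib q_el) built from
        # partition functions directly, not from H and S
        for inp, T in ((N2, 300.0), (H2CO, 500.0), (N2, 1000.0)):
            mass = sum(ATOMIC_MASSES[s] for s in inp.geometry.symbols) * AMU_KG
            q_trans = (
                (2 * np.pi * mass * BOLTZMANN_K * T / PLANCK_H**2) ** 1.5
                * BOLTZMANN_K * T / ATM_PA
            )
            masses = np.array([ATOMIC_MASSES[s] for s in inp.geometry.symbols]) * AMU_KG
            coords = inp.geometry.coords * 1e-10
            com = (masses[:, None] * coords).sum(0) / masses.sum()
            r = coords - com
            tensor = np.zeros((3, 3))
            for mi, ri in zip(masses, r):
                tensor += mi * (np.dot(ri, ri) * np.eye(3) - np.outer(ri, ri))
            moments = np.sort(np.linalg.eigvalsh(tensor))
            if moments[0] < 1e-50:  # linear
                q_rot = (
                    8 * np.pi**2 * moments[-1] * BOLTZMANN_K * T
                    / (inp.symmetry_number * PLANCK_H**2)
                )
            else:
                q_rot = (
                    np.sqrt(np.pi) / inp.symmetry_number
                    * (8 * np.pi**2 * BOLTZMANN_K * T / PLANCK_H**2) ** 1.5
                    * np.sqrt(np.prod(moments))
                )
            x = inp.frequencies * CM1_TO_KCAL / (R_KCAL * T)
            q_vib = np.prod(1.0 / (1.0 - np.exp(-x)))
            g_oracle = (
                inp.electronic_energy
                + zpe(inp.frequencies)
                - R_KCAL * T * np.log(q_trans * q_rot * q_vib * inp.multiplicity)
            )
            assert gibbs(inp, T).g == pytest.approx(g_oracle, abs=1e-6)

    def test_vibrational_entropy_vanishes_at_low_t(self):
        assert gibbs(H2CO, 5.0).components["s_vib"] < 1e-10

    def test_classical_limit_of_vibrational_energy(self):
        # a soft mode approaches kT of thermal energy at high temperature
        soft = ThermoInput(
            Geometry(("N", "N"), np.array([[0.0, 0, 0], [0, 0, 1.098]])),
            np.array([100.0]),
            0.0,
        )
        u_vib = gibbs(soft, 5000.0).components["u_vib"]
        assert abs(u_vib - R_KCAL * 5000.0) / (R_KCAL * 5000.0) < 0.02

    def test_g_decreasing_in_t(self):
        temps = [100.0, 300.0, 500.0, 1000.0, 2000.0]
        gs = [gibbs(H2CO, T).g for T in temps]
        assert all(a > b for a, b in zip(gs, gs[1:]))

    def test_invalid_temperature(self):
        with pytest.raises(ValueError):
            gibbs(N2, 0.0)


class TestActivation:
    def test_identical_inputs_zero_at_all_temperatures(self):
        prof = delta_g_activation_profile(H2CO, H2CO)
        assert set(prof) == {300.0, 500.0, 1000.0}
        assert all(v == 0.0 for v in prof.values())

    def test_pure_energy_shift(self):
        shifted = ThermoInput(
            H2CO.geometry, H2CO.frequencies, H2CO.electronic_energy + 10.0,
            symmetry_number=H2CO.symmetry_number,
        )
        for T in (300.0, 500.0, 1000.0):
            assert delta_g_activation(H2CO, shifted, T) == pytest.approx(10.0)

    def test_ts_input_drops_imaginary_mode(self):
        inp = thermo_input_from_species(
            H2CO.geometry,
            np.array([-900.0, 1167.0, 1249.0, 1500.0, 1746.0, 2782.0]),
            25.0,
        )
        assert (inp.frequencies > 0).all() and len(inp.frequencies) == 5

    def test_synthetic_pair_matches_scripted_oracle(self, small_dataset):
        records, _, _ = small_dataset
        rec = records[0]
        r = thermo_input_from_species(
            rec.geom_reactant, rec.reactant.frequencies, rec.reactant.energy
        )
        ts = thermo_input_from_species(rec.geom_ts, rec.ts.frequencies, rec.ts.energy)
        dg = delta_g_activation(r, ts, 300.0)
        gr, gt = gibbs(r, 300.0), gibbs(ts, 300.0)
        oracle = (
            (ts.electronic_energy + gt.zpe + gt.h_corr - 300.0 * gt.s_total / 1000.0)
            - (r.electronic_energy + gr.zpe + gr.h_corr - 300.0 * gr.s_total / 1000.0)
        )
        assert dg == pytest.approx(oracle, abs=1e-6)


def test_imaginary_frequency_rejected_by_thermo_input():
    with pytest.raises(ValueError):
        ThermoInput(N2.geometry, np.array([-100.0, 2358.0]), 0.0)
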