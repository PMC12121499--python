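"""Exciton Hamiltonian: couplings, diagonalization, oscillator strengths,
gap arithmetic — checked against closed forms and the published fixtures."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from chlorotune.constants import CM1_PER_EV, cm1_to_ev
from chlorotune.excitonics import (
    ExcitonSystem,
    build_system,
    diagonalize,
    oscillator_strengths,
    point_dipole_coupling,
    site_energy_gap,
)
from chlorotune.pigment_geometry import ChemType, Pigment, SiteLabel


def dipole_pigment(center, axis, pid="p", mu=4.0):
    axis = np.asarray(axis, float)
    return Pigment(
        pigment_id=pid,
        chem_type=ChemType.chl_a,
        site_label=SiteLabel.other,
        atom_names=["C1"],
        elements=["C"],
        coords=np.asarray([center], float),
        mg_position=np.asarray(center, float),
        qy_unit_vector=axis / np.linalg.norm(axis),
        dipole_magnitude=mu,
    )


def dimer(e1, e2, v_ev, ids=("a", "b")):
    return ExcitonSystem(
        pigment_ids=list(ids),
        site_energies=np.array([e1, e2]),
        couplings=np.array([[0.0, v_ev], [v_ev, 0.0]]),
    )


class TestPointDipoleCoupling:
    def test_parallel_perpendicular_closed_form(self):
        # kappa = 1: 5034.1 * 4 * 4 / 8^3 = 157.3 cm^-1
        p1 = dipole_pigment((0, 0, 0), (0, 0, 1))
        p2 = dipole_pigment((8, 0, 0), (0, 0, 1))
        assert point_dipole_coupling(p1, p2, screening_f=1.0) == pytest.approx(
            157.3, abs=0.05
        )

    def test_orthogonal_dipoles_give_zero(self):
        p1 = dipole_pigment((0, 0, 0), (0, 0, 1))
        p2 = dipole_pigment((8, 0, 0), (0, 1, 0))
        assert point_dipole_coupling(p1, p2, 1.0) == pytest.approx(0.0, abs=1e-10)

    def test_collinear_head_to_tail_is_minus_two_kappa(self):
        p1 = dipole_pigment((0, 0, 0), (0, 0, 1))
        p2 = dipole_pigment((8, 0, 0), (0, 0, 1))
        v1 = point_dipole_coupling(p1, p2, 1.0)
        q1 = dipole_pigment((0, 0, 0), (1, 0, 0))
        q2 = dipole_pigment((8, 0, 0), (1, 0, 0))
        assert point_dipole_coupling(q1, q2, 1.0) == pytest.approx(-2 * v1)

    def test_too_close_rejected(self):
        p1 = dipole_pigment((0, 0, 0), (0, 0, 1))
        p2 = dipole_pigment((1.5, 0, 0), (0, 0, 1))
        with pytest.raises(ValueError, match="point-dipole"):
            point_dipole_coupling(p1, p2)

    @given(
        r=st.floats(4.0, 30.0),
        scale=st.floats(1.1, 3.0),
        theta=st.floats(0, np.pi),
    )
    def test_symmetry_kappa_bound_and_r_cubed_scaling(self, r, scale, theta):
        axis = (np.sin(theta), 0, np.cos(theta))
        p1 = dipole_pigment((0, 0, 0), (0, 0, 1))
        p2 = dipole_pigment((r, 0, 0), axis)
        v = point_dipole_coupling(p1, p2, 1.0)
        assert point_dipole_coupling(p2, p1, 1.0) == pytest.approx(v, rel=1e-12)
        kappa = v * r**3 / (5034.1 * 16.0)
        assert abs(kappa) <= 2.0 + 1e-12
        p2_far = dipole_pigment((r * scale, 0, 0), axis)
        v_far = point_dipole_coupling(p1, p2_far, 1.0)
        assert v_far == pytest.approx(v / scale**3, rel=1e-9)


class TestBuildSystem:
    def test_table_one_wl_fixture_converts_coupling(self, tmp_path):
        e = tmp_path / "e.csv"
        c = tmp_path / "c.csv"
        pd.DataFrame(
            {"pigment_id": ["P_D1", "P_D2", "Chl_D1"],
             "value": [1.946, 1.946, 1.993], "unit": "eV"}
        ).to_csv(e, index=False)
        pd.DataFrame(
            {"pigment_i": ["P_D1"], "pigment_j": ["P_D2"],
             "value": [77.0], "unit": ["cm-1"]}
        ).to_csv(c, index=False)
        sys_ = build_system(e, c, model_label="WL")
        assert sys_.couplings[0, 1] == pytest.approx(77.0 / CM1_PER_EV, abs=1e-9)
        assert sys_.couplings[0, 1] == pytest.approx(0.009547, abs=1e-6)

    def test_ev_couplings_pass_through(self):
        e = pd.DataFrame(
            {"pigment_id": ["a", "b"], "value": [1.9, 1.9], "unit": "eV"}
        )
        c = pd.DataFrame(
            {"pigment_i": ["a"], "pigment_j": ["b"], "value": [0.01],
             "unit": ["eV"]}
        )
        assert build_system(e, c).couplings[0, 1] == 0.01

    def test_asymmetric_coupling_rejected(self):
        e = pd.DataFrame(
            {"pigment_id": ["a", "b"], "value": [1.9, 1.9], "unit": "eV"}
        )
        c = pd.DataFrame(
            {"pigment_i": ["a", "b"], "pigment_j": ["b", "a"],
             "value": [0.01, 0.02], "unit": ["eV", "eV"]}
        )
        with pytest.raises(ValueError, match="asymmetric"):
            build_system(e, c)

    def test_missing_unit_and_unknown_id_rejected(self):
        e = pd.DataFrame({"pigment_id": ["a"], "value": [1.9]})
        with pytest.raises(ValueError, match="unit"):
            build_system(e)
        e2 = pd.DataFrame(
            {"pigment_id": ["a", "b"], "value": [1.9, 1.9], "unit": "eV"}
        )
        c = pd.DataFrame(
            {"pigment_i": ["a"], "pigment_j": ["zz"], "value": [1.0],
             "unit": ["cm-1"]}
        )
        with pytest.raises(ValueError, match="zz"):
            build_system(e2, c)


class TestDiagonalize:
    def test_published_chl_d_dimer_eigenvalues(self):
        # 2-site closed form: mean +/- sqrt(delta^2/4 + V^2)
        sys_ = dimer(1.936, 1.904, cm1_to_ev(97.0))
        states = diagonalize(sys_)
        assert states.energies == pytest.approx([1.9000, 1.9400], abs=1e-4)

    def test_zero_coupling_reduces_to_site_energies(self, fixtures):
        sys_ = ExcitonSystem(
            ["a", "b", "c"], np.array([1.9, 1.8, 2.0]), np.zeros((3, 3))
        )
        states = diagonalize(sys_)
        assert states.energies == pytest.approx([1.8, 1.9, 2.0])
        assert states.participation_ratios == pytest.approx([1, 1, 1])

    def test_degenerate_dimer_splits_by_2v_and_delocalizes(self):
        v = 0.01
        states = diagonalize(dimer(1.9, 1.9, v))
        assert states.energies[1] - states.energies[0] == pytest.approx(2 * v)
        assert states.participation_ratios == pytest.approx([2.0, 2.0])

    @given(
        e1=st.floats(1.5, 2.5),
        delta=st.floats(-0.3, 0.3),
        v=st.floats(-0.05, 0.05),
    )
    def test_two_site_analytic_oracle(self, e1, delta, v):
        e2 = e1 + delta
        states = diagonalize(dimer(e1, e2, v))
        mean, half = (e1 + e2) / 2, np.sqrt(delta**2 / 4 + v**2)
        assert states.energies == pytest.approx(
            [mean - half, mean + half], abs=1e-10
        )
        # trace conservation and orthonormality
        assert states.energies.sum() == pytest.approx(e1 + e2, abs=1e-10)
        gram = states.coefficients @ states.coefficients.T
        assert np.abs(gram - np.eye(2)).max() < 1e-8

    def test_spread_monotone_in_coupling(self):
        spreads = [
            np.ptp(diagonalize(dimer(1.9, 1.95, v)).energies)
            for v in (0.0, 0.005, 0.01, 0.02)
        ]
        assert np.all(np.diff(spreads) >= 0)

    def test_sign_convention_largest_component_positive(self):
        states = diagonalize(dimer(1.9, 1.95, -0.01))
        for row in states.coefficients:
            assert row[np.argmax(np.abs(row))] > 0


class TestOscillatorStrengths:
    def test_monomer_closed_form(self):
        p = dipole_pigment((0, 0, 0), (1, 0, 0))
        sys_ = ExcitonSystem(["p"], np.array([1.840]), np.zeros((1, 1)))
        states = diagonalize(sys_, pigments=[p])
        assert states.oscillator_strengths[0] == pytest.approx(0.1117, abs=0.001)

    def test_antiparallel_dimer_has_dark_state(self):
        p1 = dipole_pigment((0, 0, 0), (0, 0, 1), "a")
        p2 = dipole_pigment((10, 0, 0), (0, 0, -1), "b")
        sys_ = dimer(1.9, 1.9, 0.01)
        states = diagonalize(sys_, pigments=[p1, p2])
        assert states.oscillator_strengths.min() == pytest.approx(0.0, abs=1e-12)
        assert states.is_dark().any()

    @given(
        e=st.lists(st.floats(1.6, 2.2), min_size=2, max_size=5),
        seed=st.integers(0, 1000),
    )
    def test_dipole_strength_sum_rule(self, e, seed):
        rng = np.random.default_rng(seed)
        n = len(e)
        pigments = [
            dipole_pigment(
                (10 * i, 0, 0), rng.normal(size=3) + 1e-3, f"p{i}",
                mu=rng.uniform(2, 6),
            )
            for i in range(n)
        ]
        v = rng.normal(0, 0.01, (n, n))
        v = (v + v.T) / 2
        np.fill_diagonal(v, 0.0)
        sys_ = ExcitonSystem([p.pigment_id for p in pigments], np.array(e), v)
        states = diagonalize(sys_)
        f = oscillator_strengths(states, pigments)
        mu2_exciton = np.sum(
            (states.coefficients
             @ np.array([p.dipole_magnitude * p.qy_unit_vector
                         for p in pigments])) ** 2
        )
        mu2_site = sum(p.dipole_magnitude**2 for p in pigments)
        assert mu2_exciton == pytest.approx(mu2_site, rel=1e-9)
        assert (f >= 0).all()


class TestSiteEnergyGap:
    @pytest.mark.parametrize(
        "name, expected",
        [("chl_d_at_chl_d1", 0.032), ("chl_f_at_chl_d1", 0.046)],
    )
    def test_published_gaps(self, fixtures, name, expected):
        sys_ = fixtures["exciton_systems"][name]
        assert site_energy_gap(sys_, "P_D1", "Chl_D1") == pytest.approx(
            expected, abs=1e-12
        )

    def test_gap_is_signed_and_zero_on_identity(self, fixtures):
        sys_ = fixtures["exciton_systems"]["wl"]
        assert site_energy_gap(sys_, "Chl_D1", "P_D1") == pytest.approx(
            -site_energy_gap(sys_, "P_D1", "Chl_D1")
        )
        assert site_energy_gap(sys_, "Chl_D1", "Chl_D1") == 0.0

    def test_unknown_site_rejected(self, fixtures):
        with pytest.raises(KeyError):
            site_energy_gap(fixtures["exciton_systems"]["wl"], "P_D1", "nope")
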