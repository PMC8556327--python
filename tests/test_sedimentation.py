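"""Hydrodynamics: s20w, Svedberg masses, Lamm solver, c(s) inversion."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phycoring.sedimentation import (DEFAULT_BUFFER, WATER_20C, HydroParams,
                                     SedimentationDataset, assign_oligomer,
                                     cell_mass, cpc_concentration,
                                     diffusion_from_s, fit_cs, lamm_simulate,
                                     peaks_to_species, read_scan_csv,
                                     s20w_correction, sphere_s_from_mass,
                                     svedberg_mass, write_scan_csv)
from phycoring.synthetic import AUCSpec, simulate_auc


class TestS20wCorrection:
    def test_identity_for_standard_water(self):
        assert s20w_correction(5.0, WATER_20C) == pytest.approx(5.0, abs=1e-12)

    @pytest.mark.parametrize("s_obs,expected", [(3.15, 3.33), (5.24, 5.56),
                                                (7.97, 8.45), (11.32, 12.00)])
    def test_reproduces_published_standardization(self, s_obs, expected):
        assert s20w_correction(s_obs, DEFAULT_BUFFER) == \
            pytest.approx(expected, abs=0.01)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(s=st.floats(0.1, 50.0), scale=st.floats(0.1, 10.0))
    def test_linearity(self, s, scale):
        one = s20w_correction(s, DEFAULT_BUFFER)
        scaled = s20w_correction(scale * s, DEFAULT_BUFFER)
        assert scaled == pytest.approx(scale * one, rel=1e-12)

    def test_dense_solvent_rejected(self):
        heavy = HydroParams(rho=1.5, eta=0.0103, vbar=0.73)
        with pytest.raises(ValueError, match="buoyancy"):
            s20w_correction(5.0, heavy)


class TestSvedbergMass:
    @pytest.mark.parametrize("s_obs,m_kda", [(3.15, 37.1), (5.24, 79.8),
                                             (7.97, 149.5), (11.32, 253.1)])
    def test_reproduces_published_masses(self, s_obs, m_kda):
        est = svedberg_mass(s_obs, 1.195, DEFAULT_BUFFER)
        assert est.M / 1000.0 == pytest.approx(m_kda, rel=0.01)

    def test_svedberg_relation_internally_consistent(self):
        est = svedberg_mass(5.24, 1.195, DEFAULT_BUFFER)
        # s/D == M (1 - vbar rho) / RT
        lhs = 5.24e-13 / est.D
        rhs = est.M * DEFAULT_BUFFER.buoyancy / (8.314462618e7 * 293.15)
        assert lhs == pytest.approx(rhs, rel=1e-12)

    def test_mass_scales_as_s_to_three_halves(self):
        m1 = svedberg_mass(4.0, 1.2, DEFAULT_BUFFER).M
        m2 = svedberg_mass(8.0, 1.2, DEFAULT_BUFFER).M
        assert m2 / m1 == pytest.approx(2.0 ** 1.5, rel=1e-9)

    def test_sphere_round_trip(self):
        M0 = 150_000.0
        s = sphere_s_from_mass(M0, DEFAULT_BUFFER, f_ratio=1.0)
        back = svedberg_mass(s, 1.0, DEFAULT_BUFFER)
        assert back.M == pytest.approx(M0, rel=1e-6)

    def test_unphysical_f_ratio_rejected(self):
        with pytest.raises(ValueError, match="unphysical"):
            svedberg_mass(5.0, 0.9, DEFAULT_BUFFER)
        with pytest.raises(ValueError, match="unphysical"):
            diffusion_from_s(5.0, 0.5, DEFAULT_BUFFER)


class TestLammSolver:
    def test_mass_conserved_in_closed_cell(self):
        times = np.arange(400.0, 4400.0, 400.0)
        data = lamm_simulate([(5.24, 6.13e-7, 0.5)], DEFAULT_BUFFER,
                             (6.0, 7.2), times, n_cells=400)
        masses = [cell_mass(data, k) for k in range(times.size)]
        assert (max(masses) - min(masses)) / masses[0] < 1e-3

    def test_faxen_boundary_law(self):
        """Boundary midpoint tracks r_m exp(s w^2 t) within 1%."""
        s, D = 5.24, 6.13e-7
        times = np.arange(400.0, 4400.0, 400.0)
        data = lamm_simulate([(s, D, 0.5)], DEFAULT_BUFFER, (6.0, 7.2),
                             times, n_cells=400)
        w2 = DEFAULT_BUFFER.omega ** 2
        for k in (2, 5, 8):
            t = times[k]
            plateau = 0.5 * math.exp(-2.0 * s * 1e-13 * w2 * t)
            pred = 6.0 * math.exp(s * 1e-13 * w2 * t)
            prof = data.scans[k]
            idx = int(np.argmin(np.abs(prof - plateau / 2.0)))
            sl = slice(max(0, idx - 6), idx + 6)
            r_mid = float(np.interp(plateau / 2.0, prof[sl], data.radii[sl]))
            assert r_mid == pytest.approx(pred, rel=0.01)

    def test_zero_rotor_speed_relaxes_to_uniform(self):
        still = HydroParams(rho=1.0098, eta=0.01029, vbar=0.73149,
                            rotor_speed=0.0)
        data = lamm_simulate([(5.0, 5e-6, 0.4)], still, (6.0, 7.2),
                             [50_000.0], n_cells=200)
        assert data.scans[0].std() < 1e-9
        assert data.scans[0].mean() == pytest.approx(0.4, rel=1e-6)

    def test_zero_loading_gives_zero_scans(self):
        data = lamm_simulate([(5.0, 5e-7, 0.0)], DEFAULT_BUFFER, (6.0, 7.2),
                             [600.0, 1200.0], n_cells=400)
        assert np.all(data.scans == 0.0)

    def test_coarse_grid_rejected_with_advice(self):
        with pytest.raises(ValueError, match="finer radial grid"):
            lamm_simulate([(11.32, 4.17e-7, 0.5)], DEFAULT_BUFFER,
                          (6.0, 7.2), [1000.0], n_cells=200)

    def test_bad_geometry_and_species(self):
        with pytest.raises(ValueError):
            lamm_simulate([(5.0, 5e-7, 0.5)], DEFAULT_BUFFER, (7.2, 6.0),
                          [100.0])
        with pytest.raises(ValueError):
            lamm_simulate([(-1.0, 5e-7, 0.5)], DEFAULT_BUFFER, (6.0, 7.2),
                          [100.0])


class TestCsInversion:
    def test_noise_free_single_species_peak_on_grid(self):
        data, _ = simulate_auc(AUCSpec(species=((5.0, 1.2, 0.5),),
                                       noise_sigma=0.0), DEFAULT_BUFFER)
        dist = fit_cs(data, f_ratio=1.2)
        species = peaks_to_species(dist, DEFAULT_BUFFER)
        assert len(species) == 1
        step = float(np.mean(np.diff(dist.s_grid)))
        assert species[0].s_obs == pytest.approx(5.0, abs=step)

    def test_all_zero_scans_rejected(self):
        data = SedimentationDataset(radii=np.linspace(6.0, 7.2, 50),
                                    times=np.array([600.0, 1200.0]),
                                    scans=np.zeros((2, 50)))
        with pytest.raises(ValueError, match="all-zero"):
            fit_cs(data)

    def test_single_scan_rejected(self):
        data = SedimentationDataset(radii=np.linspace(6.0, 7.2, 50),
                                    times=np.array([600.0]),
                                    scans=np.ones((1, 50)))
        with pytest.raises(ValueError, match="two scan times"):
            fit_cs(data)


class TestPeaksToSpecies:
    def test_flat_distribution_warns_empty(self):
        from phycoring.sedimentation import CSDistribution
        dist = CSDistribution(s_grid=np.linspace(1, 15, 50),
                              c=np.zeros(50), f_ratio=1.2,
                              lambda_reg=0.0, fit_rmsd=0.0)
        with pytest.warns(UserWarning):
            assert peaks_to_species(dist) == []

    def test_oligomer_assignment(self):
        est = svedberg_mass(7.97, 1.195, DEFAULT_BUFFER)
        est.loading = 1.0
        label = assign_oligomer(est, monomer_mass=37_300.0)
        assert label == "(ab)_4"
        small = svedberg_mass(3.15, 1.195, DEFAULT_BUFFER)
        assert assign_oligomer(small, monomer_mass=37_300.0) == "(ab)_1"


class TestConcentrationAssay:
    @pytest.mark.parametrize("a615,a652,expected",
                             [(0.0, 0.0, 0.0),
                              (5.34, 0.0, 1.0),
                              (1.0, 0.5, (1.0 - 0.474 * 0.5) / 5.34)])
    def test_values(self, a615, a652, expected):
        assert cpc_concentration(a615, a652) == pytest.approx(expected,
                                                              abs=1e-12)

    def test_negative_result_warns(self):
        with pytest.warns(UserWarning, match="negative"):
            assert cpc_concentration(0.0, 1.0) < 0

    def test_negative_input_rejected(self):
        with pytest.raises(ValueError):
            cpc_concentration(-0.1, 0.0)


class TestScanCsv:
    def test_round_trip(self, tmp_path):
        data, _ = simulate_auc(AUCSpec(seed=3), DEFAULT_BUFFER)
        path = tmp_path / "scans.csv"
        write_scan_csv(data, path)
        back = read_scan_csv(path)
        assert np.allclose(back.radii, data.radii)
        assert np.allclose(back.times, data.times)
        assert np.allclose(back.scans, data.scans, atol=1e-10)
        # cell-centre convention reconstructs the simulated cell geometry
        assert back.meniscus == pytest.approx(6.0, abs=1e-9)
        assert back.bottom == pytest.approx(7.2, abs=1e-6)

    def test_header_only_rejected(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("radius_cm\n6.0\n")
        with pytest.raises(ValueError, match="at least one scan"):
            read_scan_csv(p)
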