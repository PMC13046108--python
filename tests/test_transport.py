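"""Monte Carlo engine: sampling oracles, conservation, determinism."""

import numpy as np
import pytest
from scipy import integrate

from inkdose import BeamSpec, build_phantom, run_simulation
from inkdose import physics as P
from inkdose import transport as T
from inkdose._kernel import sample_compton_batch
from inkdose.errors import ConfigurationError


def kn_mean_scattered_fraction(energy):
    """Quadrature oracle: <eps> under the Klein-Nishina differential."""
    k = energy / P.MEC2

    def dsigma(eps):
        t = (1 - eps) / (k * eps)
        sin2 = t * (2 - t)
        return (1 / eps + eps) * (1 - eps * sin2 / (1 + eps**2))

    lo = 1 / (1 + 2 * k)
    norm, _ = integrate.quad(dsigma, lo, 1, limit=200)
    mom, _ = integrate.quad(lambda e: e * dsigma(e), lo, 1, limit=200)
    return mom / norm


class TestBeamSpec:
    def test_default_sigma_is_two_percent(self):
        assert BeamSpec("photon", 6.0).sigma == pytest.approx(0.12)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"particle": "proton", "nominal_energy": 6.0},
            {"particle": "photon", "nominal_energy": -1.0},
            {"particle": "photon", "nominal_energy": 6.0, "field_size": 0},
            {"particle": "photon", "nominal_energy": 6.0, "source_model": "fan"},
        ],
    )
    def test_invalid_beams_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            BeamSpec(**kwargs)


class TestComptonSampling:
    @pytest.mark.parametrize("energy", [1.0, 6.0])
    def test_kernel_mean_matches_quadrature_within_3_sigma(self, energy):
        n = 100_000
        eps, ct = sample_compton_batch(energy, n, 123)
        expected = kn_mean_scattered_fraction(energy)
        se = eps.std(ddof=1) / np.sqrt(n)
        assert abs(eps.mean() - expected) < 3 * se

    def test_python_api_conserves_energy_exactly(self, water_mat):
        rng = np.random.default_rng(7)
        for energy in (0.5, 6.0, 18.0):
            for _ in range(200):
                out = T.sample_photon_interaction(energy, water_mat, rng)
                if out.kind == "compton":
                    total = out.scattered_photon_energy + out.secondaries[0].energy
                    assert total == pytest.approx(energy, rel=1e-12)
                elif out.kind == "pair":
                    total = sum(s.energy for s in out.secondaries) + 2 * P.MEC2
                    assert total == pytest.approx(energy, rel=1e-12)

    def test_compton_edge_respected(self):
        # max electron energy 2E^2/(mc^2 + 2E) at 6 MeV
        eps, _ = sample_compton_batch(6.0, 50_000, 5)
        t_e = 6.0 * (1 - eps)
        edge = 2 * 6.0**2 / (P.MEC2 + 2 * 6.0)
        assert t_e.max() <= edge + 1e-9
        assert t_e.max() > 0.98 * edge


class TestElectronStepping:
    def test_zero_length_step_is_identity(self, water_mat):
        rng = np.random.default_rng(0)
        s = T.ElectronState(np.zeros(3), np.array([0, 0, 1.0]), 6.0)
        out, dep = T.step_electron(s, water_mat, 0.0, rng)
        assert dep == 0.0
        assert out.energy == 6.0

    def test_full_slowdown_path_matches_csda_reference(self, water_mat):
        ref = P.water_reference()["csda"]
        expected_cm = float(
            ref.loc[np.isclose(ref["energy_mev"], 6.0), "csda_range_g_cm2"].iloc[0]
        )  # water density 1 -> cm
        rng = np.random.default_rng(11)
        paths = []
        for _ in range(30):
            s = T.ElectronState(np.zeros(3), np.array([0, 0, 1.0]), 6.0)
            path = 0.0
            while s.energy > 0.05:
                prev = s.position.copy()
                s, _ = T.step_electron(s, water_mat, 0.5, rng)
                path += np.linalg.norm(s.position - prev)
            paths.append(path / 10.0)  # mm -> cm
        assert np.mean(paths) == pytest.approx(expected_cm, rel=0.10)

    def test_denser_high_z_medium_deflects_more(self, brown100, dermis):
        rms = {}
        for mat in (brown100, dermis):
            rng = np.random.default_rng(3)
            angles = []
            for _ in range(400):
                s = T.ElectronState(np.zeros(3), np.array([0, 0, 1.0]), 2.0)
                out, _ = T.step_electron(s, mat, 0.1, rng)
                angles.append(np.arccos(np.clip(out.direction[2], -1, 1)))
            rms[mat.name] = np.sqrt(np.mean(np.square(angles)))
        assert rms[brown100.name] > rms[dermis.name]

    def test_energy_strictly_decreases(self, water_mat):
        rng = np.random.default_rng(4)
        s = T.ElectronState(np.zeros(3), np.array([0, 0, 1.0]), 6.0)
        for _ in range(50):
            out, dep = T.step_electron(s, water_mat, 0.2, rng)
            assert out.energy < s.energy
            assert dep > 0
            s = out


class TestAttenuationSampling:
    def test_first_interaction_depths_follow_beer_lambert(self, water_mat):
        energy, n = 6.0, 40_000
        depths = T.first_interaction_depths(water_mat, energy, n, seed=2)
        mu = float(P.mass_attenuation(water_mat, energy))  # density 1
        se = depths.std(ddof=1) / np.sqrt(n)
        assert abs(depths.mean() - 1 / mu) < 3 * se


class TestRunSimulation:
    def test_bit_identical_for_same_seed(self, control_phantom):
        beam = BeamSpec("electron", 6.0)
        a = run_simulation(control_phantom, beam, 3000, seed=9)
        b = run_simulation(control_phantom, beam, 3000, seed=9)
        assert np.array_equal(a.dose, b.dose)
        assert np.array_equal(a.rel_uncertainty, b.rel_uncertainty)
        c = run_simulation(control_phantom, beam, 3000, seed=10)
        assert not np.array_equal(a.dose, c.dose)

    @pytest.mark.parametrize("particle,energy", [("photon", 6.0), ("electron", 6.0)])
    def test_energy_deposited_bounded_by_emitted(
        self, control_phantom, particle, energy
    ):
        g = run_simulation(
            control_phantom, BeamSpec(particle, energy), 20_000, seed=3
        )
        assert 0 < g.deposited_energy_mev <= g.emitted_energy_mev

    def test_invalid_configuration_rejected_before_sampling(
        self, control_phantom
    ):
        with pytest.raises(ConfigurationError):
            run_simulation(control_phantom, BeamSpec("photon", 6.0), 0, seed=1)
        with pytest.raises(ConfigurationError):
            run_simulation(control_phantom, BeamSpec("photon", 30.0), 10, seed=1)

    def test_dose_csv_round_trip(self, control_phantom, tmp_path):
        g = run_simulation(control_phantom, BeamSpec("electron", 6.0), 2000, seed=5)
        path = tmp_path / "dose.csv"
        g.to_csv(path, extended=True)
        back = T.DoseGrid.from_csv(path)
        assert np.allclose(back.dose, g.dose)
        assert np.allclose(back.rel_uncertainty, g.rel_uncertainty)
        assert np.allclose(back.z_edges, g.z_edges)
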