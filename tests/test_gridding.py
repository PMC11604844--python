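"""Kaiser-Bessel kernel, density compensation and gridding reconstruction."""

import time

import numpy as np
import pytest

from xerecon.gridding import (
    GriddingConfig,
    NufftOperator,
    density_compensation,
    grid_reconstruct,
    kaiser_bessel,
    kb_beta_beatty,
)
from xerecon.trajectory import generate_spoke_directions, sample_positions


def i0_series(x, terms=60):
    """Independent modified-Bessel-I0 oracle via its power series."""
    total, term = 1.0, 1.0
    for k in range(1, terms):
        term *= (x / 2.0) ** 2 / k**2
        total += term
    return total


class TestKernel:
    def test_peak_at_center(self):
        beta = kb_beta_beatty(8, 1.25)
        u = np.linspace(-4, 4, 401)
        w = kaiser_bessel(u, 8, beta)
        assert w.max() == w[200]
        assert w[200] == kaiser_bessel(0.0, 8, beta)

    @pytest.mark.parametrize("u", [0.5, 1.0, 3.0])
    def test_even_symmetry(self, u):
        beta = kb_beta_beatty(8, 1.25)
        assert kaiser_bessel(u, 8, beta) == kaiser_bessel(-u, 8, beta)

    def test_compact_support(self):
        beta = kb_beta_beatty(8, 1.25)
        assert kaiser_bessel(4.0, 8, beta) == 0.0
        assert kaiser_bessel(5.0, 8, beta) == 0.0

    @pytest.mark.parametrize("u", [0.0, 1.0, 2.0])
    def test_values_match_bessel_series_oracle(self, u):
        w, beta = 8, kb_beta_beatty(8, 1.25)
        expected = i0_series(beta * np.sqrt(1 - (2 * u / w) ** 2)) / i0_series(beta)
        assert abs(kaiser_bessel(u, w, beta) - expected) < 1e-12

    def test_invalid_beta_rejected(self):
        with pytest.raises(ValueError):
            kaiser_bessel(0.0, 8, -1.0)


class TestDensityCompensation:
    def test_radial_weights_increase_outward(self):
        traj = sample_positions(np.array([[0.0, 0.0, 1.0]]), 2)
        w = density_compensation(traj)
        assert w[1] > w[0] > 0
        np.testing.assert_allclose(w.sum(), 1.0)

    def test_voronoi_uniform_lattice_equal_weights(self):
        """A uniform Cartesian lattice has identical Voronoi cell volumes."""
        g = np.linspace(-0.4, 0.4, 5)
        pts = np.stack(np.meshgrid(g, g, g, indexing="ij"), axis=-1).reshape(-1, 3)

        class FakeTraj:
            def flat_coords(self):
                return pts

        w = density_compensation(FakeTraj(), mode="voronoi")
        np.testing.assert_allclose(w, 1.0 / len(pts), rtol=1e-9)

    def test_dcf_suppresses_psf_sidelobes(self):
        """Density compensation lowers off-center PSF energy for radial data."""
        traj = sample_positions(generate_spoke_directions(200), 16)
        cfg = GriddingConfig(matrix=16)
        ones = np.ones(traj.n_samples, dtype=complex)  # delta object's data
        with_dcf = np.abs(grid_reconstruct(ones, traj, cfg))
        flat = np.full(traj.n_samples, 1.0 / traj.n_samples)
        without = np.abs(grid_reconstruct(ones, traj, cfg, dcf=flat))
        center = (8, 8, 8)

        def sidelobe_fraction(psf):
            main = np.zeros_like(psf, dtype=bool)
            main[center[0] - 1 : center[0] + 2,
                 center[1] - 1 : center[1] + 2,
                 center[2] - 1 : center[2] + 2] = True
            return psf[~main].sum() / psf.sum()

        assert sidelobe_fraction(with_dcf) < sidelobe_fraction(without)


class TestNufftOperator:
    def test_adjointness_dot_product(self):
        rng = np.random.default_rng(3)
        traj = sample_positions(generate_spoke_directions(50), 8)
        op = NufftOperator(traj.flat_coords(), 8)
        assert op.dot_test(seed=1) <= 1e-8

    def test_forward_zero_image(self):
        op = NufftOperator(np.zeros((5, 3)), 8)
        assert np.all(op.forward(np.zeros((8, 8, 8), complex)) == 0)

    def test_forward_matches_brute_force_dft(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal((8,) * 3) + 1j * rng.standard_normal((8,) * 3)
        k = rng.uniform(-0.5, 0.5, size=(20, 3))
        op = NufftOperator(k, 8)
        grid = np.stack(
            np.meshgrid(*(np.arange(8) - 4,) * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        ref = np.exp(-2j * np.pi * (k @ grid.T)) @ x.ravel()
        got = op.forward(x)
        assert np.linalg.norm(got - ref) < 1e-3 * np.linalg.norm(ref)

    def test_out_of_range_coordinates_rejected(self):
        with pytest.raises(ValueError):
            NufftOperator(np.array([[0.6, 0.0, 0.0]]), 8)


class TestGridReconstruct:
    def test_dc_only_data_gives_flat_image(self):
        """A single DC sample reconstructs to a near-constant volume."""
        op = NufftOperator(np.zeros((1, 3)), 16)
        img = np.abs(op.adjoint(np.array([1.0 + 0j])))
        sub = img[4:12, 4:12, 4:12]  # central half-FOV
        assert sub.std() / sub.mean() < 0.01

    def test_zero_data_zero_image(self):
        traj = sample_positions(generate_spoke_directions(20), 8)
        img = grid_reconstruct(
            np.zeros(traj.n_samples), traj, GriddingConfig(matrix=8)
        )
        assert np.all(img == 0)

    def test_matches_adjoint_dft_oracle(self):
        """Gridding equals brute-force conjugate-transpose DFT with same DCF."""
        rng = np.random.default_rng(5)
        traj = sample_positions(generate_spoke_directions(200), 8)
        cfg = GriddingConfig(matrix=8)
        dcf = density_compensation(traj)
        y = rng.standard_normal(traj.n_samples) + 1j * rng.standard_normal(traj.n_samples)
        img = grid_reconstruct(y, traj, cfg, dcf=dcf)
        kf = traj.flat_coords()
        from xerecon.gridding import sampled_k_volume

        w = sampled_k_volume(kf) * dcf  # same weights + volume convention
        grid = np.stack(
            np.meshgrid(*(np.arange(8) - 4,) * 3, indexing="ij"), axis=-1
        ).reshape(-1, 3)
        ref = (np.exp(-2j * np.pi * (kf @ grid.T)).conj().T @ (w * y)).reshape((8,) * 3)
        nrms = np.linalg.norm(img - ref) / np.linalg.norm(ref)
        assert nrms < 0.02

    def test_linear_energy_scaling(self):
        traj = sample_positions(generate_spoke_directions(30), 8)
        cfg = GriddingConfig(matrix=8)
        rng = np.random.default_rng(2)
        y = rng.standard_normal(traj.n_samples) + 1j * rng.standard_normal(traj.n_samples)
        a = grid_reconstruct(y, traj, cfg)
        b = grid_reconstruct(3.0 * y, traj, cfg)
        np.testing.assert_allclose(b, 3.0 * a, rtol=1e-9, atol=1e-12 * np.abs(a).max())
        assert abs(np.linalg.norm(b) - 3.0 * np.linalg.norm(a)) < 1e-9 * np.linalg.norm(b)

    def test_shift_property(self):
        """A voxel-shifted phantom reconstructs to the shifted image."""
        from xerecon.phantom import SimulationParams, SequenceParams, simulate_kspace
        from xerecon.phantom import DigitalLungPhantom
        from xerecon.decomposition import ResonanceModel

        n = 16
        rho = np.zeros((n,) * 3)
        rho[6:10, 6:10, 6:10] = 1.0
        shift = (2, 0, 1)
        rho_shift = np.roll(rho, shift, axis=(0, 1, 2))
        traj = sample_positions(generate_spoke_directions(400), 16)
        cfg = GriddingConfig(matrix=n)
        model = ResonanceModel(
            delta_f_hz={"gas": 0.0, "membrane": 0.0, "rbc": 0.0},
            t2star_ms={"gas": 1e9, "membrane": 1e9, "rbc": 1e9},
        )
        seq = SequenceParams(te_ms=(1.0,), flip_gas_deg=90.0)
        sim = SimulationParams(noise_sigma=0.0)

        def recon(vol):
            ph = DigitalLungPhantom(
                matrix=n,
                rho={"gas": vol, "membrane": np.zeros_like(vol), "rbc": np.zeros_like(vol)},
                lung_mask=vol > 0,
            )
            k = simulate_kspace(ph, traj, model, seq, sim).flat()[0]
            return grid_reconstruct(k, traj, cfg)

        a = np.roll(recon(rho), shift, axis=(0, 1, 2))
        b = recon(rho_shift)
        # off-grid k makes the adjoint image non-periodic, so the identity
        # holds away from the FOV boundary; compare the interior
        c = slice(3, 13)
        err = np.linalg.norm((a - b)[c, c, c]) / np.linalg.norm(b[c, c, c])
        assert err < 1e-3

    def test_protocol_scale_runtime(self):
        """Default 1.2x/width-8/32^3 gridding of 934 spokes stays interactive."""
        traj = sample_positions(generate_spoke_directions(934), 32)
        y = np.ones(traj.n_samples, dtype=complex)
        t0 = time.time()
        img = grid_reconstruct(y, traj, GriddingConfig())
        elapsed = time.time() - t0
        assert img.shape == (32, 32, 32)
        assert elapsed < 10.0

    def test_zero_dcf_rejected(self):
        traj = sample_positions(generate_spoke_directions(10), 4)
        with pytest.raises(ValueError):
            grid_reconstruct(
                np.ones(traj.n_samples), traj, GriddingConfig(matrix=8),
                dcf=np.zeros(traj.n_samples),
            )
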