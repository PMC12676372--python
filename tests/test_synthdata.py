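"""Generators, the NLLS oracle, the CG baseline, and file I/O."""

import numpy as np
import pytest

from qmrifit.core import ValidationError
from qmrifit.models import get_model, sense_adjoint, sense_forward
from qmrifit.synthdata import (
    caipi_mask,
    gen_gaussian_toy,
    gen_monoexp_volume,
    gen_phantom_recon,
    gen_twopool_volume,
    lsqr_baseline,
    nlls_oracle,
)


class TestGenerators:
    def test_same_seed_reproduces_noisy_signal(self):
        a = gen_monoexp_volume(shape=(4, 4, 4), snr=20, seed=11)
        b = gen_monoexp_volume(shape=(4, 4, 4), snr=20, seed=11)
        assert np.array_equal(a.signal, b.signal)
        assert not np.array_equal(
            a.signal, gen_monoexp_volume(shape=(4, 4, 4), snr=20, seed=12).signal
        )

    def test_noise_sd_matches_snr_definition(self):
        data = gen_monoexp_volume(shape=(12, 12, 12), snr=10, seed=13)
        noise = data.signal - data.signal_clean
        ref = np.mean(data.signal_clean[data.mask][..., 0])
        assert noise.size > 1e4
        assert np.std(noise) == pytest.approx(ref / 10, rel=0.02)
        assert data.noise_sd == pytest.approx(ref / 10)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValidationError):
            gen_monoexp_volume(s0_range=(100.0, 100.0))

    def test_twopool_f_one_reduces_to_monoexp(self):
        data = gen_twopool_volume(
            shape=(3, 3, 3), snr=1e9, seed=1,
            ranges={"S0": (900, 1100), "f": (1 - 1e-9, 1.0), "R2a": (0.05, 0.1),
                    "R2b": (0.01, 0.02)},
        )
        from qmrifit.models import monoexp_signal

        ref = np.asarray(monoexp_signal(data.truth["S0"], data.truth["R2a"],
                                        data.grid["echo_times"]))
        assert np.allclose(data.signal_clean, ref, rtol=1e-6)

    def test_gaussian_toy_closed_form(self):
        toy = gen_gaussian_toy(n_obs=100, theta_true=2.0, sigma=1.0, seed=3, n_voxels=4)
        assert toy["posterior_sd"] == pytest.approx(0.1)
        assert np.allclose(toy["posterior_mean"], toy["y"].mean(axis=1))
        big = gen_gaussian_toy(n_obs=200_000, theta_true=2.0, sigma=1.0, seed=3)
        assert big["posterior_mean"][0] == pytest.approx(2.0, abs=0.01)


class TestCaipiMask:
    def test_sampling_fraction_is_one_over_rz(self):
        m = caipi_mask((4, 6, 18), Rz=9, z_shift=3, z_te_shift=2, n_echoes=6)
        frac = m.reshape(6, -1).mean(axis=1)
        assert np.allclose(frac, 1 / 9)

    def test_three_consecutive_ky_rows_cover_three_kz_offsets(self):
        m = caipi_mask((1, 9, 18), Rz=9, z_shift=3, z_te_shift=0, n_echoes=1)
        offsets = set()
        for ky in range(3):
            kz = np.flatnonzero(m[0, 0, ky])
            offsets.add(int(kz[0] % 9))
        assert len(offsets) == 3

    def test_te_shift_rotates_pattern_across_echoes(self):
        m = caipi_mask((1, 6, 18), Rz=9, z_shift=3, z_te_shift=2, n_echoes=2)
        kz0 = np.flatnonzero(m[0, 0, 0])
        kz1 = np.flatnonzero(m[1, 0, 0])
        assert np.array_equal((kz0 + 2) % 18, kz1)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValidationError):
            caipi_mask((4, 6, 16), Rz=9, z_shift=3, z_te_shift=2, n_echoes=2)
        with pytest.raises(ValidationError):
            caipi_mask((4, 6, 18), Rz=9, z_shift=9, z_te_shift=2, n_echoes=2)


@pytest.fixture(scope="module")
def small():
    return gen_phantom_recon(spatial=(4, 6, 9), n_coils=4, Rz=3, z_shift=1,
                             z_te_shift=1, n_echoes=3, seed=2)


class TestPhantomRecon:

    def test_coils_partition_of_unity(self, small):
        assert np.allclose(np.sum(np.abs(small.coils) ** 2, axis=0), 1.0, atol=1e-12)

    def test_fully_sampled_kspace_reproduces_truth(self, small):
        full = np.ones_like(small.mask_u)
        k = np.asarray(sense_forward(small.image, small.coils, full))
        back = np.asarray(sense_adjoint(k, small.coils, full))
        assert np.linalg.norm(back - small.image) / np.linalg.norm(small.image) < 1e-12

    def test_seed_reproducibility(self):
        a = gen_phantom_recon(spatial=(4, 6, 9), n_coils=4, Rz=3, z_shift=1,
                              z_te_shift=1, n_echoes=2, noise_sd=0.01, seed=5)
        b = gen_phantom_recon(spatial=(4, 6, 9), n_coils=4, Rz=3, z_shift=1,
                              z_te_shift=1, n_echoes=2, noise_sd=0.01, seed=5)
        assert np.array_equal(a.kspace, b.kspace)


class TestNllsOracle:
    def test_noiseless_voxel_recovered_exactly(self):
        data = gen_monoexp_volume(shape=(2, 2, 2), snr=1e9, seed=6)
        est, status = nlls_oracle(get_model("monoexp_r2s"), data.signal, data.mask,
                                  grid=data.grid)
        assert status.min() > 0
        for p in ("S0", "R2star"):
            assert np.allclose(est[p], data.truth[p], rtol=1e-6)

    def test_underdetermined_voxel_rejected(self):
        data = gen_monoexp_volume(shape=(2, 2, 2), snr=50, seed=6,
                                  echo_times=np.array([5.0]))
        with pytest.raises(ValidationError):
            nlls_oracle(get_model("monoexp_r2s"), data.signal, data.mask, grid=data.grid)


class TestCgBaseline:
    def test_fully_sampled_recovers_truth(self, small):
        full = np.ones_like(small.mask_u)
        k = np.asarray(sense_forward(small.image, small.coils, full))
        rec = lsqr_baseline(k, small.coils, full, lam_tikhonov=0.0, max_iter=50)
        assert np.linalg.norm(rec - small.image) / np.linalg.norm(small.image) < 1e-6

    def test_large_tikhonov_shrinks_solution_to_zero(self, small):
        rec = lsqr_baseline(small.kspace, small.coils, small.mask_u,
                            lam_tikhonov=1e8, max_iter=50)
        assert np.linalg.norm(rec) < 1e-4 * np.linalg.norm(small.image)


class TestIO:
    def test_nifti_roundtrip(self, tmp_path, rng):
        from qmrifit.io import read_volume, write_volume

        vol = rng.standard_normal((4, 4, 4, 2))
        write_volume(tmp_path / "v.nii.gz", vol)
        back, affine = read_volume(tmp_path / "v.nii.gz")
        assert np.allclose(back, vol)
        assert affine.shape == (4, 4)

    def test_edge_list_roundtrip_strict_zero_based(self, tmp_path):
        from qmrifit.io import read_edge_list, write_edge_list
        from qmrifit.regularizers import GraphAdjacency

        g = GraphAdjacency.from_edges([[0, 1], [1, 2]])
        write_edge_list(tmp_path / "e.txt", g)
        back = read_edge_list(tmp_path / "e.txt")
        assert np.array_equal(back.edges, g.edges)

    def test_malformed_edge_list_reports_line(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("0 1\n2 x\n")
        from qmrifit.io import read_edge_list

        with pytest.raises(ValidationError, match=":2"):
            read_edge_list(p)

    def test_kspace_container_roundtrip(self, tmp_path, rng):
        from qmrifit.io import read_kspace, write_kspace

        k = rng.standard_normal((2, 2, 4, 4, 4)) + 1j * rng.standard_normal((2, 2, 4, 4, 4))
        C = rng.standard_normal((2, 4, 4, 4)) + 0j
        m = rng.random((2, 4, 4, 4)) < 0.5
        write_kspace(tmp_path / "k.h5", k, C, m)
        k2, C2, m2 = read_kspace(tmp_path / "k.h5")
        assert np.array_equal(k, k2) and np.array_equal(C, C2) and np.array_equal(m, m2)

    def test_unknown_config_key_rejected(self, tmp_path):
        from qmrifit.io import load_config

        p = tmp_path / "cfg.yaml"
        p.write_text("model: monoexp_r2s\nbogus_key: 1\n")
        with pytest.raises(ValidationError, match="bogus_key"):
            load_config(p)
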