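import numpy as np
import pytest

from cestlab.bm_simulator import CestVolume, symmetric_offsets
from cestlab.denoise_classic import (Bm3dConfig, NlmConfig, PcaConfig,
                                     bm3d_denoise, nlm_denoise, pca_denoise,
                                     select_k_malinowski, select_k_median,
                                     select_k_nelson)
from cestlab.fixtures import FixtureSpec, make_fixture
from cestlab.metrics import psnr
from cestlab.noise import NoiseSpec, add_kspace_noise


class TestSelectKMedian:
    def test_single_dominant(self):
        assert select_k_median(np.array([100.0, 1, 1, 1, 1])) == 1

    def test_all_equal_gives_zero(self):
        assert select_k_median(np.array([3.0, 3.0, 3.0, 3.0])) == 0

    def test_zero_padding_invariant(self):
        ev = np.array([50.0, 10.0, 1.0, 1.0, 1.0])
        padded = np.concatenate([ev, np.zeros(5)])
        assert select_k_median(ev) == select_k_median(padded)


class TestSelectKMalinowski:
    @staticmethod
    def brute_force(eigvals, n_voxels, dyn):
        best, best_ind = None, np.inf
        for n in range(1, dyn):
            re = np.sqrt(sum(eigvals[n:]) / (n_voxels * (dyn - n)))
            ind = re / (dyn - n) ** 2
            if ind < best_ind:
                best, best_ind = n, ind
        return best

    def test_sharp_elbow(self):
        ev = np.array([200.0, 80.0, 30.0] + [0.01] * 7)
        expected = self.brute_force(ev, 500, 10)
        assert expected == 3  # oracle: elbow at 3 components
        assert select_k_malinowski(ev, 500, 10) == 3

    def test_matches_brute_force_on_random_spectra(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            dyn = int(rng.integers(4, 15))
            ev = np.sort(rng.gamma(2.0, 1.0, dyn))[::-1]
            nv = int(rng.integers(50, 500))
            assert select_k_malinowski(ev, nv, dyn) == \
                self.brute_force(ev, nv, dyn)

    def test_geometric_spectrum_total_function(self):
        ev = 2.0 ** -np.arange(12)
        k = select_k_malinowski(ev, 100, 12)
        assert 1 <= k <= 11


class TestSelectKNelson:
    def test_smooth_loading_counted(self):
        t = np.linspace(0, 2 * np.pi, 50)
        comps = np.stack([np.sin(t), np.cos(t)])
        assert select_k_nelson(comps) == 2

    def test_white_noise_not_counted(self):
        rng = np.random.default_rng(0)
        comps = rng.normal(size=(3, 200))
        assert select_k_nelson(comps) == 0

    def test_stops_at_first_failure(self):
        t = np.linspace(0, 2 * np.pi, 100)
        rng = np.random.default_rng(1)
        comps = np.stack([np.sin(t), rng.normal(size=100), np.cos(t)])
        assert select_k_nelson(comps) == 1

    def test_all_smooth_counts_all(self):
        t = np.linspace(0, np.pi, 60)
        comps = np.stack([np.sin((i + 1) * t / 6) for i in range(4)])
        assert select_k_nelson(comps) == 4


class TestPcaDenoise:
    def test_full_rank_is_identity(self, rank1_32):
        _, noisy = rank1_32
        out, k = pca_denoise(noisy, PcaConfig(k_override=noisy.dyn))
        assert k == noisy.dyn
        np.testing.assert_allclose(out.data[noisy.mask],
                                   noisy.data[noisy.mask], atol=1e-8)

    def test_background_untouched(self, rank1_32):
        _, noisy = rank1_32
        out, _ = pca_denoise(noisy, PcaConfig("median"))
        bg = ~noisy.mask
        np.testing.assert_array_equal(out.data[bg], noisy.data[bg])

    def test_equivalence_with_truncated_svd_oracle(self):
        # independent oracle: numpy SVD truncation of the centred matrix
        rng = np.random.default_rng(7)
        dyn = 10
        data = rng.uniform(0.2, 1.0, size=(8, 8, dyn))
        vol = CestVolume(data=data, offsets_ppm=symmetric_offsets(4.0, dyn),
                         m0=np.ones((8, 8)), mask=np.ones((8, 8), bool))
        for k in (1, 3, 7):
            out, _ = pca_denoise(vol, PcaConfig(k_override=k))
            x = data.reshape(-1, dyn)
            mu = x.mean(axis=0)
            u, s, vt = np.linalg.svd(x - mu, full_matrices=False)
            recon = (u[:, :k] * s[:k]) @ vt[:k] + mu
            np.testing.assert_allclose(out.data.reshape(-1, dyn), recon,
                                       atol=1e-8)

    def test_denoising_gain_on_rank1(self, rank1_32):
        clean, noisy = rank1_32
        out, k = pca_denoise(noisy, PcaConfig("median"))
        assert psnr(clean, out) > psnr(clean, noisy)
        assert k <= 3

    def test_nelson_retains_more_than_median_on_noise(self):
        _, noisy, _ = make_fixture(
            FixtureSpec("pure-noise", grid=(32, 32), dyn=20, sigma=0.1,
                        seed=5))
        _, k_med = pca_denoise(noisy, PcaConfig("median"))
        _, k_nel = pca_denoise(noisy, PcaConfig("nelson"))
        assert k_nel >= k_med

    @pytest.mark.parametrize("sigma", [0.05, 0.1, 0.2])
    def test_median_gain_positive_above_005(self, sigma):
        clean, noisy, _ = make_fixture(
            FixtureSpec("creatine-ladder", grid=(32, 32), dyn=25,
                        sigma=sigma, seed=2))
        out, _ = pca_denoise(noisy, PcaConfig("median"))
        assert psnr(clean, out) > psnr(clean, noisy)

    def test_too_few_offsets_rejected(self, rank1_32):
        _, noisy = rank1_32
        tiny = noisy.copy_with(data=noisy.data[:, :, :2],
                               offsets_ppm=noisy.offsets_ppm[:2])
        with pytest.raises(ValueError):
            pca_denoise(tiny, PcaConfig("median"))


class TestNlm:
    def test_naming_convention(self):
        assert NlmConfig(21, 5).name == "NLM BW_21_SW_5"

    def test_window_validation(self):
        with pytest.raises(ValueError):
            NlmConfig(big_window=5, small_window=7)
        with pytest.raises(ValueError):
            NlmConfig(big_window=8, small_window=5)

    def test_constant_image_unchanged(self):
        vol = CestVolume(data=np.full((24, 24, 3), 0.7),
                         offsets_ppm=symmetric_offsets(3.0, 3),
                         m0=np.ones((24, 24)), mask=np.ones((24, 24), bool))
        out = nlm_denoise(vol, NlmConfig(big_window=11, small_window=3))
        np.testing.assert_allclose(out.data, vol.data, atol=1e-6)

    def test_variance_reduction_on_step_edge(self):
        rng = np.random.default_rng(0)
        img = np.zeros((32, 32)) + 0.3
        img[:, 16:] = 0.8
        noisy = img + rng.normal(0, 0.05, img.shape)
        vol = CestVolume(data=noisy[:, :, None],
                         offsets_ppm=np.array([0.0]),
                         m0=np.ones((32, 32)), mask=np.ones((32, 32), bool))
        out = nlm_denoise(vol, NlmConfig(big_window=11, small_window=3,
                                         h=0.05))
        for plateau in (np.s_[:, :12], np.s_[:, 20:]):
            assert out.data[:, :, 0][plateau].var() < noisy[plateau].var()

    def test_window_too_large_rejected(self, rank1_32):
        _, noisy = rank1_32
        with pytest.raises(ValueError):
            nlm_denoise(noisy, NlmConfig(big_window=101, small_window=5))


class TestBm3d:
    def test_naming_convention(self):
        assert Bm3dConfig(11, 4).name == "BM3D WS_11_BS_4"

    def test_block_vs_window_validation(self):
        with pytest.raises(ValueError):
            Bm3dConfig(window_size=4, block_size=11)

    def test_vanishing_noise_limit(self, rank1_32):
        clean, _ = rank1_32
        out = bm3d_denoise(clean, Bm3dConfig(11, 4, sigma=1e-9))
        np.testing.assert_allclose(out.data, clean.data, atol=1e-6)

    def test_gain_on_piecewise_constant(self):
        clean, noisy, _ = make_fixture(
            FixtureSpec("creatine-ladder", grid=(32, 32), dyn=5, sigma=0.1,
                        seed=9))
        out = bm3d_denoise(noisy, Bm3dConfig(11, 4))
        assert psnr(clean, out) > psnr(clean, noisy)


class TestIdempotentSafety:
    """No denoiser may destroy a noiseless volume."""

    @pytest.mark.parametrize("method", ["pca", "nlm", "bm3d"])
    def test_noiseless_input_preserved(self, ladder32, method):
        clean, _, _ = ladder32
        if method == "pca":
            out, _ = pca_denoise(clean, PcaConfig("median"))
        elif method == "nlm":
            out = nlm_denoise(clean, NlmConfig(big_window=11, small_window=3))
        else:
            out = bm3d_denoise(clean, Bm3dConfig(11, 4))
        assert psnr(clean, out) > 35.0
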