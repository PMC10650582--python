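import numpy as np
import pytest

from cestlab.bench import generate_phantom_volume
from cestlab.denoise_nn import (Adam, DenoiseNet, ModelConfig,
                                ReduceLROnPlateau, TrainConfig,
                                apply_denoiser, build_model,
                                load_checkpoint, save_checkpoint, train)
from cestlab.denoise_nn.layers import Param
from cestlab.metrics import psnr
from cestlab.noise import NoiseSpec, add_kspace_noise, random_offset_crop


@pytest.fixture(scope="module")
def tiny_cfg():
    return ModelConfig(arch="resunet", noise_estimation=True, depth=2,
                       in_channels=5, base_channels=4)


@pytest.fixture(scope="module")
def train_vols():
    return [generate_phantom_volume(s, (16, 16), 50, n_layers=4)
            for s in range(12)]


class TestBuildModel:
    def test_stage_counts(self, tiny_cfg):
        model = build_model(tiny_cfg)
        assert len(model.enc) == 2
        assert len(model.dec) == 2
        assert len(model.latent) == 2

    def test_depth4_stage_counts(self):
        model = build_model(ModelConfig(depth=4, in_channels=4,
                                        base_channels=2))
        assert len(model.enc) == len(model.dec) == 4

    def test_forward_preserves_shape(self, tiny_cfg):
        model = build_model(tiny_cfg)
        x = np.random.default_rng(0).normal(size=(2, 5, 16, 16))
        assert model.forward(x).shape == (2, 5, 16, 16)

    def test_resunet_has_more_parameters_than_unet(self):
        kw = dict(depth=2, in_channels=5, base_channels=4)
        unet = build_model(ModelConfig(arch="unet", **kw))
        res = build_model(ModelConfig(arch="resunet", **kw))
        assert res.n_parameters() > unet.n_parameters()

    def test_ne_variants_share_backbone_size(self):
        kw = dict(arch="resunet", depth=2, in_channels=5, base_channels=4)
        yes = build_model(ModelConfig(noise_estimation=True, **kw))
        no = build_model(ModelConfig(noise_estimation=False, **kw))
        assert yes.n_parameters() == no.n_parameters()

    def test_indivisible_spatial_size_rejected(self, tiny_cfg):
        model = build_model(tiny_cfg)
        with pytest.raises(ValueError, match="divisible"):
            model.forward(np.zeros((1, 5, 18, 18)))

    def test_gradient_matches_numerical(self, tiny_cfg):
        model = build_model(tiny_cfg, seed=1)
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 5, 8, 8))
        t = rng.normal(size=(1, 5, 8, 8))
        y = model.forward(x)
        diff = y - t
        model.zero_grad()
        model.backward(2.0 * diff / diff.size)
        for p in model.params[::5]:
            idx = tuple(rng.integers(0, s) for s in p.value.shape)
            eps, old = 1e-6, p.value[idx]
            p.value[idx] = old + eps
            lp = float(np.mean((model.forward(x) - t) ** 2))
            p.value[idx] = old - eps
            lm = float(np.mean((model.forward(x) - t) ** 2))
            p.value[idx] = old
            num = (lp - lm) / (2 * eps)
            assert p.grad[idx] == pytest.approx(num, rel=1e-4, abs=1e-9)

    def test_all_parameters_receive_gradient(self, tiny_cfg):
        model = build_model(tiny_cfg, seed=2)
        rng = np.random.default_rng(1)
        x = rng.normal(size=(2, 5, 16, 16))
        y = model.forward(x)
        model.zero_grad()
        model.backward(np.ones_like(y))
        assert all(np.any(p.grad != 0) for p in model.params)


class TestApplyDenoiser:
    def test_zero_weight_ne_yes_is_identity(self, tiny_cfg, train_vols):
        model = build_model(tiny_cfg)
        for p in model.params:
            p.value[...] = 0.0
        vol = train_vols[0].copy_with(
            data=train_vols[0].data[:, :, :5],
            offsets_ppm=train_vols[0].offsets_ppm[:5])
        out = apply_denoiser(model, vol)
        np.testing.assert_array_equal(out.data, vol.data)

    def test_ne_no_preserves_metadata(self, train_vols):
        cfg = ModelConfig(arch="unet", noise_estimation=False, depth=2,
                          in_channels=5, base_channels=4)
        model = build_model(cfg)
        vol = train_vols[0].copy_with(
            data=train_vols[0].data[:, :, :5],
            offsets_ppm=train_vols[0].offsets_ppm[:5])
        out = apply_denoiser(model, vol)
        assert out.shape == vol.shape
        np.testing.assert_array_equal(out.offsets_ppm, vol.offsets_ppm)
        assert out.meta["method"] == "UNet-NE-no"


class TestOptim:
    def test_adam_reduces_quadratic(self):
        p = Param(np.array([5.0]))
        opt = Adam([p], lr=0.1)
        for _ in range(200):
            p.grad[...] = 2 * p.value
            opt.step()
        assert abs(p.value[0]) < 1e-2

    def test_plateau_scheduler_decrements(self):
        p = Param(np.zeros(1))
        opt = Adam([p], lr=0.01)
        sched = ReduceLROnPlateau(opt, patience=3, factor=0.1)
        sched.step(1.0)          # sets best
        for _ in range(3):       # within patience: unchanged
            sched.step(1.0)
        assert opt.lr == pytest.approx(0.01)
        sched.step(1.0)          # beyond patience: reduce
        assert opt.lr == pytest.approx(0.001)

    def test_improvement_resets_patience(self):
        p = Param(np.zeros(1))
        opt = Adam([p], lr=0.01)
        sched = ReduceLROnPlateau(opt, patience=2, factor=0.1)
        for loss in (1.0, 1.0, 0.5, 0.5, 0.5):
            sched.step(loss)
        assert opt.lr == pytest.approx(0.01)


class TestTrain:
    def test_loss_decreases(self, train_vols):
        cfg = ModelConfig(arch="resunet", noise_estimation=True, depth=2,
                          in_channels=41, base_channels=6)
        model = build_model(cfg, seed=0)
        tc = TrainConfig(epochs=4, batch_size=4, lr=0.003, seed=1)
        model, hist = train(model, train_vols, tc)
        assert hist["val_loss"][-1] < hist["val_loss"][0]
        assert len(hist["train_loss"]) == 4

    def test_deterministic_given_seed(self, train_vols):
        losses = []
        for _ in range(2):
            cfg = ModelConfig(arch="unet", noise_estimation=False, depth=2,
                              in_channels=41, base_channels=4)
            model = build_model(cfg, seed=3)
            tc = TrainConfig(epochs=2, batch_size=6, lr=0.003, seed=5)
            _, hist = train(model, train_vols, tc)
            losses.append(hist["train_loss"])
        assert losses[0] == losses[1]

    def test_empty_dataset_rejected(self, tiny_cfg):
        with pytest.raises(ValueError):
            train(build_model(tiny_cfg), [], TrainConfig(epochs=1))

    def test_smoke_gain_over_baseline(self, train_vols):
        # miniature end-to-end check; the acceptance suite trains the
        # full smoke model
        cfg = ModelConfig(arch="resunet", noise_estimation=True, depth=2,
                          in_channels=41, base_channels=44)
        model = build_model(cfg, seed=0)
        model.head.weight.value[...] = 0.0
        tc = TrainConfig(epochs=10, batch_size=1, lr=0.002,
                         scheduler_patience=10, sigma_range=(0.05, 0.15),
                         seed=1)
        model, _ = train(model, train_vols, tc)
        clean = generate_phantom_volume(99, (16, 16), 50, n_layers=4)
        noisy = add_kspace_noise(clean, NoiseSpec(0.1, seed=9))
        c41 = random_offset_crop(clean, seed=9)
        n41 = random_offset_crop(noisy, seed=9)
        den = apply_denoiser(model, n41)
        assert psnr(c41, den) > psnr(c41, n41)


class TestCheckpoint:
    def test_round_trip(self, tiny_cfg, tmp_path):
        model = build_model(tiny_cfg, seed=4)
        path = tmp_path / "model.npz"
        save_checkpoint(str(path), model)
        loaded = load_checkpoint(str(path))
        assert loaded.cfg == model.cfg
        x = np.random.default_rng(0).normal(size=(1, 5, 16, 16))
        np.testing.assert_array_equal(loaded.forward(x), model.forward(x))
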