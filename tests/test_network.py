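import numpy as np
import pytest
from scipy.signal import correlate2d

from pddc.network import (
    PDDCModel,
    StageConfig,
    TrainConfig,
    TrainResult,
    evaluate,
    make_slice_dataset,
    psnr,
)

SMALL = StageConfig(n_conv_layers=2, n_channels=4)


@pytest.fixture(scope="module")
def tiny_dataset():
    return make_slice_dataset(4, seed=0, shape=(32, 32))


def _np_extractor(x, layers):
    """Independent numpy forward of the per-domain feature extractor,
    built on scipy's correlate2d rather than the autodiff conv."""
    for li, (w, b) in enumerate(layers):
        out = np.empty((x.shape[0], w.data.shape[0]) + x.shape[2:])
        for n in range(x.shape[0]):
            for o in range(w.data.shape[0]):
                acc = np.zeros(x.shape[2:])
                for c in range(x.shape[1]):
                    acc += correlate2d(x[n, c], w.data[o, c], mode="same")
                out[n, o] = acc + b.data[o]
        x = out if li == len(layers) - 1 else np.maximum(out, 0.0)
    return x


class TestStageContracts:
    def test_zero_weights_preserve_input(self, tiny_dataset):
        """With every weight zero and hard consistency, a stage keeps the
        input image and only re-imposes measurements in k-space."""
        model = PDDCModel(SMALL, seed=0)
        model.zero_residual_branches()
        s = tiny_dataset[0]
        out, internals = model.cascade_forward(
            s["k_meas"], s["mask"], return_internals=True
        )
        zf = internals["zero_filled"]
        for img_t in internals["stage_images"]:
            stage_img = img_t.data[:, 0] + 1j * img_t.data[:, 1]
            assert np.allclose(stage_img[0], zf, atol=1e-12)
        assert np.allclose(out, zf, atol=1e-10)

    def test_hard_dc_exact_after_every_stage(self, tiny_dataset):
        model = PDDCModel(SMALL, seed=1)
        s = tiny_dataset[0]
        _, internals = model.cascade_forward(
            s["k_meas"], s["mask"], return_internals=True
        )
        meas = s["k_meas"][s["mask"]]
        for k_t in internals["stage_kspaces"]:
            k = (k_t.data[:, 0] + 1j * k_t.data[:, 1])[0]
            assert np.array_equal(k[s["mask"]], meas)

    def test_forward_deterministic(self, tiny_dataset):
        s = tiny_dataset[0]
        a = PDDCModel(SMALL, seed=3).cascade_forward(s["k_meas"], s["mask"])
        b = PDDCModel(SMALL, seed=3).cascade_forward(s["k_meas"], s["mask"])
        assert np.array_equal(a, b)


class TestCascadeContracts:
    def test_full_sampling_returns_measurement_image(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(32, 32)) + 1j * rng.normal(size=(32, 32))
        k_full = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(img), norm="ortho"))
        mask = np.ones((32, 32), dtype=bool)
        model = PDDCModel(SMALL, seed=2)
        out = model.cascade_forward(k_full, mask)
        assert np.allclose(out, img, atol=1e-10)

    def test_terminal_output_consistent_with_measurement(self, tiny_dataset):
        s = tiny_dataset[0]
        out = PDDCModel(SMALL, seed=4).cascade_forward(s["k_meas"], s["mask"])
        k_out = np.fft.fftshift(np.fft.fft2(np.fft.ifftshift(out), norm="ortho"))
        assert np.allclose(k_out[s["mask"]], s["k_meas"][s["mask"]], atol=1e-10)

    def test_residual_telescoping_identity_fusion(self, tiny_dataset):
        """Under identity fusion the stage-5 image equals the stage-1 input
        plus the sum of per-stage residual-branch outputs (oracle: an
        independent scipy-based forward of each extractor)."""
        model = PDDCModel(StageConfig(n_conv_layers=3, n_channels=4), seed=5)
        # give extractors nonzero output scale
        s = tiny_dataset[0]
        out, internals = model.cascade_forward(
            s["k_meas"], s["mask"], identity_fusion=True,
            terminal_dc=False, return_internals=True,
        )
        zf = internals["zero_filled"]
        x = np.stack([zf.real, zf.imag], axis=0)[None]
        acc = x.copy()
        for stage in model.stages:
            r = _np_extractor(acc, stage["extract_img"])
            acc = acc + r
        expected = acc[0, 0] + 1j * acc[0, 1]
        final = internals["stage_images"][-1].data
        final = final[:, 0] + 1j * final[:, 1]
        rel = np.abs(final[0] - expected).max() / np.abs(expected).max()
        assert rel < 1e-5


class TestTraining:
    def test_overfit_single_sample(self, tiny_dataset):
        model = PDDCModel(SMALL, seed=6)
        data = [tiny_dataset[0]]
        result = model.fit(data, TrainConfig(epochs=60, learning_rate=1e-3,
                                             batch_size=1, seed=0))
        assert isinstance(result, TrainResult)
        assert result.final_loss < 0.1 * result.loss_history[0]

    def test_lr_zero_keeps_parameters(self, tiny_dataset):
        model = PDDCModel(SMALL, seed=7)
        before = [p.data.copy() for p in model.parameters()]
        result = model.fit(tiny_dataset, TrainConfig(epochs=2, learning_rate=0.0,
                                                     seed=0))
        for p, b in zip(model.parameters(), before):
            assert np.array_equal(p.data, b)
        assert np.allclose(result.loss_history, result.loss_history[0])

    def test_seeded_training_reproducible(self, tiny_dataset):
        cfg = TrainConfig(epochs=2, learning_rate=1e-3, seed=11)
        h1 = PDDCModel(SMALL, seed=8).fit(tiny_dataset, cfg).loss_history
        h2 = PDDCModel(SMALL, seed=8).fit(tiny_dataset, cfg).loss_history
        assert h1 == h2


class TestGradientFlow:
    def test_zeroed_branches_identity_gradient(self):
        report = PDDCModel(SMALL, seed=9).gradient_flow_check(shape=(16, 16))
        assert report["zeroed_identity_ok"]
        assert report["zeroed_max_grad_diff"] < 1e-6

    def test_random_weights_gradient_survives_cascade(self):
        report = PDDCModel(SMALL, seed=10).gradient_flow_check(shape=(16, 16))
        assert report["random_input_grad_norm"] > 0


class TestEvaluate:
    def test_identity_reconstruction_metrics(self):
        rng = np.random.default_rng(1)
        img = rng.normal(size=(16, 16))
        assert psnr(img, img) == np.inf
        assert np.isfinite(psnr(img, np.zeros_like(img)))

    def test_empty_test_set_rejected(self):
        with pytest.raises(ValueError):
            evaluate(PDDCModel(SMALL, seed=0), [])


def test_model_save_load_round_trip(tmp_path, tiny_dataset):
    model = PDDCModel(SMALL, seed=12)
    s = tiny_dataset[0]
    before = model.cascade_forward(s["k_meas"], s["mask"])
    path = tmp_path / "model.npz"
    model.save(path)
    loaded = PDDCModel.load(path)
    after = loaded.cascade_forward(s["k_meas"], s["mask"])
    assert np.array_equal(before, after)
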