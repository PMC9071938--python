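"""Parallel dual-domain concatenated cascade for compressed-sensing MRI.

The model is a cascade of five stages.  Each stage runs a convolutional
feature extractor in the image domain and another in the k-space domain
(same structure, no parameter sharing within a stage or across stages), with
a data-consistency layer on the k-space branch re-imposing the measured
samples.  A cross-fusion step augments each domain's output with the
Fourier (or inverse-Fourier) transform of the other domain's output before
a 1x1 fusion convolution, and a residual connection adds the stage input::

    a_{m+1} = g(a_m) + K(a_m, c_m)

so the cascade output telescopes into the stage-1 input plus the sum of the
per-stage residual updates, and the identity path keeps gradients flowing to
the earliest stage.  Stages 1-4 are structurally identical (artifact
reduction / detail restoration); stage 5 carries an extra output-head
convolution and emits the final image, which passes through one terminal
data-consistency application.

Complex images and spectra are carried as two real channels (re, im).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np
from skimage.metrics import structural_similarity

from . import autodiff as ad
from .autodiff import Tensor
from .kspace import KSpace, SamplingMask, make_mask
from .phantom import PhantomSpec, make_phantom

__all__ = [
    "StageConfig",
    "TrainConfig",
    "PDDCModel",
    "TrainResult",
    "make_slice_dataset",
    "psnr",
    "evaluate",
]

N_STAGES = 5


@dataclass
class StageConfig:
    """Structure of the per-domain feature extractor within one stage."""

    n_conv_layers: int = 5
    n_channels: int = 32
    kernel_size: int = 3
    activation: str = "relu"

    def __post_init__(self) -> None:
        if self.n_conv_layers < 2:
            raise ValueError("n_conv_layers must be >= 2")
        if self.kernel_size % 2 == 0:
            raise ValueError("kernel_size must be odd")
        if self.activation != "relu":
            raise ValueError("only relu activation is supported")


@dataclass
class TrainConfig:
    loss: str = "mse"
    optimizer: str = "adam"
    learning_rate: float = 1e-4
    epochs: int = 20
    batch_size: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclass
class TrainResult:
    """Outcome of a training run: per-step loss history and the fitted model."""

    model: "PDDCModel"
    loss_history: list[float]
    config: TrainConfig

    @property
    def final_loss(self) -> float:
        return self.loss_history[-1]


def _init_extractor(rng, cfg: StageConfig) -> list[tuple[Tensor, Tensor]]:
    chans = [2] + [cfg.n_channels] * (cfg.n_conv_layers - 1)
    layers = []
    for li in range(cfg.n_conv_layers):
        cin = chans[li]
        cout = 2 if li == cfg.n_conv_layers - 1 else cfg.n_channels
        k = cfg.kernel_size
        scale = np.sqrt(2.0 / (cin * k * k))
        w = Tensor(rng.normal(0.0, scale, (cout, cin, k, k)), requires_grad=True)
        b = Tensor(np.zeros(cout), requires_grad=True)
        layers.append((w, b))
    return layers


def _init_1x1(rng, cin: int, cout: int) -> tuple[Tensor, Tensor]:
    # fusion maps start at zero so the untrained cascade reduces to the
    # zero-filled baseline; training moves them away from zero
    w = Tensor(np.zeros((cout, cin, 1, 1)), requires_grad=True)
    b = Tensor(np.zeros(cout), requires_grad=True)
    return w, b


def _run_extractor(x: Tensor, layers, last_linear: bool = True) -> Tensor:
    for li, (w, b) in enumerate(layers):
        x = ad.conv2d(x, w, b)
        if li < len(layers) - 1 or not last_linear:
            x = ad.relu(x)
    return x


def _c2ch(z: np.ndarray) -> np.ndarray:
    """complex (N, H, W) -> real (N, 2, H, W)"""
    return np.stack([z.real, z.imag], axis=1)


def _ch2c(x: np.ndarray) -> np.ndarray:
    return x[:, 0] + 1j * x[:, 1]


class PDDCModel:
    """Five-stage parallel dual-domain cascade with residual connections.

    Parameters are independent per stage and per domain.  ``identity_fusion``
    switches the cross-fusion map (and the stage-5 head) to a pass-through of
    the native branch, which exposes the pure residual telescoping of the
    cascade for diagnostics.
    """

    def __init__(self, stage_config: StageConfig | None = None, seed: int = 0):
        self.stage_config = stage_config or StageConfig()
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.stages = []
        for si in range(N_STAGES):
            stage = {
                "extract_img": _init_extractor(rng, self.stage_config),
                "extract_k": _init_extractor(rng, self.stage_config),
                "fuse_img": _init_1x1(rng, 4, 2),
                "fuse_k": _init_1x1(rng, 4, 2),
            }
            if si == N_STAGES - 1:
                k = self.stage_config.kernel_size
                stage["head"] = (
                    Tensor(np.zeros((2, 2, k, k)), requires_grad=True),
                    Tensor(np.zeros(2), requires_grad=True),
                )
            self.stages.append(stage)

    # -- parameter plumbing ------------------------------------------------

    def parameters(self) -> list[Tensor]:
        params = []
        for stage in self.stages:
            for key, val in stage.items():
                if key.startswith("extract"):
                    for w, b in val:
                        params.extend([w, b])
                else:
                    params.extend(val)
        return params

    def zero_residual_branches(self) -> None:
        """Zero every learned weight so each stage reduces to its direct path."""
        for p in self.parameters():
            p.data[...] = 0.0

    # -- data consistency inside the graph ----------------------------------

    @staticmethod
    def _dc(k: Tensor, k_meas_ch: np.ndarray, mask: np.ndarray,
            lam: float | None = None) -> Tensor:
        m = mask[None, None].astype(np.float64)
        if lam is None:
            return k * Tensor(1.0 - m) + Tensor(k_meas_ch * m)
        keep_w = 1.0 - m + m / (1.0 + lam)
        meas_w = m * lam / (1.0 + lam)
        return k * Tensor(keep_w) + Tensor(k_meas_ch * meas_w)

    # -- forward passes ------------------------------------------------------

    def stage_forward(
        self,
        img_in: Tensor,
        k_in: Tensor,
        k_meas_ch: np.ndarray,
        mask: np.ndarray,
        stage: dict,
        identity_fusion: bool = False,
        lam: float | None = None,
        is_last: bool = False,
    ) -> tuple[Tensor, Tensor, Tensor]:
        """One cascade stage; returns (img_out, k_out, image residual update)."""
        r_img = _run_extractor(img_in, stage["extract_img"])
        r_k = _run_extractor(k_in, stage["extract_k"])
        k_dc = self._dc(k_in + r_k, k_meas_ch, mask, lam)
        if identity_fusion:
            img_out = img_in + r_img
            return img_out, k_dc, r_img
        u_img = ad.conv2d(
            ad.concat([r_img, ad.ifft2c(k_dc)]), *stage["fuse_img"]
        )
        img_out = img_in + u_img
        if is_last and "head" in stage:
            img_out = img_out + ad.conv2d(img_out, *stage["head"])
        u_k = ad.conv2d(ad.concat([r_k, ad.fft2c(img_out)]), *stage["fuse_k"])
        k_out = self._dc(k_in + u_k, k_meas_ch, mask, lam)
        return img_out, k_out, u_img

    def cascade_forward(
        self,
        k_meas: np.ndarray,
        mask: np.ndarray,
        identity_fusion: bool = False,
        lam: float | None = None,
        terminal_dc: bool = True,
        return_internals: bool = False,
    ):
        """Run the full five-stage cascade on measured k-space.

        ``k_meas`` is complex with shape (H, W) or (N, H, W); ``mask`` is the
        boolean keep-pattern of one slice.  Stage 1 consumes the zero-filled
        image and the measured k-space; every stage consumes the original
        measurement in its data-consistency layer.  Returns the complex
        reconstruction (and internals when requested).
        """
        k_meas = np.asarray(k_meas, dtype=np.complex128)
        single = k_meas.ndim == 2
        if single:
            k_meas = k_meas[None]
        mask = np.asarray(mask, dtype=bool)
        k_meas_masked = k_meas * mask
        k_ch = _c2ch(k_meas_masked)
        zf = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(k_meas_masked, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1),
        )
        img = Tensor(_c2ch(zf))
        k = Tensor(k_ch)
        stage_imgs, stage_ks, residuals = [], [], []
        for si, stage in enumerate(self.stages):
            img, k, r = self.stage_forward(
                img, k, k_ch, mask, stage,
                identity_fusion=identity_fusion, lam=lam,
                is_last=(si == N_STAGES - 1),
            )
            stage_imgs.append(img)
            stage_ks.append(k)
            residuals.append(r)
        if terminal_dc:
            k_final = self._dc(ad.fft2c(img), k_ch, mask, lam)
            img = ad.ifft2c(k_final)
        out = _ch2c(img.data)
        if single:
            out = out[0]
        if return_internals:
            return out, {
                "zero_filled": zf if not single else zf[0],
                "image_tensor": img,
                "stage_images": stage_imgs,
                "stage_kspaces": stage_ks,
                "residual_updates": residuals,
            }
        return out

    def reconstruct(self, k_meas: KSpace, mask: SamplingMask) -> np.ndarray:
        """Reconstruct a complex image from one measured slice."""
        return self.cascade_forward(k_meas.values, mask.keep)

    # -- training -------------------------------------------------------------

    def fit(self, dataset: list[dict], cfg: TrainConfig | None = None) -> TrainResult:
        """Train the cascade on (k-space, mask, target image) samples with Adam
        on a mean-squared-error image loss; returns the loss history.
        """
        cfg = cfg or TrainConfig()
        if len(dataset) < 1:
            raise ValueError("dataset must be non-empty")
        rng = np.random.default_rng(cfg.seed)
        opt = ad.Adam(self.parameters(), lr=cfg.learning_rate)
        history: list[float] = []
        n = len(dataset)
        for _epoch in range(cfg.epochs):
            order = rng.permutation(n)
            for start in range(0, n, cfg.batch_size):
                batch = [dataset[i] for i in order[start : start + cfg.batch_size]]
                mask = batch[0]["mask"]
                k_meas = np.stack([s["k_meas"] for s in batch])
                target = _c2ch(np.stack([s["image"] for s in batch]))
                _, internals = self.cascade_forward(
                    k_meas, mask, return_internals=True
                )
                loss = ad.mse_loss(internals["image_tensor"], target)
                if not np.isfinite(loss.data):
                    raise RuntimeError(
                        f"training diverged: non-finite loss at step {len(history)}"
                    )
                opt.zero_grad()
                loss.backward()
                opt.step()
                history.append(float(loss.data))
        return TrainResult(self, history, cfg)

    # -- diagnostics -----------------------------------------------------------

    def gradient_flow_check(self, shape=(32, 32), seed: int = 0) -> dict:
        """Verify the residual identity path keeps gradients alive.

        With every residual branch zeroed the stage chain is the identity, so
        the loss gradient at the cascade input must equal the gradient at the
        output (the unit term of the chain rule through the residual sum).
        With random weights, the input gradient of the full cascade must have
        strictly positive norm.
        """
        rng = np.random.default_rng(seed)
        h, w = shape
        target = _c2ch(rng.normal(size=(1, h, w)) + 1j * rng.normal(size=(1, h, w)))

        zeroed = PDDCModel(self.stage_config, seed=self.seed)
        zeroed.zero_residual_branches()
        x0 = Tensor(rng.normal(size=(1, 2, h, w)), requires_grad=True)
        img, k = x0, Tensor(np.zeros((1, 2, h, w)))
        mask_all = np.zeros((h, w), dtype=bool)  # DC inert: nothing sampled
        kz = np.zeros((1, 2, h, w))
        for si, stage in enumerate(zeroed.stages):
            img, k, _ = zeroed.stage_forward(
                img, k, kz, mask_all, stage,
                identity_fusion=True, is_last=(si == N_STAGES - 1),
            )
        loss = ad.mse_loss(img, target)
        loss.backward()
        grad_at_output = 2.0 * (img.data - target) / target.size
        max_diff = float(np.max(np.abs(x0.grad - grad_at_output)))

        mask = make_mask((h, w), acceleration=4.0, seed=seed).keep
        k_full = _fft_np(rng.normal(size=(1, h, w)) + 1j * rng.normal(size=(1, h, w)))
        zf = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(k_full * mask, axes=(-2, -1)), norm="ortho"),
            axes=(-2, -1),
        )
        x_in = Tensor(_c2ch(zf), requires_grad=True)
        img, k = x_in, Tensor(_c2ch(k_full * mask))
        for si, stage in enumerate(self.stages):
            img, k, _ = self.stage_forward(
                img, k, _c2ch(k_full * mask), mask, stage,
                is_last=(si == N_STAGES - 1),
            )
        loss2 = ad.mse_loss(img, target)
        loss2.backward()
        input_grad_norm = float(np.linalg.norm(x_in.grad))
        return {
            "zeroed_max_grad_diff": max_diff,
            "zeroed_identity_ok": max_diff < 1e-6,
            "random_input_grad_norm": input_grad_norm,
        }

    # -- serialization -----------------------------------------------------------

    def save(self, path) -> None:
        """Single-file checkpoint: weights plus embedded config JSON."""
        arrays = {}
        for si, stage in enumerate(self.stages):
            for key, val in stage.items():
                if key.startswith("extract"):
                    for li, (w, b) in enumerate(val):
                        arrays[f"s{si}.{key}.{li}.w"] = w.data
                        arrays[f"s{si}.{key}.{li}.b"] = b.data
                else:
                    arrays[f"s{si}.{key}.w"] = val[0].data
                    arrays[f"s{si}.{key}.b"] = val[1].data
        arrays["config_json"] = np.frombuffer(
            json.dumps({"stage_config": asdict(self.stage_config), "seed": self.seed}).encode(),
            dtype=np.uint8,
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "PDDCModel":
        with np.load(path) as data:
            cfg = json.loads(bytes(data["config_json"]).decode())
            model = cls(StageConfig(**cfg["stage_config"]), seed=cfg["seed"])
            for si, stage in enumerate(model.stages):
                for key, val in stage.items():
                    if key.startswith("extract"):
                        for li, (w, b) in enumerate(val):
                            w.data[...] = data[f"s{si}.{key}.{li}.w"]
                            b.data[...] = data[f"s{si}.{key}.{li}.b"]
                    else:
                        val[0].data[...] = data[f"s{si}.{key}.w"]
                        val[1].data[...] = data[f"s{si}.{key}.b"]
        return model


def _fft_np(z: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(
        np.fft.fft2(np.fft.ifftshift(z, axes=(-2, -1)), norm="ortho"), axes=(-2, -1)
    )


# --------------------------------------------------------------------------
# Datasets and evaluation
# --------------------------------------------------------------------------


def make_slice_dataset(
    n_slices: int,
    seed: int,
    shape: tuple[int, int] = (64, 64),
    acceleration: float = 4.0,
    center_fraction: float = 0.08,
    mask: np.ndarray | None = None,
) -> list[dict]:
    """Phantom 2D slices with their undersampled measurements.

    Each sample holds the normalized ground-truth complex slice, the shared
    undersampling mask and the masked measured k-space.  Passing ``mask``
    pins the sampling pattern (the acquisition protocol) across datasets,
    e.g. to evaluate on held-out phantoms under the training protocol.
    """
    if mask is None:
        mask = make_mask(shape, acceleration, center_fraction, seed=seed).keep
    else:
        mask = np.asarray(mask, dtype=bool)
    samples = []
    si = 0
    phantom_seed = seed
    while len(samples) < n_slices:
        spec = PhantomSpec(
            grid_shape=(shape[0], shape[1], 8),
            voxel_spacing=(3.0, 3.0, 3.0),
            n_background_ellipsoids=6,
            cmb_specs=[],
            vein_specs=[],
            lacune_specs=[],
            noise_sigma=0.0,
            seed=phantom_seed + 50000,
        )
        subject = make_phantom(spec)
        vol = subject.complex_image.values
        for z in range(2, vol.shape[2] - 2):
            sl = vol[:, :, z]
            peak = np.abs(sl).max()
            if peak < 1e-6:
                continue
            sl = sl / peak
            k_full = _fft_np(sl[None])[0]
            samples.append(
                {"image": sl, "k_full": k_full, "k_meas": k_full * mask, "mask": mask}
            )
            if len(samples) >= n_slices:
                break
        phantom_seed += 1
    return samples


def psnr(reference: np.ndarray, test: np.ndarray) -> float:
    """Peak signal-to-noise ratio in dB, peak taken from the reference."""
    ref = np.abs(np.asarray(reference))
    tst = np.abs(np.asarray(test))
    mse = float(np.mean((ref - tst) ** 2))
    if mse == 0:
        return float("inf")
    peak = float(ref.max())
    return 10.0 * np.log10(peak * peak / mse)


def evaluate(model: PDDCModel, test_set: list[dict]) -> dict:
    """PSNR/SSIM of the cascade vs the zero-filled baseline on held-out slices."""
    if not test_set:
        raise ValueError("test set is empty")
    rows = []
    for i, s in enumerate(test_set):
        recon = model.cascade_forward(s["k_meas"], s["mask"])
        zf = np.fft.fftshift(
            np.fft.ifft2(np.fft.ifftshift(s["k_meas"] * s["mask"]), norm="ortho")
        )
        ref = np.abs(s["image"])
        dr = float(ref.max() - ref.min()) or 1.0
        rows.append(
            {
                "slice": i,
                "psnr_recon": psnr(s["image"], recon),
                "psnr_zero_filled": psnr(s["image"], zf),
                "ssim_recon": structural_similarity(ref, np.abs(recon), data_range=dr),
                "ssim_zero_filled": structural_similarity(ref, np.abs(zf), data_range=dr),
            }
        )
    finite = lambda key: [r[key] for r in rows if np.isfinite(r[key])]
    summary = {
        "per_slice": rows,
        "mean_psnr_recon": float(np.mean(finite("psnr_recon"))),
        "mean_psnr_zero_filled": float(np.mean(finite("psnr_zero_filled"))),
        "mean_ssim_recon": float(np.mean([r["ssim_recon"] for r in rows])),
        "mean_ssim_zero_filled": float(np.mean([r["ssim_zero_filled"] for r in rows])),
    }
    summary["psnr_gain_db"] = summary["mean_psnr_recon"] - summary["mean_psnr_zero_filled"]
    return summary
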