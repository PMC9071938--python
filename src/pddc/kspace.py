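"""Fourier operators, Cartesian undersampling masks and the data-consistency
operator shared by the reconstruction cascade and the SWI chain.

Conventions fixed project-wide:

* The discrete Fourier transform is **orthonormal** (``norm="ortho"``) and
  **centered** (DC component at the grid center), so Parseval's identity
  holds exactly and the transform pair is unitary.
* Masks undersample a single phase-encode axis (the last axis) with a
  variable-density random pattern plus a fully sampled central band.
* Data consistency defaults to *hard* replacement of the measured samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np

__all__ = [
    "ComplexImage",
    "KSpace",
    "SamplingMask",
    "forward_fft",
    "inverse_fft",
    "make_mask",
    "data_consistency",
    "zero_filled",
    "save_kspace_h5",
    "load_kspace_h5",
]


def _check_finite(values: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(values)):
        raise ValueError(f"{name} contains non-finite values")


@dataclass
class ComplexImage:
    """A complex-valued image grid (2D slice or 3D volume) with voxel spacing in mm."""

    values: np.ndarray
    spacing: tuple[float, ...] = (1.0, 1.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != self.values.ndim:
            raise ValueError(
                f"spacing has {len(self.spacing)} entries for a "
                f"{self.values.ndim}-dimensional grid"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel spacing must be positive")
        _check_finite(self.values, "image")

    @property
    def magnitude(self) -> np.ndarray:
        return np.abs(self.values)

    @property
    def phase(self) -> np.ndarray:
        return np.angle(self.values)


@dataclass
class KSpace:
    """Spatial-frequency counterpart of :class:`ComplexImage`.

    ``centered`` records whether the DC component sits at the grid center
    (always true for data produced by :func:`forward_fft`).
    """

    values: np.ndarray
    centered: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.complex128)
        _check_finite(self.values, "k-space")


@dataclass
class SamplingMask:
    """Boolean keep-pattern for Cartesian undersampling along the last axis."""

    keep: np.ndarray
    acceleration: float
    center_fraction: float = 0.08
    seed: int | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        self.keep = np.asarray(self.keep, dtype=bool)

    @property
    def kept_fraction(self) -> float:
        return float(self.keep.mean())


def forward_fft(img: ComplexImage | np.ndarray) -> KSpace:
    """Centered orthonormal FFT over all axes of the grid."""
    values = img.values if isinstance(img, ComplexImage) else np.asarray(img)
    _check_finite(values, "image")
    k = np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(values), norm="ortho"))
    return KSpace(k, centered=True)


def inverse_fft(k: KSpace | np.ndarray, spacing: tuple[float, ...] | None = None) -> ComplexImage:
    """Inverse of :func:`forward_fft`; exact round trip up to float precision."""
    values = k.values if isinstance(k, KSpace) else np.asarray(k)
    _check_finite(values, "k-space")
    img = np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(values), norm="ortho"))
    if spacing is None:
        spacing = (1.0,) * img.ndim
    return ComplexImage(img, spacing)


def make_mask(
    shape: tuple[int, ...],
    acceleration: float,
    center_fraction: float = 0.08,
    seed: int = 0,
) -> SamplingMask:
    """Variable-density random Cartesian mask along the last (phase-encode) axis.

    The central ``center_fraction`` of phase-encode lines is always kept; the
    remaining lines are kept with probability decaying with distance from the
    center, scaled so the total kept fraction is close to ``1/acceleration``.
    """
    if acceleration < 1:
        raise ValueError("acceleration must be >= 1")
    if center_fraction >= 1:
        raise ValueError("center_fraction must be < 1")
    n_pe = shape[-1]
    if acceleration == 1:
        return SamplingMask(np.ones(shape, dtype=bool), 1.0, center_fraction, seed)

    rng = np.random.default_rng(seed)
    n_center = max(int(round(center_fraction * n_pe)), 1)
    center = np.zeros(n_pe, dtype=bool)
    lo = (n_pe - n_center) // 2
    center[lo : lo + n_center] = True

    # Variable-density selection: a fixed number of extra lines is drawn
    # without replacement, with probability decaying quadratically from the
    # center, so the kept fraction is exactly round(n_pe/acceleration)/n_pe.
    x = np.abs(np.arange(n_pe) - n_pe / 2) / (n_pe / 2)
    profile = (1 - x) ** 2 + 1e-3
    n_extra = max(int(round(n_pe / acceleration)) - n_center, 0)
    outside = np.flatnonzero(~center)
    keep_line = center.copy()
    if n_extra > 0 and outside.size:
        n_extra = min(n_extra, outside.size)
        p = profile[outside] / profile[outside].sum()
        chosen = rng.choice(outside, size=n_extra, replace=False, p=p)
        keep_line[chosen] = True
    keep = np.broadcast_to(keep_line, shape).copy()
    return SamplingMask(keep, float(acceleration), center_fraction, seed)


def data_consistency(
    k_pred: KSpace,
    k_meas: KSpace,
    mask: SamplingMask,
    lam: float | None = None,
) -> KSpace:
    """Re-impose the measured samples on a predicted k-space.

    At unsampled locations the prediction passes through.  At sampled
    locations, hard mode (``lam=None``, the default) replaces the prediction
    with the measurement exactly; soft mode returns the convex combination
    ``(k_pred + lam * k_meas) / (1 + lam)``.
    """
    if k_pred.values.shape != k_meas.values.shape or k_pred.values.shape != mask.keep.shape:
        raise ValueError("k_pred, k_meas and mask shapes must agree")
    if lam is not None and lam < 0:
        raise ValueError("lam must be non-negative")
    keep = mask.keep
    out = k_pred.values.copy()
    if lam is None:
        out[keep] = k_meas.values[keep]
    else:
        out[keep] = (k_pred.values[keep] + lam * k_meas.values[keep]) / (1.0 + lam)
    return KSpace(out, centered=k_pred.centered)


def zero_filled(k_meas: KSpace, mask: SamplingMask, spacing=None) -> ComplexImage:
    """Zero-filled reconstruction: inverse FFT with missing samples at zero.

    This is the baseline every learned reconstruction is scored against.
    """
    return inverse_fft(KSpace(k_meas.values * mask.keep), spacing=spacing)


def save_kspace_h5(path, k: KSpace, mask: SamplingMask) -> None:
    """Serialize a k-space/mask pair to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=k.values)
        f.create_dataset("mask", data=mask.keep)
        f.attrs["acceleration"] = mask.acceleration
        f.attrs["center_fraction"] = mask.center_fraction
        if mask.seed is not None:
            f.attrs["seed"] = mask.seed


def load_kspace_h5(path) -> tuple[KSpace, SamplingMask]:
    with h5py.File(path, "r") as f:
        k = KSpace(f["kspace"][()])
        mask = SamplingMask(
            f["mask"][()],
            float(f.attrs["acceleration"]),
            float(f.attrs.get("center_fraction", 0.08)),
            int(f.attrs["seed"]) if "seed" in f.attrs else None,
        )
    return k, mask
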