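"""Detection of cerebral microbleeds (CMBs) and lacunar infarctions.

CMBs are compact, quasi-spherical hypointense foci on susceptibility-weighted
volumes with equivalent diameters of about 1.5-6.5 mm.  Candidates are voxels
falling well below the local background (robust z-score against a median-
filtered background), grouped into 3D 26-connected components.  Components
are kept as CMBs when their equivalent diameter lies in the band, they are
not elongated, and their slice span is consistent with a compact object;
elongated components that trace a course through many contiguous slices are
flagged as vessels (flow voids / veins) and excluded from the count.

Lacunar infarctions are cavities under 15 mm diameter that are hypointense
on the T1-like volume and hyperintense on the T2-like volume (long T1, long
T2) with clear boundaries; both criteria must hold jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LesionCandidate",
    "DetectionParams",
    "detect_cmb",
    "detect_lacune",
    "count_per_subject",
    "candidates_table",
]


@dataclass
class LesionCandidate:
    centroid_mm: tuple[float, float, float]
    equivalent_diameter_mm: float
    contrast: float  # robust z-score vs local background (negative = dark)
    elongation: float  # max axis extent / equivalent diameter
    n_slices_spanned: int
    lesion_class: str  # cmb | lacune | vessel_excluded | calcification_excluded

    def __post_init__(self) -> None:
        if self.equivalent_diameter_mm <= 0:
            raise ValueError("equivalent diameter must be positive")
        if self.elongation < 1:
            raise ValueError("elongation must be >= 1")


@dataclass
class DetectionParams:
    cmb_diameter_band_mm: tuple[float, float] = (1.5, 6.5)
    lacune_max_diameter_mm: float = 15.0
    hypointensity_z: float = -3.0
    elongation_max: float = 3.0
    background_kernel_mm: float = 10.0
    sigma_floor_frac: float = 0.08  # noise-scale floor, fraction of tissue level
    min_voxels: int = 2
    connectivity: int = 26

    def __post_init__(self) -> None:
        lo, hi = self.cmb_diameter_band_mm
        if not lo < hi:
            raise ValueError("diameter band lower bound must be below upper bound")
        if self.connectivity not in (6, 18, 26):
            raise ValueError("connectivity must be 6, 18 or 26")


_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


def _foreground(volume: np.ndarray, spacing, kernel_mm: float) -> np.ndarray:
    """Head mask eroded by the background-kernel radius.

    Detection is confined to this region: outside the head there is only
    noise, and at the head boundary the local-background estimate breaks
    down, so both are excluded rather than thresholded.
    """
    vmax = float(np.percentile(volume, 99.5))
    if vmax <= 0:
        return np.zeros(volume.shape, dtype=bool)
    fg = volume > 0.25 * vmax
    fg = ndimage.binary_closing(fg, iterations=2)
    fg = ndimage.binary_fill_holes(fg)  # dark cavities are inside the head
    radius_vox = tuple(max(int(round(kernel_mm / (2 * s))), 1) for s in spacing)
    struct = np.ones(tuple(2 * r + 1 for r in radius_vox), dtype=bool)
    return ndimage.binary_erosion(fg, structure=struct)


def _sigma(ref: np.ndarray, scale_ref: np.ndarray, floor_frac: float) -> float:
    """MAD-based noise scale with a floor relative to the tissue level,
    so ordinary tissue texture does not register as lesion contrast."""
    mad = np.median(np.abs(ref - np.median(ref)))
    sigma = 1.4826 * float(mad)
    floor = floor_frac * float(np.median(scale_ref)) if scale_ref.size else 0.0
    sigma = max(sigma, floor)
    return sigma if sigma > 0 else (float(ref.std()) or 1.0)


def _robust_z(volume: np.ndarray, spacing, kernel_mm: float,
              within: np.ndarray, floor_frac: float) -> np.ndarray:
    """Voxelwise z-score against a median-filtered local background."""
    size = tuple(max(int(round(kernel_mm / s)) | 1, 3) for s in spacing)
    background = ndimage.median_filter(volume, size=size)
    resid = volume - background
    ref = resid[within] if within.any() else resid
    scale_ref = volume[within] if within.any() else volume
    return resid / _sigma(ref, scale_ref, floor_frac)


def _global_z(volume: np.ndarray, within: np.ndarray, floor_frac: float) -> np.ndarray:
    """Z-score against the foreground tissue median; suited to cavities that
    are larger than any local-background kernel."""
    ref = volume[within] if within.any() else volume
    med = float(np.median(ref))
    return (volume - med) / _sigma(ref - med, ref, floor_frac)


def _component_candidates(
    mask: np.ndarray, zmap: np.ndarray, spacing, params: DetectionParams
) -> list[dict]:
    labels, n = ndimage.label(mask, structure=_STRUCTS[params.connectivity])
    spacing = np.asarray(spacing, dtype=float)
    voxel_vol = float(np.prod(spacing))
    out = []
    for lab, sl in enumerate(ndimage.find_objects(labels), start=1):
        if sl is None:
            continue
        comp = labels[sl] == lab
        n_vox = int(comp.sum())
        if n_vox < params.min_voxels:
            continue
        idx = np.argwhere(comp) + [s.start for s in sl]
        centroid = idx.mean(axis=0) * spacing
        extents_mm = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing
        eq_diam = (6.0 * n_vox * voxel_vol / np.pi) ** (1.0 / 3.0)
        elongation = max(float(extents_mm.max()) / eq_diam, 1.0)
        out.append(
            {
                "centroid": tuple(float(v) for v in centroid),
                "diameter": float(eq_diam),
                "elongation": elongation,
                "n_slices": int(idx[:, 2].max() - idx[:, 2].min() + 1),
                "contrast": float(zmap[sl][comp].mean()),
                "n_voxels": n_vox,
            }
        )
    return out


def detect_cmb(
    swi_values: np.ndarray,
    spacing: tuple[float, float, float],
    params: DetectionParams | None = None,
) -> list[LesionCandidate]:
    """Detect microbleed candidates on an SWI volume.

    Returns every retained component: compact in-band hypointensities as
    ``cmb``, elongated slice-spanning hypointensities as ``vessel_excluded``.
    """
    params = params or DetectionParams()
    if spacing is None or len(spacing) != 3:
        raise ValueError("a 3-element mm spacing is required")
    vol = np.asarray(swi_values, dtype=np.float64)
    fg = _foreground(vol, spacing, params.background_kernel_mm)
    zmap = _robust_z(vol, spacing, params.background_kernel_mm, fg,
                     params.sigma_floor_frac)
    mask = (zmap < params.hypointensity_z) & fg
    lo, hi = params.cmb_diameter_band_mm

    # course tracing: at a laxer threshold a vessel's dark track reconnects
    # across contiguous slices even where the strict threshold fragments it
    lax_mask = (zmap < params.hypointensity_z / 2.0) & fg
    lax_labels, _ = ndimage.label(lax_mask, structure=_STRUCTS[params.connectivity])
    spacing_arr = np.asarray(spacing, dtype=float)

    def _on_vessel_course(centroid_mm) -> bool:
        vox = tuple(
            int(np.clip(round(c / s), 0, n - 1))
            for c, s, n in zip(centroid_mm, spacing_arr, vol.shape)
        )
        lab = lax_labels[vox]
        if lab == 0:
            return False
        idx = np.argwhere(lax_labels == lab)
        extents_mm = (idx.max(axis=0) - idx.min(axis=0) + 1) * spacing_arr
        n_vox = len(idx)
        eq = (6.0 * n_vox * float(np.prod(spacing_arr)) / np.pi) ** (1 / 3)
        return extents_mm.max() / eq > params.elongation_max or extents_mm.max() > 2 * hi

    candidates: list[LesionCandidate] = []
    for comp in _component_candidates(mask, zmap, spacing, params):
        diameter = comp["diameter"]
        max_extent = comp["elongation"] * diameter
        if comp["elongation"] > params.elongation_max or _on_vessel_course(
            comp["centroid"]
        ):
            cls = "vessel_excluded"
        elif lo <= diameter <= hi and max_extent <= 2.0 * hi:
            cls = "cmb"
        else:
            continue  # out-of-band compact object: not reported
        candidates.append(
            LesionCandidate(
                centroid_mm=comp["centroid"],
                equivalent_diameter_mm=diameter,
                contrast=comp["contrast"],
                elongation=comp["elongation"],
                n_slices_spanned=comp["n_slices"],
                lesion_class=cls,
            )
        )
    return candidates


def detect_lacune(
    t1_like: np.ndarray,
    t2_like: np.ndarray,
    spacing: tuple[float, float, float],
    params: DetectionParams | None = None,
) -> list[LesionCandidate]:
    """Detect lacunar cavities: jointly T1-hypointense and T2-hyperintense,
    equivalent diameter below 15 mm."""
    params = params or DetectionParams()
    t1 = np.asarray(t1_like, dtype=np.float64)
    t2 = np.asarray(t2_like, dtype=np.float64)
    if t1.shape != t2.shape:
        raise ValueError("t1_like and t2_like grids differ")
    fg = _foreground(t1, spacing, params.background_kernel_mm)
    z1 = _global_z(t1, fg, params.sigma_floor_frac)
    z2 = _global_z(t2, fg, params.sigma_floor_frac)
    mask = (z1 < params.hypointensity_z) & (z2 > -params.hypointensity_z) & fg
    candidates: list[LesionCandidate] = []
    for comp in _component_candidates(mask, z1, spacing, params):
        if comp["diameter"] >= params.lacune_max_diameter_mm:
            continue
        candidates.append(
            LesionCandidate(
                centroid_mm=comp["centroid"],
                equivalent_diameter_mm=comp["diameter"],
                contrast=comp["contrast"],
                elongation=comp["elongation"],
                n_slices_spanned=comp["n_slices"],
                lesion_class="lacune",
            )
        )
    return candidates


def count_per_subject(candidates: list[LesionCandidate], lesion_class: str) -> int:
    """Count candidates of one class; subject positivity is count >= 1."""
    return sum(1 for c in candidates if c.lesion_class == lesion_class)


def candidates_table(candidates: list[LesionCandidate], subject_id: str = "") -> pd.DataFrame:
    rows = [
        {
            "subject_id": subject_id,
            "class": c.lesion_class,
            "x_mm": c.centroid_mm[0],
            "y_mm": c.centroid_mm[1],
            "z_mm": c.centroid_mm[2],
            "diameter_mm": c.equivalent_diameter_mm,
            "contrast": c.contrast,
            "elongation": c.elongation,
        }
        for c in candidates
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "subject_id", "class", "x_mm", "y_mm", "z_mm",
            "diameter_mm", "contrast", "elongation",
        ],
    )
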