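"""Synthetic brain-like phantoms, vessel geometry and two-group cohorts.

The generator produces every input the rest of the pipeline consumes, so the
whole chain is testable without any acquired data:

* 3D multi-contrast volumes (T1-like, T2-like, complex gradient-echo-like)
  containing quasi-spherical hypointense microbleeds, tubular veins and
  lacunar cavities, each recorded in a ground-truth table;
* paired vertebral + basilar artery centerlines with controllable diameter
  asymmetry and basilar curvature type (normal / C / reverse-C / S);
* a two-group cohort (case vs control) with group-specific lesion-count and
  dominance distributions.

Geometry is expressed in mm with the world origin at the volume corner and
axes aligned with the voxel axes (voxel ``i`` sits at ``i * spacing``).
Microbleeds and veins are implanted with a locally *negative* constant phase
offset, so the susceptibility-weighting phase mask darkens them by
construction; a full dipole-field simulation is deliberately out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

from .kspace import ComplexImage

__all__ = [
    "PhantomSpec",
    "VesselGeometrySpec",
    "VesselTree",
    "SyntheticSubject",
    "CohortSpec",
    "CMB_DIAMETER_BAND_MM",
    "LACUNE_MAX_DIAMETER_MM",
    "make_phantom",
    "make_vessel_tree",
    "make_cohort",
    "random_phantom_spec",
    "save_subject",
]

CMB_DIAMETER_BAND_MM = (1.5, 6.5)
LACUNE_MAX_DIAMETER_MM = 15.0

CURVATURE_TYPES = ("normal", "C", "reverse_C", "S")


# --------------------------------------------------------------------------
# Specs
# --------------------------------------------------------------------------


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject volume.

    ``cmb_specs``: (center mm, diameter mm, susceptibility contrast) triples;
    ``vein_specs``: (polyline mm, radius mm, contrast); ``lacune_specs``:
    (center mm, diameter mm).  Contrast is the magnitude attenuation factor
    in (0, 1] and simultaneously sets the implanted negative phase offset.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 32)
    voxel_spacing: tuple[float, float, float] = (2.0, 2.0, 2.0)
    n_background_ellipsoids: int = 6
    cmb_specs: list = field(default_factory=list)
    vein_specs: list = field(default_factory=list)
    lacune_specs: list = field(default_factory=list)
    noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        self.voxel_spacing = tuple(float(s) for s in self.voxel_spacing)
        if any(n < 4 for n in self.grid_shape):
            raise ValueError("grid_shape axes must each have >= 4 voxels")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be positive")
        fov = self.fov_mm
        lo_band, hi_band = CMB_DIAMETER_BAND_MM
        for center, diameter, _ in self.cmb_specs:
            self._check_center(center, fov, "cmb")
            if not (lo_band <= float(diameter) <= hi_band):
                raise ValueError(
                    f"cmb diameter {diameter} mm outside the "
                    f"{lo_band}-{hi_band} mm microbleed band"
                )
        for center, diameter in self.lacune_specs:
            self._check_center(center, fov, "lacune")
            if not 0 < float(diameter) < LACUNE_MAX_DIAMETER_MM:
                raise ValueError(
                    f"lacune diameter {diameter} mm must be in "
                    f"(0, {LACUNE_MAX_DIAMETER_MM}) mm"
                )
        for polyline, radius, _ in self.vein_specs:
            if float(radius) <= 0:
                raise ValueError("vein radius must be positive")
            for p in polyline:
                self._check_center(p, fov, "vein point")
        self._check_overlap()

    @property
    def fov_mm(self) -> tuple[float, float, float]:
        return tuple((n - 1) * s for n, s in zip(self.grid_shape, self.voxel_spacing))

    @staticmethod
    def _check_center(center, fov, what: str) -> None:
        c = np.asarray(center, dtype=float)
        if c.shape != (3,):
            raise ValueError(f"{what} center must be a 3-vector of mm coordinates")
        if np.any(c < 0) or np.any(c > np.asarray(fov)):
            raise ValueError(f"{what} center {c.tolist()} outside the field of view")

    def _check_overlap(self, tolerance_mm: float = 0.0) -> None:
        blobs = [(np.asarray(c, float), float(d) / 2) for c, d, _ in self.cmb_specs]
        blobs += [(np.asarray(c, float), float(d) / 2) for c, d in self.lacune_specs]
        for i in range(len(blobs)):
            for j in range(i + 1, len(blobs)):
                ci, ri = blobs[i]
                cj, rj = blobs[j]
                if np.linalg.norm(ci - cj) < ri + rj - tolerance_mm:
                    raise ValueError(
                        f"lesions at {ci.tolist()} and {cj.tolist()} overlap"
                    )


@dataclass
class VesselGeometrySpec:
    """Ground truth for one subject's vertebrobasilar tree."""

    left_diameter: float = 3.2
    right_diameter: float = 3.2
    basilar_curvature_type: str = "normal"
    basilar_amplitude: float = 0.0
    confluence_point: tuple[float, float, float] = (0.0, 0.0, 0.0)
    basilar_length: float = 30.0
    vertebral_length: float = 25.0
    seed: int = 0

    def __post_init__(self) -> None:
        for d in (self.left_diameter, self.right_diameter):
            if not 0.5 < float(d) < 6.0:
                raise ValueError(f"vertebral diameter {d} mm outside (0.5, 6.0) mm")
        if self.basilar_curvature_type not in CURVATURE_TYPES:
            raise ValueError(
                f"curvature type must be one of {CURVATURE_TYPES}, "
                f"got {self.basilar_curvature_type!r}"
            )
        if self.basilar_amplitude < 0:
            raise ValueError("basilar_amplitude must be >= 0")
        if (self.basilar_curvature_type == "normal") != (self.basilar_amplitude == 0):
            raise ValueError("normal type requires amplitude 0 and vice versa")


@dataclass
class SyntheticSubject:
    """One phantom subject: volumes, complex image, lesion truth, vessel truth."""

    subject_id: str
    group: str
    t1_like: np.ndarray
    t2_like: np.ndarray
    complex_image: ComplexImage
    truth_lesions: list  # (class, center mm, diameter mm)
    vessel_truth: VesselGeometrySpec
    spacing: tuple[float, float, float]

    def truth_table(self) -> pd.DataFrame:
        rows = [
            {
                "subject_id": self.subject_id,
                "class": cls,
                "x_mm": c[0],
                "y_mm": c[1],
                "z_mm": c[2],
                "diameter_mm": d,
            }
            for cls, c, d in self.truth_lesions
        ]
        return pd.DataFrame(
            rows, columns=["subject_id", "class", "x_mm", "y_mm", "z_mm", "diameter_mm"]
        )


@dataclass
class CohortSpec:
    """Two-group cohort design: case (symptomatic) vs control.

    Lacune counts are Poisson unless ``lacune_count_sds`` implies
    overdispersion, in which case a negative binomial with the matching mean
    and variance is used.  CMB counts given positivity are zero-truncated
    Poisson.
    """

    n_per_group: int = 30
    lacune_count_means: tuple[float, float] = (2.400, 0.672)
    lacune_count_sds: tuple[float, float] | None = (3.358, 1.252)
    cmb_positive_prob: tuple[float, float] = (14 / 30, 4 / 30)
    cmb_count_given_positive: tuple[float, float] = (3.5, 2.9)
    dominance_prob: tuple[float, float] = (19 / 30, 8 / 30)
    curvature_abnormal_prob: tuple[float, float] = (10 / 30, 4 / 30)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_group < 2:
            raise ValueError("n_per_group must be >= 2")
        for p in (*self.cmb_positive_prob, *self.dominance_prob, *self.curvature_abnormal_prob):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if any(m < 0 for m in self.lacune_count_means):
            raise ValueError("lacune count means must be >= 0")


# --------------------------------------------------------------------------
# Phantom volume synthesis
# --------------------------------------------------------------------------


def _mm_grids(shape, spacing):
    axes = [np.arange(n) * s for n, s in zip(shape, spacing)]
    return np.meshgrid(*axes, indexing="ij")


def _ellipsoid_mask(grids, center, semi_axes):
    q = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return q <= 1.0


def _sphere_mask(grids, center, diameter):
    r = diameter / 2
    q = sum((g - c) ** 2 for g, c in zip(grids, center))
    return q <= r * r


def _tube_mask(shape, spacing, polyline, radius):
    """Voxels within `radius` mm of the polyline (segment-wise, bbox-limited).

    The rasterization radius is floored at the voxel half-diagonal so a thin
    vessel stays voxel-connected along its course, emulating the partial-
    volume darkening a sub-voxel vein produces in every voxel it crosses.
    """
    mask = np.zeros(shape, dtype=bool)
    pts = np.asarray(polyline, dtype=float)
    sp = np.asarray(spacing)
    radius = max(float(radius), float(np.linalg.norm(sp)) / 2)
    for a, b in zip(pts[:-1], pts[1:]):
        lo = np.maximum(np.floor((np.minimum(a, b) - radius) / sp).astype(int), 0)
        hi = np.minimum(
            np.ceil((np.maximum(a, b) + radius) / sp).astype(int) + 1, np.asarray(shape)
        )
        if np.any(lo >= hi):
            continue
        sub = [np.arange(l, h) * s for l, h, s in zip(lo, hi, sp)]
        gx, gy, gz = np.meshgrid(*sub, indexing="ij")
        p = np.stack([gx, gy, gz], axis=-1)
        ab = b - a
        denom = float(ab @ ab)
        if denom == 0:
            t = np.zeros(p.shape[:-1])
        else:
            t = np.clip(((p - a) @ ab) / denom, 0.0, 1.0)
        closest = a + t[..., None] * ab
        d2 = np.sum((p - closest) ** 2, axis=-1)
        mask[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius * radius
    return mask


def make_phantom(spec: PhantomSpec) -> SyntheticSubject:
    """Build one synthetic subject from its spec.

    The magnitude is a piecewise-smooth head-like ellipsoid with internal
    intensity structure; implanted microbleeds and veins attenuate the
    magnitude and carry a negative phase offset; lacunes are cavities that
    are dark on the T1-like and bright on the T2-like volume.
    """
    rng = np.random.default_rng(spec.seed)
    shape, spacing = spec.grid_shape, spec.voxel_spacing
    grids = _mm_grids(shape, spacing)
    fov = np.asarray(spec.fov_mm)
    center = fov / 2

    brain = _ellipsoid_mask(grids, center, fov * 0.42 + 1e-9)
    magnitude = np.where(brain, 0.8, 0.0)
    t1 = np.where(brain, 0.7, 0.0)
    t2 = np.where(brain, 0.4, 0.0)

    for _ in range(spec.n_background_ellipsoids):
        c = center + (rng.random(3) - 0.5) * fov * 0.4
        axes = fov * (0.05 + 0.12 * rng.random(3))
        m = _ellipsoid_mask(grids, c, axes) & brain
        bump = 0.15 * (rng.random() - 0.5)
        magnitude[m] += bump
        t1[m] += 0.2 * (rng.random() - 0.5)
        t2[m] += 0.2 * (rng.random() - 0.5)

    # light smoothing keeps the background piecewise-smooth rather than staircased
    magnitude = ndimage.gaussian_filter(magnitude, 0.8)
    t1 = ndimage.gaussian_filter(t1, 0.8)
    t2 = ndimage.gaussian_filter(t2, 0.8)

    # smooth low-frequency background phase (radians), well inside (-pi, pi)
    phase = sum(
        0.1 * np.sin(2 * np.pi * g / (f + 1e-9) + rng.random() * 2 * np.pi)
        for g, f in zip(grids, fov)
    )

    truth = []
    for c, diameter, contrast in spec.cmb_specs:
        m = _sphere_mask(grids, np.asarray(c, float), float(diameter))
        magnitude[m] *= 1.0 - float(contrast)
        phase[m] -= 2.0 * float(contrast)  # locally negative phase offset
        t2[m] *= 0.6
        truth.append(("cmb", tuple(float(v) for v in c), float(diameter)))

    for polyline, radius, contrast in spec.vein_specs:
        m = _tube_mask(shape, spacing, polyline, float(radius))
        magnitude[m] *= 1.0 - float(contrast)
        phase[m] -= 1.5 * float(contrast)
        mid = np.asarray(polyline, float).mean(axis=0)
        truth.append(("vein", tuple(float(v) for v in mid), 2 * float(radius)))

    for c, diameter in spec.lacune_specs:
        m = _sphere_mask(grids, np.asarray(c, float), float(diameter))
        t1[m] = 0.12  # long T1: hypointense
        t2[m] = 0.95  # long T2: hyperintense
        magnitude[m] *= 0.85
        truth.append(("lacune", tuple(float(v) for v in c), float(diameter)))

    magnitude = np.clip(magnitude, 0.0, None)
    complex_vals = magnitude * np.exp(1j * phase)
    if spec.noise_sigma > 0:
        noise = rng.normal(0.0, spec.noise_sigma, size=shape + (2,))
        complex_vals = complex_vals + noise[..., 0] + 1j * noise[..., 1]
        t1 = t1 + rng.normal(0.0, spec.noise_sigma, size=shape)
        t2 = t2 + rng.normal(0.0, spec.noise_sigma, size=shape)

    vessel_truth = VesselGeometrySpec(seed=spec.seed)
    return SyntheticSubject(
        subject_id=f"phantom-{spec.seed:05d}",
        group="case",
        t1_like=t1,
        t2_like=t2,
        complex_image=ComplexImage(complex_vals, spacing),
        truth_lesions=truth,
        vessel_truth=vessel_truth,
        spacing=spacing,
    )


def random_phantom_spec(
    seed: int,
    n_cmb: int = 2,
    n_lacune: int = 1,
    n_vein: int = 1,
    grid_shape=(64, 64, 32),
    voxel_spacing=(2.0, 2.0, 2.0),
    cmb_diameter_range=(3.0, 6.0),
    noise_sigma: float = 0.01,
) -> PhantomSpec:
    """Draw a valid random phantom spec with non-overlapping lesions."""
    rng = np.random.default_rng(seed)
    fov = np.asarray([(n - 1) * s for n, s in zip(grid_shape, voxel_spacing)])
    placed: list[tuple[np.ndarray, float]] = []

    veins = []
    vein_segments: list[tuple[np.ndarray, np.ndarray, float]] = []
    for _ in range(n_vein):
        start = fov * (0.25 + 0.5 * rng.random(3))
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = float(rng.uniform(20.0, 35.0))
        end = np.clip(start + direction * length, fov * 0.1, fov * 0.9)
        veins.append(([tuple(start), tuple(end)], 1.0, 0.6))
        vein_segments.append((start, end, 1.0))

    def _seg_dist(c, a, b):
        ab = b - a
        t = np.clip(((c - a) @ ab) / (ab @ ab), 0.0, 1.0)
        return float(np.linalg.norm(c - (a + t * ab)))

    center = fov / 2
    semi = fov * 0.42

    def place(diameter, margin=0.22):
        # deep-brain placement: inside 75% of the background ellipsoid radius
        for _ in range(300):
            c = fov * (margin + (1 - 2 * margin) * rng.random(3))
            if np.linalg.norm((c - center) / semi) > 0.75:
                continue
            clear_blobs = all(
                np.linalg.norm(c - pc) > (diameter + pd_) / 2 + 4.0
                for pc, pd_ in placed
            )
            clear_veins = all(
                _seg_dist(c, a, b) > diameter / 2 + r + 4.0
                for a, b, r in vein_segments
            )
            if clear_blobs and clear_veins:
                placed.append((c, diameter))
                return tuple(float(v) for v in c)
        raise RuntimeError("could not place lesion without overlap")

    cmbs = []
    for _ in range(n_cmb):
        d = float(rng.uniform(*cmb_diameter_range))
        cmbs.append((place(d), d, 0.75))
    lacunes = []
    for _ in range(n_lacune):
        d = float(rng.uniform(6.0, 12.0))
        lacunes.append((place(d), d))
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_spacing=voxel_spacing,
        cmb_specs=cmbs,
        vein_specs=veins,
        lacune_specs=lacunes,
        noise_sigma=noise_sigma,
        seed=seed,
    )


# --------------------------------------------------------------------------
# Vessel geometry
# --------------------------------------------------------------------------


@dataclass
class VesselTree:
    """Centerlines (mm point arrays) plus a per-branch width field."""

    left_centerline: np.ndarray
    right_centerline: np.ndarray
    basilar_centerline: np.ndarray
    widths: dict  # branch name -> callable(arc_mm) -> width mm

    def width_field(self, branch: str, arc_mm):
        return self.widths[branch](np.asarray(arc_mm, dtype=float))


def _deviation_profile(curvature_type: str, amplitude: float, t: np.ndarray) -> np.ndarray:
    """Signed lateral deviation (mm) of the basilar axis vs its chord.

    Positive deviation points toward the subject's left.  C bows left once,
    reverse-C right once, S crosses zero exactly once with excursions of the
    full amplitude on both sides.
    """
    if curvature_type == "normal":
        return np.zeros_like(t)
    if curvature_type == "C":
        return amplitude * np.sin(np.pi * t)
    if curvature_type == "reverse_C":
        return -amplitude * np.sin(np.pi * t)
    if curvature_type == "S":
        return amplitude * np.sin(2 * np.pi * t)
    raise ValueError(f"unknown curvature type {curvature_type!r}")


def make_vessel_tree(spec: VesselGeometrySpec, n_points: int = 101) -> VesselTree:
    """Construct the two vertebral centerlines, the basilar centerline and
    the width field realizing the requested geometry.

    The vertebral arteries rise toward the confluence point with a lateral
    offset that closes smoothly; the basilar continues superiorly along +z
    with the type-defining lateral (x) deviation profile.
    """
    conf = np.asarray(spec.confluence_point, dtype=float)
    t = np.linspace(0.0, 1.0, n_points)

    def vertebral(side: int) -> np.ndarray:
        # side +1 = left (+x), -1 = right
        x = conf[0] + side * 8.0 * (1 - t) ** 1.5
        y = conf[1] + 0.0 * t
        z = conf[2] - spec.vertebral_length * (1 - t)
        return np.stack([x, y, z], axis=1)

    dev = _deviation_profile(spec.basilar_curvature_type, spec.basilar_amplitude, t)
    basilar = np.stack(
        [conf[0] + dev, np.full_like(t, conf[1]), conf[2] + spec.basilar_length * t],
        axis=1,
    )

    widths = {
        "left": lambda s, d=spec.left_diameter: np.full_like(np.asarray(s, float), d),
        "right": lambda s, d=spec.right_diameter: np.full_like(np.asarray(s, float), d),
        "basilar": lambda s, d=(spec.left_diameter + spec.right_diameter) / 2: np.full_like(
            np.asarray(s, float), d
        ),
    }
    return VesselTree(vertebral(+1), vertebral(-1), basilar, widths)


# --------------------------------------------------------------------------
# Cohort generation
# --------------------------------------------------------------------------


def _draw_counts(rng, mean, sd, size):
    """Poisson, or negative binomial when the requested variance exceeds the mean."""
    if mean == 0:
        return np.zeros(size, dtype=int)
    if sd is not None and sd * sd > mean:
        var = sd * sd
        p = mean / var
        r = mean * mean / (var - mean)
        return rng.negative_binomial(r, p, size=size)
    return rng.poisson(mean, size=size)


def _zero_truncated_poisson(rng, mean, size):
    out = np.empty(size, dtype=int)
    for i in range(size):
        k = rng.poisson(mean)
        while k == 0:
            k = rng.poisson(mean)
        out[i] = k
    return out


def make_cohort(
    spec: CohortSpec, with_volumes: bool = False
) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Draw a two-group cohort; returns subjects and the CSV-ready table.

    With ``with_volumes=False`` (default) subjects carry empty volumes and
    only the tabulated truth, which is what the statistical layer consumes;
    ``with_volumes=True`` additionally builds full phantom volumes with the
    drawn lesion counts implanted.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    subjects: list[SyntheticSubject] = []
    for gi, group in enumerate(("case", "control")):
        mean = spec.lacune_count_means[gi]
        sd = spec.lacune_count_sds[gi] if spec.lacune_count_sds is not None else None
        lacune_counts = _draw_counts(rng, mean, sd, spec.n_per_group)
        positives = rng.random(spec.n_per_group) < spec.cmb_positive_prob[gi]
        cmb_counts = np.zeros(spec.n_per_group, dtype=int)
        n_pos = int(positives.sum())
        if n_pos:
            cmb_counts[positives] = _zero_truncated_poisson(
                rng, spec.cmb_count_given_positive[gi], n_pos
            )
        dominant = rng.random(spec.n_per_group) < spec.dominance_prob[gi]
        diffs = np.where(
            dominant, rng.uniform(0.3, 2.0, spec.n_per_group),
            rng.uniform(0.0, 0.3, spec.n_per_group),
        )
        sides = np.where(
            dominant, rng.choice(["left", "right"], spec.n_per_group), "none"
        )
        abnormal = rng.random(spec.n_per_group) < spec.curvature_abnormal_prob[gi]
        ctypes = np.where(
            abnormal, rng.choice(["C", "reverse_C", "S"], spec.n_per_group), "normal"
        )
        for i in range(spec.n_per_group):
            sid = f"{group}-{i:03d}"
            rows.append(
                {
                    "subject_id": sid,
                    "group": group,
                    "lacune_count": int(lacune_counts[i]),
                    "cmb_count": int(cmb_counts[i]),
                    "cmb_positive": bool(positives[i]),
                    "dominant_side": str(sides[i]),
                    "diameter_diff_mm": float(diffs[i]),
                    "curvature_type": str(ctypes[i]),
                }
            )
            base = 3.2
            left = base + (diffs[i] / 2 if sides[i] == "left" else -diffs[i] / 2)
            right = base + (diffs[i] / 2 if sides[i] == "right" else -diffs[i] / 2)
            amp = 3.0 if ctypes[i] != "normal" else 0.0
            vessel = VesselGeometrySpec(
                left_diameter=float(np.clip(left, 0.6, 5.9)),
                right_diameter=float(np.clip(right, 0.6, 5.9)),
                basilar_curvature_type=str(ctypes[i]),
                basilar_amplitude=amp,
                seed=spec.seed + 7919 * gi + i,
            )
            if with_volumes:
                pspec = random_phantom_spec(
                    seed=spec.seed + 104729 * gi + i,
                    n_cmb=int(cmb_counts[i]),
                    n_lacune=int(lacune_counts[i]),
                    n_vein=1,
                )
                subject = make_phantom(pspec)
                subject.subject_id = sid
                subject.group = group
                subject.vessel_truth = vessel
            else:
                empty = np.zeros((1, 1, 1))
                subject = SyntheticSubject(
                    sid, group, empty, empty,
                    ComplexImage(empty.astype(complex), (1.0, 1.0, 1.0)),
                    [], vessel, (1.0, 1.0, 1.0),
                )
            subjects.append(subject)
    table = pd.DataFrame(rows)
    return subjects, table


# --------------------------------------------------------------------------
# Serialization
# --------------------------------------------------------------------------


def save_subject(subject: SyntheticSubject, out_dir) -> dict:
    """Write a subject's volumes (NIfTI), truth table (CSV) and spec (JSON)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    affine = np.diag(list(subject.spacing) + [1.0])
    paths = {}
    for name, vol in (
        ("t1_like", subject.t1_like),
        ("t2_like", subject.t2_like),
        ("magnitude", subject.complex_image.magnitude),
        ("phase", subject.complex_image.phase),
    ):
        p = out / f"{subject.subject_id}_{name}.nii"
        nib.save(nib.Nifti1Image(np.asarray(vol, dtype=np.float32), affine), p)
        paths[name] = str(p)
    truth_path = out / f"{subject.subject_id}_truth.csv"
    subject.truth_table().to_csv(truth_path, index=False)
    paths["truth"] = str(truth_path)
    meta_path = out / f"{subject.subject_id}_meta.json"
    meta_path.write_text(
        json.dumps(
            {
                "subject_id": subject.subject_id,
                "group": subject.group,
                "spacing_mm": list(subject.spacing),
                "vessel_truth": {
                    "left_diameter": subject.vessel_truth.left_diameter,
                    "right_diameter": subject.vessel_truth.right_diameter,
                    "basilar_curvature_type": subject.vessel_truth.basilar_curvature_type,
                    "basilar_amplitude": subject.vessel_truth.basilar_amplitude,
                },
            },
            indent=2,
        )
    )
    paths["meta"] = str(meta_path)
    return paths
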