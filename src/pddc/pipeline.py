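"""End-to-end pipeline orchestration.

One JSON-configurable run chains: phantom simulation -> k-space
undersampling -> reconstruction (trained cascade or zero-filled ablation)
-> SWI processing -> lesion detection -> vertebrobasilar morphometry ->
cohort statistics.  Every run writes a manifest with the config hash and
per-artifact checksums; a single global seed fans out to per-stage seeds
through a documented splitting rule so each stage is independently
reproducible.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .kspace import KSpace, forward_fft, make_mask, save_kspace_h5, zero_filled
from .lesions import DetectionParams, candidates_table, detect_cmb, detect_lacune
from .network import PDDCModel, StageConfig, TrainConfig, make_slice_dataset
from .phantom import CohortSpec, make_cohort, make_vessel_tree, save_subject
from .stats import cohort_report, report_to_markdown
from .swi import min_intensity_projection, swi_from_complex
from .vessels import Centerline, basilar_metrics, measure_diameter, morphometry_row

log = logging.getLogger("pddc")

# Documented acquisition defaults the synthetic protocol emulates
# (gradient-echo SWI-type protocol on a 3 T system).
SCAN_DEFAULTS = {
    "tr_ms": 17.0,
    "te_ms": 25.0,
    "flip_deg": 15.0,
    "slice_thickness_mm": 2.0,
    "fov_mm": (230.0, 183.0, 100.0),
}

_STAGE_OFFSETS = {
    "simulate": 1,
    "mask": 2,
    "train": 3,
    "detect": 4,
    "morph": 5,
    "stats": 6,
}


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: low 31 bits of SHA-256 over 'seed:stage-offset'."""
    digest = hashlib.sha256(f"{global_seed}:{_STAGE_OFFSETS[stage]}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    out_dir: str = ""
    seed: int = 0
    n_subjects_per_group: int = 2
    grid_shape: tuple[int, int, int] = (64, 64, 16)
    acceleration: float = 4.0
    center_fraction: float = 0.08
    train_model: bool = False
    train_slices: int = 24
    train_epochs: int = 6
    stage_channels: int = 8
    stage_layers: int = 3
    swi_window: int = 32
    swi_m: int = 4
    mip_slab: int = 4
    alpha: float = 0.05
    scan: dict = field(default_factory=lambda: dict(SCAN_DEFAULTS))

    @classmethod
    def from_json(cls, path_or_str) -> "RunConfig":
        try:
            is_file = Path(str(path_or_str)).exists()
        except OSError:  # raw JSON text can exceed filename limits
            is_file = False
        text = Path(path_or_str).read_text() if is_file else str(path_or_str)
        data = json.loads(text)
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "grid_shape" in data:
            data["grid_shape"] = tuple(data["grid_shape"])
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, default=list)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=list).encode()
        ).hexdigest()


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns the manifest dict.

    Any stage failure raises with the failing stage named; artifacts of
    completed stages are preserved on disk.
    """
    if not config.out_dir:
        raise ValueError("config.out_dir must be set before running")
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "started": time.time(),
        "stages": {},
        "artifacts": {},
    }
    (out / "config.json").write_text(config.to_json())

    stage = "simulate"
    try:
        t0 = time.time()
        cohort_spec = CohortSpec(
            n_per_group=config.n_subjects_per_group, seed=stage_seed(config.seed, "simulate")
        )
        subjects, cohort_table = make_cohort(cohort_spec, with_volumes=True)
        cohort_path = out / "cohort.csv"
        cohort_table.to_csv(cohort_path, index=False)
        manifest["artifacts"]["cohort"] = _sha256(cohort_path)
        for subject in subjects:
            for name, p in save_subject(subject, out / "subjects").items():
                manifest["artifacts"][f"{subject.subject_id}/{name}"] = _sha256(Path(p))
        manifest["stages"]["simulate"] = {"seconds": time.time() - t0,
                                          "n_subjects": len(subjects)}
        log.info("simulate: %d subjects in %.1fs", len(subjects), time.time() - t0)

        stage = "reconstruct"
        t0 = time.time()
        model = None
        if config.train_model:
            train_set = make_slice_dataset(
                config.train_slices, stage_seed(config.seed, "train"),
                shape=config.grid_shape[:2], acceleration=config.acceleration,
                center_fraction=config.center_fraction,
            )
            model = PDDCModel(
                StageConfig(n_conv_layers=config.stage_layers,
                            n_channels=config.stage_channels),
                seed=stage_seed(config.seed, "train"),
            )
            model.fit(train_set, TrainConfig(epochs=config.train_epochs,
                                             learning_rate=3e-4,
                                             seed=stage_seed(config.seed, "train")))
            model.save(out / "model.npz")
            manifest["artifacts"]["model"] = _sha256(out / "model.npz")
        mask = make_mask(
            tuple(config.grid_shape[:2]), config.acceleration,
            config.center_fraction, seed=stage_seed(config.seed, "mask"),
        )
        recon_rows = []
        for subject in subjects:
            vol = subject.complex_image.values
            recon = np.empty_like(vol)
            mid = vol.shape[2] // 2
            k_mid = forward_fft(vol[:, :, mid])
            save_kspace_h5(out / f"{subject.subject_id}_kspace.h5", k_mid, mask)
            for z in range(vol.shape[2]):
                k_full = forward_fft(vol[:, :, z])
                k_meas = KSpace(k_full.values * mask.keep)
                if model is not None:
                    recon[:, :, z] = model.cascade_forward(k_meas.values, mask.keep)
                else:
                    recon[:, :, z] = zero_filled(k_meas, mask).values
            subject.complex_image.values = recon
            recon_rows.append(subject.subject_id)
        manifest["stages"]["reconstruct"] = {
            "seconds": time.time() - t0,
            "mode": "cascade" if model is not None else "zero_filled",
        }
        log.info("reconstruct (%s): %.1fs, acceleration %.1fx",
                 manifest["stages"]["reconstruct"]["mode"],
                 time.time() - t0, config.acceleration)

        stage = "swi_detect"
        t0 = time.time()
        lesion_rows = []
        detect_params = DetectionParams()
        for subject in subjects:
            swi = swi_from_complex(
                subject.complex_image, window=config.swi_window, m=config.swi_m
            )
            min_intensity_projection(swi, config.mip_slab)
            cands = detect_cmb(swi.values, subject.spacing, detect_params)
            cands += detect_lacune(
                subject.t1_like, subject.t2_like, subject.spacing, detect_params
            )
            lesion_rows.append(candidates_table(cands, subject.subject_id))
        lesions = pd.concat(lesion_rows, ignore_index=True) if lesion_rows else pd.DataFrame()
        lesions_path = out / "lesions.csv"
        lesions.to_csv(lesions_path, index=False)
        manifest["artifacts"]["lesions"] = _sha256(lesions_path)
        manifest["stages"]["swi_detect"] = {"seconds": time.time() - t0}

        stage = "morphometry"
        t0 = time.time()
        morph_rows = []
        for subject in subjects:
            tree = make_vessel_tree(subject.vessel_truth)
            left, _ = measure_diameter(
                Centerline(tree.left_centerline),
                lambda s: tree.width_field("left", s), from_end=True,
            )
            right, _ = measure_diameter(
                Centerline(tree.right_centerline),
                lambda s: tree.width_field("right", s), from_end=True,
            )
            shape = basilar_metrics(Centerline(tree.basilar_centerline))
            morph_rows.append(morphometry_row(subject.subject_id, left, right, shape))
        morph = pd.DataFrame(morph_rows)
        morph_path = out / "morphometry.csv"
        morph.to_csv(morph_path, index=False)
        manifest["artifacts"]["morphometry"] = _sha256(morph_path)
        manifest["stages"]["morphometry"] = {"seconds": time.time() - t0}

        stage = "stats"
        t0 = time.time()
        report = cohort_report(cohort_table, alpha=config.alpha)
        (out / "report.json").write_text(json.dumps(report, indent=2))
        (out / "report.md").write_text(report_to_markdown(report))
        manifest["artifacts"]["report"] = _sha256(out / "report.json")
        manifest["stages"]["stats"] = {"seconds": time.time() - t0}
    except Exception as exc:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {exc}") from exc

    manifest["finished"] = time.time()
    manifest_path = out / "manifest.json"
    manifest_stable = {k: v for k, v in manifest.items() if k not in ("started", "finished")}
    manifest_stable["stages"] = {
        k: {kk: vv for kk, vv in v.items() if kk != "seconds"}
        for k, v in manifest["stages"].items()
    }
    manifest_path.write_text(json.dumps(manifest, indent=2, default=str))
    (out / "manifest_stable.json").write_text(json.dumps(manifest_stable, indent=2))
    return manifest
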