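"""End-to-end orchestration: phantom study -> preprocess -> lag maps -> stats.

A :class:`RunConfig` (usually loaded from YAML) fully determines a run:
every stage parameter, the seed, and the output directory.  ``run_pipeline``
executes the four stages, writes NIfTI/CSV/JSON artifacts under the output
directory, and returns a manifest listing every file with its SHA-256 hash
— two runs with the same config and seed produce byte-identical outputs.

Subjects whose lag map fails histogram QC (narrow zero peak) are excluded
from group statistics automatically; the exclusion and the offending
histogram are logged and recorded in the manifest.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import phantom as ph
from . import preprocess as pp
from . import stats as gs
from .errors import ParameterError
from .lagmap import LagMap, compute_lagmap, lag_histogram_qc

log = logging.getLogger("lagflow")

__all__ = ["RunConfig", "run_pipeline", "Manifest", "load_config", "demo_config_path"]


class PhantomConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    grid_shape: tuple[int, int, int] = (16, 16, 8)
    tr: float = 2.0
    n_volumes: int = 180
    slfo_band: tuple[float, float] = (0.008, 0.07)
    noise_sd: float = 1.0
    voxel_size_mm: float = 3.0
    delay_span: float = 4.0
    tap_shift: float = -2.5
    age_slope: float = 0.05


class CohortConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_pairs: int = 11
    n_controls: int = 40
    age_range: tuple[float, float] = (20.0, 80.0)
    jitter_sd: float = 0.5


class PreprocessConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    discard_s: float = 10.0
    trans_thresh: float = 3.0
    rot_thresh: float = 3.0
    rate_window: float = 0.5
    band: tuple[float, float] = (0.008, 0.07)
    dt: float = 0.5


class LagmapConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    max_lag: float = 7.0
    step: float = 0.5
    qc_zero_frac: float = 0.6


class StatsConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    fwhm_mm: float = 6.0
    height_p: float = 0.005
    cluster_p: float = 0.005
    n_perm: int = 2000
    fdr_q: float = 0.05
    min_cluster_mm3: float = 1600.0  # 200 voxels at 2 mm isotropic


class RunConfig(BaseModel):
    """Validated, drift-protected run configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    outdir: str = "lagflow_out"
    log_level: str = "INFO"
    phantom: PhantomConfig = Field(default_factory=PhantomConfig)
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    preprocess: PreprocessConfig = Field(default_factory=PreprocessConfig)
    lagmap: LagmapConfig = Field(default_factory=LagmapConfig)
    stats: StatsConfig = Field(default_factory=StatsConfig)

    @model_validator(mode="after")
    def _cross_checks(self) -> "RunConfig":
        nyq = 1.0 / (2.0 * self.phantom.tr)
        for name, band in (("phantom.slfo_band", self.phantom.slfo_band),
                           ("preprocess.band", self.preprocess.band)):
            if not (0.0 < band[0] < band[1] < nyq):
                raise ValueError(
                    f"{name}={band} must lie within (0, Nyquist={nyq}) for tr={self.phantom.tr}"
                )
        if self.preprocess.dt > self.phantom.tr:
            raise ValueError("preprocess.dt must not exceed the TR")
        if self.lagmap.step < self.preprocess.dt:
            raise ValueError("lagmap.step must be >= the resampled interval")
        return self


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def demo_config_path() -> Path:
    return Path(__file__).parent / "data" / "demo.yaml"


# ---------------------------------------------------------------------------
@dataclass
class Manifest:
    config: dict
    files: dict[str, str]  # relative path -> sha256
    excluded_subjects: list[str]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "config": self.config,
                    "files": self.files,
                    "excluded_subjects": self.excluded_subjects,
                },
                indent=2,
                sort_keys=True,
            )
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _derive_seed(base: int, k: int) -> int:
    return int(np.random.SeedSequence([base, k]).generate_state(1)[0] % (2**31 - 1))


def _subject_lagmap(
    entry, session: str, cfg: RunConfig
) -> tuple[LagMap, "pp.ScrubReport"]:
    series, motion = entry[session]
    pc = cfg.preprocess
    clean, report = pp.run_preprocessing(
        series,
        motion,
        discard_s=pc.discard_s,
        trans_thresh=pc.trans_thresh,
        rot_thresh=pc.rot_thresh,
        rate_window=pc.rate_window,
        band=pc.band,
        dt=pc.dt,
    )
    lm = compute_lagmap(clean, max_lag=cfg.lagmap.max_lag, step=cfg.lagmap.step)
    return lm, report


def run_pipeline(config: RunConfig | str | Path, stages: tuple[str, ...] | None = None) -> Manifest:
    """Run the synthetic study end to end and write all artifacts.

    ``stages`` may restrict execution (subset of ``("simulate",
    "preprocess", "lagmap", "stats")`` — later stages recompute what they
    need in memory, so restriction mainly controls which files appear).
    Returns the :class:`Manifest`; also written as ``manifest.json``.
    """
    if not isinstance(config, RunConfig):
        config = load_config(config)
    cfg = config
    logging.basicConfig(level=getattr(logging, cfg.log_level.upper(), logging.INFO))
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    run_stages = stages or ("simulate", "preprocess", "lagmap", "stats")
    log.info("run config: %s", cfg.model_dump())

    truth = ph.default_ground_truth(
        grid_shape=cfg.phantom.grid_shape,
        delay_span=cfg.phantom.delay_span,
        tap_shift=cfg.phantom.tap_shift,
        age_slope=cfg.phantom.age_slope,
    )
    spec = ph.PhantomSpec(
        grid_shape=cfg.phantom.grid_shape,
        tr=cfg.phantom.tr,
        n_volumes=cfg.phantom.n_volumes,
        slfo_band=cfg.phantom.slfo_band,
        noise_sd=cfg.phantom.noise_sd,
        voxel_size_mm=cfg.phantom.voxel_size_mm,
    )
    patients = ph.synthesize_cohort(
        n_subjects=cfg.cohort.n_pairs,
        age_range=(70.0, 85.0),
        truth=truth,
        spec=spec,
        jitter_sd=cfg.cohort.jitter_sd,
        paired=True,
        group="patient",
        seed=_derive_seed(cfg.seed, 1),
    )
    controls = ph.synthesize_cohort(
        n_subjects=cfg.cohort.n_controls,
        age_range=cfg.cohort.age_range,
        truth=truth,
        spec=spec,
        jitter_sd=cfg.cohort.jitter_sd,
        paired=False,
        group="control",
        seed=_derive_seed(cfg.seed, 2),
    )

    files: dict[str, str] = {}

    def record(path: Path) -> None:
        files[str(path.relative_to(out))] = _sha256(path)

    if "simulate" in run_stages:
        sim = out / "simulate"
        sim.mkdir(exist_ok=True)
        design = pd.concat([patients.design, controls.design], ignore_index=True)
        design.to_csv(sim / "design.csv", index=False)
        record(sim / "design.csv")
        import nibabel as nib

        for name, arr in (
            ("truth_delay", truth.delay_field),
            ("truth_shift", truth.shift_field),
            ("truth_age_slope", truth.age_slope_field),
            ("mask", truth.mask.astype(np.uint8)),
        ):
            p = sim / f"{name}.nii"
            nib.Nifti1Image(np.asarray(arr, dtype=np.float32), spec.affine).to_filename(str(p))
            record(p)
        # one example subject on disk (full cohorts stay in memory)
        series, motion = patients.subjects[0]["pre"]
        series.to_nifti(sim / "sub000_pre_bold.nii")
        motion.to_file(sim / "sub000_pre_motion.txt")
        record(sim / "sub000_pre_bold.nii")
        record(sim / "sub000_pre_motion.txt")

    excluded: list[str] = []
    patient_maps: dict[str, dict[str, LagMap]] = {}
    control_maps: list[LagMap] = []
    control_rows: list[int] = []
    if {"lagmap", "stats"} & set(run_stages):
        lmdir = out / "lagmap"
        lmdir.mkdir(exist_ok=True)
        for entry in patients.subjects:
            sid = entry["subject_id"]
            pair: dict[str, LagMap] = {}
            ok = True
            for sess in ("pre", "post"):
                lm, _ = _subject_lagmap(entry, sess, cfg)
                qc = lag_histogram_qc(lm, cfg.lagmap.qc_zero_frac)
                if qc.failed:
                    log.warning(
                        "subject %s %s failed lag-histogram QC "
                        "(zero-peak fraction %.2f > %.2f); excluded",
                        sid, sess, qc.zero_peak_fraction, qc.threshold,
                    )
                    qc.to_json(lmdir / f"{sid}_{sess}_qc_failed.json")
                    record(lmdir / f"{sid}_{sess}_qc_failed.json")
                    ok = False
                    break
                pair[sess] = lm
            if ok:
                patient_maps[sid] = pair
                if "lagmap" in run_stages:
                    for sess, lm in pair.items():
                        for p in lm.to_nifti(lmdir / f"{sid}_{sess}").values():
                            record(p)
            else:
                excluded.append(sid)
        for i, entry in enumerate(controls.subjects):
            sid = entry["subject_id"]
            lm, _ = _subject_lagmap(entry, "single", cfg)
            qc = lag_histogram_qc(lm, cfg.lagmap.qc_zero_frac)
            if qc.failed:
                log.warning("control %s failed lag-histogram QC; excluded", sid)
                excluded.append(sid)
                continue
            control_maps.append(lm)
            control_rows.append(i)
            if "lagmap" in run_stages:
                for p in lm.to_nifti(lmdir / f"{sid}").values():
                    record(p)

    if "stats" in run_stages:
        import nibabel as nib

        stdir = out / "stats"
        stdir.mkdir(exist_ok=True)
        vs = np.full(3, cfg.phantom.voxel_size_mm)
        min_cluster = gs.cluster_voxels_for_volume(cfg.stats.min_cluster_mm3, vs)

        if patient_maps:
            pre_s, post_s = [], []
            joint_valid = None
            for pair in patient_maps.values():
                v = pair["pre"].valid & pair["post"].valid
                joint_valid = v if joint_valid is None else (joint_valid & v)
            for pair in patient_maps.values():
                pre_s.append(
                    gs.smooth_gaussian(pair["pre"].lag, cfg.stats.fwhm_mm, vs, joint_valid)
                )
                post_s.append(
                    gs.smooth_gaussian(pair["post"].lag, cfg.stats.fwhm_mm, vs, joint_valid)
                )
            contrast = gs.paired_contrast(
                pre_s,
                post_s,
                height_p=cfg.stats.height_p,
                cluster_p=cfg.stats.cluster_p,
                n_perm=cfg.stats.n_perm,
                mask=joint_valid,
                affine=spec.affine,
                seed=_derive_seed(cfg.seed, 3),
            )
            nib.Nifti1Image(contrast.t_map.astype(np.float32), spec.affine).to_filename(
                str(stdir / "paired_t.nii")
            )
            record(stdir / "paired_t.nii")
            for direction in ("decrease", "increase"):
                tab = getattr(contrast, direction).table
                tab.to_csv(stdir / f"paired_clusters_{direction}.csv", index=False)
                record(stdir / f"paired_clusters_{direction}.csv")

        if control_maps:
            design = controls.design.iloc[control_rows].reset_index(drop=True)
            reg = gs.age_regression(
                control_maps, design, fdr_q=cfg.stats.fdr_q, min_cluster=min_cluster
            )
            for name, arr in (("age_beta", reg.beta_age), ("age_t", reg.t_age)):
                p = stdir / f"{name}.nii"
                nib.Nifti1Image(arr.astype(np.float32), spec.affine).to_filename(str(p))
                record(p)
            sigmask = reg.significant_mask().astype(np.uint8)
            nib.Nifti1Image(sigmask, spec.affine).to_filename(str(stdir / "age_sig.nii"))
            record(stdir / "age_sig.nii")
            for direction in ("positive", "negative"):
                tab = getattr(reg, direction).table
                tab.to_csv(stdir / f"age_clusters_{direction}.csv", index=False)
                record(stdir / f"age_clusters_{direction}.csv")

            med = float(np.median(design["age"]))
            young_lab = design["age"] <= med
            roi_design = design.assign(group=np.where(young_lab, "young", "elderly"))
            try:
                roi = gs.roi_group_compare(
                    control_maps, truth.regions["deep"], roi_design, ("young", "elderly")
                )
                summary = {
                    "roi_phase_young_s": roi.means["young"],
                    "roi_phase_elderly_s": roi.means["elderly"],
                    "roi_t": roi.t,
                    "roi_p": roi.p,
                }
            except Exception as exc:  # pragma: no cover - tiny demo cohorts
                summary = {"roi_error": str(exc)}
            (stdir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True))
            record(stdir / "summary.json")

    manifest = Manifest(
        config=json.loads(cfg.model_dump_json()),
        files=dict(sorted(files.items())),
        excluded_subjects=excluded,
    )
    manifest.to_json(out / "manifest.json")
    (out / "provenance.json").write_text(
        json.dumps({"config": manifest.config, "stages": list(run_stages)}, indent=2, sort_keys=True)
    )
    return manifest
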