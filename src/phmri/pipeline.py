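"""End-to-end pipeline: synth -> maps -> features -> predict -> evaluate.

Each stage writes its outputs into a run directory together with a
MANIFEST recording completeness, a structured log line per stage, and a
serialized copy of the configuration so a run is reproducible from its
directory alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from phmri import models
from phmri.features import (
    core_volume,
    extract_voi,
    percentile_features,
    register_translation,
    tmax_volume_and_reperfusion,
)
from phmri.perfusion import (
    compute_cbv_ratio,
    compute_tmax,
    fit_leakage,
    reference_curve,
    signal_to_concentration,
)
from phmri.records import PatientRecord, cohort_to_frame
from phmri.synthetic import (
    AcquisitionConfig,
    CohortConfig,
    GroupFeatureParams,
    gamma_variate_aif,
    generate_cohort,
)

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "apply_published_models",
    "load_features_csv",
    "save_nifti",
    "load_nifti",
]


def save_nifti(data: np.ndarray, path: str | Path, voxel_size=(2.0, 2.0, 5.0)) -> None:
    affine = np.diag(list(voxel_size[:3]) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), img.affine


@dataclass
class PipelineConfig:
    """Everything a run needs; serializable, reproducible given the seeds."""

    output_dir: str
    cohort: CohortConfig = field(default_factory=CohortConfig)
    acquisition: AcquisitionConfig = field(default_factory=AcquisitionConfig)
    volume_shape: tuple[int, int, int] = (32, 32, 12)
    voi_z_threshold: float = 2.0
    sv_threshold: float = 0.15
    tree_policy: str = "logistic_fallback"
    registration_radius: int = 1
    save_volumes: bool = False
    fit_models: bool = False

    REQUIRED = ("output_dir",)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort"]["ph_features"] = dataclasses.asdict(self.cohort.ph_features)
        d["cohort"]["no_ph_features"] = dataclasses.asdict(self.cohort.no_ph_features)
        d["cohort"]["pooled_features"] = dataclasses.asdict(self.cohort.pooled_features)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        for key in cls.REQUIRED:
            if key not in d:
                raise ValueError(f"missing required config field: {key!r}")
        cohort_d = dict(d.get("cohort", {}))
        for pair in ("age", "sbp", "nihss"):
            if pair in cohort_d:
                cohort_d[pair] = tuple(cohort_d[pair])
        for grp in ("ph_features", "no_ph_features", "pooled_features"):
            if grp in cohort_d:
                g = cohort_d[grp]
                cohort_d[grp] = GroupFeatureParams(
                    cbv_p10=tuple(g["cbv_p10"]),
                    adc_p10=tuple(g["adc_p10"]),
                    k2_p90=tuple(g["k2_p90"]),
                )
        kwargs = {
            "output_dir": d["output_dir"],
            "cohort": CohortConfig(**cohort_d),
            "acquisition": AcquisitionConfig(**d.get("acquisition", {})),
        }
        for key in (
            "voi_z_threshold", "sv_threshold", "tree_policy",
            "registration_radius", "save_volumes", "fit_models",
        ):
            if key in d:
                kwargs[key] = d[key]
        if "volume_shape" in d:
            kwargs["volume_shape"] = tuple(d["volume_shape"])
        return cls(**kwargs)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class _RunLog:
    def __init__(self, path: Path):
        self.path = path
        self.path.write_text("")

    def stage(self, name: str, t0: float, **info) -> None:
        entry = {"stage": name, "duration_s": round(time.monotonic() - t0, 3), **info}
        with self.path.open("a") as fh:
            fh.write(json.dumps(entry) + "\n")


def load_features_csv(path: str | Path) -> pd.DataFrame:
    """Read a cohort features CSV, reporting malformed rows by index."""
    try:
        frame = pd.read_csv(path)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed CSV {path}: {exc}") from exc
    for col in ("cbv_p10", "k2_p90"):
        if col not in frame.columns:
            raise ValueError(f"features CSV must have a {col!r} column")
        coerced = pd.to_numeric(frame[col], errors="coerce")
        bad = coerced.isna() & frame[col].notna()
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise ValueError(f"non-numeric {col!r} value at row index {idx}")
        frame[col] = coerced
    return frame


def apply_published_models(
    frame: pd.DataFrame, tree_policy: str = "logistic_fallback"
) -> tuple[pd.DataFrame, dict | None]:
    """Append published-model predictions; evaluate when labels are present.

    Adds ``logit_score``, ``logistic_label`` and ``tree_label`` columns.
    Returns ``(predictions, report)`` where the report is None without a
    usable ``ph_label`` column.
    """
    logistic = models.published_logistic()
    tree = models.published_tree(policy=tree_policy)

    out = frame.copy()
    scores, log_labels, tree_labels = [], [], []
    for i, row in frame.iterrows():
        rec = {"cbv_p10": row["cbv_p10"], "k2_p90": row["k2_p90"]}
        for col in ("cbv_p10", "k2_p90"):
            if not np.isfinite(rec[col]):
                raise ValueError(f"non-finite {col!r} at row index {i}")
        score, label = models.logistic_score(rec, logistic)
        scores.append(score)
        log_labels.append(label)
        tree_labels.append(models.tree_predict(rec, tree))
    out["logit_score"] = scores
    out["logistic_label"] = log_labels
    out["tree_label"] = tree_labels

    report = None
    if "ph_label" in out.columns and out["ph_label"].notna().all() and len(out):
        y = out["ph_label"].astype(int).to_numpy()
        if len(np.unique(y)) == 2:
            log_counts, log_rep = models.evaluate(y, out["logistic_label"], scores=out["logit_score"])
            tree_counts, tree_rep = models.evaluate(y, out["tree_label"])
            report = {
                "tree_policy": tree_policy,
                "logistic": {"counts": dataclasses.asdict(log_counts), **log_rep.to_dict()},
                "tree": {"counts": dataclasses.asdict(tree_counts), **tree_rep.to_dict()},
            }
    return out, report


def process_patient(volumes, config: PipelineConfig) -> dict:
    """Maps + features for one patient's volumes; returns measured values."""
    acq = config.acquisition
    truth = volumes.truth

    conc = signal_to_concentration(volumes.dsc, volumes.brain_mask)
    ref = reference_curve(conc, truth.contralateral_mask)
    fit = fit_leakage(conc, ref)
    cbv_ratio = compute_cbv_ratio(conc, fit, truth.contralateral_mask)
    aif = gamma_variate_aif(
        acq.times,
        arrival=acq.bolus_arrival,
        recirc_amplitude=acq.recirc_amplitude,
        recirc_delay=acq.recirc_delay,
    )
    tmax = compute_tmax(conc, aif, sv_threshold=config.sv_threshold)

    reg = register_translation(volumes.dwi, volumes.adc, search_radius=config.registration_radius)
    voi = extract_voi(
        reg.aligned, volumes.brain_mask, truth.contralateral_mask,
        z_threshold=config.voi_z_threshold,
    )
    valid = conc.valid & fit.valid
    cbv_p10, adc_p10, k2_p90 = percentile_features(cbv_ratio, volumes.adc, fit.k2, voi, valid)
    core_ml = core_volume(volumes.adc, volumes.brain_mask, truth.voxel_volume_ml)
    tmax6_ml, _ = tmax_volume_and_reperfusion(tmax, None, truth.voxel_volume_ml, volumes.brain_mask)

    return {
        "cbv_p10": cbv_p10,
        "adc_p10": adc_p10,
        "k2_p90": k2_p90,
        "core_volume_ml": core_ml,
        "tmax6_volume_ml": tmax6_ml,
        "registration_shift": reg.shift,
        "n_flagged_voxels": int((~valid).sum()),
        "maps": {"cbv_ratio": cbv_ratio, "k2": fit.k2, "tmax": tmax},
    }


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full pipeline into ``config.output_dir``.

    Writes cohort_truth.csv (generating records), cohort_features.csv
    (measured), predictions.csv, report.json, MANIFEST.json and a
    structured log. Any stage failure leaves partial outputs behind with
    the MANIFEST marking how far the run got, then re-raises.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(json.dumps(config.to_dict(), indent=2))
    log = _RunLog(out / "run.log")

    manifest = {"stages": {}, "seed": config.cohort.rng_seed}

    def mark(stage: str, status: str) -> None:
        manifest["stages"][stage] = status
        (out / "MANIFEST.json").write_text(json.dumps(manifest, indent=2))

    stage = "synth"
    try:
        t0 = time.monotonic()
        cohort = generate_cohort(
            config.cohort, config.acquisition, with_volumes=True,
            volume_shape=config.volume_shape,
        )
        truth_frame = cohort_to_frame([rec for _, rec in cohort])
        truth_frame.to_csv(out / "cohort_truth.csv", index=False)
        mark(stage, "complete")
        log.stage(stage, t0, n_patients=len(cohort), seed=config.cohort.rng_seed,
                  checksum=_sha256(out / "cohort_truth.csv"))

        stage = "maps+features"
        t0 = time.monotonic()
        measured_rows = []
        maps_dir = out / "maps"
        for volumes, rec in cohort:
            result = process_patient(volumes, config)
            if config.save_volumes:
                maps_dir.mkdir(exist_ok=True)
                for name, arr in result["maps"].items():
                    save_nifti(arr, maps_dir / f"{rec.patient_id}_{name}.nii.gz",
                               volumes.truth.voxel_size_mm)
            measured = PatientRecord(
                patient_id=rec.patient_id,
                cbv_p10=result["cbv_p10"],
                adc_p10=result["adc_p10"],
                k2_p90=result["k2_p90"],
                core_volume_ml=result["core_volume_ml"],
                tmax6_volume_ml=result["tmax6_volume_ml"],
                penumbral_pattern=rec.penumbral_pattern,
                age=rec.age, sex=rec.sex, hypertension=rec.hypertension,
                diabetes=rec.diabetes, sbp=rec.sbp, nihss=rec.nihss,
                iv_tpa=rec.iv_tpa, thrombectomy=rec.thrombectomy,
                ph_label=rec.ph_label,
            )
            measured_rows.append(measured)
        features_frame = cohort_to_frame(measured_rows)
        features_frame.to_csv(out / "cohort_features.csv", index=False)
        mark(stage, "complete")
        log.stage(stage, t0, checksum=_sha256(out / "cohort_features.csv"))

        stage = "predict"
        t0 = time.monotonic()
        predictions, report = apply_published_models(features_frame, config.tree_policy)
        predictions.to_csv(out / "predictions.csv", index=False)
        models_out = {"logistic": models.published_logistic().to_dict(),
                      "tree": models.published_tree(config.tree_policy).to_dict()}
        if config.fit_models:
            fitted_logistic = models.fit_logistic_backward(
                features_frame, ["cbv_p10", "adc_p10", "k2_p90"])
            fitted_tree = models.fit_tree(features_frame, ["cbv_p10", "k2_p90"])
            models_out["fitted_logistic"] = fitted_logistic.to_dict()
            models_out["fitted_tree"] = fitted_tree.to_dict()
        (out / "models.json").write_text(json.dumps(models_out, indent=2))
        mark(stage, "complete")
        log.stage(stage, t0, checksum=_sha256(out / "predictions.csv"))

        stage = "evaluate"
        t0 = time.monotonic()
        (out / "report.json").write_text(json.dumps(report, indent=2))
        mark(stage, "complete")
        log.stage(stage, t0)
    except Exception:
        mark(stage, "failed")
        raise
    return out
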