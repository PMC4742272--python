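"""Batch orchestration: calibrate -> segment -> classify -> score -> aggregate.

The per-nucleus path is pure in-memory (:func:`process_nucleus`,
:func:`process_patient`); :func:`run_pipeline` wraps it with file I/O, a run
manifest and per-item error isolation, and :func:`run_synthetic_cohort`
drives the same path over a generated cohort for end-to-end verification.
"""

from __future__ import annotations

import datetime
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import CalibrationRecord, calibrate_to_zdisk
from .image_model import BinaryMask, GrayImage, ThresholdConfig, read_gray_image, read_mask
from .scores import (
    NucleusScores,
    PatientRecord,
    aggregate_patient,
    classify_patient,
    compute_nuc_cs,
    compute_per_cs,
)
from .segmentation import NucleusSegmentation, segment_nucleus

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class NucleusResult:
    """Outcome of the per-nucleus pipeline."""

    nucleus_id: str
    continuous: bool
    nuc_cs: float | None
    per_cs: float | None
    inner_perimeter: float
    calibration: CalibrationRecord | None
    segmentation: NucleusSegmentation


@dataclass
class RunManifest:
    """Reproducibility record for one batch run."""

    config: dict
    items: list = field(default_factory=list)
    version: str = __version__
    started: str = ""
    finished: str = ""

    def add(self, item_id: str, status: str, detail: str = "") -> None:
        self.items.append({"id": item_id, "status": status, "detail": detail})

    @property
    def ok(self) -> bool:
        return all(item["status"] in ("ok", "skipped") for item in self.items)

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "config": self.config,
            "started": self.started,
            "finished": self.finished,
            "items": self.items,
        }


def process_nucleus(
    image: GrayImage,
    roi: BinaryMask,
    cfg: ThresholdConfig = ThresholdConfig(),
    zdisk_mask: BinaryMask | None = None,
    nucleolus_mask: BinaryMask | None = None,
    nucleus_id: str = "",
) -> NucleusResult:
    """Calibrate (when a Z-disk ROI is given), segment and score one nucleus.

    Scores are ``None`` for discontinuous nuclei, for which only the
    continuity verdict is meaningful.
    """
    record = None
    if zdisk_mask is not None:
        image, record = calibrate_to_zdisk(image, zdisk_mask, cfg)
    seg = segment_nucleus(image, roi, cfg, nucleolus_mask, nucleus_id)
    nuc_cs = per_cs = None
    if seg.continuous:
        nuc_cs = compute_nuc_cs(image, seg, cfg)
        per_cs = compute_per_cs(image, seg, cfg)
    return NucleusResult(
        nucleus_id=nucleus_id,
        continuous=seg.continuous,
        nuc_cs=nuc_cs,
        per_cs=per_cs,
        inner_perimeter=seg.inner_perimeter,
        calibration=record,
        segmentation=seg,
    )


def process_patient(
    patient_id: str,
    results: list[NucleusResult],
    covariates: dict | None = None,
    event: str = "none",
) -> PatientRecord:
    """Classify a patient from nucleus results and aggregate the scores."""
    group, consistent = classify_patient([r.continuous for r in results])
    record = PatientRecord(
        patient_id=patient_id,
        nuclei=results,
        group=group,
        consistent=consistent,
        covariates=covariates or {},
        event=event,
    )
    if group == "N":
        scores = [
            NucleusScores(r.nucleus_id, r.nuc_cs, r.per_cs)
            for r in results
            if r.continuous
        ]
        summary = aggregate_patient(scores)
        record.patient_nuc_cs = summary.patient_nuc_cs
        record.patient_per_cs = summary.patient_per_cs
    return record


def run_synthetic_cohort(
    table: pd.DataFrame,
    image_sets: dict,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the full pipeline over a generated cohort.

    Returns ``(patient_df, nucleus_df)``; the patient table carries the
    pipeline's group call and mean scores next to the generator's truth
    columns, ready for the cohort statistics layer.
    """
    patient_rows = []
    nucleus_rows = []
    for _, row in table.iterrows():
        pid = row["patient_id"]
        results = []
        for j, nucleus in enumerate(image_sets[pid]):
            res = process_nucleus(
                nucleus.image,
                nucleus.roi,
                cfg,
                zdisk_mask=nucleus.zdisk_mask,
                nucleus_id=f"{pid}-n{j + 1:02d}",
            )
            results.append(res)
            nucleus_rows.append({
                "patient_id": pid,
                "nucleus_id": res.nucleus_id,
                "continuous": res.continuous,
                "nuc_cs": res.nuc_cs,
                "per_cs": res.per_cs,
                "expected_nuc_cs": nucleus.truth.expected_nuc_cs,
                "expected_per_cs": nucleus.truth.expected_per_cs,
                "true_continuous": nucleus.truth.continuous,
            })
        record = process_patient(pid, results, event=row.get("event", "none"))
        patient_rows.append({
            "patient_id": pid,
            "group": record.group,
            "true_group": row.get("true_group", ""),
            "consistent": record.consistent,
            "nuc_cs": record.patient_nuc_cs,
            "per_cs": record.patient_per_cs,
            "event": record.event,
            "n_nuclei": len(results),
        })
    return pd.DataFrame(patient_rows), pd.DataFrame(nucleus_rows)


# ---------------------------------------------------------------------------
# file-based batch


def load_manifest(path: str | Path) -> dict:
    """Load a batch description (YAML: ``patients`` -> list of nucleus files)."""
    with open(path) as fh:
        manifest = yaml.safe_load(fh)
    if not isinstance(manifest, dict) or "patients" not in manifest:
        raise ValueError("manifest must be a mapping with a 'patients' list")
    return manifest


def run_pipeline(
    manifest: dict,
    cfg: ThresholdConfig,
    out_dir: str | Path,
) -> RunManifest:
    """Process a file-based batch and write cohort/nucleus CSVs + manifest.

    Each nucleus entry needs ``image`` and ``roi`` paths and may carry
    ``zdisk`` and ``nucleolus`` masks.  Failures are recorded per item and
    the run continues; the returned manifest's ``ok`` flag is False when
    any item errored.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    run = RunManifest(config=cfg.to_dict())
    run.started = datetime.datetime.now(datetime.timezone.utc).isoformat()
    patients = manifest.get("patients", [])
    if not patients:
        raise ValueError("empty batch")

    nucleus_rows = []
    patient_rows = []
    for patient in patients:
        pid = str(patient["patient_id"])
        results: list[NucleusResult] = []
        for j, entry in enumerate(patient.get("nuclei", [])):
            nid = entry.get("id", f"{pid}-n{j + 1:02d}")
            try:
                image = read_gray_image(entry["image"])
                roi = read_mask(entry["roi"], image.shape)
                zdisk = (
                    read_mask(entry["zdisk"], image.shape)
                    if entry.get("zdisk")
                    else None
                )
                nucleolus = (
                    read_mask(entry["nucleolus"], image.shape)
                    if entry.get("nucleolus")
                    else None
                )
                res = process_nucleus(image, roi, cfg, zdisk, nucleolus, nid)
            except Exception as exc:  # noqa: BLE001 - isolate per-item failures
                logger.error("nucleus %s failed: %s", nid, exc)
                run.add(nid, "error", str(exc))
                continue
            run.add(nid, "ok")
            results.append(res)
            nucleus_rows.append({
                "patient_id": pid,
                "nucleus_id": nid,
                "continuous": res.continuous,
                "nuc_cs": res.nuc_cs,
                "per_cs": res.per_cs,
            })
        if not results:
            run.add(pid, "error", "no nucleus processed")
            continue
        record = process_patient(
            pid, results,
            covariates=patient.get("covariates"),
            event=patient.get("event", "none"),
        )
        patient_rows.append({
            "patient_id": pid,
            "group": record.group,
            "consistent": record.consistent,
            "nuc_cs": record.patient_nuc_cs,
            "per_cs": record.patient_per_cs,
            "event": record.event,
            "n_nuclei": len(results),
        })

    pd.DataFrame(nucleus_rows).to_csv(out_dir / "nuclei.csv", index=False)
    pd.DataFrame(patient_rows).to_csv(out_dir / "cohort.csv", index=False)
    run.finished = datetime.datetime.now(datetime.timezone.utc).isoformat()
    (out_dir / "manifest.json").write_text(json.dumps(run.to_dict(), indent=2))
    return run
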