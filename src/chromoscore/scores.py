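"""Chromatin scores, patient-level aggregation and the two-step risk rule.

Two morphometric scores are computed for each continuous-ring nucleus, with
condensed chromatin defined as the top grayscale quartile (DN >= ``t_cond``):

* **Nuc-CS** (nucleoplasmic chromatin score, %):
  100 x (condensed area inside the nucleoplasm, nucleolus excluded)
      / (nucleoplasm area, nucleolus excluded).
* **Per-CS** (perinuclear chromatin score, px):
  (condensed area within the perinuclear rim) / (inner nuclear perimeter) —
  an effective rim thickness in pixels.

The Per-CS numerator is the condensed subset of the rim mask (the rim itself
is delineated at the lower ``t_peri`` threshold); this is the only reading
that reconciles the two thresholds.

Patients are classified from their nuclei's continuity verdicts (all
discontinuous -> Group A, all continuous -> Group N; real cohorts show no
mixing, so a mixed patient is resolved by majority vote and flagged).  The
two-step rule assigns Group A to the high-risk stratum outright and, for
Group N, flags low chromatin scores — either score at or below its cutoff —
as elevated risk.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .image_model import GrayImage, ThresholdConfig
from .segmentation import NucleusSegmentation

logger = logging.getLogger(__name__)

_PERCENTILES = (10, 25, 50, 75, 90)


class ScoreError(ValueError):
    """Score requested for a discontinuous nucleus or empty region."""


@dataclass(frozen=True)
class NucleusScores:
    """Nuc-CS (%) and Per-CS (px) for one continuous-ring nucleus."""

    nucleus_id: str
    nuc_cs: float
    per_cs: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.nuc_cs <= 100.0):
            raise ValueError("nuc_cs must lie in [0, 100]")
        if self.per_cs < 0:
            raise ValueError("per_cs must be >= 0")


@dataclass(frozen=True)
class PatientScoreSummary:
    """Patient-level score aggregate: mean plus dispersion percentiles."""

    patient_nuc_cs: float
    patient_per_cs: float
    nuc_cs_percentiles: dict[int, float]
    per_cs_percentiles: dict[int, float]
    n_nuclei: int


@dataclass
class PatientRecord:
    """One patient: nuclei, group verdict, scores, covariates, outcome."""

    patient_id: str
    nuclei: list
    group: str  # "A" | "N"
    consistent: bool = True
    patient_nuc_cs: float | None = None
    patient_per_cs: float | None = None
    covariates: dict = field(default_factory=dict)
    event: str = "none"  # "VAD" | "death" | "none"

    def __post_init__(self) -> None:
        if self.group not in ("A", "N"):
            raise ValueError("group must be 'A' or 'N'")
        if not self.nuclei:
            raise ValueError("patient must carry at least one nucleus")
        if self.group == "A" and (
            self.patient_nuc_cs is not None or self.patient_per_cs is not None
        ):
            raise ValueError("Group A patients carry no chromatin scores")

    @property
    def had_event(self) -> bool:
        return self.event != "none"


def compute_nuc_cs(
    image: GrayImage, seg: NucleusSegmentation, cfg: ThresholdConfig = ThresholdConfig()
) -> float:
    """Nucleoplasmic chromatin score (%): condensed fraction of the
    nucleolus-free nucleoplasm."""
    if not seg.continuous:
        raise ScoreError("Nuc-CS is defined only for continuous-ring nuclei")
    region = seg.interior_mask.pixels & ~seg.nucleolus_mask.pixels
    denom = int(region.sum())
    if denom == 0:
        raise ScoreError("empty nucleolus-free nucleoplasm")
    condensed = int(((image.pixels >= cfg.t_cond) & region).sum())
    return 100.0 * condensed / denom


def compute_per_cs(
    image: GrayImage, seg: NucleusSegmentation, cfg: ThresholdConfig = ThresholdConfig()
) -> float:
    """Perinuclear chromatin score (px): condensed rim area per unit of
    inner nuclear perimeter."""
    if not seg.continuous:
        raise ScoreError("Per-CS is defined only for continuous-ring nuclei")
    if seg.inner_perimeter <= 0:
        raise ScoreError("inner perimeter must be positive")
    condensed = int(((image.pixels >= cfg.t_cond) & seg.ring_mask.pixels).sum())
    return condensed / seg.inner_perimeter


def score_nucleus(
    image: GrayImage,
    seg: NucleusSegmentation,
    cfg: ThresholdConfig = ThresholdConfig(),
) -> NucleusScores:
    """Convenience wrapper computing both scores for one nucleus."""
    return NucleusScores(
        nucleus_id=seg.nucleus_id,
        nuc_cs=compute_nuc_cs(image, seg, cfg),
        per_cs=compute_per_cs(image, seg, cfg),
    )


def classify_patient(nucleus_verdicts: list[bool]) -> tuple[str, bool]:
    """Group a patient from per-nucleus continuity verdicts.

    All discontinuous -> ("A", consistent); all continuous -> ("N",
    consistent).  Mixed patterns are not expected biologically; they are
    resolved by majority vote (ties go to A, the high-risk group) and
    flagged inconsistent with a logged warning.
    """
    if not nucleus_verdicts:
        raise ValueError("at least one nucleus verdict is required")
    n_cont = sum(bool(v) for v in nucleus_verdicts)
    n = len(nucleus_verdicts)
    if n_cont == 0:
        return "A", True
    if n_cont == n:
        return "N", True
    group = "N" if n_cont > n - n_cont else "A"
    logger.warning(
        "mixed continuity verdicts (%d/%d continuous): majority vote -> %s",
        n_cont,
        n,
        group,
    )
    return group, False


def aggregate_patient(scores: list[NucleusScores]) -> PatientScoreSummary:
    """Patient-level summary: arithmetic means plus 10/25/50/75/90th
    percentiles of each score for the variability report."""
    if not scores:
        raise ValueError("cannot aggregate an empty score list")
    nuc = np.array([s.nuc_cs for s in scores], dtype=float)
    per = np.array([s.per_cs for s in scores], dtype=float)
    return PatientScoreSummary(
        patient_nuc_cs=float(nuc.mean()),
        patient_per_cs=float(per.mean()),
        nuc_cs_percentiles={p: float(np.percentile(nuc, p)) for p in _PERCENTILES},
        per_cs_percentiles={p: float(np.percentile(per, p)) for p in _PERCENTILES},
        n_nuclei=len(scores),
    )


def two_step_evaluate(
    patient: PatientRecord,
    cutoff_nuc: float | None = None,
    cutoff_per: float | None = None,
) -> str:
    """Two-step risk stratification.

    Step 1: a Group A patient is high-risk regardless of scores.
    Step 2: a Group N patient whose mean Nuc-CS or mean Per-CS falls at or
    below its cutoff is elevated-risk (OR-combination: each score is
    independently discriminative); otherwise low-risk.  Cutoffs default to
    ``None`` (no trigger): no validated decision thresholds exist, so by
    default the rule is report-only.
    """
    if patient.group == "A":
        return "high-risk"
    if patient.patient_nuc_cs is None or patient.patient_per_cs is None:
        raise ScoreError("Group N patient lacks aggregated chromatin scores")
    low_nuc = cutoff_nuc is not None and patient.patient_nuc_cs <= cutoff_nuc
    low_per = cutoff_per is not None and patient.patient_per_cs <= cutoff_per
    return "elevated-risk" if (low_nuc or low_per) else "low-risk"
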