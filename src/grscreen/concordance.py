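"""Concordance between organoid drug-sensitivity calls and clinical outcome.

Clinical response is binary. For patients treated before surgery (NAT
group) it derives from the histological regression grade of the resected
primary tumour (grades 0–3; grade 1 split into 1a/1b): grade 2 or 3 is a
GOOD response, grade 0 or 1 POOR. Treatment-naive patients are labelled
GOOD/POOR from post-operative follow-up (imaging, endoscopy, tumour
markers). Records without an outcome are excluded from all statistics.

Orientation (documented, since both conventions appear in the literature):
the positive class is *clinically GOOD responder predicted sensitive* —
sensitivity is the fraction of good responders the assay flags sensitive,
specificity the fraction of poor responders it flags resistant. The ROC is
computed on the continuous AUCsum score, sign-flipped so that a *low*
AUCsum argues for a GOOD response.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .classify import PredictedClass
from .errors import FormatError, ValidationError


class JSEDGrade(str, enum.Enum):
    """Histological chemotherapy-response grades of the resected tumour."""

    G0 = "G0"  # ineffective: no recognisable therapeutic effect
    G1a = "G1a"  # viable cancer cells >= 2/3 of tumour area
    G1b = "G1b"  # viable cancer cells in [1/3, 2/3)
    G2 = "G2"  # moderately effective: viable cells < 1/3
    G3 = "G3"  # markedly effective: no viable cancer cells


class Response(str, enum.Enum):
    GOOD = "GOOD"
    POOR = "POOR"


class Group(str, enum.Enum):
    NAT = "NAT"
    TREATMENT_NAIVE = "TREATMENT_NAIVE"


def jsed_to_binary(grade: JSEDGrade | str) -> Response:
    """Grade 2 or 3 is a GOOD histological response; grade 0/1a/1b POOR."""
    try:
        grade = JSEDGrade(grade)
    except ValueError:
        raise FormatError(f"unknown histological grade: {grade!r}") from None
    return Response.GOOD if grade in (JSEDGrade.G2, JSEDGrade.G3) else Response.POOR


@dataclass(frozen=True)
class ClinicalRecord:
    patient_id: str
    group: Group
    jsed_grade: JSEDGrade | None = None
    response: Response | None = None

    def resolved_response(self) -> Response | None:
        """Observed binary outcome; None when lost to follow-up."""
        if self.group is Group.NAT and self.jsed_grade is not None:
            return jsed_to_binary(self.jsed_grade)
        return self.response


def read_clinical_csv(path: str | Path) -> list[ClinicalRecord]:
    """Read clinical records (columns patient_id, group, jsed_grade, response)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"clinical file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in ("patient_id", "group") if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    records = []
    for row in df.itertuples(index=False):
        try:
            group = Group(str(row.group))
        except ValueError:
            raise FormatError(f"unknown group token: {row.group!r}") from None
        grade = getattr(row, "jsed_grade", None)
        grade = None if grade is None or pd.isna(grade) else JSEDGrade(str(grade))
        resp = getattr(row, "response", None)
        resp = None if resp is None or pd.isna(resp) else Response(str(resp))
        records.append(
            ClinicalRecord(
                patient_id=str(row.patient_id), group=group, jsed_grade=grade, response=resp
            )
        )
    return records


@dataclass(frozen=True)
class ConcordanceReport:
    """Confusion counts and derived statistics (positive = GOOD & sensitive)."""

    tp: int
    fn: int
    tn: int
    fp: int
    n_excluded: int = 0

    @property
    def n_evaluable(self) -> int:
        return self.tp + self.fn + self.tn + self.fp

    @property
    def sensitivity(self) -> float | None:
        denom = self.tp + self.fn
        return self.tp / denom if denom else None

    @property
    def specificity(self) -> float | None:
        denom = self.tn + self.fp
        return self.tn / denom if denom else None

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n_evaluable

    def mirrored(self) -> "ConcordanceReport":
        """Statistics with the positive class flipped (POOR & resistant)."""
        return ConcordanceReport(
            tp=self.tn, fn=self.fp, tn=self.tp, fp=self.fn, n_excluded=self.n_excluded
        )

    def to_dict(self) -> dict:
        return {
            "tp": self.tp,
            "fn": self.fn,
            "tn": self.tn,
            "fp": self.fp,
            "n_evaluable": self.n_evaluable,
            "n_excluded": self.n_excluded,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
        }


def concordance_stats(
    predictions: Mapping[str, PredictedClass | str],
    records: Iterable[ClinicalRecord],
) -> ConcordanceReport:
    """Cross-tabulate assay calls against observed clinical responses.

    Records without a resolvable response are dropped and tallied in
    ``n_excluded``; every evaluable record must have a prediction.
    """
    tp = fn = tn = fp = excluded = 0
    for rec in records:
        outcome = rec.resolved_response()
        if outcome is None:
            excluded += 1
            continue
        if rec.patient_id not in predictions:
            raise ValidationError(f"no prediction for evaluable patient {rec.patient_id!r}")
        pred = PredictedClass(predictions[rec.patient_id])
        sensitive = pred is PredictedClass.PREDICTED_SENSITIVE
        if outcome is Response.GOOD:
            tp += sensitive
            fn += not sensitive
        else:
            tn += not sensitive
            fp += sensitive
    if tp + fn + tn + fp == 0:
        raise ValidationError("no evaluable patients")
    return ConcordanceReport(tp=tp, fn=fn, tn=tn, fp=fp, n_excluded=excluded)


def roc_auc(scores: Sequence[float], labels: Sequence[bool | int]) -> float:
    """Rank-based ROC AUC; higher score argues for the positive class.

    Equivalent to the all-pairs concordance statistic with ties counted 1/2.
    Raises when only one class is present.
    """
    labels = np.asarray(labels, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    if labels.all() or not labels.any():
        raise ValidationError("ROC AUC needs both classes present")
    return float(roc_auc_score(labels, scores))


def dst_roc_auc(
    auc_sums: Sequence[float], responses: Sequence[Response | str]
) -> float:
    """ROC AUC of AUCsum against clinical response (positive = GOOD).

    The score sign is flipped internally so the statistic measures how well
    a *low* AUCsum discriminates good responders.
    """
    labels = [Response(r) is Response.GOOD for r in responses]
    return roc_auc([-s for s in auc_sums], labels)


@dataclass(frozen=True)
class ThresholdResult:
    threshold: float
    youden_j: float
    flags: tuple[str, ...] = ()


def youden_threshold(
    auc_sums: Sequence[float], responses: Sequence[Response | str]
) -> ThresholdResult:
    """Data-driven AUCsum cutoff maximising Youden's J = sens + spec - 1.

    Candidate thresholds are the midpoints of adjacent sorted unique scores;
    a patient is predicted sensitive when AUCsum <= threshold. Ties in J are
    resolved toward the smaller threshold. When the classes are inseparable
    (best J <= 0) the flag ``no-separation`` is raised.
    """
    scores = np.asarray(auc_sums, dtype=float)
    good = np.array([Response(r) is Response.GOOD for r in responses])
    if good.all() or not good.any():
        raise ValidationError("Youden threshold needs both classes present")
    uniq = np.unique(scores)
    if uniq.size < 2:
        raise ValidationError("need at least two distinct scores")
    candidates = (uniq[:-1] + uniq[1:]) / 2.0
    n_good, n_poor = int(good.sum()), int((~good).sum())
    best_thr, best_j = None, -math.inf
    for thr in candidates:
        sens = float(np.sum(good & (scores <= thr))) / n_good
        spec = float(np.sum(~good & (scores > thr))) / n_poor
        j = sens + spec - 1.0
        if j > best_j:  # strict: ties keep the smaller threshold
            best_thr, best_j = float(thr), j
    flags = ("no-separation",) if best_j <= 0 else ()
    return ThresholdResult(threshold=best_thr, youden_j=best_j, flags=flags)
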