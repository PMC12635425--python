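"""Turn GR summaries into calls.

Three decision rules:

* **AUCsum chemoresistance call** — a patient is predicted resistant to the
  TP (paclitaxel + cisplatin) regimen when AUCsum exceeds the threshold
  (default 1.134); equality falls on the sensitive side.
* **Per-drug decision tree** — RESISTANT when GR100 > Cmax (including GR100
  never reached, treated as +inf); SENSITIVE when GR100 < Cmax and
  GRmax < -0.5; PARTIAL otherwise (including GR100 == Cmax exactly).
* **Alternative-therapy ranking** — drugs sorted by descending Cmax/GR100;
  the top drug is the recommended alternative for TP-resistant patients.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .errors import MissingDrugError, ValidationError
from .gr import DrugResponseSummary, PatientScore, auc_sum, summarize_drug
from .plate import DrugRegistry, DrugSpec, ScreenDataset, Stage
from .prelim import CandidateSet, ViabilityProfile, compute_viability, select_candidates


@dataclass(frozen=True)
class ClassifierConfig:
    """Decision constants: the AUCsum resistance threshold and GRmax cutoff."""

    aucsum_threshold: float = 1.134
    grmax_cutoff: float = -0.5

    def __post_init__(self) -> None:
        if not 0.0 < self.aucsum_threshold < 2.0:
            raise ValidationError(
                f"aucsum_threshold must be in (0, 2), got {self.aucsum_threshold}"
            )
        if not -1.0 < self.grmax_cutoff < 1.0:
            raise ValidationError(
                f"grmax_cutoff must be in (-1, 1), got {self.grmax_cutoff}"
            )


class PredictedClass(str, enum.Enum):
    PREDICTED_SENSITIVE = "PREDICTED_SENSITIVE"
    PREDICTED_RESISTANT = "PREDICTED_RESISTANT"


class ResponseLabel(str, enum.Enum):
    SENSITIVE = "SENSITIVE"
    PARTIAL = "PARTIAL"
    RESISTANT = "RESISTANT"


@dataclass(frozen=True)
class DrugCall:
    label: ResponseLabel
    basis: dict  # gr100, grmax, cmax actually used


@dataclass(frozen=True)
class RankedAlternatives:
    ranking: tuple[tuple[str, float], ...]  # (drug, cmax_over_gr100), descending
    recommendation: str
    flags: tuple[str, ...] = ()


def classify_aucsum(score: PatientScore, cfg: ClassifierConfig | None = None) -> PredictedClass:
    """Resistant iff AUCsum strictly exceeds the threshold."""
    cfg = cfg or ClassifierConfig()
    if score.auc_sum > cfg.aucsum_threshold:
        return PredictedClass.PREDICTED_RESISTANT
    return PredictedClass.PREDICTED_SENSITIVE


def classify_drug(
    summary: DrugResponseSummary,
    spec: DrugSpec,
    cfg: ClassifierConfig | None = None,
) -> DrugCall:
    """Per-drug decision tree over (GR100, GRmax, Cmax)."""
    cfg = cfg or ClassifierConfig()
    if summary.drug != spec.name:
        raise ValidationError(
            f"summary drug {summary.drug!r} does not match spec {spec.name!r}"
        )
    if summary.grmax is None:
        raise ValidationError("missing grmax")
    gr100 = summary.gr100  # None == never reached == +inf
    if gr100 is None or gr100 > spec.cmax:
        label = ResponseLabel.RESISTANT
    elif gr100 < spec.cmax and summary.grmax < cfg.grmax_cutoff:
        label = ResponseLabel.SENSITIVE
    else:
        label = ResponseLabel.PARTIAL
    return DrugCall(
        label=label,
        basis={"gr100": gr100, "grmax": summary.grmax, "cmax": spec.cmax},
    )


def rank_alternatives(
    summaries: list[DrugResponseSummary],
    registry: DrugRegistry | None = None,
) -> RankedAlternatives:
    """Sort drugs by descending Cmax/GR100 and recommend the top one.

    Ties keep registry order (or input order when no registry is given) and
    raise the ``tied-ranking`` flag; an all-zero ranking — no drug achieves
    complete growth-rate inhibition at any dose — raises
    ``no-effective-agent``.
    """
    if not summaries:
        raise ValidationError("rank_alternatives needs at least one summary")
    if registry is not None:
        summaries = sorted(summaries, key=lambda s: registry.order(s.drug))
    ordered = sorted(summaries, key=lambda s: -s.cmax_over_gr100)  # stable
    flags: list[str] = []
    ratios = [s.cmax_over_gr100 for s in ordered]
    if len(set(ratios)) < len(ratios):
        flags.append("tied-ranking")
    if all(r == 0.0 for r in ratios):
        flags.append("no-effective-agent")
    return RankedAlternatives(
        ranking=tuple((s.drug, s.cmax_over_gr100) for s in ordered),
        recommendation=ordered[0].drug,
        flags=tuple(flags),
    )


@dataclass(frozen=True)
class OrganoidReport:
    """Full two-step result for one organoid."""

    organoid_id: str
    viability: ViabilityProfile
    candidates: CandidateSet
    summaries: dict  # drug -> DrugResponseSummary
    calls: dict  # drug -> DrugCall
    score: PatientScore
    predicted: PredictedClass
    alternatives: RankedAlternatives

    def to_dict(self) -> dict:
        return {
            "organoid_id": self.organoid_id,
            "viability": {
                drug: {"viability": e.viability, "sd": e.sd, "n": e.n_replicates}
                for drug, e in self.viability.entries.items()
            },
            "candidates": list(self.candidates.candidates),
            "candidate_flags": list(self.candidates.flags),
            "secondary_drugs": list(self.candidates.secondary_drugs),
            "summaries": {
                drug: {
                    "grmax": s.grmax,
                    "gr50": s.gr50,
                    "gr100": s.gr100,
                    "norm_auc": s.norm_auc,
                    "cmax_over_gr100": s.cmax_over_gr100,
                    "flags": list(s.flags),
                }
                for drug, s in self.summaries.items()
            },
            "calls": {drug: c.label.value for drug, c in self.calls.items()},
            "auc_sum": self.score.auc_sum,
            "auc_sum_components": {
                "cisplatin": self.score.components[0],
                "paclitaxel": self.score.components[1],
            },
            "predicted": self.predicted.value,
            "alternatives": [list(pair) for pair in self.alternatives.ranking],
            "recommendation": self.alternatives.recommendation,
            "alternative_flags": list(self.alternatives.flags),
        }


def run_two_step(
    prelim: ScreenDataset,
    secondary: ScreenDataset,
    cfg: ClassifierConfig | None = None,
) -> dict[str, OrganoidReport]:
    """Orchestrate the full two-step screen for every organoid present.

    For each organoid: preliminary viability and candidate selection, then
    per-drug GR summaries and decision-tree calls for every drug screened in
    the secondary dataset, the AUCsum chemoresistance call (cisplatin and
    paclitaxel are mandatory in the secondary screen) and the Cmax/GR100
    alternative ranking. Deterministic given its inputs.
    """
    cfg = cfg or ClassifierConfig()
    if prelim.stage is not Stage.PRELIMINARY or secondary.stage is not Stage.SECONDARY:
        raise ValidationError("run_two_step expects (PRELIMINARY, SECONDARY) datasets")
    reports: dict[str, OrganoidReport] = {}
    for organoid_id in prelim.organoids:
        profile = compute_viability(prelim, organoid_id)
        candidates = select_candidates(profile)
        drugs = secondary.drugs_for(organoid_id)
        for required in ("cisplatin", "paclitaxel"):
            if required not in drugs:
                raise MissingDrugError(
                    f"secondary screen for {organoid_id!r} lacks {required}; "
                    "AUCsum is undefined"
                )
        summaries = {drug: summarize_drug(secondary, organoid_id, drug) for drug in drugs}
        calls = {
            drug: classify_drug(summary, secondary.registry[drug], cfg)
            for drug, summary in summaries.items()
        }
        score = auc_sum(
            summaries["cisplatin"].norm_auc,
            summaries["paclitaxel"].norm_auc,
            organoid_id=organoid_id,
        )
        reports[organoid_id] = OrganoidReport(
            organoid_id=organoid_id,
            viability=profile,
            candidates=candidates,
            summaries=summaries,
            calls=calls,
            score=score,
            predicted=classify_aucsum(score, cfg),
            alternatives=rank_alternatives(list(summaries.values()), secondary.registry),
        )
    return reports
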