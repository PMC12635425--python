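"""Stage 1: single-dose viability at Cmax and candidate-drug selection.

The preliminary screen is an endpoint assay: each drug is applied at its
clinical maximum plasma concentration and viability is the ratio of treated
to negative-control ATP signal. Candidates for the secondary titration are
the drugs with viability <= 20% (boundary inclusive), ranked by inhibitory
effect and capped at three; the cisplatin + paclitaxel (TP) regimen drugs
are always carried into the secondary screen regardless of their
preliminary viability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateControlError, MissingDrugError, ValidationError
from .plate import ScreenDataset, Stage

#: Selection boundary: viability at or below this fraction qualifies.
VIABILITY_CUTOFF = 0.20
#: At most this many candidates advance beyond the TP pair.
MAX_CANDIDATES = 3
#: TP regimen drugs, always included in the secondary screen.
ALWAYS_INCLUDED = ("paclitaxel", "cisplatin")


@dataclass(frozen=True)
class ViabilityEntry:
    viability: float  # treated/NC ATP ratio
    sd: float  # replicate SD of treated signal / NC mean
    n_replicates: int


@dataclass(frozen=True)
class ViabilityProfile:
    """Per-drug viability fractions for one organoid, in registry order."""

    organoid_id: str
    entries: dict[str, ViabilityEntry]

    def viability(self, drug: str) -> float:
        try:
            return self.entries[drug].viability
        except KeyError:
            raise MissingDrugError(
                f"no viability for drug {drug!r} (organoid {self.organoid_id})"
            ) from None


@dataclass(frozen=True)
class CandidateSet:
    """Drugs advancing to secondary screening for one organoid."""

    organoid_id: str
    candidates: tuple[str, ...]
    always_included: tuple[str, ...] = ALWAYS_INCLUDED
    flags: tuple[str, ...] = ()

    @property
    def secondary_drugs(self) -> tuple[str, ...]:
        """Candidates plus the forced TP pair, deduplicated, order kept."""
        out: dict[str, None] = {}
        for name in (*self.candidates, *self.always_included):
            out.setdefault(name, None)
        return tuple(out)


def compute_viability(dataset: ScreenDataset, organoid_id: str) -> ViabilityProfile:
    """Viability = mean treated signal / mean NC signal, per drug.

    Replicates are aggregated by the arithmetic mean with no outlier
    rejection; dispersion is the replicate SD of the treated wells divided by
    the NC mean. Entries follow registry order so downstream tie-breaks are
    deterministic.
    """
    if dataset.stage is not Stage.PRELIMINARY:
        raise ValidationError("compute_viability requires a PRELIMINARY dataset")
    wells = dataset.wells_for(organoid_id)
    if not wells:
        raise MissingDrugError(f"no wells for organoid {organoid_id!r}")
    nc_signals = [w.signal for w in wells if w.is_control]
    if not nc_signals:
        raise DegenerateControlError(f"no NC wells for organoid {organoid_id!r}")
    nc_mean = float(np.mean(nc_signals))
    if nc_mean <= 0:
        raise DegenerateControlError(
            f"NC mean signal is {nc_mean} for organoid {organoid_id!r}"
        )

    entries: dict[str, ViabilityEntry] = {}
    for drug in dataset.drugs_for(organoid_id):
        sig = np.array([w.signal for w in wells if w.drug == drug], dtype=float)
        sd = float(np.std(sig, ddof=1)) / nc_mean if sig.size > 1 else 0.0
        entries[drug] = ViabilityEntry(
            viability=float(sig.mean()) / nc_mean, sd=sd, n_replicates=int(sig.size)
        )
    if not entries:
        raise MissingDrugError(f"no drug wells for organoid {organoid_id!r}")
    return ViabilityProfile(organoid_id=organoid_id, entries=entries)


def select_candidates(
    profile: ViabilityProfile,
    *,
    threshold: float = VIABILITY_CUTOFF,
    top_n: int = MAX_CANDIDATES,
    always_included: tuple[str, ...] = ALWAYS_INCLUDED,
) -> CandidateSet:
    """Apply the <=20%-then-top-3 selection rule to a viability profile.

    Qualifying drugs (viability <= ``threshold``, compared without rounding)
    are sorted ascending by viability — ties keep profile (registry) order —
    and truncated to ``top_n``. The TP pair is appended unconditionally. An
    empty qualifying set raises the ``no-candidate`` flag; a truncation that
    severs a tie raises ``tie-truncated``.
    """
    if not profile.entries:
        raise ValidationError("empty viability profile")
    qualifying = [
        (entry.viability, drug)
        for drug, entry in profile.entries.items()
        if entry.viability <= threshold
    ]
    qualifying.sort(key=lambda pair: pair[0])  # stable: ties keep profile order
    flags: list[str] = []
    selected = qualifying[:top_n]
    if len(qualifying) > top_n and qualifying[top_n][0] == selected[-1][0]:
        flags.append("tie-truncated")
    if not selected:
        flags.append("no-candidate")
    return CandidateSet(
        organoid_id=profile.organoid_id,
        candidates=tuple(drug for _, drug in selected),
        always_included=always_included,
        flags=tuple(flags),
    )
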