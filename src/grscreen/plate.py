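"""Plate-level data model: drugs, wells, screen datasets and their CSV I/O.

Concentrations are micromolar (µM) throughout — there is deliberately no unit
conversion layer. Well tables are long/tidy (one well per row); plate
geometry is not modelled because nothing downstream uses positional
information.

The built-in ``table2`` registry carries the ten screening compounds with
their clinical maximum plasma concentration (Cmax, the single preliminary
screening dose) and the top dose of the six-point fourfold secondary
titration.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import pandas as pd

from .errors import FormatError, RegistryError, ValidationError

#: Drug tag used for vehicle-only negative-control wells.
NC_TAG = "NC"

CSV_COLUMNS = ("organoid_id", "drug", "concentration_uM", "timepoint", "replicate", "signal")
REGISTRY_COLUMNS = ("name", "cmax_uM", "secondary_start_uM", "dilution_factor", "n_points")


class Timepoint(str, enum.Enum):
    """When a well's ATP luminescence was read: treatment start or end."""

    T0 = "T0"
    TEND = "TEND"


class Stage(str, enum.Enum):
    """Screening stage: single-dose preliminary or titrated secondary."""

    PRELIMINARY = "PRELIMINARY"
    SECONDARY = "SECONDARY"


@dataclass(frozen=True)
class DrugSpec:
    """A screening compound: identity, clinical Cmax and titration design.

    Parameters
    ----------
    name:
        Unique identifier within a registry.
    cmax:
        Maximum plasma concentration (µM); the preliminary screening dose and
        the clinical reference in the Cmax/GR100 index.
    secondary_start:
        Top dose (µM) of the secondary serial dilution.
    dilution_factor:
        Ratio between consecutive titration doses (default fourfold).
    n_points:
        Number of titration doses (default six).
    """

    name: str
    cmax: float
    secondary_start: float
    dilution_factor: float = 4.0
    n_points: int = 6

    def __post_init__(self) -> None:
        if not self.name:
            raise ValidationError("drug name must be non-empty")
        if not self.cmax > 0:
            raise ValidationError(f"{self.name}: cmax must be > 0, got {self.cmax}")
        if not self.secondary_start > 0:
            raise ValidationError(
                f"{self.name}: secondary_start must be > 0, got {self.secondary_start}"
            )
        if not self.dilution_factor > 1:
            raise ValidationError(
                f"{self.name}: dilution_factor must be > 1, got {self.dilution_factor}"
            )
        if self.n_points < 1:
            raise ValidationError(f"{self.name}: n_points must be >= 1, got {self.n_points}")


def dilution_series(spec: DrugSpec) -> list[float]:
    """Descending geometric dose series for a drug's secondary titration.

    Returns ``n_points`` concentrations starting at ``secondary_start`` and
    dividing by ``dilution_factor`` at each step, e.g. 50, 12.5, 3.125, ...
    """
    return [spec.secondary_start / spec.dilution_factor**i for i in range(spec.n_points)]


class DrugRegistry:
    """Ordered collection of :class:`DrugSpec`, unique by name.

    Registry order is the declared tie-break order everywhere a deterministic
    ordering among drugs is needed (candidate selection, rankings).
    """

    def __init__(self, drugs: Iterable[DrugSpec]):
        self._drugs: dict[str, DrugSpec] = {}
        for spec in drugs:
            if spec.name in self._drugs:
                raise RegistryError(f"duplicate drug name: {spec.name!r}")
            self._drugs[spec.name] = spec

    def __iter__(self) -> Iterator[DrugSpec]:
        return iter(self._drugs.values())

    def __len__(self) -> int:
        return len(self._drugs)

    def __contains__(self, name: object) -> bool:
        return name in self._drugs

    def __getitem__(self, name: str) -> DrugSpec:
        try:
            return self._drugs[name]
        except KeyError:
            raise RegistryError(f"unknown drug: {name!r}") from None

    @property
    def names(self) -> list[str]:
        return list(self._drugs)

    def order(self, name: str) -> int:
        """Position of *name* in registry order (used for tie-breaking)."""
        try:
            return self.names.index(name)
        except ValueError:
            raise RegistryError(f"unknown drug: {name!r}") from None

    @classmethod
    def from_csv(cls, path: str | Path) -> "DrugRegistry":
        df = pd.read_csv(path)
        missing = [c for c in REGISTRY_COLUMNS[:3] if c not in df.columns]
        if missing:
            raise FormatError(f"registry file missing column(s): {', '.join(missing)}")
        drugs = []
        for row in df.itertuples(index=False):
            kwargs = dict(
                name=str(row.name),
                cmax=float(row.cmax_uM),
                secondary_start=float(row.secondary_start_uM),
            )
            if "dilution_factor" in df.columns and not pd.isna(getattr(row, "dilution_factor")):
                kwargs["dilution_factor"] = float(row.dilution_factor)
            if "n_points" in df.columns and not pd.isna(getattr(row, "n_points")):
                kwargs["n_points"] = int(row.n_points)
            drugs.append(DrugSpec(**kwargs))
        return cls(drugs)

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame(
            [
                (d.name, d.cmax, d.secondary_start, d.dilution_factor, d.n_points)
                for d in self
            ],
            columns=list(REGISTRY_COLUMNS),
        ).to_csv(path, index=False)


# The ten screening compounds: (name, Cmax µM, secondary top dose µM).
_TABLE2_ROWS = (
    ("cisplatin", 13.67, 50.0),
    ("paclitaxel", 5.10, 50.0),
    ("fluorouracil", 7.5, 50.0),
    ("SN-38", 0.15, 5.0),
    ("fedratinib", 3.44, 50.0),
    ("gemcitabine", 101.04, 750.0),
    ("epirubicin", 0.16, 5.0),
    ("doxorubicin", 6.90, 50.0),
    ("palbociclib", 0.22, 5.0),
    ("docetaxel", 2.98, 50.0),
)


def builtin_registry() -> DrugRegistry:
    """The packaged ten-drug registry (fourfold six-point titrations)."""
    return DrugRegistry(DrugSpec(name, cmax, start) for name, cmax, start in _TABLE2_ROWS)


def load_registry(source: str | Path) -> DrugRegistry:
    """Load a registry from a CSV path, or the builtin tag ``"table2"``."""
    if str(source) == "table2":
        return builtin_registry()
    path = Path(source)
    if not path.exists():
        raise FormatError(f"registry file not found: {path}")
    return DrugRegistry.from_csv(path)


@dataclass(frozen=True)
class WellMeasurement:
    """A single well's luminescence read (ATP proxy for viable cell mass)."""

    organoid_id: str
    drug: str
    concentration: float  # µM; 0 for NC wells
    timepoint: Timepoint
    replicate: int
    signal: float

    def __post_init__(self) -> None:
        if self.signal < 0:
            raise ValidationError(
                f"negative signal {self.signal} (well {self.organoid_id}/{self.drug})"
            )
        if self.concentration < 0:
            raise ValidationError(f"negative concentration {self.concentration}")
        if self.drug == NC_TAG and self.concentration != 0:
            raise ValidationError("NC wells must have concentration 0")
        if self.replicate < 1:
            raise ValidationError(f"replicate must be >= 1, got {self.replicate}")

    @property
    def is_control(self) -> bool:
        return self.drug == NC_TAG


@dataclass(frozen=True)
class ScreenDataset:
    """A validated set of well measurements for one screening stage."""

    stage: Stage
    wells: tuple[WellMeasurement, ...]
    registry: DrugRegistry

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        for w in self.wells:
            if not w.is_control and w.drug not in self.registry:
                raise ValidationError(f"well drug {w.drug!r} not in registry")
        if self.stage is Stage.PRELIMINARY:
            concs: dict[str, set[float]] = {}
            for w in self.wells:
                if not w.is_control:
                    concs.setdefault(w.drug, set()).add(w.concentration)
            for drug, cset in concs.items():
                if len(cset) != 1:
                    raise ValidationError(
                        f"preliminary screen must use a single dose per drug; "
                        f"{drug} has {sorted(cset)}"
                    )
        elif self.stage is Stage.SECONDARY:
            nc_tp = {w.timepoint for w in self.wells if w.is_control}
            if self.wells and nc_tp != {Timepoint.T0, Timepoint.TEND}:
                raise ValidationError(
                    "secondary screen requires NC wells at both T0 and TEND"
                )

    @property
    def organoids(self) -> list[str]:
        seen: dict[str, None] = {}
        for w in self.wells:
            seen.setdefault(w.organoid_id, None)
        return list(seen)

    def wells_for(self, organoid_id: str, drug: str | None = None) -> list[WellMeasurement]:
        return [
            w
            for w in self.wells
            if w.organoid_id == organoid_id and (drug is None or w.drug == drug)
        ]

    def drugs_for(self, organoid_id: str) -> list[str]:
        """Non-control drugs screened for an organoid, in registry order."""
        present = {w.drug for w in self.wells if w.organoid_id == organoid_id and not w.is_control}
        return [name for name in self.registry.names if name in present]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (w.organoid_id, w.drug, w.concentration, w.timepoint.value, w.replicate, w.signal)
                for w in self.wells
            ],
            columns=list(CSV_COLUMNS),
        )


def read_screen_csv(
    path: str | Path, stage: Stage | str, registry: DrugRegistry | None = None
) -> ScreenDataset:
    """Read a long-format well table into a validated :class:`ScreenDataset`.

    The CSV must carry the header columns ``organoid_id, drug,
    concentration_uM, timepoint, replicate, signal``; ``timepoint`` tokens are
    ``T0``/``TEND``. ``registry`` defaults to the builtin ten-drug registry.
    """
    stage = Stage(stage)
    registry = registry if registry is not None else builtin_registry()
    path = Path(path)
    if not path.exists():
        raise FormatError(f"input file not found: {path}")
    df = pd.read_csv(path)
    missing = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"missing column(s): {', '.join(missing)}")
    wells = []
    for row in df.itertuples(index=False):
        try:
            tp = Timepoint(str(row.timepoint))
        except ValueError:
            raise FormatError(f"unknown timepoint tag: {row.timepoint!r}") from None
        wells.append(
            WellMeasurement(
                organoid_id=str(row.organoid_id),
                drug=str(row.drug),
                concentration=float(row.concentration_uM),
                timepoint=tp,
                replicate=int(row.replicate),
                signal=float(row.signal),
            )
        )
    return ScreenDataset(stage=stage, wells=tuple(wells), registry=registry)


def write_screen_csv(dataset: ScreenDataset, path: str | Path) -> None:
    """Write a dataset back to the long CSV dialect (UTF-8, '.' decimals)."""
    dataset.to_frame().to_csv(path, index=False)
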