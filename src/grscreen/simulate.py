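"""Generative model for every input the pipeline consumes.

The simulator is the exact generative inverse of the GR transform. Each
virtual organoid grows exponentially over the assay window with control
division rate ``k0`` (doublings/day); a drug at concentration ``c`` rescales
the division rate through its true GR sigmoid::

    GR_true(c) = gr_inf + (1 - gr_inf) / (1 + (c/gec50)^hill)
    k(c)       = k0 * log2(GR_true(c) + 1)
    x(c)       = x0 * 2^(k(c) * duration)

so that applying the GR transform to noiseless simulated signals returns
``GR_true`` exactly — the pipeline's correctness can be checked against
ground truth. Measurement noise is multiplicative lognormal (mean one) on
the luminescence, the standard error model for ATP luminescence plate
reads; seeding-density variation is folded into the same term.

Cohort generation draws a latent sensitive/resistant class per patient:
resistant organoids get weak-effect TP parameters (gr_inf near 0, gec50 far
above Cmax), sensitive ones strong-effect parameters (gr_inf < -0.5, gec50
far below Cmax). The recorded clinical response equals the latent class,
flipped with a configurable probability to emulate organoid/clinic
discordance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .concordance import ClinicalRecord, Group, JSEDGrade, Response
from .errors import ValidationError
from .plate import (
    NC_TAG,
    DrugRegistry,
    ScreenDataset,
    Stage,
    Timepoint,
    WellMeasurement,
    builtin_registry,
    dilution_series,
)

#: Floor applied to GR_true + 1 before taking log2 (complete-kill limit).
GROWTH_FLOOR = 1e-12


@dataclass(frozen=True)
class DrugTruth:
    """True sigmoid parameters for one organoid-drug pair."""

    gr_inf: float
    gec50: float  # µM
    hill: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.gr_inf <= 1.0:
            raise ValidationError(f"gr_inf must be in [-1, 1], got {self.gr_inf}")
        if not self.gec50 > 0:
            raise ValidationError(f"gec50 must be > 0, got {self.gec50}")
        if not self.hill > 0:
            raise ValidationError(f"hill must be > 0, got {self.hill}")

    def gr(self, conc: float) -> float:
        if conc <= 0:
            return 1.0
        return self.gr_inf + (1.0 - self.gr_inf) / (1.0 + (conc / self.gec50) ** self.hill)


@dataclass(frozen=True)
class SimOrganoid:
    organoid_id: str
    k0: float  # control division rate, doublings/day
    t0_signal_mean: float  # luminescence per seeded well
    drug_truths: dict  # drug -> DrugTruth

    def __post_init__(self) -> None:
        if not self.k0 > 0:
            raise ValidationError(f"k0 must be > 0, got {self.k0}")
        if not self.t0_signal_mean > 0:
            raise ValidationError(f"t0_signal_mean must be > 0, got {self.t0_signal_mean}")


@dataclass(frozen=True)
class SimDesign:
    """Plate design: assay window, replication and measurement noise."""

    stage: Stage = Stage.SECONDARY
    duration: float = 4.0  # days of drug exposure
    replicates: int = 3
    noise_cv: float = 0.08  # lognormal CV of the luminescence read
    seed: int | None = None

    def __post_init__(self) -> None:
        if not self.duration > 0:
            raise ValidationError(f"duration must be > 0, got {self.duration}")
        if self.replicates < 1:
            raise ValidationError(f"replicates must be >= 1, got {self.replicates}")
        if self.noise_cv < 0:
            raise ValidationError(f"noise_cv must be >= 0, got {self.noise_cv}")


@dataclass(frozen=True)
class SimCohort:
    """Cohort structure: 24 evaluable patients, 14/24 resistant, and a
    1-in-6 chance that the clinic contradicts the latent class — the scale
    and discordance rate typical of a perioperative-chemotherapy cohort."""

    n_patients: int = 24
    resistant_fraction: float = 14 / 24
    label_flip_prob: float = 1 / 6

    def __post_init__(self) -> None:
        if self.n_patients < 2:
            raise ValidationError("n_patients must be >= 2")
        for name in ("resistant_fraction", "label_flip_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name} must be in [0, 1], got {v}")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def _noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Mean-one multiplicative lognormal noise with coefficient of variation cv."""
    if cv == 0:
        return np.ones(size)
    sigma = math.sqrt(math.log(1.0 + cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_organoid(
    registry: DrugRegistry | None = None,
    seed: int | np.random.Generator | None = None,
    *,
    organoid_id: str = "SIM-1",
    k0_range: tuple[float, float] = (0.3, 0.7),
    t0_mean_range: tuple[float, float] = (800.0, 1200.0),
    gec50_log10_range: tuple[float, float] = (-2.0, 2.0),
    hill_range: tuple[float, float] = (0.5, 4.0),
    gr_inf_range: tuple[float, float] = (-1.0, 0.5),
) -> SimOrganoid:
    """Reproducible draw of an organoid's division rate, baseline signal and
    per-drug true dose-response parameters (gec50 log-uniform)."""
    for name, (lo, hi) in (
        ("k0_range", k0_range),
        ("t0_mean_range", t0_mean_range),
        ("gec50_log10_range", gec50_log10_range),
        ("hill_range", hill_range),
        ("gr_inf_range", gr_inf_range),
    ):
        if not lo <= hi:
            raise ValidationError(f"invalid bounds for {name}: {(lo, hi)}")
    if not -1.0 <= gr_inf_range[0] <= gr_inf_range[1] <= 1.0:
        raise ValidationError(f"gr_inf_range must lie in [-1, 1], got {gr_inf_range}")
    registry = registry if registry is not None else builtin_registry()
    rng = _rng(seed)
    k0 = float(rng.uniform(*k0_range))
    t0_mean = float(rng.uniform(*t0_mean_range))
    truths = {
        spec.name: DrugTruth(
            gr_inf=float(rng.uniform(*gr_inf_range)),
            gec50=float(10.0 ** rng.uniform(*gec50_log10_range)),
            hill=float(rng.uniform(*hill_range)),
        )
        for spec in registry
    }
    return SimOrganoid(
        organoid_id=organoid_id, k0=k0, t0_signal_mean=t0_mean, drug_truths=truths
    )


def _tend_signal(org: SimOrganoid, truth: DrugTruth, conc: float, duration: float) -> float:
    growth = max(truth.gr(conc) + 1.0, GROWTH_FLOOR)
    k = org.k0 * math.log2(growth)
    return org.t0_signal_mean * 2.0 ** (k * duration)


def simulate_screen(
    org: SimOrganoid,
    design: SimDesign,
    registry: DrugRegistry | None = None,
    *,
    drugs: list[str] | None = None,
    seed: int | np.random.Generator | None = None,
) -> ScreenDataset:
    """Simulate one organoid's plate for the given stage.

    SECONDARY plates carry paired T0 and TEND NC wells plus a full titration
    per drug; PRELIMINARY plates are endpoint-only (TEND), each drug at its
    Cmax plus NC wells. With ``noise_cv = 0`` the GR transform applied to
    the output recovers each drug's true GR exactly.
    """
    registry = registry if registry is not None else builtin_registry()
    rng = _rng(seed if seed is not None else design.seed)
    names = drugs if drugs is not None else registry.names
    wells: list[WellMeasurement] = []
    reps = design.replicates

    def add(drug: str, conc: float, timepoint: Timepoint, mean_signal: float) -> None:
        for rep, eps in enumerate(_noise(rng, design.noise_cv, reps), start=1):
            wells.append(
                WellMeasurement(
                    organoid_id=org.organoid_id,
                    drug=drug,
                    concentration=conc,
                    timepoint=timepoint,
                    replicate=rep,
                    signal=mean_signal * float(eps),
                )
            )

    nc_end = org.t0_signal_mean * 2.0 ** (org.k0 * design.duration)
    if design.stage is Stage.SECONDARY:
        add(NC_TAG, 0.0, Timepoint.T0, org.t0_signal_mean)
        add(NC_TAG, 0.0, Timepoint.TEND, nc_end)
        for name in names:
            truth = org.drug_truths[name]
            for conc in dilution_series(registry[name]):
                add(name, conc, Timepoint.TEND, _tend_signal(org, truth, conc, design.duration))
    else:
        add(NC_TAG, 0.0, Timepoint.TEND, nc_end)
        for name in names:
            spec = registry[name]
            truth = org.drug_truths[name]
            add(name, spec.cmax, Timepoint.TEND,
                _tend_signal(org, truth, spec.cmax, design.duration))
    return ScreenDataset(stage=design.stage, wells=tuple(wells), registry=registry)


# Weak-effect (resistant) and strong-effect (sensitive) TP parameter regimes,
# expressed relative to each drug's Cmax so the separation is dose-meaningful.
_RESISTANT_REGIME = dict(gr_inf=(-0.1, 0.3), gec50_over_cmax=(10.0, 100.0), hill=(1.0, 3.0))
_SENSITIVE_REGIME = dict(gr_inf=(-1.0, -0.6), gec50_over_cmax=(0.01, 0.1), hill=(1.0, 3.0))

_TP_DRUGS = ("cisplatin", "paclitaxel")


@dataclass(frozen=True)
class CohortData:
    preliminary: ScreenDataset
    secondary: ScreenDataset
    clinical: tuple[ClinicalRecord, ...]
    truth: pd.DataFrame  # one row per patient: latent class, k0, TP truths


def _draw_truth(rng: np.random.Generator, cmax: float, regime: dict) -> DrugTruth:
    return DrugTruth(
        gr_inf=float(rng.uniform(*regime["gr_inf"])),
        gec50=float(cmax * rng.uniform(*regime["gec50_over_cmax"])),
        hill=float(rng.uniform(*regime["hill"])),
    )


def simulate_cohort(
    cohort: SimCohort,
    registry: DrugRegistry | None = None,
    design: SimDesign | None = None,
    seed: int | np.random.Generator | None = None,
) -> CohortData:
    """Simulate a patient cohort: paired preliminary/secondary plates,
    clinical records and a ground-truth table for recovery scoring.

    Half the patients are assigned to the NAT group (their response is
    recorded as a histological grade consistent with the binary outcome),
    half to the treatment-naive group (binary follow-up response directly).
    """
    registry = registry if registry is not None else builtin_registry()
    design = design if design is not None else SimDesign()
    rng = _rng(seed)
    prelim_design = SimDesign(
        stage=Stage.PRELIMINARY,
        duration=design.duration,
        replicates=design.replicates,
        noise_cv=design.noise_cv,
    )

    prelim_wells: list[WellMeasurement] = []
    secondary_wells: list[WellMeasurement] = []
    clinical: list[ClinicalRecord] = []
    truth_rows: list[dict] = []
    resistant_draws = rng.random(cohort.n_patients) < cohort.resistant_fraction
    flip_draws = rng.random(cohort.n_patients) < cohort.label_flip_prob

    for i in range(cohort.n_patients):
        organoid_id = f"SIM{i + 1:02d}"
        resistant = bool(resistant_draws[i])
        org = simulate_organoid(registry, rng, organoid_id=organoid_id)
        regime = _RESISTANT_REGIME if resistant else _SENSITIVE_REGIME
        truths = dict(org.drug_truths)
        for name in _TP_DRUGS:
            truths[name] = _draw_truth(rng, registry[name].cmax, regime)
        org = SimOrganoid(
            organoid_id=organoid_id,
            k0=org.k0,
            t0_signal_mean=org.t0_signal_mean,
            drug_truths=truths,
        )
        prelim_wells.extend(simulate_screen(org, prelim_design, registry, seed=rng).wells)
        secondary_wells.extend(simulate_screen(org, design, registry, seed=rng).wells)

        latent = Response.POOR if resistant else Response.GOOD
        observed = latent
        if flip_draws[i]:
            observed = Response.GOOD if latent is Response.POOR else Response.POOR
        if i % 2 == 0:  # NAT patient: outcome recorded as a histological grade
            grade = (
                JSEDGrade(rng.choice(["G2", "G3"]))
                if observed is Response.GOOD
                else JSEDGrade(rng.choice(["G0", "G1a", "G1b"]))
            )
            clinical.append(
                ClinicalRecord(patient_id=organoid_id, group=Group.NAT, jsed_grade=grade)
            )
        else:
            clinical.append(
                ClinicalRecord(
                    patient_id=organoid_id, group=Group.TREATMENT_NAIVE, response=observed
                )
            )
        row = {
            "organoid_id": organoid_id,
            "latent_class": "RESISTANT" if resistant else "SENSITIVE",
            "clinical_response": observed.value,
            "label_flipped": bool(flip_draws[i]),
            "k0": org.k0,
            "t0_signal_mean": org.t0_signal_mean,
        }
        for name in _TP_DRUGS:
            t = truths[name]
            row.update(
                {
                    f"{name}_gr_inf": t.gr_inf,
                    f"{name}_gec50": t.gec50,
                    f"{name}_hill": t.hill,
                }
            )
        truth_rows.append(row)

    return CohortData(
        preliminary=ScreenDataset(Stage.PRELIMINARY, tuple(prelim_wells), registry),
        secondary=ScreenDataset(Stage.SECONDARY, tuple(secondary_wells), registry),
        clinical=tuple(clinical),
        truth=pd.DataFrame(truth_rows),
    )
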