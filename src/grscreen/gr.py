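"""Stage 2 analytics: GR transform, sigmoid fits, GR metrics and AUC scores.

The growth-rate-inhibition value normalises a drug effect to the control
division rate, which makes it invariant to seeding density and assay
duration as long as growth is exponential over the window::

    GR(c) = 2 ** ( log2(x(c)/x0) / log2(x_ctrl/x0) ) - 1

with ``x0`` the mean start-of-treatment ATP signal, ``x_ctrl`` the mean
end-of-treatment negative-control signal and ``x(c)`` the treated signal.
GR = 1 means no effect, 0 complete cytostasis, -1 complete kill.

Fitted dose-response metrics:

* ``GRmax`` — minimum observed mean GR across tested doses (maximal effect).
* ``GR50`` / ``GR100`` — concentrations at which the fitted sigmoid
  ``GR(c) = gr_inf + (1 - gr_inf) / (1 + (c/gec50)^hill)`` crosses 0.5 / 0.
  GR100 (complete growth-rate inhibition) is a concentration directly
  comparable with Cmax; Cmax/GR100 >> 1 means full growth arrest is reached
  well below clinically attainable exposure.
* ``norm_auc`` — trapezoidal area under the raw viability-vs-log10(dose)
  curve divided by the maximal possible area (1 = fully resistant,
  0 = fully sensitive).
* ``AUCsum`` — cisplatin norm_auc + paclitaxel norm_auc, the patient-level
  chemoresistance score for the TP regimen.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares

from .errors import (
    InsufficientDataError,
    MissingDrugError,
    NoGrowthError,
    ValidationError,
)
from .plate import DrugSpec, ScreenDataset, Stage, Timepoint

#: Smallest usable treated signal, as a fraction of x0, when a well reads <= 0.
SIGNAL_FLOOR_FRACTION = 1e-6

#: Minimum observed mean-GR dynamic range for a sigmoid fit to be trusted.
MIN_GR_RANGE = 0.1


def gr_value(x0: float, x_ctrl: float, x_c: float, *, signal_floor: float | None = None) -> float:
    """Growth-rate-inhibition value from paired start/end ATP reads.

    Parameters
    ----------
    x0:
        Mean signal at the start of treatment (must be > 0).
    x_ctrl:
        Mean negative-control signal at the end of treatment; must exceed
        ``x0`` (the control population has to grow for GR to be defined).
    x_c:
        Treated signal at the end of treatment. Non-positive values raise
        unless ``signal_floor`` is given, in which case they are clamped.
    """
    if x0 <= 0:
        raise ValidationError(f"x0 must be > 0, got {x0}")
    if x_ctrl <= x0:
        raise NoGrowthError(
            f"control did not grow (x_ctrl={x_ctrl} <= x0={x0}); GR undefined"
        )
    if x_c <= 0:
        if signal_floor is None:
            raise ValidationError(f"treated signal must be > 0, got {x_c}")
        x_c = signal_floor
    return float(2.0 ** (math.log2(x_c / x0) / math.log2(x_ctrl / x0)) - 1.0)


@dataclass(frozen=True)
class GRPoint:
    concentration: float  # µM
    gr_mean: float
    gr_replicates: tuple[float, ...]


@dataclass(frozen=True)
class GRProfile:
    """Per-concentration GR values for one (organoid, drug) pair."""

    organoid_id: str
    drug: str
    points: tuple[GRPoint, ...]  # ascending concentration
    x0: float
    x_ctrl: float
    flags: tuple[str, ...] = ()

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([p.concentration for p in self.points])

    @property
    def gr_means(self) -> np.ndarray:
        return np.array([p.gr_mean for p in self.points])


def build_gr_profile(dataset: ScreenDataset, organoid_id: str, drug: str) -> GRProfile:
    """Aggregate a secondary-screen dataset into a GR profile.

    ``x0`` is the mean of all start-of-treatment reads for the organoid and
    ``x_ctrl`` the mean end-of-treatment NC read; per-well GR values are
    averaged within each concentration. Wells reading <= 0 are clamped to a
    small positive floor and flagged ``clamped-signal``.
    """
    if dataset.stage is not Stage.SECONDARY:
        raise ValidationError("build_gr_profile requires a SECONDARY dataset")
    wells = dataset.wells_for(organoid_id)
    if not wells:
        raise MissingDrugError(f"no wells for organoid {organoid_id!r}")
    t0 = [w.signal for w in wells if w.timepoint is Timepoint.T0]
    ctrl = [w.signal for w in wells if w.timepoint is Timepoint.TEND and w.is_control]
    if not t0:
        raise ValidationError(f"no T0 wells for organoid {organoid_id!r}")
    if not ctrl:
        raise ValidationError(f"no TEND NC wells for organoid {organoid_id!r}")
    x0 = float(np.mean(t0))
    x_ctrl = float(np.mean(ctrl))
    treated = [
        w
        for w in wells
        if w.drug == drug and w.timepoint is Timepoint.TEND and not w.is_control
    ]
    if not treated:
        raise MissingDrugError(f"no {drug!r} wells for organoid {organoid_id!r}")

    floor = x0 * SIGNAL_FLOOR_FRACTION
    flags: list[str] = []
    by_conc: dict[float, list[float]] = {}
    for w in treated:
        if w.signal <= 0:
            flags.append("clamped-signal")
        gr = gr_value(x0, x_ctrl, w.signal, signal_floor=floor)
        by_conc.setdefault(w.concentration, []).append(gr)
    points = tuple(
        GRPoint(concentration=c, gr_mean=float(np.mean(v)), gr_replicates=tuple(v))
        for c, v in sorted(by_conc.items())
    )
    return GRProfile(
        organoid_id=organoid_id,
        drug=drug,
        points=points,
        x0=x0,
        x_ctrl=x_ctrl,
        flags=tuple(dict.fromkeys(flags)),
    )


@dataclass(frozen=True)
class GRCurveFit:
    """Three-parameter GR sigmoid fit (asymptote, midpoint, slope)."""

    gr_inf: float
    gec50: float  # µM
    hill: float
    converged: bool
    rss: float

    def predict(self, conc: np.ndarray | float) -> np.ndarray | float:
        conc = np.asarray(conc, dtype=float)
        with np.errstate(divide="ignore"):
            ratio = np.where(conc > 0, conc / self.gec50, 0.0)
        return self.gr_inf + (1.0 - self.gr_inf) / (1.0 + ratio**self.hill)


def _sigmoid_residuals(params: np.ndarray, logc: np.ndarray, gr: np.ndarray) -> np.ndarray:
    gr_inf, log_gec50, hill = params
    return gr_inf + (1.0 - gr_inf) / (1.0 + 10.0 ** ((logc - log_gec50) * hill)) - gr


def fit_gr_curve(profile: GRProfile) -> GRCurveFit:
    """Least-squares fit of the GR sigmoid on log10 concentration.

    Requires at least four distinct concentrations. Multiple starts over the
    Hill slope and midpoint guard against local minima; if the optimiser
    fails or the observed GR range is too flat to constrain a sigmoid, a
    flat-model fallback (``gr_inf`` = mean GR, ``converged=False``) is
    returned rather than a spurious fit.
    """
    concs = profile.concentrations
    gr = profile.gr_means
    if len(concs) < 4:
        raise InsufficientDataError(
            f"need >= 4 distinct concentrations, got {len(concs)}"
        )
    logc = np.log10(concs)
    flat = GRCurveFit(
        gr_inf=float(gr.mean()),
        gec50=float(10 ** logc.mean()),
        hill=1.0,
        converged=False,
        rss=float(((gr - gr.mean()) ** 2).sum()),
    )
    if gr.max() - gr.min() < MIN_GR_RANGE:
        return flat

    lo = np.array([-1.0, logc.min() - 4.0, 0.05])
    hi = np.array([1.0, logc.max() + 4.0, 10.0])
    gr_inf0 = float(np.clip(gr.min(), -1.0, 1.0))
    best: tuple[float, np.ndarray] | None = None
    mids = [float(logc.mean()), float(logc.min()), float(logc.max())]
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        for mid0 in mids:
            p0 = np.clip(np.array([gr_inf0, mid0, hill0]), lo, hi)
            try:
                res = least_squares(
                    _sigmoid_residuals,
                    p0,
                    args=(logc, gr),
                    bounds=(lo, hi),
                    xtol=1e-14,
                    ftol=1e-14,
                    gtol=1e-14,
                )
            except Exception:  # numerical failure on this start only
                continue
            rss = float((res.fun**2).sum())
            if res.success and (best is None or rss < best[0]):
                best = (rss, res.x)
                if rss < 1e-18:  # exact fit found; further starts cannot improve
                    break
        if best is not None and best[0] < 1e-18:
            break
    if best is None:
        return flat
    rss, (gr_inf, log_gec50, hill) = best
    return GRCurveFit(
        gr_inf=float(gr_inf),
        gec50=float(10**log_gec50),
        hill=float(hill),
        converged=True,
        rss=rss,
    )


def solve_gr_level(fit: GRCurveFit, level: float) -> float | None:
    """Concentration where the fitted sigmoid equals *level* (closed form).

    Returns ``None`` when the curve never reaches the level (asymptote above
    it, or level >= 1).
    """
    if not (fit.gr_inf < level < 1.0):
        return None
    ratio = (1.0 - level) / (level - fit.gr_inf)
    return float(fit.gec50 * ratio ** (1.0 / fit.hill))


def _interpolate_crossing(concs: np.ndarray, gr: np.ndarray, level: float) -> float | None:
    """Log-linear interpolation between the first pair bracketing *level*."""
    for i in range(len(concs) - 1):
        g0, g1 = gr[i], gr[i + 1]
        if (g0 - level) * (g1 - level) <= 0 and g0 != g1:
            t = (level - g0) / (g1 - g0)
            logc = math.log10(concs[i]) + t * (math.log10(concs[i + 1]) - math.log10(concs[i]))
            return float(10**logc)
    return None


@dataclass(frozen=True)
class DrugResponseSummary:
    """Derived per-(organoid, drug) response metrics."""

    organoid_id: str
    drug: str
    grmax: float
    gr50: float | None  # µM; None when the fitted curve never reaches 0.5
    gr100: float | None  # µM; None when complete cytostasis is never reached
    norm_auc: float | None
    cmax_over_gr100: float
    flags: tuple[str, ...] = ()


def gr_metrics(
    fit: GRCurveFit,
    profile: GRProfile,
    spec: DrugSpec,
    *,
    norm_auc: float | None = None,
    extrapolation_factor: float = 4.0,
) -> DrugResponseSummary:
    """Summarise a fitted GR curve into GRmax, GR50, GR100 and Cmax/GR100.

    GR50/GR100 are the closed-form roots of the fitted sigmoid. When the fit
    did not converge but the measured points bracket the level, a log-linear
    interpolation between the bracketing doses is used instead (flag
    ``interpolated``). Crossings outside the tested dose range are still
    reported but flagged ``extrapolated``; more than one dilution step
    outside additionally emits a warning. ``cmax_over_gr100`` is defined as
    0 when GR100 is absent (a drug that never halts net growth cannot be
    recommended at any dose).
    """
    if profile.drug != spec.name:
        raise ValidationError(
            f"profile drug {profile.drug!r} does not match spec {spec.name!r}"
        )
    concs = profile.concentrations
    gr = profile.gr_means
    grmax = float(gr.min())
    flags: list[str] = list(profile.flags)

    levels: dict[str, float | None] = {}
    for key, level in (("gr50", 0.5), ("gr100", 0.0)):
        if fit.converged:
            crossing = solve_gr_level(fit, level)
        else:
            crossing = _interpolate_crossing(concs, gr, level)
            if crossing is not None:
                flags.append("interpolated")
        if crossing is not None:
            cmin, cmax_tested = float(concs.min()), float(concs.max())
            if not (cmin <= crossing <= cmax_tested):
                step = extrapolation_factor
                flags.append("extrapolated")
                if crossing < cmin / step or crossing > cmax_tested * step:
                    warnings.warn(
                        f"{profile.organoid_id}/{spec.name}: {key} crossing "
                        f"{crossing:.4g} µM is more than one dilution step outside "
                        f"the tested range [{cmin:.4g}, {cmax_tested:.4g}] µM",
                        stacklevel=2,
                    )
        levels[key] = crossing

    gr100 = levels["gr100"]
    cmax_over_gr100 = spec.cmax / gr100 if gr100 is not None and gr100 > 0 else 0.0
    return DrugResponseSummary(
        organoid_id=profile.organoid_id,
        drug=profile.drug,
        grmax=grmax,
        gr50=levels["gr50"],
        gr100=gr100,
        norm_auc=norm_auc,
        cmax_over_gr100=float(cmax_over_gr100),
        flags=tuple(dict.fromkeys(flags)),
    )


def normalized_auc(concs, viability) -> float:
    """Normalized area under the viability-vs-log10(dose) curve.

    Viability fractions are clipped to [0, 1] (with a warning) and integrated
    by the trapezoid rule over log10 concentration; the integral is divided
    by the maximal possible area (viability 1 over the full log span), so the
    result lies in [0, 1] and is invariant to the ordering of the input.
    """
    concs = np.asarray(concs, dtype=float)
    v = np.asarray(viability, dtype=float)
    if concs.shape != v.shape:
        raise ValidationError("concs and viability must have equal length")
    if concs.size < 2:
        raise InsufficientDataError("normalized AUC needs >= 2 concentrations")
    if np.any(concs <= 0):
        raise ValidationError("concentrations must be positive")
    order = np.argsort(concs)
    concs, v = concs[order], v[order]
    if np.any(np.diff(concs) == 0):
        raise ValidationError("duplicate concentrations in AUC input")
    if np.any((v < 0) | (v > 1)):
        warnings.warn("viability values outside [0, 1] clipped before integration",
                      stacklevel=2)
        v = np.clip(v, 0.0, 1.0)
    x = np.log10(concs)
    return float(np.trapezoid(v, x) / (x[-1] - x[0]))


@dataclass(frozen=True)
class ViabilityCurveFit:
    """Two-free-parameter log-logistic viability fit (top 100%, bottom 0%)."""

    ec50: float  # µM
    hill: float
    converged: bool
    top: float = 100.0
    bottom: float = 0.0

    def predict(self, conc) -> np.ndarray:
        conc = np.asarray(conc, dtype=float)
        return self.top / (1.0 + (conc / self.ec50) ** self.hill)


def fit_viability_curve(concs, viability_pct) -> ViabilityCurveFit:
    """Fit viability(%) = 100 / (1 + (c/EC50)^h) with the activity range
    constrained to [0, 100]%. Used for reporting/plots; AUC scoring always
    uses the raw points."""
    concs = np.asarray(concs, dtype=float)
    v = np.asarray(viability_pct, dtype=float)
    if concs.size < 3:
        raise InsufficientDataError("viability fit needs >= 3 concentrations")
    logc = np.log10(concs)

    def residuals(params):
        log_ec50, hill = params
        return 100.0 / (1.0 + 10.0 ** ((logc - log_ec50) * hill)) - v

    best = None
    for hill0 in (0.5, 1.0, 2.0, 4.0):
        try:
            res = least_squares(
                residuals,
                x0=[float(logc.mean()), hill0],
                bounds=([logc.min() - 4.0, 0.05], [logc.max() + 4.0, 10.0]),
            )
        except Exception:
            continue
        rss = float((res.fun**2).sum())
        if res.success and (best is None or rss < best[0]):
            best = (rss, res.x)
    if best is None:
        return ViabilityCurveFit(ec50=float(10 ** logc.mean()), hill=1.0, converged=False)
    _, (log_ec50, hill) = best
    return ViabilityCurveFit(ec50=float(10**log_ec50), hill=float(hill), converged=True)


@dataclass(frozen=True)
class PatientScore:
    """AUCsum: per-patient chemoresistance score for the TP regimen."""

    organoid_id: str
    auc_sum: float
    components: tuple[float, float]  # (cisplatin norm_auc, paclitaxel norm_auc)


def auc_sum(cis: float, ptx: float, organoid_id: str = "") -> PatientScore:
    """Sum of the standardized AUCs for cisplatin and paclitaxel (in [0, 2])."""
    for name, value in (("cisplatin", cis), ("paclitaxel", ptx)):
        if value is None:
            raise ValidationError(f"missing {name} normalized AUC")
        if not 0.0 <= value <= 1.0:
            raise ValidationError(f"{name} normalized AUC {value} outside [0, 1]")
    return PatientScore(organoid_id=organoid_id, auc_sum=float(cis + ptx),
                        components=(float(cis), float(ptx)))


def secondary_viabilities(
    dataset: ScreenDataset, organoid_id: str, drug: str
) -> tuple[np.ndarray, np.ndarray]:
    """Raw per-dose viability fractions (treated TEND / NC TEND) for one drug."""
    wells = dataset.wells_for(organoid_id)
    ctrl = [w.signal for w in wells if w.timepoint is Timepoint.TEND and w.is_control]
    if not ctrl or float(np.mean(ctrl)) <= 0:
        raise ValidationError(f"degenerate TEND NC for organoid {organoid_id!r}")
    nc_mean = float(np.mean(ctrl))
    by_conc: dict[float, list[float]] = {}
    for w in wells:
        if w.drug == drug and w.timepoint is Timepoint.TEND and not w.is_control:
            by_conc.setdefault(w.concentration, []).append(w.signal)
    if not by_conc:
        raise MissingDrugError(f"no {drug!r} wells for organoid {organoid_id!r}")
    concs = np.array(sorted(by_conc))
    viab = np.array([np.mean(by_conc[c]) / nc_mean for c in concs])
    return concs, viab


def summarize_drug(
    dataset: ScreenDataset, organoid_id: str, drug: str
) -> DrugResponseSummary:
    """End-to-end per-drug summary from a secondary dataset: GR profile,
    sigmoid fit, GR metrics and the raw-data normalized AUC."""
    profile = build_gr_profile(dataset, organoid_id, drug)
    fit = fit_gr_curve(profile)
    concs, viab = secondary_viabilities(dataset, organoid_id, drug)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # clipping handled via flags upstream
        auc = normalized_auc(concs, viab)
    return gr_metrics(fit, profile, dataset.registry[drug], norm_auc=auc)
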