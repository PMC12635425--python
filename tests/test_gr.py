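"""GR transform, sigmoid fitting, GR metrics, normalized AUC and AUCsum."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grscreen import (
    DrugSpec,
    GRCurveFit,
    GRPoint,
    GRProfile,
    InsufficientDataError,
    NoGrowthError,
    ValidationError,
    auc_sum,
    build_gr_profile,
    fit_gr_curve,
    fit_viability_curve,
    gr_metrics,
    gr_value,
    normalized_auc,
    solve_gr_level,
    summarize_drug,
)


def make_profile(concs, gr_means, drug="cisplatin", organoid="A"):
    points = tuple(
        GRPoint(concentration=c, gr_mean=g, gr_replicates=(g,))
        for c, g in sorted(zip(concs, gr_means))
    )
    return GRProfile(organoid_id=organoid, drug=drug, points=points, x0=100.0, x_ctrl=400.0)


class TestGRValue:
    @pytest.mark.parametrize(
        "x_c, expected",
        [
            (400.0, 1.0),  # treated equals control: no effect
            (100.0, 0.0),  # treated equals start: complete cytostasis
            (200.0, math.sqrt(2) - 1),  # closed form 2^(1/2) - 1
        ],
    )
    def test_closed_forms(self, x_c, expected):
        assert gr_value(100.0, 400.0, x_c) == pytest.approx(expected, abs=1e-12)

    def test_no_growth_is_an_error(self):
        with pytest.raises(NoGrowthError):
            gr_value(100.0, 100.0, 50.0)
        with pytest.raises(NoGrowthError):
            gr_value(100.0, 80.0, 50.0)

    def test_nonpositive_signal_clamps_only_with_floor(self):
        with pytest.raises(ValidationError):
            gr_value(100.0, 400.0, 0.0)
        clamped = gr_value(100.0, 400.0, 0.0, signal_floor=1e-4)
        assert -1.0 < clamped < -0.99

    def test_approaches_minus_one_from_above_for_complete_kill(self):
        values = [gr_value(100.0, 400.0, x_c) for x_c in (10.0, 1.0, 0.1, 1e-3)]
        assert all(v > -1.0 for v in values)
        assert values == sorted(values, reverse=True)
        assert values[-1] == pytest.approx(-1.0, abs=1e-2)

    @settings(derandomize=True, max_examples=100)
    @given(
        x_a=st.floats(1.0, 1e5),
        factor=st.floats(1.001, 100.0),
    )
    def test_monotone_increasing_in_treated_signal(self, x_a, factor):
        assert gr_value(100.0, 400.0, x_a * factor) > gr_value(100.0, 400.0, x_a)


class TestCurveFit:
    def test_noiseless_parameters_recovered_within_one_percent(self):
        concs = [50.0 / 4**i for i in range(6)]
        truth = GRCurveFit(gr_inf=-0.6, gec50=1.0, hill=2.0, converged=True, rss=0.0)
        profile = make_profile(concs, [float(truth.predict(c)) for c in concs])
        fit = fit_gr_curve(profile)
        assert fit.converged
        assert fit.gr_inf == pytest.approx(-0.6, rel=0.01, abs=0.01)
        assert fit.gec50 == pytest.approx(1.0, rel=0.01)
        assert fit.hill == pytest.approx(2.0, rel=0.01)

    def test_inert_drug_falls_back_to_flat_model(self):
        concs = [50.0 / 4**i for i in range(6)]
        profile = make_profile(concs, [1.0, 0.99, 1.0, 1.01, 1.0, 0.995])
        fit = fit_gr_curve(profile)
        assert not fit.converged
        assert fit.gr_inf == pytest.approx(1.0, abs=0.02)

    def test_fitted_curve_crosses_zero_where_expected(self):
        # gr_inf=-0.5, gec50=1, hill=1: 0 = -0.5 + 1.5/(1+c) at c = 2
        concs = [50.0 / 4**i for i in range(6)]
        model = GRCurveFit(gr_inf=-0.5, gec50=1.0, hill=1.0, converged=True, rss=0.0)
        fit = fit_gr_curve(make_profile(concs, [float(model.predict(c)) for c in concs]))
        assert solve_gr_level(fit, 0.0) == pytest.approx(2.0, rel=1e-6)

    def test_too_few_concentrations_raise(self):
        with pytest.raises(InsufficientDataError):
            fit_gr_curve(make_profile([1.0, 2.0, 4.0], [0.9, 0.5, 0.1]))

    def test_closed_form_crossings_agree_with_bisection(self):
        from scipy.optimize import brentq

        rng = np.random.default_rng(5)
        for _ in range(50):
            fit = GRCurveFit(
                gr_inf=float(rng.uniform(-1.0, 0.4)),
                gec50=float(10 ** rng.uniform(-2, 2)),
                hill=float(rng.uniform(0.5, 4.0)),
                converged=True,
                rss=0.0,
            )
            for level in (0.0, 0.5):
                closed = solve_gr_level(fit, level)
                if closed is None:
                    assert fit.gr_inf >= level
                    continue
                numeric = brentq(
                    lambda c: float(fit.predict(c)) - level, closed / 1e6, closed * 1e6,
                    xtol=1e-15, rtol=1e-14,
                )
                assert closed == pytest.approx(numeric, rel=1e-9)


class TestGRMetrics:
    def spec(self, cmax=13.67):
        return DrugSpec("cisplatin", cmax=cmax, secondary_start=50.0)

    def test_gr100_closed_form(self):
        concs = [50.0 / 4**i for i in range(6)]
        model = GRCurveFit(gr_inf=-0.5, gec50=1.0, hill=1.0, converged=True, rss=0.0)
        profile = make_profile(concs, [float(model.predict(c)) for c in concs])
        summary = gr_metrics(fit_gr_curve(profile), profile, self.spec())
        assert summary.gr100 == pytest.approx(2.0, rel=1e-6)
        assert summary.gr50 == pytest.approx(0.5, rel=1e-6)
        assert summary.grmax == pytest.approx(min(p.gr_mean for p in profile.points))

    def test_never_cytostatic_drug_has_absent_gr100_and_zero_index(self):
        concs = [50.0 / 4**i for i in range(6)]
        model = GRCurveFit(gr_inf=0.2, gec50=1.0, hill=1.0, converged=True, rss=0.0)
        profile = make_profile(concs, [float(model.predict(c)) for c in concs])
        summary = gr_metrics(fit_gr_curve(profile), profile, self.spec())
        assert summary.gr100 is None
        assert summary.cmax_over_gr100 == 0.0

    def test_cmax_over_gr100_ratio(self):
        # a potent drug: crossing far below Cmax gives a large index
        spec = DrugSpec("doxorubicin", cmax=6.90, secondary_start=50.0)
        gr100 = 6.90 / 76.73
        concs = [50.0 / 4**i for i in range(6)]
        # choose gec50 so the curve crosses zero exactly at gr100:
        # 0 = -0.8 + 1.8/(1+c/gec50) -> c = gec50 * (1.8/0.8 - 1) = 1.25 gec50
        model = GRCurveFit(gr_inf=-0.8, gec50=gr100 / 1.25, hill=1.0, converged=True, rss=0.0)
        profile = make_profile(
            concs, [float(model.predict(c)) for c in concs], drug="doxorubicin"
        )
        summary = gr_metrics(fit_gr_curve(profile), profile, spec)
        assert summary.cmax_over_gr100 == pytest.approx(76.73, rel=1e-3)

    def test_extrapolated_crossing_flagged_and_warned(self):
        # crossing far below the lowest tested dose is reported but flagged
        spec = DrugSpec("doxorubicin", cmax=6.90, secondary_start=50.0)
        concs = [50.0 / 4**i for i in range(6)]
        model = GRCurveFit(gr_inf=-0.8, gec50=0.005, hill=1.0, converged=True, rss=0.0)
        profile = make_profile(
            concs, [float(model.predict(c)) for c in concs], drug="doxorubicin"
        )
        with pytest.warns(UserWarning):
            summary = gr_metrics(fit_gr_curve(profile), profile, spec)
        assert summary.gr100 is not None
        assert summary.gr100 < concs[-1]
        assert "extrapolated" in summary.flags

    def test_interpolation_fallback_when_fit_unconverged(self):
        concs = [50.0 / 4**i for i in range(6)]
        # flat-ish profile that still brackets zero empirically
        gr = [0.04, 0.03, 0.02, 0.01, -0.005, -0.04]
        profile = make_profile(concs, list(reversed(gr)))
        fit = fit_gr_curve(profile)
        assert not fit.converged
        summary = gr_metrics(fit, profile, self.spec())
        assert summary.gr100 is not None
        assert "interpolated" in summary.flags


class TestNormalizedAUC:
    def test_constant_viability_extremes(self):
        concs = [50.0 / 4**i for i in range(6)]
        assert normalized_auc(concs, [1.0] * 6) == pytest.approx(1.0, abs=1e-12)
        assert normalized_auc(concs, [0.0] * 6) == pytest.approx(0.0, abs=1e-12)

    def test_hand_trapezoid_worked_example(self):
        concs = sorted(50.0 / 4**i for i in range(6))  # ascending dose
        viability = [1, 1, 0.5, 0, 0, 0]
        assert normalized_auc(concs, viability) == pytest.approx(0.4, abs=1e-12)

    def test_reversal_invariance_and_brute_force_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(2, 10))
            concs = np.sort(10 ** rng.uniform(-3, 3, size=n))
            while np.any(np.diff(concs) == 0):
                concs = np.sort(10 ** rng.uniform(-3, 3, size=n))
            v = rng.uniform(0, 1, size=n)
            got = normalized_auc(concs, v)
            # independent trapezoid: sum of segment areas over log10 axis
            x = np.log10(concs)
            oracle = sum(
                0.5 * (v[i] + v[i + 1]) * (x[i + 1] - x[i]) for i in range(n - 1)
            ) / (x[-1] - x[0])
            assert got == pytest.approx(oracle, abs=1e-12)
            assert normalized_auc(concs[::-1], v[::-1]) == pytest.approx(got, abs=1e-12)

    def test_clipping_and_error_paths(self):
        with pytest.warns(UserWarning):
            assert normalized_auc([1.0, 10.0], [1.5, 1.5]) == pytest.approx(1.0)
        with pytest.raises(InsufficientDataError):
            normalized_auc([1.0], [0.5])
        with pytest.raises(ValidationError):
            normalized_auc([0.0, 1.0], [0.5, 0.5])


class TestAUCSum:
    @pytest.mark.parametrize("cis, ptx, total", [(1.0, 1.0, 2.0), (0.5, 0.7, 1.2)])
    def test_addition(self, cis, ptx, total):
        score = auc_sum(cis, ptx, organoid_id="A")
        assert score.auc_sum == pytest.approx(total, abs=1e-12)
        assert score.auc_sum == pytest.approx(sum(score.components), abs=1e-12)

    def test_missing_or_invalid_component(self):
        with pytest.raises(ValidationError):
            auc_sum(None, 0.5)
        with pytest.raises(ValidationError):
            auc_sum(1.2, 0.5)


def test_viability_curve_fit_constrained_range():
    concs = np.array([50.0 / 4**i for i in range(6)])
    truth_ec50, truth_hill = 2.0, 1.5
    v = 100.0 / (1.0 + (concs / truth_ec50) ** truth_hill)
    fit = fit_viability_curve(concs, v)
    assert fit.converged
    assert fit.ec50 == pytest.approx(truth_ec50, rel=1e-3)
    assert fit.hill == pytest.approx(truth_hill, rel=1e-3)
    preds = fit.predict(np.logspace(-3, 3, 50))
    assert np.all((preds >= 0.0) & (preds <= 100.0))


def test_summarize_drug_recovers_truth_end_to_end(registry, noiseless_organoid, noiseless_secondary):
    """Full path (simulate -> GR -> fit -> metrics) against generative truth."""
    truth = noiseless_organoid.drug_truths["paclitaxel"]
    profile = build_gr_profile(noiseless_secondary, "ORG-A", "paclitaxel")
    for point in profile.points:
        assert point.gr_mean == pytest.approx(truth.gr(point.concentration), abs=1e-9)
    fit = fit_gr_curve(profile)
    if fit.converged and max(p.gr_mean for p in profile.points) - min(
        p.gr_mean for p in profile.points
    ) > 0.2:
        assert fit.gr_inf == pytest.approx(truth.gr_inf, rel=0.01, abs=0.01)
        assert fit.gec50 == pytest.approx(truth.gec50, rel=0.01)
        assert fit.hill == pytest.approx(truth.hill, rel=0.01)
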