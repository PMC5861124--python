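import numpy as np
import pytest

from dnacyclize.fitting import (
    FitParams,
    KnobRegression,
    PeriodicProfileModel,
    calibrate_simple_model,
    degenerate_family,
    f_periodic,
    fit_profile,
    knob_regression,
)
from dnacyclize.geometry import solve_helix_params
from dnacyclize.io import generate_profile_fixture
from dnacyclize import reference


class TestFPeriodic:
    def test_zero_at_phase(self):
        assert f_periodic(147.16, 147.16, 10.5) == 0.0

    def test_periodicity(self):
        assert abs(f_periodic(147.16 + 10.5, 147.16, 10.5)) < 1e-12
        assert abs(f_periodic(147.16 - 3 * 10.5, 147.16, 10.5)) < 1e-12

    def test_half_period_wraps_to_lower_boundary(self):
        # mod arithmetic sends phi + p/2 to -p/2 (the trough)
        assert np.isclose(f_periodic(150.0 + 5.25, 150.0, 10.5), -5.25)

    def test_range(self):
        N = np.arange(100, 200, 0.37)
        f = f_periodic(N, 147.2, 10.48)
        assert f.min() >= -10.48 / 2 and f.max() < 10.48 / 2

    def test_bad_period(self):
        with pytest.raises(ValueError):
            f_periodic(150.0, 147.0, 0.0)


def _model_values(N, params):
    return (
        params.a
        + params.b * (N - params.phi)
        + params.c * f_periodic(N, params.phi, params.p) ** 2
    )


class TestExactRecovery:
    def test_reference_row(self):
        # the reference molecule's parameters are recovered exactly from
        # noiseless data
        truth = FitParams(147.16, 10.48, 1.35, 0.017, -0.112)
        df = generate_profile_fixture(truth)
        res = fit_profile(df["N"], df["log10J"])
        for name in ("phi", "p", "a", "b", "c"):
            assert abs(getattr(res, name) - getattr(truth, name)) < 1e-6
        assert res.rss < 1e-12

    def test_random_parameters(self, rng):
        for _ in range(5):
            p = rng.uniform(9.6, 11.4)
            truth = FitParams(
                phi=145 + rng.uniform(0.5, p - 0.5),
                p=p,
                a=rng.uniform(-1, 2),
                b=rng.uniform(-0.04, 0.04),
                c=rng.uniform(-0.15, -0.03),
            )
            N = np.arange(146, 171)
            res = fit_profile(N, _model_values(N, truth))
            for name in ("phi", "p", "a", "b", "c"):
                assert abs(getattr(res, name) - getattr(truth, name)) < 1e-6

    def test_phi_reported_in_window(self):
        # a phase outside (145, 145+p] is folded back; the curve and its
        # peak height are unchanged because (phi, a) shift together
        truth = FitParams(158.0, 10.4, 1.2, 0.02, -0.1)
        N = np.arange(146, 171)
        y = _model_values(N, truth)
        res = fit_profile(N, y)
        assert 145 < res.phi <= 145 + res.p
        assert np.isclose(res.phi, 158.0 - 10.4, atol=1e-6)
        assert np.allclose(res.predict(N), y, atol=1e-8)

    def test_noisy_recovery_of_peak_height(self):
        truth = FitParams(147.16, 10.48, 1.35, 0.017, -0.112)
        recovered = []
        for seed in range(30):
            df = generate_profile_fixture(truth, noise_sigma=0.05, seed=seed)
            res = fit_profile(
                df["N"], df["log10J"], p_step=0.02, phi_step=0.05
            )
            recovered.append(res.a)
        assert abs(np.mean(recovered) - truth.a) < 0.03

    def test_weighted_fit_downweights_outlier(self):
        truth = FitParams(147.16, 10.48, 1.35, 0.017, -0.112)
        df = generate_profile_fixture(truth)
        y = df["log10J"].to_numpy().copy()
        y[5] += 2.0  # corrupted point
        w = np.ones_like(y)
        w[5] = 1e-8
        res = fit_profile(df["N"].to_numpy(), y, weights=w)
        assert abs(res.a - truth.a) < 1e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            PeriodicProfileModel(np.arange(5), np.zeros(5))

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="span"):
            PeriodicProfileModel(np.arange(146, 156), np.zeros(10)).fit()


@pytest.fixture(scope="module")
def res():
    truth = FitParams(147.16, 10.48, 1.35, 0.017, -0.112)
    df = generate_profile_fixture(truth, noise_sigma=0.03, seed=4)
    return PeriodicProfileModel(df["N"], df["log10J"]).fit()


class TestResultsObject:

    def test_params_series(self, res):
        assert list(res.params.index) == ["phi", "p", "a", "b", "c"]
        assert res.nobs == 25 and res.df_resid == 20

    def test_peak_to_trough(self, res):
        # -c (p/2)^2; approximately 27.6 |c| at p = 10.5
        assert np.isclose(res.peak_to_trough, -res.c * (res.p / 2) ** 2)
        assert np.isclose((10.5 / 2) ** 2, 27.6, atol=0.1)

    def test_residuals_and_fit(self, res):
        assert res.resid.shape == (25,)
        assert res.rss == pytest.approx(np.sum(res.resid**2))

    def test_bse_finite(self, res):
        assert np.all(np.isfinite(res.bse))
        assert res.bse["a"] < 0.1

    def test_summary_text(self, res):
        text = res.summary()
        for key in ("phi", "rss", "peak-to-trough"):
            assert key in text


class TestKnobRegression:
    def test_bend_angle_response(self):
        # restricted 60-120 degree range around the 90-degree reference
        tab = reference.bend_angle_fits.query("knob >= 60")
        reg = knob_regression(tab["knob"], tab["a"], reference=90.0)
        assert round(reg.slope, 3) == 0.021
        assert round(reg.intercept, 2) == 1.31

    def test_helical_repeat_response(self):
        tab = reference.helical_repeat_fits
        reg = knob_regression(tab["knob"], tab["phi"], reference=10.5)
        assert round(reg.slope, 1) == 14.3
        assert round(reg.intercept, 1) == 147.2

    def test_twist_stiffness_response(self):
        tab = reference.twist_stiffness_fits
        reg = knob_regression(tab["knob"], tab["c"], reference=1.5)
        assert round(reg.slope, 3) == -0.077
        assert round(reg.intercept, 3) == -0.114

    def test_predict(self):
        reg = KnobRegression("bend", "a", 0.021, 1.31, 90.0)
        assert np.isclose(reg.predict(90.0), 1.31)

    def test_too_few_points(self):
        with pytest.raises(ValueError):
            knob_regression([1, 2], [3, 4])


class TestDegenerateFamilies:
    def test_bend_stiffness_reference_point(self):
        (spec,) = degenerate_family("bend-stiffness", [1.0])
        assert spec.segments[0].bend_total_deg == 90.0
        assert spec.stiffness.scale_beta == 1.0

    def test_bend_stiffness_tradeoff(self):
        specs = degenerate_family("bend-stiffness", [0.9, 1.0, 1.1])
        bends = [s.segments[0].bend_total_deg for s in specs]
        assert np.allclose(bends, [90 - 21.2, 90.0, 90 + 21.2])

    def test_twist_helicity_bend_members(self):
        # repeats 10.4 / 10.35 map to the documented (ratio, bend) pairs
        (s,) = degenerate_family("twist-helicity-bend", [10.4])
        assert np.isclose(s.segments[0].pitch_over_circumf, 0.584)
        assert np.isclose(s.segments[0].bend_total_deg, 98.4, atol=0.05)
        (s,) = degenerate_family("twist-helicity-bend", [10.35])
        assert np.isclose(s.segments[0].pitch_over_circumf, 0.876)
        assert np.isclose(s.segments[0].bend_total_deg, 102.5, atol=0.05)

    def test_members_have_solvable_helices(self):
        for s in degenerate_family("twist-helicity-bend", [10.4, 10.6]):
            seg = s.segments[0]
            hp = solve_helix_params(
                np.deg2rad(seg.bend_total_deg) / seg.n_bp,
                seg.pitch_over_circumf,
                s.helical_repeat,
            )
            assert np.sign(hp.alpha) == np.sign(seg.pitch_over_circumf)

    def test_out_of_validity_rejected(self):
        with pytest.raises(ValueError, match="beyond the validated"):
            degenerate_family("twist-helicity-bend", [10.3])
        with pytest.raises(ValueError, match="60-120"):
            degenerate_family("bend-stiffness", [1.25])
        with pytest.raises(ValueError, match="unknown"):
            degenerate_family("nope", [1.0])


class TestCalibration:
    def test_reference_curvature_maps_to_reference_ratio(self):
        res = calibrate_simple_model(1.35, -0.114, 90.0)
        assert np.isclose(res.k3_over_k1, 1.5)

    def test_worked_example(self):
        res = calibrate_simple_model(0.847, -0.0723, 100.0)
        assert round(res.beta, 2) == 1.15
        assert round(res.k3_over_k1, 1) == 1.0

    def test_refined_estimate(self):
        res = calibrate_simple_model(0.847, -0.0723, 100.0, refine=True)
        assert round(res.beta, 2) == 1.12

    def test_consistency_with_degenerate_family(self):
        # a profile generated on the bend-stiffness tradeoff line calibrates
        # back to its own beta
        for beta in (0.92, 1.0, 1.08):
            bend = 90.0 + 212.0 * (beta - 1.0)
            a = 1.325 + 0.021 * (bend - 90.0) - 4.45 * (beta - 1.0)
            res = calibrate_simple_model(a, -0.114, bend)
            assert abs(res.beta - beta) < 1e-9
            assert not res.extrapolated

    def test_extrapolation_flag(self):
        assert calibrate_simple_model(0.0, -0.3, 90.0).extrapolated
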