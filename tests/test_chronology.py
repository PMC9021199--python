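"""Curve parsing, calibration against brute-force oracles, HPD intervals,
and the phase-sequence sampler's constraints, reduction and outliers."""

import io
import math

import numpy as np
import pytest
from scipy import stats

from shellseasons import synthetic as syn
from shellseasons.chronology import (
    CalibrationCurve,
    PhaseAssignment,
    PhaseSequenceModel,
    PosteriorDensity,
    RadiocarbonDate,
    ReservoirCorrection,
    apply_delta_r,
    calibrate,
    date_marginal,
    flag_outliers,
    hpd,
    phase_estimates,
    read_calcurve,
    sample_hpd,
    sample_phase_model,
    write_calcurve,
)


def _date(cra, sigma=30.0, lab="d1", material="bone", species=""):
    return RadiocarbonDate(lab_id=lab, unit_id="u", material=material,
                           cra_bp=cra, sigma=sigma, species=species)


class TestCurveParsing:
    def test_three_line_fixture(self):
        text = "# header\n1000,1100,10,0,0\n1005,1105,10,0,0\n1010,1111,12,0,0\n"
        curve = read_calcurve(io.StringIO(text))
        assert len(curve.cal_bp) == 3
        assert curve.covers(1005.0)

    def test_comments_only_is_error(self):
        with pytest.raises(ValueError):
            read_calcurve(io.StringIO("# only\n# comments\n"))

    def test_bad_line_reports_number(self):
        text = "1000,1100,10\n1005,not-a-number,10\n"
        with pytest.raises(ValueError, match="line 2"):
            read_calcurve(io.StringIO(text))

    def test_non_monotone_grid_rejected(self):
        text = "1000,1100,10\n1000,1105,10\n1010,1111,12\n"
        with pytest.raises(ValueError, match="monotone"):
            read_calcurve(io.StringIO(text))

    def test_linear_interpolation_at_midpoint(self):
        text = "1000,1100,10\n1010,1120,20\n"
        curve = read_calcurve(io.StringIO(text))
        assert curve.mean_at(1005.0) == pytest.approx((1100 + 1120) / 2)
        assert curve.sigma_at(1005.0) == pytest.approx(15.0)

    def test_write_read_round_trip(self, tmp_path):
        curve = syn.simulate_calcurve(seed=3, span=(7000.0, 7500.0))
        path = tmp_path / "c.14c"
        write_calcurve(curve, path)
        back = read_calcurve(path)
        np.testing.assert_allclose(back.cal_bp, curve.cal_bp)
        np.testing.assert_allclose(back.c14_age, curve.c14_age, atol=0.05)


class TestReservoirCorrection:
    def test_lineatus_offset_example(self):
        d = _date(7800.0, 40.0, material="shell", species="Phorcus lineatus")
        corr = ReservoirCorrection("Phorcus lineatus", -257.0, 120.0)
        out = apply_delta_r(d, corr)
        assert out.cra_bp == pytest.approx(8057.0)
        assert out.sigma == pytest.approx(math.hypot(40.0, 120.0))  # ~126.5

    def test_zero_correction_is_identity(self):
        d = _date(7800.0, 40.0, material="shell", species="s")
        out = apply_delta_r(d, ReservoirCorrection("s", 0.0, 0.0))
        assert (out.cra_bp, out.sigma) == (7800.0, 40.0)

    def test_sigma_never_shrinks(self):
        d = _date(7800.0, 40.0, material="shell", species="s")
        for drs in (0.0, 10.0, 120.0, 400.0):
            out = apply_delta_r(d, ReservoirCorrection("s", -100.0, drs))
            assert out.sigma >= max(40.0, drs)

    def test_species_mismatch_rejected(self):
        d = _date(7800.0, 40.0, material="shell", species="a")
        with pytest.raises(ValueError):
            apply_delta_r(d, ReservoirCorrection("b", -100.0, 50.0))

    def test_terrestrial_material_rejected(self):
        with pytest.raises(ValueError):
            apply_delta_r(_date(7800.0, material="bone"),
                          ReservoirCorrection("", 0.0, 0.0))


class TestCalibration:
    def test_identity_curve_gives_gaussian(self, identity_curve):
        d = _date(8300.0, 40.0)
        post = calibrate(d, identity_curve, grid_step=1.0)
        ks = np.max(np.abs(np.cumsum(post.pmf)
                           - stats.norm.cdf(post.cal_bp + 0.5, 8300.0, 40.0)))
        assert ks < 0.01

    def test_constant_curve_gives_uniform(self):
        cal = np.arange(8000.0, 8100.0, 1.0)
        curve = CalibrationCurve("flat", cal, np.full_like(cal, 7500.0),
                                 np.full_like(cal, 20.0))
        post = calibrate(_date(7500.0), curve)
        assert np.ptp(post.pmf) < 1e-12

    def test_matches_brute_force_grid(self, wiggly_curve):
        """Independent dense evaluation with scipy's normal pdf."""
        d = _date(float(wiggly_curve.mean_at(8400.0)), 35.0)
        post = calibrate(d, wiggly_curve, grid_step=1.0)
        grid = post.cal_bp
        mu = np.interp(grid, wiggly_curve.cal_bp, wiggly_curve.c14_age)
        sd = np.sqrt(35.0**2 + np.interp(grid, wiggly_curve.cal_bp,
                                         wiggly_curve.sigma) ** 2)
        brute = stats.norm.pdf(d.cra_bp, mu, sd)
        brute = brute / brute.sum()
        assert 0.5 * np.abs(post.pmf - brute).sum() < 1e-6

    def test_date_outside_coverage_rejected(self, wiggly_curve):
        with pytest.raises(ValueError, match="coverage"):
            calibrate(_date(50000.0), wiggly_curve)


class TestHPD:
    def test_gaussian_two_sigma(self, identity_curve):
        post = calibrate(_date(8300.0, 50.0), identity_curve, grid_step=1.0)
        ((lo, hi),) = hpd(post, 0.954)
        assert lo == pytest.approx(8300 - 2 * 50, abs=3)
        assert hi == pytest.approx(8300 + 2 * 50, abs=3)

    def test_near_total_mass_covers_support(self):
        grid = np.arange(0.0, 10.0)
        post = PosteriorDensity(grid, np.full(10, 0.1))
        ((lo, hi),) = hpd(post, 1.0 - 1e-9)
        assert lo <= grid[0] and hi >= grid[-1]

    def test_bimodal_gives_two_intervals(self):
        grid = np.arange(0.0, 400.0)
        dens = stats.norm.pdf(grid, 100, 10) + stats.norm.pdf(grid, 300, 10)
        post = PosteriorDensity(grid, dens / dens.sum())
        intervals = hpd(post, 0.90)
        assert len(intervals) == 2
        assert intervals[0][1] < intervals[1][0]

    def test_invalid_mass_rejected(self):
        grid = np.arange(0.0, 10.0)
        post = PosteriorDensity(grid, np.full(10, 0.1))
        with pytest.raises(ValueError):
            hpd(post, 1.5)


class TestPhaseModel:
    def test_single_date_reduces_to_calibration(self, wiggly_curve):
        d = _date(float(wiggly_curve.mean_at(8300.0)), 30.0)
        post = calibrate(d, wiggly_curve, grid_step=5.0)
        model = PhaseSequenceModel(
            phases=("p",), dates=(PhaseAssignment(d, wiggly_curve, "p"),),
            outlier_prior=0.0,
        )
        samples = sample_phase_model(model, n_iter=50_000, burn_in=5_000, seed=2)
        marg = date_marginal(samples, 0, post.cal_bp)
        assert 0.5 * np.abs(marg.pmf - post.pmf).sum() < 0.05

    def test_ordering_constraints_hold_in_every_draw(self, wiggly_curve):
        rng = np.random.default_rng(0)
        assigns = []
        for j, (old, young) in enumerate([(8900, 8700), (8600, 8400)]):
            ages = rng.uniform(young, old, 3)
            for d in syn.simulate_dates(ages, wiggly_curve, sigma=30.0,
                                        seed=j, lab_prefix=f"p{j}"):
                assigns.append(PhaseAssignment(d, wiggly_curve, f"P{j}"))
        model = PhaseSequenceModel(phases=("P0", "P1"), dates=tuple(assigns))
        s = sample_phase_model(model, n_iter=3000, burn_in=500, seed=1)
        pidx = [model.phase_index[a.phase] for a in model.dates]
        for i, j in enumerate(pidx):
            assert np.all(s.theta[:, i] <= s.start[:, j] + 1e-9)
            assert np.all(s.theta[:, i] >= s.end[:, j] - 1e-9)
        assert np.all(s.start[:, 0] >= s.end[:, 0])
        assert np.all(s.end[:, 0] >= s.start[:, 1])
        assert np.all(s.start[:, 1] >= s.end[:, 1])

    def test_bitwise_reproducible_under_seed(self, wiggly_curve):
        d = _date(float(wiggly_curve.mean_at(8300.0)), 30.0)
        model = PhaseSequenceModel(
            phases=("p",), dates=(PhaseAssignment(d, wiggly_curve, "p"),)
        )
        a = sample_phase_model(model, n_iter=2000, burn_in=200, seed=9)
        b = sample_phase_model(model, n_iter=2000, burn_in=200, seed=9)
        np.testing.assert_array_equal(a.theta, b.theta)
        np.testing.assert_array_equal(a.start, b.start)
        np.testing.assert_array_equal(a.outlier, b.outlier)

    def test_unsatisfiable_constraints_reported(self, identity_curve):
        # the "older" phase holds a clearly younger date
        young = PhaseAssignment(_date(7000.0, 20.0, lab="young"), identity_curve, "P0")
        old = PhaseAssignment(_date(9000.0, 20.0, lab="old"), identity_curve, "P1")
        model = PhaseSequenceModel(phases=("P0", "P1"), dates=(young, old))
        with pytest.raises(ValueError, match="unsatisfiable"):
            sample_phase_model(model, n_iter=1000, burn_in=100, seed=0)

    def test_empty_phase_rejected(self, identity_curve):
        d = PhaseAssignment(_date(8000.0), identity_curve, "P0")
        with pytest.raises(ValueError, match="empty"):
            PhaseSequenceModel(phases=("P0", "P1"), dates=(d,))


class TestOutliers:
    def _fit(self, curve, extra_shift=0.0, seed=0):
        rng = np.random.default_rng(seed)
        ages = rng.uniform(8200, 8400, 5)
        dates = syn.simulate_dates(ages, curve, sigma=25.0, seed=seed, lab_prefix="ok")
        assigns = [PhaseAssignment(d, curve, "p") for d in dates]
        suspect = _date(float(curve.mean_at(8300.0)) + extra_shift, 25.0, lab="suspect")
        assigns.append(PhaseAssignment(suspect, curve, "p"))
        model = PhaseSequenceModel(phases=("p",), dates=tuple(assigns))
        s = sample_phase_model(model, n_iter=6000, burn_in=1000, seed=seed + 1)
        return flag_outliers(s)

    def test_consistent_date_stays_near_prior(self, wiggly_curve):
        report = self._fit(wiggly_curve, extra_shift=0.0, seed=3)
        p = report.set_index("lab_id").loc["suspect", "outlier_probability"]
        assert p < 0.25
        assert not report.set_index("lab_id").loc["suspect", "flagged"]

    def test_shifted_date_is_flagged_in_sequence(self, wiggly_curve):
        """A date 500 14C y too old for its stratigraphic position cannot be
        absorbed by stretching when neighbouring phases pin the boundaries."""
        bounds = [(8900.0, 8650.0), (8570.0, 8380.0), (8300.0, 8080.0)]
        rng = np.random.default_rng(8)
        assigns = []
        for j, (old, young) in enumerate(bounds):
            ages = rng.uniform(young, old, 4)
            for d in syn.simulate_dates(ages, wiggly_curve, sigma=25.0,
                                        seed=20 + j, lab_prefix=f"p{j}"):
                assigns.append(PhaseAssignment(d, wiggly_curve, f"P{j}"))
        suspect = _date(float(wiggly_curve.mean_at(8470.0)) + 500.0, 25.0,
                        lab="suspect")
        assigns.append(PhaseAssignment(suspect, wiggly_curve, "P1"))
        model = PhaseSequenceModel(phases=("P0", "P1", "P2"),
                                   dates=tuple(assigns))
        s = sample_phase_model(model, n_iter=6000, burn_in=1000, seed=9)
        row = flag_outliers(s).set_index("lab_id").loc["suspect"]
        assert row["outlier_probability"] > 0.5
        assert bool(row["flagged"])

    def test_probabilities_in_unit_interval(self, wiggly_curve):
        report = self._fit(wiggly_curve, extra_shift=200.0, seed=5)
        assert ((report["outlier_probability"] >= 0)
                & (report["outlier_probability"] <= 1)).all()


class TestPhaseEstimates:
    def _samples(self, wiggly_curve, draws):
        d = _date(float(wiggly_curve.mean_at(8300.0)), 30.0)
        model = PhaseSequenceModel(
            phases=("p",), dates=(PhaseAssignment(d, wiggly_curve, "p"),)
        )
        from shellseasons.chronology.phase_model import PhaseSamples

        n = len(draws)
        return PhaseSamples(
            model=model, theta=np.tile(draws, (1, 1)).T,
            start=np.array(draws).reshape(-1, 1) + 10.0,
            end=np.array(draws).reshape(-1, 1) - 10.0,
            outlier=np.zeros((n, 1), dtype=bool),
        )

    def test_lustrum_rounding(self, wiggly_curve):
        s = self._samples(wiggly_curve, [8303.7] * 10)
        est = phase_estimates(s, rounding=5)
        assert est.loc[0, "start_median_bp"] == 8315.0  # 8313.7 -> nearest 5
        assert est.loc[0, "end_median_bp"] == 8295.0

    def test_rounding_one_returns_raw_median(self, wiggly_curve):
        s = self._samples(wiggly_curve, [8303.7] * 10)
        est = phase_estimates(s, rounding=1)
        assert est.loc[0, "start_median_bp"] == pytest.approx(8313.7)

    def test_durations_non_negative(self, wiggly_curve):
        d = _date(float(wiggly_curve.mean_at(8300.0)), 30.0)
        model = PhaseSequenceModel(
            phases=("p",), dates=(PhaseAssignment(d, wiggly_curve, "p"),)
        )
        s = sample_phase_model(model, n_iter=2000, burn_in=200, seed=4)
        assert np.all(s.start - s.end >= 0)
        est = phase_estimates(s)
        assert (est["duration_median_y"] >= 0).all()


def test_sample_hpd_contains_requested_mass():
    rng = np.random.default_rng(0)
    draws = rng.normal(0.0, 1.0, 20000)
    lo, hi = sample_hpd(draws, 0.954)
    inside = np.mean((draws >= lo) & (draws <= hi))
    assert inside == pytest.approx(0.954, abs=0.01)
    assert lo == pytest.approx(-2.0, abs=0.15)
    assert hi == pytest.approx(2.0, abs=0.15)
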