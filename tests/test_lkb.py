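"""LKB model: gEUD, probit response, likelihood, fitting and uncertainty."""

import numpy as np
import pytest
from scipy import stats

from ntcp_lab.dvh_io import Cohort, DifferentialDVH, cumulative_to_differential
from ntcp_lab.lkb import (
    LKBParams,
    LKBProbitModel,
    NonIdentifiableError,
    bootstrap_fit,
    cohort_log_likelihood,
    compute_geud,
    fit_lkb,
    iso_likelihood_contour,
    lkb_ntcp,
    ntcp_confidence_bundle,
    profile_interval,
)

from conftest import random_cumulative_dvh, toy_patient


def two_point_dvh():
    return DifferentialDVH(np.array([40.0, 80.0]), np.array([0.5, 0.5]))


class TestGEUD:
    @pytest.mark.parametrize("n", [0.01, 0.1, 0.5, 1.0])
    def test_uniform_dose_is_fixed_point(self, n):
        dd = DifferentialDVH(np.array([60.0]), np.array([1.0]))
        assert compute_geud(dd, n) == pytest.approx(60.0, rel=1e-12)

    def test_n_equal_one_gives_mean_dose(self):
        assert compute_geud(two_point_dvh(), 1.0) == pytest.approx(60.0, rel=1e-12)

    def test_matches_direct_power_mean(self):
        # brute-force evaluation of the power mean at n = 0.1
        expected = (0.5 * 40.0**10 + 0.5 * 80.0**10) ** 0.1
        assert compute_geud(two_point_dvh(), 0.1) == pytest.approx(expected, rel=1e-12)

    def test_small_n_limit_approaches_max_dose(self):
        assert compute_geud(two_point_dvh(), 1e-3) == pytest.approx(80.0, rel=5e-3)

    def test_monotone_nonincreasing_in_n(self, rng):
        # power-mean inequality on random DVHs
        for _ in range(10):
            dd = cumulative_to_differential(random_cumulative_dvh(rng))
            vals = [compute_geud(dd, n) for n in (0.02, 0.1, 0.3, 0.6, 1.0)]
            assert all(a >= b - 1e-9 for a, b in zip(vals, vals[1:]))

    def test_bounded_by_dose_range(self, rng):
        for _ in range(10):
            dd = cumulative_to_differential(random_cumulative_dvh(rng))
            g = compute_geud(dd, 0.2)
            used = dd.bin_doses[dd.bin_volumes > 0]
            assert used.min() - 1e-9 <= g <= used.max() + 1e-9

    def test_invalid_exponent_rejected(self):
        with pytest.raises(ValueError):
            compute_geud(two_point_dvh(), 0.0)


class TestProbitResponse:
    params = LKBParams(d50=87.3, m=0.37, n=0.10)

    def test_half_probability_at_d50(self):
        assert lkb_ntcp(self.params.d50, self.params) == pytest.approx(0.5, abs=1e-12)

    def test_one_slope_unit_above_d50(self):
        geud = self.params.d50 * (1 + self.params.m)
        assert lkb_ntcp(geud, self.params) == pytest.approx(
            stats.norm.cdf(1.0), abs=1e-12
        )

    def test_zero_dose(self):
        assert lkb_ntcp(0.0, self.params) == pytest.approx(
            stats.norm.cdf(-1 / 0.37), abs=1e-12
        )

    def test_strictly_increasing_in_geud(self):
        g = np.linspace(0, 150, 200)
        p = lkb_ntcp(g, self.params)
        assert np.all(np.diff(p) > 0)

    def test_parameter_domains_enforced(self):
        with pytest.raises(ValueError):
            LKBParams(d50=-1, m=0.3, n=0.1)
        with pytest.raises(ValueError):
            LKBParams(d50=80, m=0.3, n=1.5)


class TestCohortLogLikelihood:
    def test_closed_form_two_patients(self):
        # one event + one non-event, both at NTCP = 0.5 (gEUD = d50)
        dvh = (0.0, 87.3 * 2)  # single interval; midpoint = d50 at n=1
        cohort = Cohort((
            toy_patient("a", 1, doses=dvh, fracs=(1.0, 0.0)),
            toy_patient("b", 0, doses=dvh, fracs=(1.0, 0.0)),
        ))
        llh = cohort_log_likelihood(cohort, LKBParams(87.3, 0.37, 1.0))
        assert llh == pytest.approx(2 * np.log(0.5), abs=1e-9)

    def test_perfect_fit_limit_approaches_zero(self):
        # all events with NTCP -> 1: LLH -> 0 from below
        cohort = Cohort(tuple(
            toy_patient(f"e{i}", 1, doses=(0.0, 300.0), fracs=(1.0, 0.0))
            for i in range(4)
        ))
        llh = cohort_log_likelihood(cohort, LKBParams(50.0, 0.05, 1.0))
        assert -1e-6 < llh <= 0

    def test_llh_nonpositive(self, small_lkb_cohort):
        assert cohort_log_likelihood(small_lkb_cohort, LKBParams(87.3, 0.37, 0.1)) <= 0


class TestFit:
    def test_fit_beats_truth_and_perturbations(self, small_lkb_cohort, fitted_lkb):
        truth = LKBParams(87.3, 0.37, 0.10)
        assert fitted_lkb.llh >= cohort_log_likelihood(small_lkb_cohort, truth) - 1e-9
        p = fitted_lkb.params
        for factors in ([1.05, 1, 1], [0.95, 1, 1], [1, 1.05, 1],
                        [1, 0.95, 1], [1, 1, 1.05], [1, 1, 0.95]):
            pert = LKBParams(p.d50 * factors[0], p.m * factors[1],
                             min(p.n * factors[2], 1.0))
            assert fitted_lkb.llh >= cohort_log_likelihood(small_lkb_cohort, pert) - 1e-9

    def test_llh_is_max_over_starts(self, fitted_lkb):
        assert fitted_lkb.llh >= max(llh for _, llh in fitted_lkb.starts) - 1e-9
        assert fitted_lkb.converged

    def test_single_class_cohort_not_identifiable(self):
        cohort = Cohort(tuple(toy_patient(f"p{i}", 0) for i in range(5)))
        with pytest.raises(NonIdentifiableError):
            fit_lkb(cohort)

    def test_estimator_api(self, small_lkb_cohort):
        est = LKBProbitModel()
        est.fit(small_lkb_cohort.dvhs, small_lkb_cohort.outcomes)
        assert est.d50_ > 0 and est.m_ > 0 and 0 < est.n_ <= 1
        proba = est.predict_proba(small_lkb_cohort.dvhs)
        assert proba.shape == (len(small_lkb_cohort), 2)
        np.testing.assert_allclose(proba.sum(axis=1), 1.0, atol=1e-12)
        # get_params/set_params round trip (sklearn contract)
        est2 = LKBProbitModel(**est.get_params())
        assert est2.get_params() == est.get_params()


class TestProfileInterval:
    def test_degenerate_confidence_collapses_to_mle(self, small_lkb_cohort, fitted_lkb):
        iv = profile_interval(small_lkb_cohort, fitted_lkb, "d50", confidence=1e-12)
        assert iv.lower == pytest.approx(fitted_lkb.params.d50, rel=1e-3)
        assert iv.upper == pytest.approx(fitted_lkb.params.d50, rel=1e-3)

    @pytest.mark.parametrize("name", ["d50", "m", "n"])
    def test_brackets_mle_and_matches_grid_oracle(self, small_lkb_cohort, fitted_lkb, name):
        iv = profile_interval(small_lkb_cohort, fitted_lkb, name, confidence=0.95)
        mle = getattr(fitted_lkb.params, name)
        assert iv.lower <= mle <= iv.upper
        # dense fixed-nuisance grid oracle
        lo_b, hi_b = {"d50": (1.0, 1e4), "m": (1e-4, 10.0), "n": (1e-6, 1.0)}[name]
        grid = np.geomspace(max(mle / 20, lo_b), min(mle * 20, hi_b), 2000)
        vals = dict(d50=fitted_lkb.params.d50, m=fitted_lkb.params.m, n=fitted_lkb.params.n)
        llh = np.array([
            cohort_log_likelihood(small_lkb_cohort, LKBParams(**{**vals, name: g}))
            for g in grid
        ])
        inside = grid[llh >= iv.target_llh]
        step = np.log(grid[1] / grid[0])
        if not iv.lower_open:
            assert abs(np.log(inside.min() / iv.lower)) <= 2 * step
        if not iv.upper_open:
            assert abs(np.log(inside.max() / iv.upper)) <= 2 * step


@pytest.fixture(scope="module")
def contours(small_lkb_cohort, fitted_lkb):
    return [
        iso_likelihood_contour(small_lkb_cohort, fitted_lkb, plane, grid=40)
        for plane in (("d50", "m"), ("d50", "n"), ("m", "n"))
    ]


class TestContourAndBundle:
    def test_mle_above_threshold(self, fitted_lkb, contours):
        for c in contours:
            assert fitted_lkb.llh >= c.threshold

    def test_contour_points_lie_on_level_set(self, small_lkb_cohort, fitted_lkb, contours):
        vals = dict(d50=fitted_lkb.params.d50, m=fitted_lkb.params.m, n=fitted_lkb.params.n)
        for c in contours:
            pts = c.points
            assert len(pts) > 0
            sample = pts[:: max(1, len(pts) // 25)]
            for p1, p2 in sample:
                llh = cohort_log_likelihood(
                    small_lkb_cohort,
                    LKBParams(**{**vals, c.plane[0]: p1, c.plane[1]: p2}),
                )
                # traced points are root-refined onto the exact level set
                assert llh == pytest.approx(c.threshold, abs=1e-6)

    def test_contour_extremes_match_profile_intervals(
        self, small_lkb_cohort, fitted_lkb, contours
    ):
        # the d50-m plane extreme along d50 should agree with the 1-D scan
        c = next(c for c in contours if c.plane == ("d50", "m"))
        iv = profile_interval(small_lkb_cohort, fitted_lkb, "d50")
        if not c.open_at_boundary:
            assert c.points[:, 0].max() == pytest.approx(iv.upper, rel=0.05)
            assert c.points[:, 0].min() == pytest.approx(iv.lower, rel=0.05)

    def test_bundle_envelope_contains_best_curve(
        self, small_lkb_cohort, fitted_lkb, contours
    ):
        dose_grid = np.linspace(0, 120, 121)
        bundle = ntcp_confidence_bundle(small_lkb_cohort, fitted_lkb, contours, dose_grid)
        assert np.all(bundle.envelope_min <= bundle.best_curve + 1e-12)
        assert np.all(bundle.best_curve <= bundle.envelope_max + 1e-12)
        # probit monotonicity of every curve in the bundle
        assert np.all(np.diff(bundle.curves, axis=1) >= -1e-12)
        # envelope at the best-fit d50 contains 0.5
        i = int(np.argmin(np.abs(dose_grid - fitted_lkb.params.d50)))
        assert bundle.envelope_min[i] - 0.05 <= 0.5 <= bundle.envelope_max[i] + 0.05


class TestBootstrap:
    def test_seeded_determinism(self, small_lkb_cohort):
        a = bootstrap_fit(small_lkb_cohort, n_runs=20, subsample_size=80, seed=7)
        b = bootstrap_fit(small_lkb_cohort, n_runs=20, subsample_size=80, seed=7)
        np.testing.assert_array_equal(a.sample_array(), b.sample_array())
        assert a.means == b.means and a.sds == b.sds

    def test_accounting(self, small_lkb_cohort):
        res = bootstrap_fit(small_lkb_cohort, n_runs=25, subsample_size=40, seed=3)
        assert len(res.samples) + res.n_failed == 25
        assert set(res.means) == {"d50", "m", "n"}
        assert all(sd >= 0 for sd in res.sds.values())

    def test_subsample_size_validation(self, small_lkb_cohort):
        with pytest.raises(ValueError):
            bootstrap_fit(small_lkb_cohort, n_runs=5,
                          subsample_size=len(small_lkb_cohort) + 1, replace=False)
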