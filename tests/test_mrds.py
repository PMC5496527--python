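import collections
import datetime as dt
import math

import numpy as np
import pytest

import bearsurv as bs
from bearsurv.data_model import Detection, History, SurveyDataset, Transect
from bearsurv.detfun import TwoPieceNormalCurve
from bearsurv.mrds import (
    CaptureTally,
    MrdsFit,
    bootstrap_mrds,
    estimate_abundance_ht,
    fit_mr_intercept,
    fit_mrds,
    tally_histories,
)
from bearsurv.scenarios import mrds_recovery_world
from bearsurv.synth import simulate_survey


def small_survey(histories, distances=None, sizes=None, w=600.0, study_area=100.0,
                 lengths=(10.0,)):
    transects = tuple(Transect(f"t{i}", dt.date(2020, 6, 1), L) for i, L in enumerate(lengths))
    distances = distances or [100.0] * len(histories)
    sizes = sizes or [1] * len(histories)
    dets = tuple(
        Detection("t0", x, s, h) for x, s, h in zip(distances, sizes, histories)
    )
    return SurveyDataset(transects, dets, truncation_w_m=w, study_area_km2=study_area)


class TestTally:
    def test_direct_count(self):
        ds = small_survey([History.BOTH, History.BOTH, History.PILOT_ONLY, History.OBSERVER_ONLY])
        assert tally_histories(ds) == CaptureTally(n10=1, n01=1, n11=2)

    def test_empty(self):
        ds = small_survey([])
        assert tally_histories(ds) == CaptureTally(0, 0, 0)

    def test_missing_history_listed(self):
        ds = small_survey([History.BOTH, None])
        with pytest.raises(ValueError, match=r"\[1\]"):
            tally_histories(ds)

    def test_synthetic_fixture_matches_enumeration(self):
        ds, _ = simulate_survey(mrds_recovery_world(seed=2))
        counts = collections.Counter(d.history for d in ds.detections)
        tally = tally_histories(ds)
        assert tally.n10 == counts[History.PILOT_ONLY]
        assert tally.n01 == counts[History.OBSERVER_ONLY]
        assert tally.n11 == counts[History.BOTH]
        assert tally.total == ds.n_detections


def mr_conditional_loglik(p1, p2, tally):
    """Independent conditional-multinomial log-likelihood for grid search."""
    pd = 1 - (1 - p1) * (1 - p2)
    return (tally.n10 * math.log(p1 * (1 - p2) / pd)
            + tally.n01 * math.log((1 - p1) * p2 / pd)
            + tally.n11 * math.log(p1 * p2 / pd))


class TestFitMrIntercept:
    def test_closed_form(self):
        p1, p2, pd = fit_mr_intercept(CaptureTally(20, 10, 30))
        assert (p1, p2) == (0.75, 0.60)
        assert pd == pytest.approx(0.90)

    def test_matches_grid_search(self):
        tally = CaptureTally(20, 10, 30)
        grid = np.linspace(0.01, 0.99, 981)
        best = max(
            ((a, b) for a in grid for b in grid),
            key=lambda ab: mr_conditional_loglik(*ab, tally),
        )
        p1, p2, _ = fit_mr_intercept(tally)
        assert p1 == pytest.approx(best[0], abs=1e-3)
        assert p2 == pytest.approx(best[1], abs=1e-3)

    def test_all_duplicated(self):
        assert fit_mr_intercept(CaptureTally(0, 0, 7)) == (1.0, 1.0, 1.0)

    def test_no_duplicates_inestimable(self):
        with pytest.raises(ValueError, match="inestimable"):
            fit_mr_intercept(CaptureTally(5, 5, 0))


class TestFitMrds:
    def test_recovery(self):
        ds, _ = simulate_survey(mrds_recovery_world(seed=3))
        fit = fit_mrds(ds)
        assert abs(fit.p_dot - 0.985) < 0.05
        assert abs(fit.curve.apex_c - 300.0) < 40.0

    def test_loglik_is_sum_of_factors(self):
        ds, _ = simulate_survey(mrds_recovery_world(seed=3))
        fit = fit_mrds(ds)
        shape_fit = bs.fit_twopiece_ml(ds.distances(), ds.strip_width_m)
        tally = tally_histories(ds)
        mr_ll = mr_conditional_loglik(fit.p1, fit.p2, tally)
        assert fit.loglik == pytest.approx(shape_fit.loglik + mr_ll, rel=1e-9)

    def test_perfect_observers_reduce_to_cds(self):
        truth = mrds_recovery_world(seed=4)
        truth = type(truth)(**{**truth.__dict__, "p1": 1.0, "p2": 1.0})
        ds, _ = simulate_survey(truth)
        assert all(d.history is History.BOTH for d in ds.detections)
        fit = fit_mrds(ds)
        assert fit.p_dot == 1.0


class TestHorvitzThompson:
    def test_single_detection(self):
        # half-normal-equivalent curve with g(x) = 0.5 at x = σ√(2 ln 2)
        sigma = 200.0
        x_half = sigma * math.sqrt(2 * math.log(2))
        curve = TwoPieceNormalCurve(0.0, sigma, sigma)
        ds = small_survey([History.BOTH], distances=[x_half], sizes=[2], w=600.0,
                          study_area=6.0, lengths=(10.0,))  # covered = study = 6 km²
        fit = MrdsFit(curve=curve, p1=1.0, p2=1.0, p_dot=1.0, loglik=0.0, w=600.0)
        est = estimate_abundance_ht(fit, ds)
        assert est.n_hat == pytest.approx(4.0, rel=1e-9)

    def test_pdot_scaling_law(self):
        curve = TwoPieceNormalCurve(0.0, 200.0, 200.0)
        ds = small_survey([History.BOTH] * 3, distances=[50.0, 150.0, 300.0], w=600.0)
        est1 = estimate_abundance_ht(MrdsFit(curve, 1.0, 1.0, 1.0, 0.0, 600.0), ds)
        est2 = estimate_abundance_ht(MrdsFit(curve, 0.5, 0.0, 0.5, 0.0, 600.0), ds)
        assert est2.n_hat == pytest.approx(2.0 * est1.n_hat, rel=1e-12)

    def test_invariant_to_transect_split(self):
        """Splitting a transect in two halves (same detections) keeps N̂."""
        curve = TwoPieceNormalCurve(0.0, 200.0, 200.0)
        fitted = MrdsFit(curve, 0.9, 0.9, 0.99, 0.0, 600.0)
        whole = small_survey([History.BOTH] * 2, distances=[100.0, 200.0], lengths=(10.0,))
        t0 = Transect("a", dt.date(2020, 6, 1), 5.0)
        t1 = Transect("b", dt.date(2020, 6, 1), 5.0)
        split = SurveyDataset(
            (t0, t1),
            (Detection("a", 100.0, 1, History.BOTH), Detection("b", 200.0, 1, History.BOTH)),
            truncation_w_m=600.0, study_area_km2=100.0,
        )
        assert estimate_abundance_ht(fitted, whole).n_hat == pytest.approx(
            estimate_abundance_ht(fitted, split).n_hat, rel=1e-12
        )

    def test_far_tail_floor(self):
        curve = TwoPieceNormalCurve(0.0, 10.0, 10.0)  # g(600) astronomically small
        ds = small_survey([History.BOTH] * 2, distances=[5.0, 590.0], w=600.0)
        fit = MrdsFit(curve, 1.0, 1.0, 1.0, 0.0, 600.0)
        with pytest.warns(UserWarning, match="g\\(x\\)"):
            est = estimate_abundance_ht(fit, ds)
        assert est.extras["n_dropped_g_floor"] == 1


class TestBootstrap:
    def test_deterministic_under_seed(self):
        ds, _ = simulate_survey(mrds_recovery_world(seed=5))
        a = bootstrap_mrds(ds, B=100, seed=11)
        b = bootstrap_mrds(ds, B=100, seed=11)
        assert (a.lo, a.hi, a.cv) == (b.lo, b.hi, b.cv)

    def test_identical_transects_give_tiny_sd(self):
        transects = tuple(Transect(f"t{i}", dt.date(2020, 6, 1), 10.0) for i in range(40))
        rng = np.random.default_rng(0)
        dets = []
        for t in transects:
            for x in rng.uniform(0, 550, size=3):
                dets.append(Detection(t.id, float(x), 1,
                                      History.BOTH if x % 2 < 1.5 else History.PILOT_ONLY))
        # duplicate the same detection layout on every transect
        base = [(d.distance_m, d.group_size, d.history) for d in dets[:3]]
        dets = tuple(Detection(t.id, x, s, h) for t in transects for (x, s, h) in base)
        ds = SurveyDataset(transects, dets, truncation_w_m=600.0, study_area_km2=100.0)
        est = bootstrap_mrds(ds, B=100, seed=1)
        assert est.cv < 1e-9

    def test_b_minimum(self):
        ds, _ = simulate_survey(mrds_recovery_world(seed=5))
        with pytest.raises(ValueError, match="B must be"):
            bootstrap_mrds(ds, B=50, seed=1)

    def test_cv_shrinks_with_more_transects(self):
        small = mrds_recovery_world(seed=6)
        big = type(small)(**{**small.__dict__, "n_transects": 468,
                             "n_bears": None, "density_bears_km2": 2000.0 / 3000.0})
        ds_small, _ = simulate_survey(small)
        ds_big, _ = simulate_survey(big)
        cv_small = bootstrap_mrds(ds_small, B=100, seed=2).cv
        cv_big = bootstrap_mrds(ds_big, B=100, seed=2).cv
        assert cv_big < cv_small


class TestJointProbabilityBound:
    def test_pdot_at_least_max_observer(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n10, n01 = (int(v) for v in rng.integers(0, 50, size=2))
            n11 = int(rng.integers(1, 60))
            p1, p2, pd = fit_mr_intercept(CaptureTally(n10, n01, n11))
            assert pd >= max(p1, p2) - 1e-12
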