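"""Calibration engine: response fit, update equations, screening,
adjustment loop, confirmation and the full session."""

import itertools

import numpy as np
import pandas as pd
import pytest

from gravical import (
    InvariantError,
    LiquidSpec,
    VolumeSummary,
    adjust_subclass,
    calibrate_liquid,
    confirm_subclass,
    default_criteria,
    derive_test_volumes,
    fit_response_line,
    screen_liquid_classes,
    update_factor_offset,
)
from gravical.calibration import recommend_class, session_report_rows
from gravical.datafiles import SCREENING_REFERENCE, data_path
from gravical.instrument_sim import commanded_volume, measure_volumes

from conftest import make_instrument


def ols_line(x, y):
    """Independent closed-form least-squares oracle."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    xbar, ybar = x.mean(), y.mean()
    slope = ((x - xbar) * (y - ybar)).sum() / ((x - xbar) ** 2).sum()
    return slope, ybar - slope * xbar


class TestFitResponseLine:
    def test_identity_data(self):
        fit = fit_response_line([16, 158, 300], [16, 158, 300])
        assert (fit.a2, fit.b2, fit.r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_matches_closed_form_ols(self):
        x, y = [16, 158, 300], [16.1, 155.9, 295.1]
        fit = fit_response_line(x, y)
        slope, intercept = ols_line(x, y)
        assert fit.a2 == pytest.approx(slope, rel=1e-12)
        assert fit.b2 == pytest.approx(intercept, rel=1e-9)
        # frozen values from the closed form
        assert fit.a2 == pytest.approx(0.982394, abs=5e-6)
        assert fit.b2 == pytest.approx(0.481690, abs=5e-6)

    def test_two_points_fit_exactly(self):
        fit = fit_response_line([10, 20], [11.0, 22.0])
        assert fit.a2 == pytest.approx(1.1)
        assert fit.b2 == pytest.approx(0.0, abs=1e-12)
        assert fit.r2 == pytest.approx(1.0)

    def test_degenerate_x_rejected(self):
        with pytest.raises(InvariantError):
            fit_response_line([100, 100], [99, 101])


class TestUpdateFactorOffset:
    def test_identity_is_fixed_point(self):
        assert update_factor_offset(1, 0, 1, 0) == (1.0, 0.0)

    def test_arithmetic(self):
        assert update_factor_offset(1, 0, 0.5, 2) == pytest.approx((2.0, -4.0))

    def test_update_from_measured_fit(self):
        a2, b2 = ols_line([16, 158, 300], [16.1, 155.9, 295.1])
        new_factor, new_offset = update_factor_offset(1.060, 0.43, a2, b2)
        assert new_factor == pytest.approx(1.0790, abs=5e-5)
        assert new_offset == pytest.approx(-0.052616, abs=5e-6)

    def test_zero_slope_rejected(self):
        with pytest.raises(InvariantError):
            update_factor_offset(1, 0, 0.0, 1)


GRID_P = [0.5, 0.8, 0.95, 1.0, 1.05, 1.2, 1.5]
GRID_Q = [-5.0, 0.0, 2.0, 5.0]


def one_round(sim, lc, sc, liquid):
    """One measure→fit→update round without the accuracy gate."""
    volumes = derive_test_volumes(sc)
    records = measure_volumes(sim, sc, liquid, list(volumes))
    means = [
        np.mean([r.measured_volume for r in records if r.target_volume == v])
        for v in volumes
    ]
    fit = fit_response_line(volumes, means)
    new_factor, new_offset = update_factor_offset(sc.factor, sc.offset, fit.a2, fit.b2)
    return sc.with_calibration(new_factor, new_offset)


class TestConvergenceProperties:
    @pytest.mark.parametrize("p,q", list(itertools.product(GRID_P, GRID_Q)))
    def test_factor_converges_to_inverse_slope_in_one_step(self, serum, ap_liquid, p, q):
        sim = make_instrument(p=p, q=q, resolution=1e-9)
        sc = one_round(sim, serum, serum.subclasses[1], ap_liquid)
        assert abs(sc.factor - 1 / p) / (1 / p) <= 1e-9

    @pytest.mark.parametrize("p,q", list(itertools.product(GRID_P, GRID_Q)))
    def test_offset_iteration_tracks_scalar_oracle(self, serum, ap_liquid, p, q):
        """Simulated updates equal the brute-force iterate b ← (1−p)b − q."""
        sim = make_instrument(p=p, q=q, resolution=1e-9)
        sc = serum.subclasses[1].with_calibration(1.06, 10.0)
        # first update also fixes the factor; oracle starts from its offset
        sc = one_round(sim, serum, sc, ap_liquid)
        oracle_b = sc.offset
        for _ in range(4):
            sc = one_round(sim, serum, sc, ap_liquid)
            oracle_b = (1 - p) * oracle_b - q
            assert sc.factor == pytest.approx(1 / p, rel=1e-9)
            assert sc.offset == pytest.approx(oracle_b, rel=1e-6, abs=1e-6)

    @pytest.mark.parametrize("p,q", [(0.8, 2.0), (0.95, -5.0), (1.2, 5.0), (1.5, -5.0)])
    def test_offset_error_contracts_by_one_minus_p(self, serum, ap_liquid, p, q):
        sim = make_instrument(p=p, q=q, resolution=1e-9)
        b_star = -q / p
        sc = one_round(sim, serum, serum.subclasses[1].with_calibration(1.06, 10.0), ap_liquid)
        err = abs(sc.offset - b_star)
        for _ in range(3):
            sc = one_round(sim, serum, sc, ap_liquid)
            new_err = abs(sc.offset - b_star)
            assert new_err == pytest.approx(abs(1 - p) * err, rel=1e-4, abs=1e-7)
            err = new_err


class TestAdjustSubclass:
    def test_one_update_then_pass_on_identity_instrument(self, serum, ap_liquid):
        """Mis-set factor 1.045/offset 0.20 on a perfect instrument: the first
        round misses the 1% accuracy limit at 300 µL (dev ≈ +4.57%), one
        update restores factor 1 / offset 0, and the second round passes."""
        sim = make_instrument()
        sc = serum.subclasses[1].with_calibration(1.045, 0.20)
        res = adjust_subclass(sim, serum, sc, ap_liquid, default_criteria("serum"))
        assert res.converged and res.attempts_used == 2
        first = res.history[0]
        assert first.summaries[2].pct_dev == pytest.approx(4.57, abs=0.02)
        assert not first.accuracy_results[2].accuracy_passed
        assert res.final_factor == pytest.approx(1.0, abs=2e-3)
        assert res.final_offset == pytest.approx(0.0, abs=0.2)
        assert res.history[-1].fit is None  # passing round computes no update

    def test_already_calibrated_passes_first_attempt(self, serum, ap_liquid):
        sim = make_instrument()
        sc = serum.subclasses[1].with_calibration(1.0, 0.0)
        res = adjust_subclass(sim, serum, sc, ap_liquid)
        assert res.converged and res.attempts_used == 1
        assert res.final_factor == 1.0 and res.final_offset == 0.0

    @pytest.mark.parametrize("idx", [1, 2, 3])
    def test_serum_subclasses_converge_within_budget(self, serum, ap_liquid, idx):
        sim = make_instrument(p=0.95, q=2.0)
        res = adjust_subclass(sim, serum, serum.subclasses[idx - 1], ap_liquid)
        assert res.converged
        assert res.attempts_used <= 4
        # 0.1 mg balance quantization limits the slope estimate at 3–15 µL
        assert res.final_factor == pytest.approx(1 / 0.95, rel=1e-2)

    def test_strong_overdelivery_diverges(self, serum, ap_liquid):
        """With response slope 2.5 the offset error grows by 1.5× per round;
        the large-offset subclass never reaches its accuracy limits."""
        sim = make_instrument(p=2.5, q=2.0)
        res = adjust_subclass(sim, serum, serum.subclasses[2], ap_liquid)
        assert not res.converged
        assert res.attempts_used == 4  # non-convergence is a state, not an error

    def test_history_records_every_attempt(self, serum, ap_liquid):
        sim = make_instrument(p=0.95, q=2.0)
        res = adjust_subclass(sim, serum, serum.subclasses[1], ap_liquid)
        assert len(res.history) == res.attempts_used
        assert all(len(att.summaries) == 3 for att in res.history)


class TestConfirmSubclass:
    def test_noiseless_converged_subclass_passes_with_zero_dev_cv(self, serum, ap_liquid):
        sim = make_instrument(p=0.95, q=2.0)
        adj = adjust_subclass(sim, serum, serum.subclasses[1], ap_liquid)
        sc = serum.subclasses[1].with_calibration(adj.final_factor, adj.final_offset)
        conf = confirm_subclass(sim, serum, sc, ap_liquid)
        assert conf.passed
        assert all(s.n == 16 for s in conf.summaries)
        assert all(s.pct_cv == pytest.approx(0.0, abs=0.05) for s in conf.summaries)

    def test_default_noise_confirmation_cv_band(self, serum, ap_liquid):
        """With the default noise model the two larger volumes of the middle
        subclass confirm with %CV in the 0.1–0.6% band."""
        sim = make_instrument(p=0.98, q=0.5, seed=5)
        sim.noise_cv, sim.noise_floor_sd = 0.004, 0.4
        adj = adjust_subclass(sim, serum, serum.subclasses[1], ap_liquid)
        assert adj.converged
        sc = serum.subclasses[1].with_calibration(adj.final_factor, adj.final_offset)
        conf = confirm_subclass(sim, serum, sc, ap_liquid)
        assert conf.passed
        for s in conf.summaries[1:]:  # 158 and 300 µL
            assert 0.1 <= s.pct_cv <= 0.6

    def test_misset_factor_fails_on_accuracy(self, serum, ap_liquid):
        sim = make_instrument()
        sc = serum.subclasses[1].with_calibration(1.10, 0.0)
        conf = confirm_subclass(sim, serum, sc, ap_liquid)
        assert not conf.passed
        assert not conf.results[2].accuracy_passed


class TestScreening:
    def reference_summaries(self, solvent):
        table = pd.read_csv(data_path(SCREENING_REFERENCE))
        rows = table[table.solvent == solvent]
        return [
            (
                r.liquid_class,
                VolumeSummary(
                    target=300, n=8, mean=r.mean_volume, min=r.min_volume,
                    max=r.max_volume, sd=r.cv_pct * r.mean_volume / 100,
                    pct_dev=r.dev_pct, pct_cv=r.cv_pct,
                ),
            )
            for r in rows.itertuples()
        ]

    def test_reference_probe_of_aluminum_phosphate_recommends_serum(self):
        # serum's 0.23% CV is the minimum of the five classes
        assert recommend_class(self.reference_summaries("AP")) == "serum"

    def test_reference_probe_of_pbs_recommends_water(self):
        assert recommend_class(self.reference_summaries("PBS")) == "water"

    def test_noiseless_tie_falls_back_to_smallest_dev(self, classes, ap_liquid):
        # all classes dispense exactly → CV 0 everywhere; the identity-
        # calibrated liquid-system class has the smallest |%DEV|
        report = screen_liquid_classes(make_instrument(), classes, ap_liquid)
        assert all(s.pct_cv == pytest.approx(0, abs=1e-9) for _, s in report.summaries)
        assert report.recommended == "liquid-system"

    def test_single_class_is_recommended(self, serum, ap_liquid):
        report = screen_liquid_classes(make_instrument(), [serum], ap_liquid)
        assert report.recommended == "serum"

    def test_recommendation_invariant_under_class_order(self, classes, ap_liquid):
        # deterministic per-tip biases give each class a distinct nonzero %CV
        bias = (0.3, -0.2, 0.1, 0.0, -0.1, 0.2, -0.3, 0.05)

        def run(ordering):
            return screen_liquid_classes(
                make_instrument(p=0.97, q=1.0, tip_bias=bias), ordering, ap_liquid
            ).recommended

        assert run(list(reversed(classes))) == run(classes)


class TestFullSession:
    def test_noiseless_miscalibrated_instrument_all_pass(self, classes, tmp_path):
        from gravical import read_liquid_class_xml

        sim = make_instrument(p=0.95, q=2.0)
        liquid = LiquidSpec("PBS", 1.020)
        out_xml = tmp_path / "cal.xml"
        out_csv = tmp_path / "report.csv"
        report = calibrate_liquid(
            sim, classes, liquid, out_xml=out_xml, out_report=out_csv
        )
        assert report.all_passed
        assert report.calibrated_class is not None
        (persisted,) = read_liquid_class_xml(out_xml)
        assert persisted.name == f"PBS_{report.selected_class}"
        # the factor inverts the latent slope on every subclass (to within
        # the balance quantization of the small-volume subclass)
        for sc in persisted.subclasses:
            assert sc.factor == pytest.approx(1 / 0.95, rel=1e-2)
        # every confirmed volume meets its accuracy criteria
        for sub in report.subclasses:
            assert sub.persisted and sub.confirmation.passed
        assert out_csv.exists()

    def test_calibrated_transfer_meets_accuracy_criteria_everywhere(self, classes):
        sim = make_instrument(p=0.95, q=2.0)
        liquid = LiquidSpec("PBS", 1.020)
        report = calibrate_liquid(sim, classes, liquid)
        selected = next(lc for lc in classes if lc.name == report.selected_class)
        criteria = default_criteria(selected.name)
        for idx, sc in enumerate(report.calibrated_class.subclasses, start=1):
            for vol_idx, v in enumerate(derive_test_volumes(sc), start=1):
                delivered = 0.95 * commanded_volume(v, sc.factor, sc.offset) + 2.0
                dev = (delivered - v) / v * 100
                assert abs(dev) <= criteria.cell(idx, vol_idx).max_abs_dev

    def test_divergent_subclass_reported_not_raised(self, serum, ap_liquid):
        sim = make_instrument(p=2.5, q=2.0)
        report = calibrate_liquid(sim, [serum], ap_liquid)
        assert not report.all_passed
        statuses = {s.subclass_idx: s.adjustment.converged for s in report.subclasses}
        assert statuses[3] is False

    def test_seeded_session_report_is_deterministic(self, classes, ap_liquid):
        def rows(seed):
            sim = make_instrument(p=0.97, q=1.0, noise_cv=0.004, seed=seed)
            sim.noise_floor_sd = 0.4
            return session_report_rows(calibrate_liquid(sim, classes, ap_liquid))

        assert rows(7) == rows(7)
        assert rows(7) != rows(8)
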