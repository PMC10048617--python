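"""Calibration: AT, stutter regressions, drop-in, saturation, Hb variance."""

import math
import warnings
from fractions import Fraction

import numpy as np
import pytest

import dscspg as d
from dscspg.simulate import NoiseRecord


def _noise(high, low, dyes=("Blue", "Green", "Yellow", "Red", "Purple")):
    return NoiseRecord(
        "n", {dy: high for dy in dyes}, {dy: low for dy in dyes},
        d.Epg("n", {}),
    )


class TestAnalyticalThresholdEstimation:
    def test_direct_arithmetic(self):
        est = d.estimate_analytical_threshold([_noise(30.0, -5.0)])
        assert all(v == pytest.approx(70.0) for v in est.by_dye.values())

    def test_degenerate_flat_baseline(self):
        est = d.estimate_analytical_threshold([_noise(12.0, 12.0)])
        assert all(v == 0.0 for v in est.by_dye.values())

    def test_non_extreme_control_changes_nothing(self):
        base = [_noise(30.0, -5.0)]
        extended = base + [_noise(10.0, -2.0)]
        assert (
            d.estimate_analytical_threshold(base).by_dye
            == d.estimate_analytical_threshold(extended).by_dye
        )

    def test_monotone_in_controls(self):
        rng = np.random.default_rng(4)
        controls = [_noise(float(rng.uniform(5, 40)), float(rng.uniform(-20, 0)))
                    for _ in range(10)]
        prev = 0.0
        for k in range(1, 11):
            at = d.estimate_analytical_threshold(controls[:k]).by_dye["Blue"]
            assert at >= prev
            prev = at

    def test_empty_controls_rejected(self):
        with pytest.raises(ValueError):
            d.estimate_analytical_threshold([])


class TestStutterFitting:
    def test_worked_regression_line(self):
        # the fitted back-stutter line for D16S539 evaluated at allele 11
        fit = d.StutterFit("linear", slope=0.0177, intercept=-0.1249)
        model = d.StutterModel()
        model.set_fit("D16S539", "back", fit)
        assert model.predict("D16S539", "back", 11) == pytest.approx(0.0698)

    def test_zero_stutter_data_fits_zero(self, panel, freqs, donors):
        epgs = [d.clean_epg_from_reference(p, panel) for p in donors[:5]]
        model = d.fit_stutter_model(epgs, donors[:5], panel)
        for locus, by_type in model.fits.items():
            for st, fit in by_type.items():
                assert fit.predict(11.0) == pytest.approx(0.0, abs=1e-12)

    def test_parameter_recovery_within_two_se(self, panel, freqs):
        slope, intercept = 0.02, -0.10
        gen = d.StutterModel()
        for locus in panel.names:
            gen.set_fit(locus, "back", d.StutterFit("linear", slope=slope,
                                                    intercept=intercept))
        cfg = d.SimulationConfig(cv_peak=0.3, lsae_sd=0.1, drop_in_rate=0.0,
                                 stutter=gen, stutter_sr_sd=0.01)
        donors = d.sample_reference_profiles(freqs, 10, 5)
        at = d.AnalyticalThresholds()
        subs, truths = [], []
        for i, seed in enumerate(d.child_seeds(6, 200)):
            donor = donors[i % 10]
            epg = d.simulate_subsample([(donor, 3)], cfg, panel, seed, freqs=freqs)
            subs.append(d.apply_analytical_threshold(epg, at, panel))
            truths.append(donor)
        fitted = d.fit_stutter_model(subs, truths, panel)
        checked = 0
        for locus in panel.names:
            fit = fitted.get_fit(locus, "back")
            if fit is None or fit.kind != "linear" or fit.n < 30:
                continue
            assert abs(fit.slope - slope) < 2 * fit.slope_se + 1e-3
            checked += 1
        assert checked >= 5


class TestDropInEstimation:
    def _control(self, n_peaks, height=300.0):
        peaks = [d.Peak(7.0 + i, height, 110 + 4 * i) for i in range(n_peaks)]
        return d.Epg("c", {"TH01": peaks} if peaks else {}, at_applied=True)

    def test_exact_quotient_over_735_opportunities(self, panel):
        controls = [self._control(1) for _ in range(11)] + [
            self._control(0) for _ in range(24)
        ]
        est = d.estimate_drop_in_rate(controls, panel)
        assert est.opportunities == 35 * 21 == 735
        assert est.events == 11
        assert est.rate == 11 / 735
        assert est.rate_exact == Fraction(11, 735)

    def test_zero_events_gives_floor_cap(self, panel):
        est = d.estimate_drop_in_rate([self._control(0) for _ in range(10)], panel)
        assert est.rate == 0.0
        assert est.cap_suggested == 1000.0

    def test_cap_rounds_up_to_next_thousand(self, panel):
        controls = [self._control(1, height=4800.0)] + [
            self._control(0) for _ in range(34)
        ]
        est = d.estimate_drop_in_rate(controls, panel)
        assert est.cap_suggested == 5000.0

    def test_contamination_warning_beyond_two_peaks(self, panel):
        with pytest.warns(UserWarning, match="contamination"):
            est = d.estimate_drop_in_rate([self._control(4)], panel)
        assert est.events == 2  # excess not counted as drop-in

    def test_no_controls_rejected(self, panel):
        with pytest.raises(ValueError):
            d.estimate_drop_in_rate([], panel)


def _saturation_standards(panel, freqs, saturation, n=60, seed=13):
    """High-template single-source profiles spanning the detector range."""
    gen = d.simple_stutter_model(loci=[loc.name for loc in panel])
    donors = d.sample_reference_profiles(freqs, 10, seed)
    at = d.AnalyticalThresholds()
    cfg_base = dict(cv_peak=0.25, lsae_sd=0.1, drop_in_rate=0.0,
                    stutter=gen, stutter_sr_sd=0.005, saturation=saturation)
    subs, truths = [], []
    for i, s in enumerate(d.child_seeds(seed + 1, n)):
        cfg = d.SimulationConfig(
            mean_height_per_cell=1500.0 + 1500.0 * (i % 8), **cfg_base
        )
        donor = donors[i % 10]
        epg = d.simulate_subsample([(donor, 5)], cfg, panel, s, freqs=freqs)
        subs.append(d.apply_analytical_threshold(epg, at, panel))
        truths.append(donor)
    return subs, truths, gen


class TestSaturation:
    def test_clipping_at_30000_detected_within_one_bin(self, panel, freqs):
        subs, truths, gen = _saturation_standards(panel, freqs, 30000.0)
        est = d.estimate_saturation_threshold(subs, truths, gen, panel)
        assert est is not None
        assert abs(est - 30000.0) <= 2000.0

    def test_clipping_at_10000_detected_within_one_bin(self, panel, freqs):
        subs, truths, gen = _saturation_standards(panel, freqs, 10000.0)
        est = d.estimate_saturation_threshold(subs, truths, gen, panel)
        assert est is not None
        assert abs(est - 10000.0) <= 2000.0

    def test_no_clipping_detects_nothing(self, panel, freqs):
        subs, truths, gen = _saturation_standards(panel, freqs, 10_000_000.0)
        est = d.estimate_saturation_threshold(subs, truths, gen, panel)
        assert est is None

    def test_insufficient_pairs_rejected(self, panel, freqs):
        subs, truths, gen = _saturation_standards(panel, freqs, 30000.0, n=1)
        with pytest.raises(ValueError, match="pairs"):
            d.estimate_saturation_threshold(subs[:1], truths[:1], gen, panel)


def _hb_epgs_from_points(panel, points):
    """Synthetic heterozygote observations at given (APH, log10 Hb)."""
    locus = "TH01"
    truth = d.ReferenceProfile("x", {locus: (7.0, 9.0)})
    epgs, truths = [], []
    lo_size = panel.size_of(locus, 7.0)
    hi_size = panel.size_of(locus, 9.0)
    for aph, lhb in points:
        r = 10.0 ** lhb  # larger-size over smaller-size
        lo = 2 * aph / (1 + r)
        hi = r * lo
        epgs.append(d.Epg("s", {locus: [
            d.Peak(7.0, lo, lo_size), d.Peak(9.0, hi, hi_size)]}))
        truths.append(truth)
    return epgs, truths


class TestHeterozygoteBalance:
    def test_perfectly_balanced_data(self, panel):
        epgs, truths = _hb_epgs_from_points(panel, [(1000.0, 0.0)] * 40)
        hb = d.heterozygote_balance_bounds(epgs, truths)
        assert hb.c_squared == pytest.approx(0.0, abs=1e-12)
        assert hb.within_bounds_fraction == 1.0

    def test_gaussian_coverage_at_95(self, panel):
        c2 = 800.0
        rng = np.random.default_rng(8)
        points = []
        for _ in range(5000):
            aph = float(rng.uniform(200, 5000))
            points.append((aph, float(rng.normal(0.0, math.sqrt(c2 / aph)))))
        epgs, truths = _hb_epgs_from_points(panel, points)
        hb = d.heterozygote_balance_bounds(epgs, truths, k=1.96)
        assert hb.within_bounds_fraction == pytest.approx(0.95, abs=0.02)
        assert hb.c_squared == pytest.approx(c2, rel=0.1)

    def test_low_template_bounds_broader(self, panel, freqs, donors):
        # moderate noise keeps analytical-threshold censoring of extreme
        # imbalance mild, so the observed variance ordering reflects template
        at = d.AnalyticalThresholds()

        def collect(cells, seed):
            cfg = d.SimulationConfig(drop_in_rate=0.0, cv_peak=0.8)
            subs, truths = [], []
            for i, s in enumerate(d.child_seeds(seed, 150)):
                donor = donors[i % len(donors)]
                epg = d.simulate_subsample([(donor, cells)], cfg, panel, s,
                                           freqs=freqs)
                subs.append(d.apply_analytical_threshold(epg, at, panel))
                truths.append(donor)
            return d.heterozygote_balance_bounds(subs, truths)

        one = collect(1, 31)
        five = collect(5, 32)
        assert one.c_squared > five.c_squared
        for aph in (500.0, 2000.0, 10000.0):
            assert one.bounds(aph) > five.bounds(aph)

    def test_no_heterozygote_observations_rejected(self, panel):
        truth = d.ReferenceProfile("x", {"TH01": (7.0, 7.0)})
        epg = d.Epg("s", {"TH01": [d.Peak(7.0, 1000.0, 173.0)]})
        with pytest.raises(ValueError):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                d.heterozygote_balance_bounds([epg], [truth])


def test_calibration_round_trip(tmp_path, panel, freqs):
    controls = [_noise(30.0, -5.0), _noise(25.0, -8.0)]
    at = d.estimate_analytical_threshold(controls)
    stutter = d.StutterModel()
    stutter.set_fit("D16S539", "back",
                    d.StutterFit("linear", slope=0.0177, intercept=-0.1249, n=40))
    drop_in = d.DropInEstimate(rate=11 / 735, events=11, opportunities=735,
                               cap_suggested=5000.0)
    hb = d.HbBounds(c_squared=900.0, k=1.96, within_bounds_fraction=0.93, n=400)
    result = d.CalibrationResult(at=at, stutter=stutter, drop_in=drop_in,
                                 saturation_rfu=30000.0, hb=hb)
    path = tmp_path / "calibration.yaml"
    d.write_calibration(result, path)
    back = d.read_calibration(path)
    assert back.at.by_dye == at.by_dye
    assert back.stutter.predict("D16S539", "back", 11) == stutter.predict(
        "D16S539", "back", 11)
    assert back.drop_in.events == 11 and back.drop_in.opportunities == 735
    assert back.saturation_rfu == 30000.0
    assert back.hb.bounds(1000.0) == hb.bounds(1000.0)
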