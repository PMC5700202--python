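import numpy as np
import pytest
from dataclasses import replace

from mpsquant import (PatternParams, RunConfig, SimulationConfig, SubregionRecord,
                      analyze_image, fit_trend, records_to_frame, simulate,
                      solve_background_for_sbr, summarize)


def _records_with_rp(rps, threshold):
    return [
        SubregionRecord("img", 0, i, neuronal=True, direction_valid=True,
                        theta_n=0.0, best_rp=rp, best_theta=0.0, best_phi=0.0,
                        detected=rp > threshold)
        for i, rp in enumerate(rps)
    ]


class TestSummarize:
    def test_abundance_and_regularity_arithmetic(self):
        s = summarize(_records_with_rp([0.1, 0.3, 0.5], 0.2), 0.2)
        assert s.n_analyzed == 3
        assert s.abundance == pytest.approx(2 / 3)
        assert s.mean_rp_above == pytest.approx(0.4)

    def test_all_below_threshold(self):
        s = summarize(_records_with_rp([0.05, 0.1], 0.2), 0.2)
        assert s.abundance == 0.0
        assert s.mean_rp_above is None

    def test_detection_map_sums_to_detected(self):
        recs = _records_with_rp([0.1, 0.3, 0.5, 0.25], 0.2)
        s = summarize(recs, 0.2)
        assert s.detection_map.sum() == s.n_detected == 3
        assert s.detection_map.dtype == np.uint8

    def test_no_analyzable_tiles(self):
        recs = [SubregionRecord("img", 0, 0, neuronal=False, direction_valid=False)]
        s = summarize(recs, 0.2)
        assert s.n_analyzed == 0 and s.abundance is None

    def test_ambiguous_direction_denominator_switch(self):
        recs = _records_with_rp([0.5], 0.2) + [
            SubregionRecord("img", 0, 1, neuronal=True, direction_valid=False)
        ]
        assert summarize(recs, 0.2).abundance == 1.0
        assert summarize(recs, 0.2, ambiguous_as_negative=True).abundance == 0.5

    def test_raising_threshold_never_raises_abundance(self):
        rps = [0.1, 0.15, 0.22, 0.3, 0.45]
        abundances = []
        for t in (0.1, 0.2, 0.3, 0.4):
            abundances.append(summarize(_records_with_rp(rps, t), t).abundance)
        assert abundances == sorted(abundances, reverse=True)


@pytest.fixture(scope="module")
def neurite_field():
    """3x3 um image with one straight structured neurite at SBR 8."""
    cfg = SimulationConfig(pattern=PatternParams(phi=0.7), theta_true=30.0,
                           seed=3, image_size=3000.0, neurite_length=4200.0)
    return simulate(solve_background_for_sbr(cfg, 8.0))


class TestAnalyzeImage:
    def test_structured_neurite_abundance(self, neurite_field):
        recs = analyze_image(neurite_field.image.astype(float), 20.0, RunConfig(),
                             threshold=0.2, image_id="field")
        assert len(recs) == 9                      # one record per tile
        s = summarize(recs, 0.2)
        assert s.n_analyzed >= 3                   # neurite crosses >= 3 tiles
        assert s.abundance >= 0.8
        frame = records_to_frame(recs)
        assert list(frame.columns) == [
            "image_id", "tile_row", "tile_col", "neuronal", "direction_valid",
            "theta_n_deg", "best_rp", "best_theta_deg", "best_phi_rad", "detected"]

    def test_pure_background_image_detects_nothing(self):
        """A structure-free background image yields no detections.

        The relative mean/std threshold always marks the brightest tail of
        the filtered noise, so some tiles may be flagged as neuronal, but
        none of them correlates with the periodic pattern.
        """
        cfg = SimulationConfig(label_density=0.0, nonspecific_density=0.0,
                               bg_mean=20.0, seed=9, image_size=2000.0)
        sim = simulate(cfg)
        recs = analyze_image(sim.image.astype(float), 20.0, RunConfig(), threshold=0.2)
        assert not any(r.detected for r in recs)
        s = summarize(recs, 0.2)
        assert s.abundance in (None, 0.0)

    def test_determinism(self, neurite_field):
        img = neurite_field.image.astype(float)
        a = analyze_image(img, 20.0, RunConfig(), 0.2, image_id="x")
        b = analyze_image(img, 20.0, RunConfig(), 0.2, image_id="x")
        assert a == b

    def test_record_state_invariants(self, neurite_field):
        recs = analyze_image(neurite_field.image.astype(float), 20.0, RunConfig(), 0.2)
        for r in recs:
            if r.detected:
                assert r.neuronal and r.direction_valid and r.best_rp is not None
            if not r.neuronal:
                assert r.theta_n is None and r.best_rp is None
            if r.neuronal and not r.direction_valid:
                assert r.best_rp is None


class TestFitTrend:
    @staticmethod
    def logistic(x, y0, y1, x50, tau):
        return y0 + (y1 - y0) / (1.0 + np.exp(-(x - x50) / tau))

    def test_noiseless_midpoint_recovered_exactly(self):
        x = np.linspace(2, 40, 12)
        y = self.logistic(x, 0.05, 0.8, 9.0, 2.0)
        fit = fit_trend(x, y, "sigmoid")
        assert fit.converged
        assert fit.midpoint == pytest.approx(9.0, abs=0.01)

    def test_noisy_midpoint_within_one_unit(self, rng):
        x = np.linspace(2, 30, 10)
        errors = []
        for _ in range(50):
            y = self.logistic(x, 0.05, 0.8, 9.0, 2.0) + rng.normal(0, 0.02, x.size)
            fit = fit_trend(x, y, "sigmoid")
            if fit.converged:
                errors.append(abs(fit.midpoint - 9.0))
        assert len(errors) >= 45
        assert np.median(errors) <= 1.0

    def test_constant_data_flagged_not_raised(self):
        fit = fit_trend([2, 8, 14, 28], [0.3, 0.3, 0.3, 0.3], "sigmoid")
        assert not fit.converged and fit.midpoint is None

    def test_exponential_trend(self):
        x = np.linspace(2, 40, 8)
        y = 0.1 + 0.7 * (1 - np.exp(-x / 6.0))
        fit = fit_trend(x, y, "exponential")
        assert fit.converged
        assert fit.params["tau"] == pytest.approx(6.0, rel=0.01)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2, 3], [0.1, 0.2, 0.3], "sigmoid")

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            fit_trend([1, 2, 3, 4], [0.1, 0.2, 0.3, 0.4], "wiggle")
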