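import numpy as np
import pytest

from beatline.beat_model import (FiducialSet, fiducials_from_masks,
                                 masks_from_fiducials)
from beatline.measure import (DelineationError, ThresholdSet,
                              calibrate_p_threshold, calibrate_thresholds,
                              delineate_maps, detect_fiducials, p_detect)
from beatline.nets import make_input
from beatline.synth import SynthParams, generate_dataset
from conftest import random_fiducials

HALF = ThresholdSet()


class TestPDetect:
    def test_flat_zero_map_rejects(self):
        assert not p_detect(np.zeros((512, 3)), 0.5)

    def test_threshold_is_inclusive(self):
        maps = np.zeros((512, 3))
        maps[100, 0] = 0.5
        assert p_detect(maps, 0.5)

    def test_clear_peak_detected(self):
        maps = np.zeros((512, 3))
        maps[100, 0] = 0.9
        assert p_detect(maps, 0.5)


class TestDetectFiducials:
    def test_step_map_half_open(self):
        f = FiducialSet(p_onset=100, p_offset=150, qrs_onset=200,
                        qrs_offset=260, t_offset=400)
        maps = masks_from_fiducials(f).values
        assert detect_fiducials(maps, HALF) == f

    def test_binary_maps_equal_mask_inverse(self, rng):
        for _ in range(200):
            f = random_fiducials(rng)
            maps = masks_from_fiducials(f).values
            assert detect_fiducials(maps, HALF) == fiducials_from_masks(
                masks_from_fiducials(f))

    def test_linear_ramp_onset_index(self):
        maps = np.zeros((512, 3))
        maps[:, 1] = np.arange(512) / 511.0
        maps[:, 2] = maps[:, 1]
        thr = ThresholdSet(thr_qrs_onset=0.25)
        f = detect_fiducials(maps, thr)
        assert f.qrs_onset == 128      # first sample with p >= 0.25

    def test_longest_run_wins_over_neighbor_bump(self):
        maps = np.zeros((512, 3))
        maps[10:30, 1] = 0.9           # neighbour-beat remnant
        maps[200:300, 1] = 0.9         # the central QRS
        maps[200:420, 2] = 0.9
        f = detect_fiducials(maps, HALF)
        assert (f.qrs_onset, f.qrs_offset) == (200, 300)

    def test_subthreshold_qrs_raises(self):
        maps = np.zeros((512, 3))
        maps[200:420, 2] = 0.9
        with pytest.raises(DelineationError):
            detect_fiducials(maps, HALF)
        assert delineate_maps(maps, HALF).failed

    def test_cross_channel_ordering_coerced_and_flagged(self):
        maps = np.zeros((512, 3))
        maps[200:300, 1] = 0.9
        maps[100:250, 2] = 0.9         # QT run ends before QRS offset
        result = delineate_maps(maps, HALF)
        assert result.coerced
        assert result.fiducials.t_offset >= result.fiducials.qrs_offset

    @pytest.mark.parametrize("which", ["onset", "offset"])
    def test_threshold_monotonicity_on_unimodal_maps(self, rng, which):
        # raising an onset threshold never moves the onset earlier;
        # raising an offset threshold never moves the offset later
        t = np.arange(512)
        for _ in range(25):
            center = rng.uniform(150, 350)
            width = rng.uniform(10, 60)
            bump = np.exp(-0.5 * ((t - center) / width) ** 2)
            maps = np.stack([bump, bump, bump], axis=1)
            prev = None
            for theta in np.linspace(0.05, 0.95, 19):
                thr = ThresholdSet(thr_qrs_onset=theta, thr_qrs_offset=theta,
                                   thr_t_offset=theta)
                f = detect_fiducials(maps, thr)
                value = f.qrs_onset if which == "onset" else f.qrs_offset
                if prev is not None:
                    if which == "onset":
                        assert value >= prev
                    else:
                        assert value <= prev
                prev = value


class TestCalibratePThreshold:
    def test_separated_classes_midpoint(self):
        scores = [(0.9, True), (0.8, True), (0.1, False), (0.2, False)]
        thr = calibrate_p_threshold(scores)
        assert thr == pytest.approx(0.5)
        assert all(s >= thr for s, y in scores if y)
        assert all(s < thr for s, y in scores if not y)

    def test_matches_exhaustive_scan(self, rng):
        for _ in range(20):
            scores = [(float(rng.random()), bool(rng.random() < 0.5))
                      for _ in range(30)]
            if len({y for _, y in scores}) < 2:
                continue
            thr = calibrate_p_threshold(scores)
            pos = [s for s, y in scores if y]
            neg = [s for s, y in scores if not y]

            def j(theta):
                return (np.mean([s >= theta for s in pos])
                        + np.mean([s < theta for s in neg]))

            grid = np.linspace(-0.01, 1.01, 4000)
            assert j(thr) >= max(j(g) for g in grid) - 1e-12

    def test_interleaved_scores_at_chance(self):
        scores = [(0.1, True), (0.2, False), (0.3, True), (0.4, False),
                  (0.5, True), (0.6, False), (0.7, True), (0.8, False)]
        thr = calibrate_p_threshold(scores)
        pos = [s for s, y in scores if y]
        neg = [s for s, y in scores if not y]
        j = np.mean([s >= thr for s in pos]) + np.mean([s < thr for s in neg])
        assert j == pytest.approx(1.0)     # chance level

    def test_one_class_rejected(self):
        with pytest.raises(ValueError):
            calibrate_p_threshold([(0.9, True), (0.8, True)])


class _MapModel:
    """Stub network returning precomputed probability maps."""

    def __init__(self, maps):
        self.maps = np.asarray(maps)

    def forward_batch(self, x, train=False):
        assert len(x) == len(self.maps)
        return self.maps


def _soft_maps(fids, steep=2.0, shift=0):
    """Logistic-edged probability maps around reference fiducials."""
    t = np.arange(512)

    def edge(on, off):
        return (1.0 / (1.0 + np.exp(-(t - (on + shift)) / steep))
                * 1.0 / (1.0 + np.exp((t - (off + shift)) / steep)))

    maps = np.zeros((512, 3))
    if fids.p_present:
        maps[:, 0] = edge(fids.p_onset, fids.p_offset)
    maps[:, 1] = edge(fids.qrs_onset, fids.qrs_offset)
    maps[:, 2] = edge(fids.qrs_onset, fids.t_offset)
    return maps


class TestCalibrateThresholds:
    @pytest.fixture(scope="class")
    @classmethod
    def calib_set(cls):
        return generate_dataset(SynthParams(n_beats=60, seed=77))

    def test_binary_reference_maps_yield_default_half(self, calib_set):
        maps = [masks_from_fiducials(f).values for _, f in calib_set]
        thr, report = calibrate_thresholds(_MapModel(maps), calib_set)
        assert thr.thr_qrs_onset == pytest.approx(0.5, abs=0.01)
        for name, st in report.te_stats.items():
            assert st.mean == pytest.approx(0.0, abs=1e-9)
        assert report.tpr == 1.0 and report.tnr == 1.0

    def test_logistic_edges_calibrate_near_half(self, calib_set):
        maps = [_soft_maps(f) for _, f in calib_set]
        thr, report = calibrate_thresholds(_MapModel(maps), calib_set)
        # the logistic edge is symmetric about the true boundary
        for name in ("thr_qrs_onset", "thr_qrs_offset", "thr_t_offset"):
            assert getattr(thr, name) == pytest.approx(0.5, abs=0.15)
        for st in report.te_stats.values():
            assert abs(st.mean) <= 0.5     # ms

    def test_shifted_maps_are_compensated(self, calib_set):
        maps = [_soft_maps(f, shift=2) for _, f in calib_set]
        thr, report = calibrate_thresholds(_MapModel(maps), calib_set)
        assert thr.thr_qrs_onset < 0.5     # earlier crossing compensates +2
        for st in report.te_stats.values():
            assert abs(st.mean) <= 0.5     # ms

    def test_grid_fallback_warns_when_unbracketable(self, calib_set):
        # maps shifted so far that no threshold zeroes the error
        maps = [_soft_maps(f, shift=25) for _, f in calib_set]
        thr, report = calibrate_thresholds(_MapModel(maps), calib_set)
        assert report.warnings
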