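import itertools

import numpy as np
import pytest

from beatline.beat_model import DurationSet, FiducialSet
from beatline.evalx import (DetectionCounts, ErrorStats, ToleranceTable,
                            cap_outliers_3sd, detection_rates,
                            drop_k_protocol, duration_errors,
                            noise_duration_errors, raw_stats, time_errors,
                            tolerance_check, trimmed_stats)


class TestTrimmedStats:
    def test_symmetric_values_all_kept(self):
        st = trimmed_stats([-2, -1, 0, 1, 2])
        assert st.mean == 0.0
        assert st.std == pytest.approx(np.sqrt(2.5))
        assert st.n_used == 5

    def test_single_outlier_trimmed(self):
        st = trimmed_stats([0.0] * 99 + [1000.0])
        assert (st.mean, st.std) == (0.0, 0.0)
        assert st.n_used == 99

    def test_constant_values(self):
        st = trimmed_stats([3.5] * 7)
        assert (st.mean, st.std) == (3.5, 0.0)

    def test_q_one_equals_raw(self, rng):
        v = rng.normal(size=50)
        full = trimmed_stats(v, q=1.0)
        raw = raw_stats(v)
        assert full.mean == raw.mean and full.std == raw.std
        assert full.n_used == 50

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            trimmed_stats([])


class TestCapOutliers:
    def test_all_equal_unchanged(self):
        v = cap_outliers_3sd([2.0, 2.0, 2.0])
        assert np.array_equal(v, [2.0, 2.0, 2.0])

    def test_single_pass_clamp(self):
        # mean 10, sample std exactly 100 -> band [-290, 310]
        v = cap_outliers_3sd([0.0] * 99 + [1000.0])
        assert v[-1] == pytest.approx(310.0)
        assert np.all(v[:-1] == 0.0)

    def test_inside_band_is_identity(self, rng):
        v = rng.normal(size=40)
        assert np.array_equal(cap_outliers_3sd(v), v)


def brute_force_drop_k(values, k):
    """Remove the size-k subset with the largest total |v - mean|."""
    v = np.asarray(values, dtype=float)
    mean = v.mean()
    best = max(itertools.combinations(range(v.size), k),
               key=lambda idx: sum(abs(v[i] - mean) for i in idx))
    keep = np.delete(v, best)
    return keep.mean(), keep.std(ddof=1) if keep.size > 1 else 0.0


class TestDropKProtocol:
    @pytest.mark.parametrize("values,k,expected", [
        ([3.0] * 100, 8, (3.0, 0.0)),
        ([0.0] * 92 + [100.0] * 8, 8, (0.0, 0.0)),
        ([0.0] * 8 + [5.0, -5.0], 2, (0.0, 0.0)),
    ])
    def test_known_cases(self, values, k, expected):
        st = drop_k_protocol(values, k)
        assert (st.mean, st.std) == pytest.approx(expected)
        assert st.n_used == len(values) - k

    def test_matches_brute_force_oracle(self, rng):
        for n in range(5, 13):
            for k in (1, 2, 4):
                v = rng.normal(size=n)
                st = drop_k_protocol(v, k)
                mean, std = brute_force_drop_k(v, k)
                assert st.mean == pytest.approx(mean)
                assert st.std == pytest.approx(std)

    def test_k_zero_equals_raw(self, rng):
        v = rng.normal(size=20)
        st = drop_k_protocol(v, 0)
        raw = raw_stats(v)
        assert (st.mean, st.std) == (raw.mean, raw.std)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            drop_k_protocol([1.0, 2.0], 2)


def fids(qrs_on=150, qrs_off=200, t_off=350, p=None):
    if p is None:
        return FiducialSet(qrs_onset=qrs_on, qrs_offset=qrs_off,
                           t_offset=t_off, p_present=False)
    return FiducialSet(p_onset=p[0], p_offset=p[1], qrs_onset=qrs_on,
                       qrs_offset=qrs_off, t_offset=t_off)


class TestTimeErrors:
    def test_identical_measurements_zero(self):
        ref = [fids(p=(50, 100)), fids()]
        te, counts = time_errors(ref, ref)
        assert all(v == 0.0 for vs in te.values() for v in vs)
        assert (counts.tp, counts.tn) == (1, 1)

    def test_two_sample_error_is_four_ms(self):
        te, _ = time_errors([fids(qrs_on=152)], [fids(qrs_on=150)], fs=500)
        assert te["qrs_onset"] == [4.0]

    def test_false_positive_p_excluded_from_te(self):
        meas = [fids(p=(50, 100))]
        ref = [fids()]
        te, counts = time_errors(meas, ref)
        assert te["p_onset"] == [] and te["p_offset"] == []
        assert counts.fp == 1 and counts.tp == 0

    def test_failed_beat_skipped(self):
        te, _ = time_errors([None, fids()], [fids(), fids()])
        assert len(te["qrs_onset"]) == 1

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            time_errors([fids()], [fids(), fids()])


class TestDurationErrors:
    def test_equal_durations_zero(self):
        d = [DurationSet(qrs_dur=100, qt_int=400, p_dur=80, pq_int=160)]
        assert duration_errors(d, d)["qt_int"] == [0.0]

    def test_signed_difference(self):
        meas = [DurationSet(qrs_dur=100, qt_int=404.0)]
        ref = [DurationSet(qrs_dur=100, qt_int=400.0)]
        assert duration_errors(meas, ref)["qt_int"] == [4.0]

    def test_absent_p_excluded(self):
        meas = [DurationSet(qrs_dur=100, qt_int=400, p_dur=80, pq_int=160)]
        ref = [DurationSet(qrs_dur=100, qt_int=400)]
        de = duration_errors(meas, ref)
        assert de["p_dur"] == [] and de["pq_int"] == []
        assert de["qrs_dur"] == [0.0]


class TestNoiseDurationErrors:
    def test_sign_convention_shortening_positive(self):
        clean = [DurationSet(qrs_dur=100.0, qt_int=400, p_dur=100, pq_int=160)]
        noisy = [DurationSet(qrs_dur=96.0, qt_int=400, p_dur=105, pq_int=160)]
        de = noise_duration_errors(clean, noisy)
        assert de["qrs_dur"] == [4.0]       # shortened measurement
        assert de["p_dur"] == [-5.0]        # prolonged measurement

    def test_identical_zero(self):
        d = [DurationSet(qrs_dur=100, qt_int=400)]
        assert noise_duration_errors(d, d)["qt_int"] == [0.0]

    def test_unpaired_rejected(self):
        with pytest.raises(ValueError):
            noise_duration_errors([], [DurationSet(qrs_dur=1, qt_int=2)])


class TestToleranceCheck:
    def test_compliant_pq_statistics_pass(self):
        stats = {"pq_int": ErrorStats(0.9, 5.8, 92, 92, "drop_k")}
        assert tolerance_check(stats)["pq_int"] is True

    def test_wide_pq_std_fails(self):
        stats = {"pq_int": ErrorStats(-0.8, 14.0, 92, 92, "drop_k")}
        verdict = tolerance_check(stats)
        assert verdict["pq_int"] is False and verdict["overall"] is False

    def test_zero_errors_pass_everywhere(self):
        stats = {name: ErrorStats(0.0, 0.0, 92, 92, "drop_k")
                 for name in ("p_dur", "pq_int", "qrs_dur", "qt_int")}
        verdict = tolerance_check(stats, ToleranceTable())
        assert verdict["overall"] is True


class TestDetectionRates:
    def test_reported_rates(self):
        tpr, tnr = detection_rates(DetectionCounts(tp=504, fn=23, tn=74, fp=2))
        assert tpr == pytest.approx(0.956, abs=5e-4)
        assert tnr == pytest.approx(0.974, abs=5e-4)

    def test_perfect_counts(self):
        assert detection_rates(DetectionCounts(tp=5, fn=0, tn=3, fp=0)) == (1, 1)

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            detection_rates(DetectionCounts(tp=5, fn=1, tn=0, fp=0))
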