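import logging
import math

import numpy as np
import pytest

from iarat.errors import (ParameterError, PhaseBelowThresholdError,
                          SegmentationError)
from iarat.io import IMURecording
from iarat.preprocess import AngularSpeedSeries, angular_speed, free_acceleration
from iarat.segmentation import (SegmentationConfig, detect_movement_windows,
                                phase_boundaries, return_termination,
                                segment_task, threshold_error_analysis)
from iarat.synthetic import minimum_jerk_speed, simulate_marker_oracle, simulate_task

from conftest import make_free


def lobe_series(centers, lengths, peaks=None, rate=50.0, t_end=None):
    """Sum of minimum-jerk speed lobes as an (unfiltered) angular-speed series."""
    peaks = peaks or [1.0] * len(centers)
    t_end = t_end or max(c + l for c, l in zip(centers, lengths)) + 0.5
    t = np.arange(0, t_end, 1 / rate)
    y = np.zeros_like(t)
    for c, l, p in zip(centers, lengths, peaks):
        y += p * minimum_jerk_speed((t - (c - l / 2)) / l)
    return AngularSpeedSeries(time=t, omega=y, rate=rate, filtered=True, cutoff=None)


class TestDetectMovementWindows:
    def test_three_separated_lobes_one_peak_each(self):
        omega = lobe_series([1.0, 3.0, 5.0], [0.8, 0.8, 0.8])
        windows = detect_movement_windows(omega, SegmentationConfig(), 3)
        assert len(windows) == 3
        for w, c in zip(windows, [1.0, 3.0, 5.0]):
            assert w[0] < c < w[1]

    def test_two_requested_on_three_lobes_keeps_two_longest(self):
        # brute-force oracle: enumerate supra-threshold runs and rank by span
        cfg = SegmentationConfig()
        omega = lobe_series([1.0, 3.0, 5.5], [0.5, 1.2, 0.9])
        t, y = omega.time, omega.omega
        above = y > cfg.theta * y.max()
        runs, start = [], None
        for i, a in enumerate(above):
            if a and start is None:
                start = i
            if not a and start is not None:
                runs.append((start, i - 1))
                start = None
        if start is not None:
            runs.append((start, len(y) - 1))
        oracle = sorted(sorted(runs, key=lambda r: t[r[1]] - t[r[0]])[-2:])
        windows = detect_movement_windows(omega, cfg, 2)
        assert len(windows) == 2
        for w, (s, e) in zip(windows, oracle):
            assert w[0] <= t[s] and t[e] <= w[1]
        # the two retained lobes are those centred at 3.0 and 5.5
        assert windows[0][0] < 3.0 < windows[0][1]
        assert windows[1][0] < 5.5 < windows[1][1]

    def test_flat_zero_signal_raises(self):
        t = np.arange(0, 3, 0.02)
        omega = AngularSpeedSeries(time=t, omega=np.zeros_like(t), rate=50.0)
        with pytest.raises(SegmentationError, match="insufficient movement lobes"):
            detect_movement_windows(omega, SegmentationConfig(), 3)

    def test_manual_windows_override(self):
        omega = lobe_series([1.0, 3.0], [0.8, 0.8])
        cfg = SegmentationConfig(manual_windows=[(0.0, 2.0), (2.0, 4.0)])
        assert detect_movement_windows(omega, cfg, 2) == [(0.0, 2.0), (2.0, 4.0)]


class TestPhaseBoundaries:
    def test_minimum_jerk_lobe_quarter_crossings(self):
        # closed form: 16 tau^2 (1-tau)^2 = 1/4 at tau = (1 -+ sqrt(1/2))/2
        L, rate = 1.0, 50.0
        omega = lobe_series([1.0], [L], rate=rate)
        on, off = phase_boundaries(omega, (0.0, 2.4), 0.25 * omega.omega.max())
        tau_lo = (1 - math.sqrt(0.5)) / 2
        start = 1.0 - L / 2
        assert on == pytest.approx(start + tau_lo * L, abs=1 / rate)
        assert off == pytest.approx(start + (1 - tau_lo) * L, abs=1 / rate)

    def test_constant_above_threshold_clamps_offset(self, caplog):
        t = np.arange(0, 2, 0.02)
        omega = AngularSpeedSeries(time=t, omega=np.full_like(t, 10.0), rate=50.0)
        with caplog.at_level(logging.WARNING, logger="iarat.segmentation"):
            on, off = phase_boundaries(omega, (0.0, 1.0), 5.0)
        assert on == t[0]
        assert off == pytest.approx(1.0, abs=0.02)
        assert any("clamped" in r.message for r in caplog.records)

    def test_lobe_below_threshold_raises(self):
        omega = lobe_series([1.0], [0.8], peaks=[0.1])
        with pytest.raises(PhaseBelowThresholdError):
            phase_boundaries(omega, (0.0, 2.0), 0.25 * 1.0)

    def test_empty_window_rejected(self):
        omega = lobe_series([1.0], [0.8])
        with pytest.raises(ParameterError):
            phase_boundaries(omega, (3.0, 3.0), 0.1)


class TestReturnTermination:
    def test_single_impact_transient_found(self, clean_item1):
        rec, gt = clean_item1
        free = free_acceleration(rec)
        t = return_termination(free, gt.phases["return"][0], SegmentationConfig())
        assert t == pytest.approx(gt.impact_time, abs=1 / rec.rate)

    def test_two_transients_takes_the_later(self):
        t = np.arange(0, 4, 0.02)
        v = np.zeros_like(t)
        for center in (1.0, 2.5):
            v += 3.0 * np.exp(-0.5 * ((t - center) / 0.03) ** 2)
        acc = np.zeros((len(t), 3))
        acc[:, 2] = v
        term = return_termination(make_free(t, acc), 0.5, SegmentationConfig())
        assert term == pytest.approx(2.5, abs=0.02)

    def test_monotone_decay_falls_back_with_warning(self, caplog):
        t = np.arange(0, 3, 0.02)
        acc = np.zeros((len(t), 3))
        acc[:, 2] = np.exp(-t)
        with caplog.at_level(logging.WARNING, logger="iarat.segmentation"):
            term = return_termination(make_free(t, acc), 0.5, SegmentationConfig(),
                                      fallback=1.23)
        assert term == 1.23
        assert any("falling back" in r.message for r in caplog.records)


class TestSegmentTask:
    def test_item1_recovers_analytic_crossings_at_default_threshold(self, clean_item1):
        rec, gt = clean_item1
        seg = segment_task(rec)
        assert list(seg.phases) == ["reaching", "manipulation", "transport",
                                    "release", "return"]
        cross = gt.crossing_times(0.25)
        for phase in ("reaching", "transport", "return"):
            on, off = seg.phases[phase]
            assert on == pytest.approx(cross[phase][0], abs=1 / rec.rate)
            if phase != "return":
                assert off == pytest.approx(cross[phase][1], abs=1 / rec.rate)
        assert seg.phases["return"][1] == pytest.approx(gt.impact_time, abs=1 / rec.rate)

    def test_gross_item_has_two_phases(self, spec):
        rec, _ = simulate_task(spec, 18, seed=5, noise=False, tremor_amp=0.0)
        seg = segment_task(rec)
        assert list(seg.phases) == ["transport", "return"]

    def test_zero_dwell_manipulation_onset_equals_offset(self, spec):
        durations = {"reaching": 0.46, "manipulation": 0.0, "transport": 0.66,
                     "release": 0.0, "return": 0.66}
        rec, gt = simulate_task(spec, 2, seed=1, noise=False, tremor_amp=0.0,
                                phase_durations=durations)
        # without dwell dips the automatic partition cannot split the lobes;
        # supply the operator's rough tri-partition on the sample grid
        edges = [gt.phases["manipulation"][0], gt.phases["release"][0]]
        grid = [rec.time[int(round(e * rec.rate))] for e in edges]
        cfg = SegmentationConfig(manual_windows=[
            (rec.time[0], grid[0]), (grid[0], grid[1]), (grid[1], rec.time[-1])])
        seg = segment_task(rec, cfg)
        on, off = seg.phases["manipulation"]
        assert on == off

    def test_phases_tile_task_window(self, spec, control_durations):
        rec, _ = simulate_task(spec, 4, seed=21, noise=False, tremor_amp=0.0,
                               phase_durations=control_durations)
        seg = segment_task(rec)
        bounds = list(seg.phases.values())
        for (_, a1), (b0, _) in zip(bounds, bounds[1:]):
            assert a1 == pytest.approx(b0, abs=1e-12)
        assert seg.task_window == (bounds[0][0], bounds[-1][1])

    def test_invariant_to_gyro_amplitude_scaling(self, clean_item1):
        rec, _ = clean_item1
        seg = segment_task(rec)
        scaled = IMURecording(time=rec.time, rate=rec.rate, accel=rec.accel,
                              gyro=rec.gyro * 1.7, rot=rec.rot, meta=rec.meta)
        seg2 = segment_task(scaled)
        for phase in seg.phases:
            np.testing.assert_allclose(seg2.phases[phase], seg.phases[phase],
                                       atol=1e-9)

    def test_time_shift_shifts_every_boundary(self, clean_item1):
        rec, _ = clean_item1
        seg = segment_task(rec)
        delta = 0.5
        shifted = IMURecording(time=rec.time + delta, rate=rec.rate,
                               accel=rec.accel, gyro=rec.gyro, rot=rec.rot,
                               meta=rec.meta)
        seg2 = segment_task(shifted)
        for phase in seg.phases:
            np.testing.assert_allclose(np.asarray(seg2.phases[phase]),
                                       np.asarray(seg.phases[phase]) + delta,
                                       atol=1e-9)

    def test_recording_without_item_rejected(self, clean_item1):
        rec, _ = clean_item1
        anon = IMURecording(time=rec.time, rate=rec.rate, accel=rec.accel,
                            gyro=rec.gyro, rot=rec.rot)
        with pytest.raises(SegmentationError, match="item"):
            segment_task(anon)

    def test_per_portion_scope_also_recovers_boundaries(self, clean_item1):
        rec, gt = clean_item1
        seg = segment_task(rec, SegmentationConfig(omega_max_scope="per_portion"))
        cross = gt.crossing_times(0.25)  # equal lobe peaks: same threshold
        assert seg.phases["reaching"][0] == pytest.approx(cross["reaching"][0],
                                                          abs=1 / rec.rate)


class TestThresholdErrorAnalysis:
    def _paired(self, spec, n_tasks, thresholds, seed0=100):
        paired = {th: [] for th in thresholds}
        for s in range(n_tasks):
            item = (s % 19) + 1
            rec, gt = simulate_task(spec, item, seed=seed0 + s, noise=False,
                                    tremor_amp=0.0)
            ref = simulate_marker_oracle(gt)
            for th in thresholds:
                try:
                    seg = segment_task(rec, SegmentationConfig(theta=th))
                except SegmentationError:
                    continue
                paired[th].append((seg, ref))
        return paired

    def test_identical_instants_give_zero_table(self, clean_item1):
        rec, _ = clean_item1
        seg = segment_task(rec)
        table = threshold_error_analysis({0.25: [(seg, seg.instants())]})
        assert np.all(table.table["mean_abs_error"].to_numpy() == 0.0)
        assert table.best_threshold == 0.25

    def test_reaverage_oracle_and_selection_rule(self, spec):
        thresholds = (0.15, 0.20, 0.25, 0.30)
        paired = self._paired(spec, 12, thresholds)
        result = threshold_error_analysis(paired)
        # brute-force recomputation of every cell from the stored instants
        for th in thresholds:
            errs = []
            for seg, ref in paired[th]:
                inst = seg.instants()
                errs.extend(abs(inst[k] - ref[k]) for k in inst if k in ref)
            row = result.table[(result.table["threshold"] == th) &
                               (result.table["instant"] == "All instants")]
            assert abs(row["mean_abs_error"].iloc[0] - np.mean(errs)) < 1e-12
        pooled = {th: result.table[(result.table["threshold"] == th) &
                                   (result.table["instant"] == "All instants")]
                  ["mean_abs_error"].iloc[0] for th in thresholds}
        assert result.best_threshold == min(pooled, key=pooled.get)

    def test_table_shape_matches_reported_layout(self, spec):
        """Rows per instant type and threshold, plus pooled 'All instants'."""
        paired = self._paired(spec, 4, (0.25,))
        result = threshold_error_analysis(paired)
        instants = set(result.table["instant"])
        assert {"T0_reaching", "T1_reaching", "T0_transport", "T1_transport",
                "T0_return", "All instants"} <= instants
        assert (result.table["mean_abs_error"] >= 0).all()
        assert (result.table["sd_abs_error"] >= 0).all()

    def test_empty_pairing_rejected(self):
        with pytest.raises(ParameterError):
            threshold_error_analysis({})
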