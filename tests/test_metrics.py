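import math

import numpy as np
import pandas as pd
import pytest

from iarat.errors import DegenerateNormativeError, ParameterError, UndefinedMetricError
from iarat.metrics import (ControlStats, JerkConfig, compute_metrics, jerk_index,
                           metrics_frame, section_summary, zscore_table)
from iarat.preprocess import free_acceleration
from iarat.segmentation import PhaseSegmentation, segment_task
from iarat.stats import spearman
from iarat.synthetic import simulate_task

from conftest import make_free


def sinusoid_free(f=2.0, amp=1.0, duration=2.0, rate=50.0):
    t = np.arange(0, duration + 1e-9, 1 / rate)
    acc = np.zeros((len(t), 3))
    acc[:, 2] = amp * np.sin(2 * np.pi * f * t)
    return make_free(t, acc, rate)


class TestJerkIndex:
    def test_sinusoid_closed_form(self):
        # mean|cos| / mean|sin| = 1 over whole periods, so the jerk/accel
        # ratio is 2 pi f and JI -> ln(2 pi f D)
        f, duration = 2.0, 2.0
        ji = jerk_index(sinusoid_free(f=f, duration=duration), (0.0, duration))
        assert ji == pytest.approx(math.log(2 * math.pi * f * duration), rel=0.02)

    def test_amplitude_invariance(self):
        free1 = sinusoid_free(amp=1.0)
        free2 = sinusoid_free(amp=37.5)
        ji1 = jerk_index(free1, (0.0, 2.0))
        ji2 = jerk_index(free2, (0.0, 2.0))
        assert abs(ji1 - ji2) < 1e-9

    def test_zero_acceleration_undefined(self):
        t = np.arange(0, 1, 0.02)
        with pytest.raises(UndefinedMetricError):
            jerk_index(make_free(t, np.zeros((len(t), 3))), (0.0, 1.0))

    def test_too_few_samples_rejected(self):
        free = sinusoid_free()
        with pytest.raises(ParameterError):
            jerk_index(free, (0.0, 0.02))

    def test_healthy_task_magnitude_matches_natural_log_convention(self, spec):
        """Whole-task JI of healthy simulations lands near the printed ~3.0
        (natural log); a base-10 convention would land near 1.3 instead."""
        values = []
        for seed in range(30):
            rec, _ = simulate_task(spec, 1, seed=800 + seed)
            try:
                seg = segment_task(rec)
            except Exception:
                continue
            values.append(compute_metrics(free_acceleration(rec), seg).jerk["task"])
        med = float(np.median(values))
        assert 2.2 < med < 3.6


class TestComputeMetrics:
    def test_durations_are_boundary_differences(self):
        phases = {"reaching": (0.0, 0.5), "manipulation": (0.5, 0.8),
                  "transport": (0.8, 1.5), "release": (1.5, 1.7),
                  "return": (1.7, 2.4)}
        seg = PhaseSegmentation(item=1, phases=phases)
        free = sinusoid_free(duration=2.4)
        ms = compute_metrics(free, seg)
        assert {k: round(v, 10) for k, v in ms.duration.items()} == {
            "reaching": 0.5, "manipulation": 0.3, "transport": 0.7,
            "release": 0.2, "return": 0.7, "task": 2.4}

    def test_task_jerk_equals_direct_call_on_task_window(self, clean_item1):
        rec, _ = clean_item1
        seg = segment_task(rec)
        free = free_acceleration(rec)
        ms = compute_metrics(free, seg)
        direct = jerk_index(free, seg.task_window)
        assert abs(ms.jerk["task"] - direct) < 1e-12

    def test_zero_length_phase_marked_undefined(self):
        phases = {"reaching": (0.0, 0.5), "manipulation": (0.5, 0.5),
                  "transport": (0.5, 1.2), "release": (1.2, 1.4),
                  "return": (1.4, 2.0)}
        seg = PhaseSegmentation(item=1, phases=phases)
        ms = compute_metrics(sinusoid_free(), seg)
        assert ms.duration["manipulation"] == 0.0
        assert ms.jerk["manipulation"] is None

    def test_reaching_duration_recovery_over_seeds(self, spec):
        """Median measured reaching duration within 10% of the 0.45 s target."""
        durations = []
        for seed in range(100):
            rec, _ = simulate_task(spec, 1, seed=2000 + seed)
            try:
                seg = segment_task(rec)
            except Exception:
                continue
            durations.append(seg.phases["reaching"][1] - seg.phases["reaching"][0])
        assert len(durations) > 90
        assert float(np.median(durations)) == pytest.approx(0.45, rel=0.10)

    def test_manipulation_jerk_grows_with_tremor(self, spec, control_durations):
        """Mean manipulation JI increases monotonically with tremor amplitude."""
        amps = [0.0, 0.5, 1.0, 2.0]
        means = []
        for amp in amps:
            vals = []
            for seed in range(50):
                rec, gt = simulate_task(spec, 1, seed=300 + seed, tremor_amp=amp,
                                        phase_durations=control_durations)
                free = free_acceleration(rec)
                vals.append(jerk_index(free, gt.phases["manipulation"]))
            means.append(float(np.mean(vals)))
        assert means == sorted(means)
        r = spearman(np.repeat(amps, 1), means, mode="exact").statistic
        assert r > 0.9


def cohort_frame(rng, n_controls=5, n_patients=4, items=(1, 2), phases=("task",)):
    rows = []
    for i in range(n_controls + n_patients):
        group = "control" if i < n_controls else "MS"
        shift = 0.0 if group == "control" else 0.8
        for item in items:
            for phase in phases:
                rows.append({"subject": f"s{i}", "group": group, "item": item,
                             "phase": phase,
                             "duration": rng.normal(2.0 + shift, 0.3),
                             "jerk": rng.normal(3.0 + shift / 2, 0.2)})
    return pd.DataFrame(rows)


class TestZScores:
    def test_control_cohort_scored_against_itself(self):
        df = cohort_frame(np.random.default_rng(5), n_patients=0)
        z = zscore_table(df)
        for (_, _, _), grp in z.cells.groupby(["item", "phase", "parameter"]):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)
        for (_, _), grp in z.subject_level.groupby(["phase", "parameter"]):
            assert grp["z"].mean() == pytest.approx(0.0, abs=1e-9)
            assert grp["z"].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_hand_checkable_three_controls(self):
        # controls {1,2,3} s on one cell: mean 2, SD 1 (n-1); patient at 4 -> z=2
        rows = [{"subject": f"c{i}", "group": "control", "item": 1,
                 "phase": "task", "duration": float(v), "jerk": 1.0 + 0.1 * i}
                for i, v in enumerate((1, 2, 3))]
        rows.append({"subject": "p", "group": "MS", "item": 1, "phase": "task",
                     "duration": 4.0, "jerk": 1.1})
        z = zscore_table(pd.DataFrame(rows))
        cell = z.cells[(z.cells["subject"] == "p") &
                       (z.cells["parameter"] == "duration")]
        assert cell["z"].iloc[0] == pytest.approx(2.0, abs=1e-12)

    def test_subject_at_control_mean_scores_zero(self):
        df = cohort_frame(np.random.default_rng(6), n_patients=0)
        stats = ControlStats.from_frame(df)
        mean_map = stats.table.set_index(["parameter", "item", "phase"])["mean"]
        rows = []
        for item in (1, 2):
            rows.append({"subject": "avg", "group": "MS", "item": item,
                         "phase": "task",
                         "duration": mean_map[("duration", item, "task")],
                         "jerk": mean_map[("jerk", item, "task")]})
        z = zscore_table(pd.concat([df, pd.DataFrame(rows)], ignore_index=True),
                         stats=stats)
        avg = z.cells[z.cells["subject"] == "avg"]
        np.testing.assert_allclose(avg["z"], 0.0, atol=1e-12)

    def test_affine_shift_equivariance(self):
        rng = np.random.default_rng(7)
        df = cohort_frame(rng)
        z1 = zscore_table(df)
        shifted = df.copy()
        mask = (shifted["item"] == 1) & (shifted["phase"] == "task")
        shifted.loc[mask, "duration"] += 5.0  # every subject and control alike
        z2 = zscore_table(shifted)
        np.testing.assert_allclose(z2.cells["z"].to_numpy(),
                                   z1.cells["z"].to_numpy(), atol=1e-9)

    def test_degenerate_control_sd_raises(self):
        rows = [{"subject": f"c{i}", "group": "control", "item": 1,
                 "phase": "task", "duration": 2.0, "jerk": float(i)}
                for i in range(3)]
        with pytest.raises(DegenerateNormativeError, match="duration"):
            zscore_table(pd.DataFrame(rows))


class TestSectionSummary:
    def test_identical_metric_returns_that_value(self):
        rows = [{"subject": "s", "group": "MS", "item": i, "phase": "task",
                 "duration": 2.5, "jerk": 3.0} for i in range(1, 20)]
        out = section_summary(pd.DataFrame(rows))
        assert set(out["section"]) == {"Grasp", "Grip", "Pinch", "Gross"}
        np.testing.assert_allclose(out["duration"], 2.5)

    def test_grasp_is_mean_of_items_1_to_6_only(self):
        rng = np.random.default_rng(8)
        rows = [{"subject": "s", "group": "MS", "item": i, "phase": "task",
                 "duration": float(rng.normal(2, 0.5)), "jerk": 3.0}
                for i in range(1, 20)]
        df = pd.DataFrame(rows)
        out = section_summary(df)
        grasp = out[out["section"] == "Grasp"]["duration"].iloc[0]
        oracle = df[df["item"] <= 6]["duration"].mean()
        assert abs(grasp - oracle) < 1e-12

    def test_brute_force_reaverage(self, spec):
        recs = [simulate_task(spec, item, seed=60 + item) for item in (1, 8, 12, 18)]
        sets = []
        for rec, _ in recs:
            seg = segment_task(rec)
            sets.append(compute_metrics(free_acceleration(rec), seg,
                                        subject="s1", group="control"))
        df = metrics_frame(sets)
        out = section_summary(df)
        for _, row in out.iterrows():
            members = df[(df["phase"] == "task") &
                         (df["item"].map(lambda i: {1: "Grasp", 8: "Grip",
                                                    12: "Pinch", 18: "Gross"}[i])
                          == row["section"])]
            assert abs(row["duration"] - members["duration"].mean()) < 1e-12
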