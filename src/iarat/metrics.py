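"""Duration and jerk-index metrics, normative z-scores, section aggregates.

For every task and sub-movement two parameters are extracted:

* **Duration** ``D`` - time between movement onset and termination, s.
* **Jerk index** ``JI = ln( (mean_t ||da/dt|| / mean_t ||a||) * D )`` - the
  natural log of the mean jerk magnitude normalised by the mean acceleration
  magnitude and multiplied by the movement duration, computed on the
  gravity-free global-frame acceleration.  JI is dimensionless, invariant to
  amplitude scaling of the acceleration, and grows with the high-frequency
  content of the movement (higher = less smooth).  For a pure sinusoid of
  frequency f over duration D, JI = ln(2 pi f D).

Deviations from normative data are expressed as z-scores

    Z_{P,i,j,k} = (P_{i,j,k} - mean_co(P)_{j,k}) / sd_co(P)_{j,k}

per parameter P (duration, jerk), subject i, item j and sub-movement k,
where the mean and the (n-1 denominator) SD are taken over the healthy
control cohort.  Subject-level summaries Z_Duration and Z_Jerk z-score the
subject's mean of the parameter across items against the distribution of
that same mean in controls.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateNormativeError, ParameterError, UndefinedMetricError
from .io import section_of_item
from .preprocess import FreeAccelSeries, lowpass_zero_lag
from .segmentation import PhaseSegmentation

log = logging.getLogger(__name__)

PARAMETERS = ("duration", "jerk")
TASK_PHASE = "task"


@dataclass
class JerkConfig:
    """Options for the jerk computation.

    accel_cutoff : optional low-pass cutoff (Hz) applied to the gravity-free
        acceleration before differentiation; ``None`` (default) leaves the
        signal untouched.
    """

    accel_cutoff: float | None = None


def jerk_index(accel: FreeAccelSeries, window: tuple[float, float],
               cfg: JerkConfig | None = None) -> float:
    """Dimensionless smoothness index over a time window.

    ``JI = ln( (mean ||da/dt|| / mean ||a||) * D )`` with the derivative by
    central finite differences (one-sided at the window edges) and
    ``D = window length``.

    Raises
    ------
    ParameterError
        If the window holds fewer than 3 samples.
    UndefinedMetricError
        If the mean acceleration magnitude in the window is zero.
    """
    cfg = cfg or JerkConfig()
    t0, t1 = window
    t = accel.time
    lo = int(np.searchsorted(t, t0 - 1e-12))
    hi = int(np.searchsorted(t, t1 + 1e-12, side="right"))
    if hi - lo < 3:
        raise ParameterError(f"window {window} holds {hi - lo} samples; need >= 3")
    a = accel.accel_global
    if cfg.accel_cutoff is not None:
        a = lowpass_zero_lag(a, cfg.accel_cutoff, accel.rate)
    a = a[lo:hi]
    dt = 1.0 / accel.rate
    jerk = np.gradient(a, dt, axis=0)
    mean_a = float(np.linalg.norm(a, axis=1).mean())
    if mean_a == 0.0:
        raise UndefinedMetricError("mean acceleration magnitude is zero in the window")
    mean_j = float(np.linalg.norm(jerk, axis=1).mean())
    duration = t1 - t0
    return math.log(mean_j / mean_a * duration)


@dataclass
class MetricSet:
    """Duration and jerk index per phase (plus the whole task) of one item."""

    subject: str | None
    group: str | None
    item: int
    duration: dict[str, float]
    jerk: dict[str, float | None]  # None where the metric is undefined

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"subject": self.subject, "group": self.group, "item": self.item,
             "phase": ph, "duration": self.duration[ph],
             "jerk": np.nan if self.jerk[ph] is None else self.jerk[ph]}
            for ph in self.duration
        ]
        return pd.DataFrame(rows)


def compute_metrics(accel: FreeAccelSeries, seg: PhaseSegmentation,
                    cfg: JerkConfig | None = None, *,
                    subject: str | None = None, group: str | None = None) -> MetricSet:
    """Durations and jerk indices for every phase and for the whole task.

    Zero-length phases (a subject who never pauses) get duration 0 and an
    undefined jerk index (``None``), excluded from aggregates.
    """
    durations: dict[str, float] = {}
    jerks: dict[str, float | None] = {}
    for name, (on, off) in seg.phases.items():
        d = off - on
        durations[name] = d
        try:
            jerks[name] = jerk_index(accel, (on, off), cfg)
        except (ParameterError, UndefinedMetricError):
            jerks[name] = None
            if d > 0:
                log.info("jerk index undefined for item %s phase %s", seg.item, name)
    t0, t1 = seg.task_window
    durations[TASK_PHASE] = t1 - t0
    jerks[TASK_PHASE] = jerk_index(accel, (t0, t1), cfg)
    return MetricSet(subject=subject, group=group, item=seg.item,
                     duration=durations, jerk=jerks)


def metrics_frame(metric_sets: Iterable[MetricSet]) -> pd.DataFrame:
    """Long-format cohort table: subject, group, item, phase, duration, jerk."""
    frames = [m.to_frame() for m in metric_sets]
    if not frames:
        return pd.DataFrame(columns=["subject", "group", "item", "phase", "duration", "jerk"])
    return pd.concat(frames, ignore_index=True)


@dataclass
class ControlStats:
    """Normative mean/SD per (parameter, item, phase) from the control group."""

    table: pd.DataFrame  # columns: parameter, item, phase, mean, sd, n

    @classmethod
    def from_frame(cls, df: pd.DataFrame, control_label: str = "control") -> "ControlStats":
        co = df[df["group"] == control_label]
        if co.empty:
            raise ParameterError(f"no rows with group == {control_label!r}")
        rows = []
        long = co.melt(id_vars=["subject", "item", "phase"],
                       value_vars=["duration", "jerk"],
                       var_name="parameter", value_name="value").dropna(subset=["value"])
        for (param, item, phase), grp in long.groupby(["parameter", "item", "phase"]):
            vals = grp["value"].to_numpy(float)
            rows.append({"parameter": param, "item": item, "phase": phase,
                         "mean": float(vals.mean()),
                         "sd": float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
                         "n": int(vals.size)})
        return cls(table=pd.DataFrame(rows))


@dataclass
class ZScoreTable:
    """Per-cell z-scores plus subject-level aggregates.

    ``cells`` columns: subject, group, item, phase, parameter, value, z.
    ``subject_level`` columns: subject, group, phase, parameter, mean_value, z
    (the subject's mean of the parameter across items, z-scored against the
    distribution of that mean in controls).
    """

    cells: pd.DataFrame
    subject_level: pd.DataFrame


def zscore_table(df: pd.DataFrame, stats: ControlStats | None = None,
                 control_label: str = "control") -> ZScoreTable:
    """Z-score every (parameter, item, phase) cell against control statistics.

    Cells whose normative SD is zero raise
    :class:`~iarat.errors.DegenerateNormativeError`; cells without normative
    statistics are dropped.
    """
    stats = stats or ControlStats.from_frame(df, control_label)
    long = df.melt(id_vars=["subject", "group", "item", "phase"],
                   value_vars=["duration", "jerk"],
                   var_name="parameter", value_name="value").dropna(subset=["value"])
    merged = long.merge(stats.table, on=["parameter", "item", "phase"], how="inner")
    zero = merged[merged["sd"] == 0.0]
    if not zero.empty:
        cell = zero.iloc[0]
        raise DegenerateNormativeError(
            f"zero control SD for (parameter={cell['parameter']}, "
            f"item={cell['item']}, phase={cell['phase']})"
        )
    merged["z"] = (merged["value"] - merged["mean"]) / merged["sd"]
    cells = merged[["subject", "group", "item", "phase", "parameter", "value", "z"]]

    # subject-level aggregates: mean across items first, then z-score
    subj = (long.groupby(["subject", "group", "phase", "parameter"], as_index=False)
            ["value"].mean().rename(columns={"value": "mean_value"}))
    co = subj[subj["group"] == control_label]
    norm = (co.groupby(["phase", "parameter"], as_index=False)["mean_value"]
            .agg(co_mean="mean", co_sd=lambda v: v.std(ddof=1)))
    subj = subj.merge(norm, on=["phase", "parameter"], how="inner")
    bad = subj[subj["co_sd"] == 0.0]
    if not bad.empty:
        cell = bad.iloc[0]
        raise DegenerateNormativeError(
            f"zero control SD for subject-level (parameter={cell['parameter']}, "
            f"phase={cell['phase']})"
        )
    subj["z"] = (subj["mean_value"] - subj["co_mean"]) / subj["co_sd"]
    subject_level = subj[["subject", "group", "phase", "parameter", "mean_value", "z"]]
    return ZScoreTable(cells=cells, subject_level=subject_level)


def section_summary(df: pd.DataFrame, value_cols: Sequence[str] = ("duration", "jerk"),
                    phase: str = TASK_PHASE) -> pd.DataFrame:
    """Per-subject, per-section means over member items of each parameter.

    Sections with missing items are averaged over the available ones (the
    count is reported in column ``n_items``).
    """
    sub = df[df["phase"] == phase].copy()
    if sub.empty:
        raise ParameterError(f"no rows with phase == {phase!r}")
    sub["section"] = sub["item"].map(section_of_item)
    expected = {"Grasp": 6, "Grip": 4, "Pinch": 6, "Gross": 3}
    out = (sub.groupby(["subject", "group", "section"], as_index=False)
           .agg(**{c: (c, "mean") for c in value_cols}, n_items=("item", "nunique")))
    short = out[out.apply(lambda r: r["n_items"] < expected[r["section"]], axis=1)]
    if not short.empty:
        log.info("section summary computed over partial item sets for %d rows", len(short))
    return out
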