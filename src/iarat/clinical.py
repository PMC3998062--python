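"""Clinical-score data model, 9HPT conversion, impairment clustering.

The MS cohort is characterised by the ARAT total (0-57), the Nine Hole Peg
Test (time in seconds, or pegs moved per minute so that subjects unable to
complete the test score 0) and Fahn's Tremor Rating Scale for postural and
intention tremor (0-4 each).  Sub-groups with different levels of upper-limb
impairment are found by agglomerative hierarchical clustering (Euclidean
distance, UPGMA average linkage) of the standardized scores.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage

from . import _tables
from .errors import ParameterError, ValidationError

UNABLE = "unable"

#: pegs per 9HPT trial (place and remove nine pegs)
PEGS_PER_TRIAL = 9

CLUSTER_FEATURES = ("arat", "nhpt_rate", "ftrs_sum")


@dataclass
class ClinicalRecord:
    """Clinical scores (and optional demographics) for one subject."""

    subject: str
    arat: int
    nhpt_time: float | None  # seconds; None encodes "unable"
    nhpt_rate: float | None = None  # pegs/min; derived when omitted
    ftrs_postural: int = 0
    ftrs_intention: int = 0
    age: float | None = None
    sex: str | None = None
    ms_type: str | None = None
    disease_duration: float | None = None
    edss: float | None = None
    cluster: str | None = None  # published impairment label, if any

    def __post_init__(self):
        if not 0 <= self.arat <= 57:
            raise ValidationError(f"{self.subject}: ARAT {self.arat} outside 0..57")
        for name, v in (("postural", self.ftrs_postural), ("intention", self.ftrs_intention)):
            if not 0 <= v <= 4:
                raise ValidationError(f"{self.subject}: FTRS {name} {v} outside 0..4")
        if self.nhpt_rate is None:
            self.nhpt_rate = pegs_per_minute(self.nhpt_time)
        if self.nhpt_time is None and self.nhpt_rate != 0.0:
            raise ValidationError(f"{self.subject}: rate must be 0 when time is 'unable'")

    @property
    def ftrs_sum(self) -> int:
        return self.ftrs_postural + self.ftrs_intention


def pegs_per_minute(time: float | str | None) -> float:
    """Convert a 9HPT completion time to pegs moved per minute.

    The per-second rate (9 pegs / time) is rounded half-up to two decimals
    before scaling to a minute; subjects unable to complete the test (``None``
    or ``"unable"``) score 0.
    """
    if time is None or (isinstance(time, str) and time.lower() == UNABLE):
        return 0.0
    time = float(time)
    if time <= 0:
        raise ParameterError(f"9HPT time must be positive, got {time}")
    per_second = PEGS_PER_TRIAL / time
    rounded = math.floor(per_second * 100 + 0.5) / 100
    return round(60.0 * rounded, 10)


def load_study_records() -> list[ClinicalRecord]:
    """The embedded 21-subject MS cohort (scores as printed)."""
    demo = {r[0]: r for r in _tables.DEMOGRAPHICS}
    records = []
    for cluster, subj, arat, t, rate, post, intent in _tables.CLINICAL:
        _, age, sex, ms_type, dur, edss = demo[subj]
        records.append(ClinicalRecord(
            subject=subj, arat=arat, nhpt_time=t, nhpt_rate=rate,
            ftrs_postural=post, ftrs_intention=intent,
            age=age, sex=sex, ms_type=ms_type, disease_duration=dur,
            edss=edss, cluster=cluster,
        ))
    return records


def records_frame(records: Iterable[ClinicalRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "subject": r.subject, "arat": r.arat, "nhpt_time": r.nhpt_time,
            "nhpt_rate": r.nhpt_rate, "ftrs_postural": r.ftrs_postural,
            "ftrs_intention": r.ftrs_intention, "ftrs_sum": r.ftrs_sum,
            "age": r.age, "sex": r.sex, "ms_type": r.ms_type,
            "disease_duration": r.disease_duration, "edss": r.edss,
            "cluster": r.cluster,
        })
    return pd.DataFrame(rows)


@dataclass
class ImpairmentClustering:
    """Result of the hierarchical clustering of clinical scores."""

    labels: dict[str, int]  # subject -> cluster id (1..k)
    linkage_matrix: np.ndarray
    k: int
    features: tuple[str, ...] = CLUSTER_FEATURES

    def clusters(self) -> list[frozenset[str]]:
        """Clusters as subject sets, largest first (ties by smallest label)."""
        groups: dict[int, set[str]] = {}
        for subj, lab in self.labels.items():
            groups.setdefault(lab, set()).add(subj)
        return [frozenset(g) for _, g in
                sorted(groups.items(), key=lambda kv: (-len(kv[1]), kv[0]))]

    def sizes(self) -> list[int]:
        return [len(c) for c in self.clusters()]


def cluster_impairment(records: Sequence[ClinicalRecord], k: int = 3,
                       features: Sequence[str] = CLUSTER_FEATURES) -> ImpairmentClustering:
    """UPGMA clustering of standardized clinical scores, cut at k clusters.

    Features default to (ARAT total, 9HPT pegs/min, FTRS postural+intention):
    pegs/min is the only 9HPT representation defined for subjects unable to
    complete the test.  Each feature is standardized (mean 0, SD 1) across
    the cohort before Euclidean distances are formed, so the result is
    invariant to affine rescaling of any raw feature.  The linkage is
    deterministic; scipy breaks merge-height ties by cluster index order.
    """
    if len(records) < k:
        raise ParameterError(f"need >= {k} records, got {len(records)}")
    df = records_frame(records)
    X = df[list(features)].to_numpy(float)
    sd = X.std(axis=0, ddof=1)
    flat = np.nonzero(sd == 0)[0]
    if flat.size:
        raise ParameterError(f"constant feature(s) cannot be standardized: "
                             f"{[features[i] for i in flat]}")
    Z = (X - X.mean(axis=0)) / sd
    lnk = linkage(Z, method="average", metric="euclidean")
    labels = fcluster(lnk, t=k, criterion="maxclust")
    return ImpairmentClustering(
        labels={s: int(l) for s, l in zip(df["subject"], labels)},
        linkage_matrix=lnk, k=k, features=tuple(features),
    )


def cohort_summary(records: Sequence[ClinicalRecord],
                   variables: Sequence[str] = ("arat", "nhpt_time", "nhpt_rate",
                                               "ftrs_sum", "age", "disease_duration"),
                   by: str | None = None) -> pd.DataFrame:
    """Median and min-max range per variable, optionally per group.

    The median of an even number of values is the midpoint of the two
    central order statistics.  Missing values (e.g. 9HPT time for subjects
    unable to complete it) are skipped.
    """
    df = records_frame(records)
    if by is not None and by not in df.columns:
        raise ParameterError(f"unknown grouping column {by!r}")
    groups = [("all", df)] if by is None else list(df.groupby(by))
    rows = []
    for name, grp in groups:
        for var in variables:
            if var not in grp.columns:
                continue
            vals = grp[var].dropna().to_numpy(float)
            if vals.size == 0:
                continue
            rows.append({"group": name, "variable": var, "n": int(vals.size),
                         "median": float(np.median(vals)),
                         "min": float(vals.min()), "max": float(vals.max())})
    return pd.DataFrame(rows)
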