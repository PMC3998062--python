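"""End-to-end orchestration: simulate/ingest, segment, score, compare.

``run_analysis`` composes the full workflow - preprocessing, segmentation,
metric extraction, normative z-scoring, clinical clustering and the
nonparametric comparison battery - into a single deterministic report.
Stage errors are collected per (subject, item) and the affected cells are
marked rather than aborting the cohort.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .clinical import ClinicalRecord, cluster_impairment, cohort_summary, records_frame
from .errors import IaratError
from .io import section_of_item
from .metrics import (JerkConfig, TASK_PHASE, ZScoreTable, compute_metrics,
                      metrics_frame, section_summary, zscore_table)
from .preprocess import free_acceleration
from .segmentation import SegmentationConfig, segment_task
from .stats import (friedman, holm_adjust, kruskal_wallis, mann_whitney,
                    pairwise_mann_whitney_holm, spearman)
from .synthetic import SEVERITY_GRADE, CohortData, SimulationSpec, simulate_cohort

#: study group sizes (controls / MS split into published sub-group sizes)
DEFAULT_COHORT = {"control": 12, "mild": 12, "moderate": 5, "severe": 4}

_MS_PHASES = ("manipulation", "transport", "release")


@dataclass
class AnalysisReport:
    """All analysis blocks plus a configuration echo, JSON-serializable."""

    config: dict
    blocks: dict
    errors: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"config": self.config, "blocks": self.blocks, "errors": self.errors}

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True, allow_nan=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _result_dict(res) -> dict:
    return {"statistic": res.statistic, "p": res.pvalue, "method": res.method,
            "n": list(res.n)}


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def process_cohort(data: CohortData, seg_cfg: SegmentationConfig | None = None,
                   jerk_cfg: JerkConfig | None = None):
    """Segment and score every task; returns (metrics frame, error list)."""
    seg_cfg = seg_cfg or SegmentationConfig()
    sets, errors = [], []
    for subj in data.subjects:
        for rec, _gt in subj.tasks:
            try:
                seg = segment_task(rec, seg_cfg)
                free = free_acceleration(rec)
                sets.append(compute_metrics(free, seg, jerk_cfg,
                                            subject=subj.subject, group=subj.group))
            except IaratError as err:
                errors.append({"subject": subj.subject, "item": rec.meta.item,
                               "error": str(err)})
    return metrics_frame(sets), errors


def _ms_mask(df: pd.DataFrame) -> pd.Series:
    return df["group"] != "control"


def run_analysis(data: CohortData | None = None, *,
                 spec: SimulationSpec | None = None,
                 n_per_group: Mapping[str, int] | None = None,
                 seed: int | None = None,
                 items: Sequence[int] | None = None,
                 clinical_records: Sequence[ClinicalRecord] | None = None,
                 seg_cfg: SegmentationConfig | None = None,
                 jerk_cfg: JerkConfig | None = None,
                 out_dir: str | Path | None = None) -> AnalysisReport:
    """Run the full analysis on a cohort (simulated or supplied).

    With ``clinical_records`` only (no recordings), the clustering and
    summary blocks are produced and the sensor-derived blocks are marked
    absent.  With ``spec`` a cohort is simulated first (``n_per_group``
    defaults to the study's 12 controls and 12/5/4 MS sub-groups).
    Deterministic: the same inputs, seed and configuration yield a
    byte-identical JSON report.
    """
    seg_cfg = seg_cfg or SegmentationConfig()
    jerk_cfg = jerk_cfg or JerkConfig()
    config = {
        "theta": seg_cfg.theta, "gyro_cutoff": seg_cfg.gyro_cutoff,
        "omega_max_scope": seg_cfg.omega_max_scope, "merge_gap": seg_cfg.merge_gap,
        "peak_prominence": seg_cfg.peak_prominence,
        "accel_cutoff": jerk_cfg.accel_cutoff, "jerk_log_base": "e",
        "seed": seed,
    }
    blocks: dict = {}
    errors: list = []

    if data is None and spec is not None:
        data = simulate_cohort(spec, dict(n_per_group or DEFAULT_COHORT), seed,
                               items=items)

    clin = list(clinical_records) if clinical_records is not None else (
        data.clinical_records() if data is not None else [])

    df = None
    if data is not None:
        df, errors = process_cohort(data, seg_cfg, jerk_cfg)

    if df is not None and not df.empty:
        z = zscore_table(df)
        blocks["section_comparison"] = _section_block(df)
        blocks["phase_comparison"] = _phase_block(df)
        blocks["friedman_sections"] = _friedman_block(z)
        blocks["subgroup_comparison"] = _subgroup_block(z)
        blocks["correlations"] = _correlation_block(z, clin)
    else:
        for key in ("section_comparison", "phase_comparison", "friedman_sections",
                    "subgroup_comparison", "correlations"):
            blocks[key] = {"absent": True, "reason": "no sensor recordings supplied"}

    blocks["clustering"] = _clustering_block(clin)

    report = AnalysisReport(config=_jsonable(config), blocks=_jsonable(blocks),
                            errors=_jsonable(errors))
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        if df is not None:
            df.to_csv(out_dir / "metrics.csv", index=False)
            z.cells.to_csv(out_dir / "z.csv", index=False)
        if clin:
            records_frame(clin).to_csv(out_dir / "clinical.csv", index=False)
        if "members" in blocks["clustering"]:
            rows = [{"subject": s, "cluster": i + 1}
                    for i, members in enumerate(blocks["clustering"]["members"])
                    for s in members]
            pd.DataFrame(rows).to_csv(out_dir / "clusters.csv", index=False)
        report.to_json(out_dir / "report.json")
    return report


def _section_block(df: pd.DataFrame) -> dict:
    """Control vs MS Mann-Whitney on per-section mean task duration/jerk."""
    sec = section_summary(df, phase=TASK_PHASE)
    out = {}
    for section, grp in sec.groupby("section"):
        co = grp[grp["group"] == "control"]
        ms = grp[_ms_mask(grp)]
        entry = {}
        for param in ("duration", "jerk"):
            x, y = co[param].dropna(), ms[param].dropna()
            if len(x) and len(y):
                entry[param] = _result_dict(mann_whitney(x, y))
        out[section] = entry
    return out


def _phase_block(df: pd.DataFrame) -> dict:
    """Control vs MS Mann-Whitney on per-phase subject means."""
    sub = df[df["phase"] != TASK_PHASE]
    means = sub.groupby(["subject", "group", "phase"], as_index=False)[
        ["duration", "jerk"]].mean()
    out = {}
    for phase, grp in means.groupby("phase"):
        co = grp[grp["group"] == "control"]
        ms = grp[_ms_mask(grp)]
        entry = {}
        for param in ("duration", "jerk"):
            x, y = co[param].dropna(), ms[param].dropna()
            if len(x) and len(y):
                entry[param] = _result_dict(mann_whitney(x, y))
        out[phase] = entry
    return out


def _friedman_block(z: ZScoreTable) -> dict:
    """Friedman across ARAT sections on manipulation/transport/release z."""
    cells = z.cells[_ms_mask(z.cells)].copy()
    cells["section"] = cells["item"].map(section_of_item)
    out = {}
    for phase in _MS_PHASES:
        for param in ("duration", "jerk"):
            sub = cells[(cells["phase"] == phase) & (cells["parameter"] == param)]
            if sub.empty:
                continue
            pivot = sub.pivot_table(index="subject", columns="section",
                                    values="z", aggfunc="mean").dropna(axis=1, how="all").dropna()
            if pivot.shape[1] < 2 or pivot.shape[0] < 2:
                continue
            res = friedman(pivot.to_numpy())
            entry = _result_dict(res)
            entry["sections"] = list(pivot.columns)
            if res.pvalue < 0.05:
                pairs, raws = [], []
                cols = list(pivot.columns)
                for i in range(len(cols)):
                    for j in range(i + 1, len(cols)):
                        pairs.append((cols[i], cols[j]))
                        raws.append(friedman(pivot[[cols[i], cols[j]]].to_numpy()).pvalue)
                adj = holm_adjust(raws)
                entry["posthoc"] = {f"{a} vs {b}": {"p_raw": r, "p_holm": h}
                                    for (a, b), r, h in zip(pairs, raws, adj)}
            out[f"{phase}/{param}"] = entry
    return out


def _subgroup_block(z: ZScoreTable) -> dict:
    """Kruskal-Wallis across MS sub-groups on subject Z_Duration/Z_Jerk."""
    subj = z.subject_level[(z.subject_level["phase"] == TASK_PHASE)]
    out = {}
    for param in ("duration", "jerk"):
        sub = subj[(subj["parameter"] == param) & _ms_mask(subj)]
        groups = {g: grp["z"].to_numpy() for g, grp in sub.groupby("group")
                  if len(grp) >= 2}
        if len(groups) < 2:
            continue
        res = kruskal_wallis(list(groups.values()))
        entry = _result_dict(res)
        entry["groups"] = sorted(groups)
        if res.pvalue < 0.05:
            post = pairwise_mann_whitney_holm(groups)
            entry["posthoc"] = {f"{a} vs {b}": {"p_raw": v["p_raw"], "p_holm": v["p_holm"]}
                                for (a, b), v in post.items()}
        out[f"Z_{param}"] = entry
    return out


def _correlation_block(z: ZScoreTable, clin: Sequence[ClinicalRecord]) -> dict:
    """Spearman correlations of z-scores with the clinical ratings."""
    if not clin:
        return {"absent": True, "reason": "no clinical records supplied"}
    cdf = records_frame(clin)
    subj = z.subject_level
    task = subj[subj["phase"] == TASK_PHASE].pivot_table(
        index=["subject", "group"], columns="parameter", values="z").reset_index()
    task = task[_ms_mask(task)].merge(cdf, on="subject", how="inner")
    out = {}
    for param, col, label in (("duration", "arat", "Z_Duration vs ARAT"),
                              ("jerk", "arat", "Z_Jerk vs ARAT"),
                              ("duration", "nhpt_rate", "Z_Duration vs 9HPT rate"),
                              ("jerk", "nhpt_rate", "Z_Jerk vs 9HPT rate")):
        sub = task[[param, col]].dropna()
        if len(sub) >= 3 and sub[param].nunique() > 1 and sub[col].nunique() > 1:
            out[label] = _result_dict(spearman(sub[param], sub[col]))
    manip = subj[(subj["phase"] == "manipulation") & (subj["parameter"] == "jerk")]
    manip = manip[_ms_mask(manip)].merge(cdf, on="subject", how="inner")
    sub = manip[["z", "ftrs_intention"]].dropna()
    if len(sub) >= 3 and sub["z"].nunique() > 1 and sub["ftrs_intention"].nunique() > 1:
        out["manipulation Z_Jerk vs FTRS intention"] = _result_dict(
            spearman(sub["z"], sub["ftrs_intention"]))
    return out


def _clustering_block(clin: Sequence[ClinicalRecord]) -> dict:
    ms = [r for r in clin if r.cluster != "control"]
    if len(ms) < 3:
        return {"absent": True, "reason": "fewer than 3 MS clinical records"}
    try:
        clustering = cluster_impairment(ms, k=3)
    except IaratError as err:
        return {"absent": True, "reason": str(err)}
    summary = cohort_summary(ms)
    return {
        "k": clustering.k,
        "sizes": clustering.sizes(),
        "members": [sorted(c) for c in clustering.clusters()],
        "cohort_medians": {row["variable"]: row["median"]
                           for row in summary.to_dict("records")},
    }
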