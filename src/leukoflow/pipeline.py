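"""End-to-end case analysis: QC -> transform -> cluster -> classify -> diagnose.

The per-tube stages feed a case-level integration step (cross-tube
matching over the CD45/scatter backbone) and the diagnosis layer.  The
result object carries every intermediate product so reports can show the
human-reviewable chain the same way a manual gating session would.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import (
    CrossTubeMatch,
    TubeModel,
    classify_clusters,
    cross_tube_match,
    integrate_cross_tube,
)
from .diagnose import (
    Diagnosis,
    DiagnosisConfig,
    MergedAbnormal,
    abnormal_fraction,
    diagnose,
    flag_unusual_expression,
    merge_abnormal_clusters,
)
from .errors import ConfigurationError
from .fcs import EventTable, transform_fluorescence
from .mdpc import CellCluster, MDPCConfig, calibrate_channel, mdpc_cluster
from .qc import QCConfig, QCReport, run_qc

__all__ = ["PipelineConfig", "TubeResult", "CaseResult", "analyze_case"]

BACKBONE_CHANNELS = ["CD45", "FSC-A", "SSC-A"]


@dataclass
class PipelineConfig:
    transform_method: str = "arcsinh"
    cofactor: float = 150.0
    qc: QCConfig = field(default_factory=QCConfig)
    mdpc: MDPCConfig = field(default_factory=MDPCConfig)
    diagnosis: DiagnosisConfig = field(default_factory=DiagnosisConfig)
    match_threshold: float = 2.0
    seed: int = 0


@dataclass
class TubeResult:
    tube_id: str
    qc: QCReport
    retained: EventTable                      # transformed scale
    clusters: list[CellCluster]
    labels: dict[str, tuple[str, float]]      # cluster_id -> (category, confidence)
    merged_abnormal: MergedAbnormal
    abnormal_pct: float


@dataclass
class CaseResult:
    tubes: dict[str, TubeResult]
    matches: list[CrossTubeMatch]
    diagnosis: Diagnosis
    config: PipelineConfig

    def cluster_table(self):
        """Flat (tube, cluster, fraction, category, confidence) table."""
        import pandas as pd

        rows = []
        for tid, tr in self.tubes.items():
            for cl in tr.clusters:
                cat, conf = tr.labels[cl.cluster_id]
                rows.append({
                    "tube_id": tid, "cluster_id": cl.cluster_id,
                    "fraction": round(cl.fraction, 4),
                    "category": cat, "confidence": round(conf, 3),
                    **{f"level:{m}": lv.name for m, lv in cl.signature.items()},
                })
        return pd.DataFrame(rows)


def analyze_case(
    tables: dict[str, EventTable],
    config: PipelineConfig | None = None,
    model: TubeModel | None = None,
    overrides: dict[tuple[str, str], str] | None = None,
) -> CaseResult:
    """Run the five-phase workflow on one multi-tube case.

    ``model`` overrides the default rule-based cluster classifier with a
    trained forest (applied to every tube whose channel layout matches).
    ``overrides`` maps (tube_id, cluster_id) to a reviewer-assigned
    category; it is how a hand-edited cluster table is fed back, and it
    is applied after cross-tube integration, before diagnosis.
    """
    cfg = config or PipelineConfig()
    if not tables:
        raise ConfigurationError("no tubes supplied")

    tube_results: dict[str, TubeResult] = {}
    extra_warnings: list[str] = []
    for tube_id, raw in tables.items():
        retained_raw, qc_report = run_qc(raw, cfg.qc)
        tbl = transform_fluorescence(retained_raw, cfg.transform_method, cfg.cofactor)
        cals = {}
        for m in tbl.markers:
            cals[m] = calibrate_channel(
                tbl.column(m), marker=m, level_fractions=cfg.mdpc.level_fractions)
        clusters = mdpc_cluster(tbl, cals, cfg.mdpc)
        if model is not None and model.model_kind == "random_forest":
            pairs = classify_clusters(clusters, model, tbl)
        else:
            pairs = classify_clusters(
                clusters, TubeModel(model_kind="rule_based", classes=[]), tbl)
        labels = {cl.cluster_id: pair for cl, pair in zip(clusters, pairs)}
        merged = merge_abnormal_clusters(clusters, labels, tube_id, cfg.diagnosis)
        tube_results[tube_id] = TubeResult(
            tube_id=tube_id, qc=qc_report, retained=tbl, clusters=clusters,
            labels=labels, merged_abnormal=merged,
            abnormal_pct=abnormal_fraction(merged, qc_report),
        )

    # cross-tube matching over the shared backbone, all ordered tube pairs
    matches: list[CrossTubeMatch] = []
    ids = list(tube_results)
    for src in ids:
        for dst in ids:
            if src == dst:
                continue
            s, d = tube_results[src], tube_results[dst]
            shared = [ch for ch in BACKBONE_CHANNELS
                      if s.retained.has_channel(ch) and d.retained.has_channel(ch)]
            matches.extend(cross_tube_match(
                s.clusters, d.clusters, s.retained, d.retained,
                shared, threshold=cfg.match_threshold))

    classifications = {tid: tr.labels for tid, tr in tube_results.items()}
    revised, xwarn = integrate_cross_tube(classifications, matches)
    extra_warnings.extend(xwarn)
    for (tube_id, cluster_id), category in (overrides or {}).items():
        if tube_id not in revised or cluster_id not in revised[tube_id]:
            raise ConfigurationError(
                f"override names unknown cluster {tube_id}/{cluster_id}")
        revised[tube_id][cluster_id] = (category, 1.0)
        extra_warnings.append(
            f"tube {tube_id} cluster {cluster_id}: category overridden to "
            f"{category} by reviewer")
    for tid, tr in tube_results.items():
        if revised[tid] != tr.labels:
            tr.labels = revised[tid]
            tr.merged_abnormal = merge_abnormal_clusters(
                tr.clusters, tr.labels, tid, cfg.diagnosis)
            tr.abnormal_pct = abnormal_fraction(tr.merged_abnormal, tr.qc)
        extra_warnings.extend(flag_unusual_expression(
            tr.clusters, tr.labels, tube_id=tid))
        extra_warnings.extend(
            f"tube {tid} QC: {w}" for w in tr.qc.warnings)

    dx = diagnose(
        {tid: tr.merged_abnormal for tid, tr in tube_results.items()},
        {tid: tr.qc for tid, tr in tube_results.items()},
        cfg.diagnosis,
        extra_warnings=extra_warnings,
    )
    return CaseResult(tubes=tube_results, matches=matches, diagnosis=dx, config=cfg)
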