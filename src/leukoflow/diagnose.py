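"""Phase-4 AI-assisted diagnosis.

Merges abnormal (blast) clusters of like phenotype, computes the
abnormal cell percentage over QC-retained nucleated events, checks
normal compartments for unusual antigen expression, and assigns the
acute-leukemia subtype (AML / B-ALL / T-ALL), Normal, or routes the case
to manual review.  The conventional >= 20% blast threshold among
nucleated cells triggers the leukemia arm of the decision layer; cases
with blasts of conflicting or dim lineage markers, or sitting just under
the threshold, are deliberately deferred to review rather than forced
into a subtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .classify import BLAST_CATEGORIES
from .errors import ConfigurationError
from .mdpc import CellCluster, ExpressionLevel
from .qc import QCReport

__all__ = [
    "DiagnosisConfig",
    "Diagnosis",
    "MergedAbnormal",
    "merge_abnormal_clusters",
    "abnormal_fraction",
    "flag_unusual_expression",
    "diagnose",
    "NORMAL_EXPECTATIONS",
]

_POS = ExpressionLevel.positive
_PART = ExpressionLevel.partial


@dataclass
class DiagnosisConfig:
    blast_threshold: float = 0.20       # fraction of nucleated cells
    review_band: float = 0.05           # threshold - band .. threshold => review
    merge_levels_tolerance: int = 4     # summed level-rank distance for merging
    review_on_ambiguous_lineage: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.blast_threshold < 1:
            raise ValueError("blast_threshold must be in (0, 1)")


@dataclass
class Diagnosis:
    label: str                          # AML | B_ALL | T_ALL | Normal | Abnormal_review
    abnormal_fraction: float            # percentage of nucleated events, 0.1% precision
    phenotype_summary: dict[str, ExpressionLevel]
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.label == "Abnormal_review" and not self.warnings:
            raise ValueError("Abnormal_review requires at least one warning")

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "abnormal_fraction": self.abnormal_fraction,
            "phenotype_summary": {m: lv.name for m, lv in self.phenotype_summary.items()},
            "warnings": list(self.warnings),
        }


@dataclass
class MergedAbnormal:
    """Union of phenotype-compatible blast clusters within one tube."""

    tube_id: str
    lineage_groups: dict[str, list[CellCluster]]   # lineage -> merged member clusters
    fraction: float                                # blast events / retained events
    signature: dict[str, ExpressionLevel]          # of the dominant lineage group
    warnings: list[str] = field(default_factory=list)


def _sig_rank_distance(a: dict[str, ExpressionLevel], b: dict[str, ExpressionLevel]) -> int:
    keys = set(a) & set(b)
    return int(sum(abs(int(a[m]) - int(b[m])) for m in keys))


def merge_abnormal_clusters(
    clusters: list[CellCluster],
    labels: dict[str, tuple[str, float]],
    tube_id: str = "",
    config: DiagnosisConfig | None = None,
) -> MergedAbnormal:
    """Union blast clusters whose signatures agree within tolerance.

    Blast clusters of distinct lineages are never merged; when more than
    one lineage group survives, an ambiguity warning is emitted.  The
    summary signature is a size-weighted per-marker level of the dominant
    lineage's merged clusters.
    """
    cfg = config or DiagnosisConfig()
    blasts = [cl for cl in clusters
              if labels.get(cl.cluster_id, ("unclassified", 0.0))[0] in BLAST_CATEGORIES]
    groups: dict[str, list[CellCluster]] = {}
    warnings: list[str] = []
    for cl in blasts:
        lineage = labels[cl.cluster_id][0]
        bucket = groups.setdefault(lineage, [])
        if bucket and min(_sig_rank_distance(cl.signature, o.signature)
                          for o in bucket) > cfg.merge_levels_tolerance:
            warnings.append(
                f"tube {tube_id}: {lineage} clusters with divergent phenotypes "
                f"(cluster {cl.cluster_id}); merged by lineage, review advised"
            )
        bucket.append(cl)
    lineages = [lin for lin in groups if lin != "blast_unassigned" and groups[lin]]
    if len(lineages) > 1:
        warnings.append(
            f"tube {tube_id}: blast populations of distinct lineages "
            f"({', '.join(sorted(lineages))}) present; not merged"
        )
    fraction = float(sum(cl.fraction for cl in blasts))
    signature: dict[str, ExpressionLevel] = {}
    if groups:
        dominant = max(groups, key=lambda lin: sum(c.fraction for c in groups[lin]))
        members = groups[dominant]
        total = sum(c.size for c in members)
        for m in members[0].signature:
            w = sum(int(c.signature[m]) * c.size for c in members if m in c.signature)
            signature[m] = ExpressionLevel(int(round(w / total)))
    return MergedAbnormal(
        tube_id=tube_id, lineage_groups=groups, fraction=fraction,
        signature=signature, warnings=warnings,
    )


def abnormal_fraction(merged: MergedAbnormal, qc: QCReport) -> float:
    """Abnormal cell percentage of nucleated (QC-retained) events, to 0.1%."""
    if qc.retained_events == 0:
        raise ValueError("no retained events; abnormal fraction undefined")
    return round(100.0 * merged.fraction, 1)


# expected five-level ranges for normal compartments (marker -> (min, max) level)
NORMAL_EXPECTATIONS: dict[str, dict[str, tuple[ExpressionLevel, ExpressionLevel]]] = {
    "granulocyte": {
        "CD13": (_PART, ExpressionLevel.bright),
        "CD33": (_PART, ExpressionLevel.bright),
        "CD45": (_PART, _POS),
    },
    "lymphocyte": {"CD45": (ExpressionLevel.bright, ExpressionLevel.bright)},
    "T_cell": {"CD45": (ExpressionLevel.bright, ExpressionLevel.bright),
               "CD3": (_POS, ExpressionLevel.bright)},
    "B_cell": {"CD45": (ExpressionLevel.bright, ExpressionLevel.bright),
               "CD19": (_POS, ExpressionLevel.bright)},
    "monocyte": {"CD45": (_POS, ExpressionLevel.bright),
                 "CD14": (_PART, ExpressionLevel.bright),
                 "CD64": (_PART, ExpressionLevel.bright)},
}


def flag_unusual_expression(
    clusters: list[CellCluster],
    labels: dict[str, tuple[str, float]],
    rulebook: dict | None = None,
    tube_id: str = "",
) -> list[str]:
    """Check normal-category clusters against their expected level ranges."""
    book = rulebook or NORMAL_EXPECTATIONS
    warnings: list[str] = []
    for cl in clusters:
        cat = labels.get(cl.cluster_id, ("unclassified", 0.0))[0]
        expected = book.get(cat)
        if not expected:
            continue
        for marker, (lo, hi) in expected.items():
            if marker not in cl.signature:
                continue
            lv = cl.signature[marker]
            if not (int(lo) <= int(lv) <= int(hi)):
                warnings.append(
                    f"tube {tube_id} cluster {cl.cluster_id} ({cat}): unusual {marker} "
                    f"expression {lv.name}, expected {lo.name}"
                    + (f"-{hi.name}" if hi != lo else "")
                )
    return warnings


def _lineage_call(sig: dict[str, ExpressionLevel]) -> tuple[str | None, list[str]]:
    """Resolve the blast lineage from the merged phenotype summary."""
    def at_least(m, lv=_POS):
        return m in sig and int(sig[m]) >= int(lv)

    b = at_least("CD19") and (at_least("CD10", _PART) or at_least("CD79a"))
    t = at_least("cCD3") or (at_least("CD3") and (at_least("CD7") or at_least("CD5")))
    my_count = sum(at_least(m) for m in ("CD13", "CD33", "CD117"))
    my = at_least("MPO") or my_count >= 2
    notes: list[str] = []
    if my and not (b or t):
        if not at_least("MPO"):
            # myeloid by CD13/CD33/CD117 pattern alone; check lymphoid cross-expression
            lymphoid_cross = [m for m in ("CD7", "CD56", "CD2") if at_least(m)]
            if lymphoid_cross:
                notes.append(
                    "MPO-negative blasts cross-expressing lymphoid antigens "
                    f"({', '.join(lymphoid_cross)})"
                )
                return None, notes
        return "AML", notes
    if b and not (t or my):
        return "B_ALL", notes
    if t and not (b or my):
        return "T_ALL", notes
    hits = [name for name, ev in (("B", b), ("T", t), ("myeloid", my)) if ev]
    if len(hits) > 1:
        notes.append(f"conflicting lineage markers ({' + '.join(hits)})")
    else:
        dim_lineage = [m for m in ("cCD3", "CD79a", "MPO")
                       if m in sig and sig[m] in (ExpressionLevel.dim, _PART)]
        if dim_lineage:
            notes.append(
                "lineage-specific markers only dim/partial "
                f"({', '.join(dim_lineage)})"
            )
        else:
            notes.append("no definitive lineage markers on the blast population")
    return None, notes


def diagnose(
    merged_per_tube: dict[str, MergedAbnormal],
    qc_per_tube: dict[str, QCReport],
    config: DiagnosisConfig | None = None,
    extra_warnings: list[str] | None = None,
) -> Diagnosis:
    """Decision layer over the per-tube merged abnormal populations.

    The case-level abnormal fraction is the median of the per-tube blast
    fractions (every tube re-measures the same marrow).  The phenotype
    summary pools each tube's merged-blast signature; markers seen in
    several tubes keep the level from the tube with the largest blast
    population.
    """
    cfg = config or DiagnosisConfig()
    if not merged_per_tube:
        raise ConfigurationError("no tubes to diagnose")
    warnings: list[str] = list(extra_warnings or [])
    for m in merged_per_tube.values():
        warnings.extend(m.warnings)

    fractions = [m.fraction for m in merged_per_tube.values()]
    frac = float(np.median(fractions))
    pct = round(100.0 * frac, 1)

    # pooled phenotype summary, largest blast population wins per marker
    summary: dict[str, ExpressionLevel] = {}
    for m in sorted(merged_per_tube.values(), key=lambda x: x.fraction):
        summary.update(m.signature)

    any_blasts = any(m.lineage_groups for m in merged_per_tube.values())
    if not any_blasts and frac < cfg.blast_threshold:
        return Diagnosis(label="Normal", abnormal_fraction=pct,
                         phenotype_summary=summary, warnings=warnings)

    if frac >= cfg.blast_threshold:
        lineage, notes = _lineage_call(summary)
        if lineage is not None:
            return Diagnosis(label=lineage, abnormal_fraction=pct,
                             phenotype_summary=summary, warnings=warnings)
        warnings.extend(f"abnormal blasts: {n}" for n in notes)
        warnings.append("manual review required: lineage not definitively assignable")
        return Diagnosis(label="Abnormal_review", abnormal_fraction=pct,
                         phenotype_summary=summary, warnings=warnings)

    if frac >= cfg.blast_threshold - cfg.review_band:
        warnings.append(
            f"abnormal cells at {pct:.1f}% sit just below the "
            f"{100 * cfg.blast_threshold:.0f}% diagnostic threshold; manual review required"
        )
        return Diagnosis(label="Abnormal_review", abnormal_fraction=pct,
                         phenotype_summary=summary, warnings=warnings)

    if any_blasts:
        warnings.append(
            f"blast population(s) present at {pct:.1f}% of nucleated cells, below "
            "the diagnostic threshold; manual review required"
        )
        return Diagnosis(label="Abnormal_review", abnormal_fraction=pct,
                         phenotype_summary=summary, warnings=warnings)

    return Diagnosis(label="Normal", abnormal_fraction=pct,
                     phenotype_summary=summary, warnings=warnings)
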