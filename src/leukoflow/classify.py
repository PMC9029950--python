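"""Phase-3 immunophenotype classification of cell clusters.

Each cluster gets a cell category per tube, either from the transparent
CD45/side-scatter gating rulebook (default) or from a bagged random
forest trained on labelled cluster features.  Clusters a single tube
cannot resolve are revisited with cross-tube matching: the shared
(backbone) channels anchor a cluster to its counterpart in another tube,
whose category it may inherit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import joblib
import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ConfigurationError
from .fcs import EventTable
from .mdpc import CellCluster, ExpressionLevel
from .util import robust_scale, robust_zscore

__all__ = [
    "CATEGORIES",
    "BLAST_CATEGORIES",
    "ClusterFeatures",
    "TubeModel",
    "CrossTubeMatch",
    "encode_features",
    "train_tube_model",
    "classify_clusters",
    "rule_classify",
    "cross_tube_match",
    "integrate_cross_tube",
    "save_model",
    "load_model",
]

CATEGORIES = (
    "lymphocyte", "T_cell", "B_cell", "NK_cell", "monocyte", "granulocyte",
    "blast_myeloid", "blast_B", "blast_T", "blast_unassigned", "NRBC",
    "unclassified",
)
BLAST_CATEGORIES = ("blast_myeloid", "blast_B", "blast_T", "blast_unassigned")

_DECILES = np.arange(10, 100, 10)

_LYMPHOID_SUBSETS = ("T_cell", "B_cell", "NK_cell")


def is_category_consistent(predicted: str, truth: str) -> bool:
    """True when a predicted category is correct or a correct generalization.

    A tube without CD3/CD19/CD56 cannot subtype lymphocytes and a tube
    without lineage markers cannot assign a blast lineage; reporting the
    superclass there is correct, not an error.
    """
    if predicted == truth:
        return True
    if predicted == "lymphocyte" and truth in _LYMPHOID_SUBSETS:
        return True
    if predicted == "blast_unassigned" and truth.startswith("blast"):
        return True
    return False


@dataclass
class ClusterFeatures:
    tube_id: str
    cluster_id: str
    fraction: float
    channel_names: list[str]
    mfi: np.ndarray          # per channel
    sd: np.ndarray           # per channel
    deciles: np.ndarray      # channels x 9, transformed scale

    def vector(self) -> np.ndarray:
        return np.concatenate([[self.fraction], self.mfi, self.sd, self.deciles.ravel()])

    @staticmethod
    def feature_names(channel_names: list[str]) -> list[str]:
        names = ["fraction"]
        names += [f"mfi:{c}" for c in channel_names]
        names += [f"sd:{c}" for c in channel_names]
        for c in channel_names:
            names += [f"d{q}:{c}" for q in _DECILES]
        return names


@dataclass
class TubeModel:
    model_kind: str                    # "rule_based" | "random_forest"
    classes: list[str]
    channel_names: list[str] = field(default_factory=list)
    trained_on: str = ""
    oob_accuracy: float | None = None
    forest: RandomForestClassifier | None = None
    confidence_threshold: float = 0.6


@dataclass
class CrossTubeMatch:
    source: tuple[str, str]            # (tube_id, cluster_id)
    target: tuple[str, str] | None
    score: float
    shared_channels: list[str]


def encode_features(cluster: CellCluster, table: EventTable) -> ClusterFeatures:
    """Deterministic cluster-level feature vector: MFI, SD and deciles per channel."""
    if cluster.size == 0:
        raise ValueError("cannot encode an empty cluster")
    vals = table.values[cluster.member_indices]
    names = [c.marker or c.short_name for c in table.channels]
    mfi = np.median(vals, axis=0)
    sd = np.array([robust_scale(vals[:, j]) for j in range(vals.shape[1])])
    deciles = np.percentile(vals, _DECILES, axis=0).T
    return ClusterFeatures(
        tube_id=table.tube_id,
        cluster_id=cluster.cluster_id,
        fraction=cluster.fraction,
        channel_names=names,
        mfi=mfi,
        sd=sd,
        deciles=deciles,
    )


# ---------------------------------------------------------------------------
# Trainable forest
# ---------------------------------------------------------------------------

def train_tube_model(
    examples: list[tuple[ClusterFeatures, str]],
    seed: int = 0,
    n_estimators: int = 200,
) -> TubeModel:
    """Bagged random forest over cluster features, with out-of-bag accuracy."""
    if not examples:
        raise ConfigurationError("no training examples")
    channel_names = examples[0][0].channel_names
    for feats, _ in examples:
        if feats.channel_names != channel_names:
            raise ConfigurationError("training examples mix channel layouts")
    y = np.array([lab for _, lab in examples])
    classes, counts = np.unique(y, return_counts=True)
    thin = [f"{c} (n={k})" for c, k in zip(classes, counts) if k < 5]
    if thin:
        raise ConfigurationError(
            "each class needs >= 5 training clusters; too few: " + ", ".join(thin)
        )
    X = np.vstack([feats.vector() for feats, _ in examples])
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        bootstrap=True,
        oob_score=True,
        random_state=seed,
        n_jobs=1,
    )
    forest.fit(X, y)
    return TubeModel(
        model_kind="random_forest",
        classes=list(forest.classes_),
        channel_names=channel_names,
        trained_on=f"{len(examples)} clusters, seed {seed}",
        oob_accuracy=float(forest.oob_score_),
        forest=forest,
    )


def save_model(model: TubeModel, path) -> None:
    joblib.dump(
        {
            "format_version": 1,
            "model_kind": model.model_kind,
            "classes": model.classes,
            "channel_names": model.channel_names,
            "trained_on": model.trained_on,
            "oob_accuracy": model.oob_accuracy,
            "forest": model.forest,
            "confidence_threshold": model.confidence_threshold,
        },
        path,
    )


def load_model(path) -> TubeModel:
    doc = joblib.load(path)
    if doc.get("format_version") != 1:
        raise ConfigurationError(f"unrecognized model file version in {path}")
    return TubeModel(
        model_kind=doc["model_kind"],
        classes=doc["classes"],
        channel_names=doc["channel_names"],
        trained_on=doc["trained_on"],
        oob_accuracy=doc["oob_accuracy"],
        forest=doc["forest"],
        confidence_threshold=doc["confidence_threshold"],
    )


# ---------------------------------------------------------------------------
# Rule-based classifier (default)
# ---------------------------------------------------------------------------

_POS = ExpressionLevel.positive


def _lvl(sig: dict[str, ExpressionLevel], marker: str) -> int | None:
    v = sig.get(marker)
    return None if v is None else int(v)


def _at_least(sig, marker, level=_POS) -> bool:
    v = _lvl(sig, marker)
    return v is not None and v >= int(level)


def rule_classify(
    cluster: CellCluster,
    table: EventTable,
) -> tuple[str, float]:
    """CD45/SSC gating logic plus lineage markers, evaluated on the cluster
    signature.  Returns (category, confidence); rule hits carry confidence
    1.0, unresolvable clusters are "unclassified" with confidence 0.

    The logic mirrors manual gating: CD45-dim + immaturity marker => blast
    (lineage via CD19/CD10/CD79a, cCD3/CD3+CD7/CD5, MPO/CD13/CD33/CD117);
    CD45-bright low-SSC => lymphocyte subsets; CD14/CD64 => monocyte;
    high-SSC => granulocyte; CD45-negative low-scatter => NRBC.
    """
    sig = cluster.signature
    cd45 = _lvl(sig, "CD45")

    # side-scatter position of the cluster within this tube's events
    ssc = table.column("SSC-A")
    ssc_med = float(np.median(ssc[cluster.member_indices]))
    ssc_pct = float((ssc < ssc_med).mean())

    b_evidence = _at_least(sig, "CD19") and (
        _at_least(sig, "CD10", ExpressionLevel.partial) or _at_least(sig, "CD79a")
    )
    t_evidence = _at_least(sig, "cCD3") or (
        _at_least(sig, "CD3") and (_at_least(sig, "CD7") or _at_least(sig, "CD5"))
    )
    my_count = sum(_at_least(sig, m) for m in ("CD13", "CD33", "CD117"))
    my_evidence = _at_least(sig, "MPO") or my_count >= 2

    immature = any(
        _at_least(sig, m) for m in ("CD34", "CD117")
    ) or _at_least(sig, "CD10", ExpressionLevel.partial)

    if cd45 is not None and cd45 <= ExpressionLevel.partial:
        # CD45-dim region: blasts and NRBCs live here
        if cd45 == ExpressionLevel.negative and not immature and ssc_pct <= 0.5 and \
                not (b_evidence or t_evidence or my_evidence):
            return "NRBC", 1.0
        if immature or cd45 == ExpressionLevel.dim:
            lineages = [lin for lin, ev in
                        (("blast_B", b_evidence), ("blast_T", t_evidence),
                         ("blast_myeloid", my_evidence)) if ev]
            if len(lineages) == 1:
                return lineages[0], 1.0
            if len(lineages) > 1:
                return "unclassified", 0.0        # contradictory lineage markers
            return "blast_unassigned", 1.0
        return "unclassified", 0.0

    if cd45 is None:
        return "unclassified", 0.0

    # CD45 positive/bright: mature compartments
    mono_evidence = _at_least(sig, "CD14", ExpressionLevel.partial) or (
        _at_least(sig, "CD64") and ssc_pct < 0.85
    )
    myeloid_granularity = any(
        _at_least(sig, m, ExpressionLevel.partial)
        for m in ("CD13", "CD33", "CD15", "CD16", "CD11b")
    )
    if b_evidence and t_evidence:
        return "unclassified", 0.0                # contradictory markers
    if mono_evidence and cd45 >= _POS and ssc_pct < 0.9:
        return "monocyte", 1.0
    if ssc_pct >= 0.55 and cd45 >= _POS and myeloid_granularity:
        return "granulocyte", 1.0
    if cd45 == ExpressionLevel.bright and ssc_pct < 0.75:
        if _at_least(sig, "CD3") or _at_least(sig, "cCD3"):
            return "T_cell", 1.0
        if _at_least(sig, "CD19") or _at_least(sig, "CD20"):
            return "B_cell", 1.0
        if _at_least(sig, "CD56") and not _at_least(sig, "CD3"):
            return "NK_cell", 1.0
        return "lymphocyte", 1.0
    # tubes without myelomonocytic markers cannot separate granulocytes and
    # monocytes by CD45/SSC alone; defer to cross-tube integration
    return "unclassified", 0.0


def classify_clusters(
    clusters: list[CellCluster],
    model: TubeModel,
    table: EventTable | None = None,
) -> list[tuple[str, float]]:
    """Label every cluster; confidence is the forest vote fraction (1.0 for rules).

    Forest labels below the model's confidence threshold become
    "unclassified" so cross-tube integration can resolve them.
    """
    if not clusters:
        return []
    if model.model_kind == "rule_based":
        if table is None:
            raise ConfigurationError("rule-based classification needs the EventTable")
        return [rule_classify(cl, table) for cl in clusters]
    if model.forest is None:
        raise ConfigurationError("random_forest model has no fitted forest")
    if table is None:
        raise ConfigurationError("classification needs the EventTable for features")
    feats = [encode_features(cl, table) for cl in clusters]
    for ft in feats:
        if ft.channel_names != model.channel_names:
            raise ConfigurationError(
                f"tube {table.tube_id!r} channels {ft.channel_names} do not match "
                f"the model's {model.channel_names}"
            )
    X = np.vstack([ft.vector() for ft in feats])
    proba = model.forest.predict_proba(X)
    out = []
    for row in proba:
        j = int(np.argmax(row))
        conf = float(row[j])
        label = model.forest.classes_[j]
        if conf < model.confidence_threshold:
            label, conf = "unclassified", conf
        out.append((label, conf))
    return out


# ---------------------------------------------------------------------------
# Cross-tube matching
# ---------------------------------------------------------------------------

def cross_tube_match(
    source_clusters: list[CellCluster],
    target_clusters: list[CellCluster],
    source_table: EventTable,
    target_table: EventTable,
    shared: list[str],
    threshold: float = 2.0,
    fraction_weight: float = 0.5,
) -> list[CrossTubeMatch]:
    """Match each source cluster to its best counterpart in another tube.

    The anchor features are the shared channels' MFIs, standardized
    against each tube's own event distribution (robust z-scores), plus a
    penalty on the cluster-fraction difference.  The best (lowest) score
    wins; above ``threshold`` the cluster stays unmatched.  Matching is
    many-to-one: several source clusters may share a target.
    """
    if not shared:
        raise ConfigurationError("cross-tube matching needs a non-empty shared channel list")

    def anchors(clusters, table):
        vecs = []
        for cl in clusters:
            z = []
            for ch in shared:
                col = table.column(ch)
                z.append(float(robust_zscore(np.array([cl.mfi[ch]]), ref=col)[0]))
            vecs.append(np.array(z))
        return vecs

    src = anchors(source_clusters, source_table)
    tgt = anchors(target_clusters, target_table)
    out: list[CrossTubeMatch] = []
    for i, cl in enumerate(source_clusters):
        best_j, best_score = None, np.inf
        for j, tcl in enumerate(target_clusters):
            d = float(np.linalg.norm(src[i] - tgt[j])) / np.sqrt(len(shared))
            score = d + fraction_weight * abs(cl.fraction - tcl.fraction)
            if score < best_score:
                best_j, best_score = j, score
        if best_j is None or best_score > threshold:
            out.append(CrossTubeMatch(
                source=(source_table.tube_id, cl.cluster_id),
                target=None, score=float(best_score), shared_channels=list(shared)))
        else:
            out.append(CrossTubeMatch(
                source=(source_table.tube_id, cl.cluster_id),
                target=(target_table.tube_id, target_clusters[best_j].cluster_id),
                score=float(best_score), shared_channels=list(shared)))
    return out


def _refinable(category: str, counterpart: str) -> bool:
    """May ``category`` inherit ``counterpart`` from a matched cluster?

    Unclassified clusters inherit anything; a generic lymphocyte may be
    refined to a T/B/NK subset and an unassigned-lineage blast to a
    lineage-assigned blast (other tubes carry the deciding markers).
    """
    if counterpart == "unclassified":
        return False
    if category == "unclassified":
        return True
    if category == "lymphocyte" and counterpart in ("T_cell", "B_cell", "NK_cell"):
        return True
    if category == "blast_unassigned" and counterpart in BLAST_CATEGORIES:
        return True
    return False


def integrate_cross_tube(
    classifications: dict[str, dict[str, tuple[str, float]]],
    matches: list[CrossTubeMatch],
    inherit_confidence: float = 0.8,
) -> tuple[dict[str, dict[str, tuple[str, float]]], list[str]]:
    """Let unresolved clusters inherit the category of a confident counterpart.

    ``classifications`` maps tube_id -> cluster_id -> (category, confidence).
    Unclassified clusters (and generic labels a counterpart can refine,
    see :func:`_refinable`) take the matched cluster's category when its
    confidence reaches ``inherit_confidence``.  Counterparts disagreeing
    about the inherited category leave the cluster as it was, with a
    warning.  Returns (revised, warnings).
    """
    revised = {t: dict(d) for t, d in classifications.items()}
    warnings: list[str] = []
    proposals: dict[tuple[str, str], set[str]] = {}
    for m in matches:
        if m.target is None:
            continue
        s_tube, s_cl = m.source
        cat, conf = classifications.get(s_tube, {}).get(s_cl, ("unclassified", 0.0))
        t_tube, t_cl = m.target
        t_cat, t_conf = classifications.get(t_tube, {}).get(t_cl, ("unclassified", 0.0))
        if t_conf < inherit_confidence or not _refinable(cat, t_cat):
            continue
        proposals.setdefault((s_tube, s_cl), set()).add(t_cat)
    for (tube, cl), cats in proposals.items():
        if len(cats) == 1:
            cat = next(iter(cats))
            revised[tube][cl] = (cat, inherit_confidence)
        else:
            was = classifications[tube][cl][0]
            state = "left unclassified" if was == "unclassified" else f"kept as {was}"
            warnings.append(
                f"tube {tube} cluster {cl}: cross-tube counterparts disagree "
                f"({', '.join(sorted(cats))}); {state}"
            )
    return revised, warnings
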