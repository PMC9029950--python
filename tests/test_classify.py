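"""Cluster classification, forest training, and cross-tube matching tests."""

import numpy as np
import pytest

from leukoflow.classify import (
    ClusterFeatures,
    CrossTubeMatch,
    TubeModel,
    classify_clusters,
    cross_tube_match,
    encode_features,
    integrate_cross_tube,
    is_category_consistent,
    load_model,
    rule_classify,
    save_model,
    train_tube_model,
)
from leukoflow.errors import ConfigurationError
from leukoflow.mdpc import CellCluster, ExpressionLevel


def _feat(rng, base, label, n=30, channel_names=("CD45", "CD19")):
    out = []
    for _ in range(n):
        mfi = np.asarray(base, dtype=float) + rng.normal(0, 0.1, len(base))
        out.append((ClusterFeatures(
            tube_id="t", cluster_id="c", fraction=0.3,
            channel_names=list(channel_names), mfi=mfi,
            sd=np.full(len(base), 0.3),
            deciles=np.tile(mfi, (9, 1)).T), label))
    return out


class TestFeatures:
    def test_identical_events_zero_spread(self, analyzed_normal):
        res, _ = analyzed_normal
        tr = res.tubes["tube1"]
        tbl = tr.retained
        cl = CellCluster("X", np.array([0, 0, 0]), 0.01,
                         mfi={}, sd={})
        feats = encode_features(cl, tbl)
        assert np.allclose(feats.sd, 0)
        assert np.allclose(feats.deciles, feats.mfi[:, None])

    def test_feature_locality(self, analyzed_normal):
        res, _ = analyzed_normal
        tbl = res.tubes["tube1"].retained
        cl = res.tubes["tube1"].clusters[0]
        a = encode_features(cl, tbl)
        shifted = tbl.subset(np.arange(tbl.n_events))
        j = shifted.channel_index("CD19")
        shifted.values[:, j] += 1.0
        b = encode_features(cl, shifted)
        names = np.array(a.channel_names)
        moved = np.where(~np.isclose(a.mfi, b.mfi))[0]
        assert set(names[moved]) == {"CD19"}

    def test_lymphocyte_cd45_bright(self, analyzed_normal):
        res, _ = analyzed_normal
        tr = res.tubes["tube2"]
        tcell = next(c for c in tr.clusters if tr.labels[c.cluster_id][0] == "T_cell")
        assert tcell.signature["CD45"] == ExpressionLevel.bright


class TestForest:
    def test_separable_classes_high_oob(self):
        rng = np.random.default_rng(0)
        ex = _feat(rng, [1.0, 0.2], "blast_B") + _feat(rng, [5.0, 4.0], "B_cell")
        model = train_tube_model(ex, seed=0)
        assert model.oob_accuracy >= 0.95
        assert model.model_kind == "random_forest"

    def test_no_signal_oob_near_chance(self):
        rng = np.random.default_rng(1)
        ex = _feat(rng, [2.0, 2.0], "A", n=50) + _feat(rng, [2.0, 2.0], "B", n=50)
        model = train_tube_model(ex, seed=0)
        assert model.oob_accuracy == pytest.approx(0.5, abs=0.1)

    def test_retrain_deterministic(self):
        rng = np.random.default_rng(2)
        ex = _feat(rng, [1.0, 0.2], "A") + _feat(rng, [4.0, 3.0], "B")
        X = np.vstack([f.vector() for f, _ in ex])
        m1 = train_tube_model(ex, seed=7)
        m2 = train_tube_model(ex, seed=7)
        np.testing.assert_array_equal(m1.forest.predict(X), m2.forest.predict(X))

    def test_missing_class_listed(self):
        rng = np.random.default_rng(3)
        ex = _feat(rng, [1.0, 0.2], "A") + _feat(rng, [4.0, 3.0], "B", n=3)
        with pytest.raises(ConfigurationError, match="B"):
            train_tube_model(ex)

    def test_model_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        ex = _feat(rng, [1.0, 0.2], "A") + _feat(rng, [4.0, 3.0], "B")
        model = train_tube_model(ex, seed=0)
        save_model(model, tmp_path / "m.joblib")
        back = load_model(tmp_path / "m.joblib")
        X = np.vstack([f.vector() for f, _ in ex])
        np.testing.assert_array_equal(model.forest.predict(X), back.forest.predict(X))
        assert back.channel_names == model.channel_names


class TestRuleClassifier:
    def _cluster(self, sig, tbl, lo_ssc=True):
        n = tbl.n_events
        ssc = tbl.column("SSC-A")
        order = np.argsort(ssc)
        members = order[:50] if lo_ssc else order[-50:]
        cl = CellCluster("X", members, 50 / n, mfi={}, sd={})
        cl.signature = {m: ExpressionLevel[v] for m, v in sig.items()}
        return cl

    def test_contradictory_markers_unclassified(self, analyzed_normal):
        res, _ = analyzed_normal
        tbl = res.tubes["tube1"].retained
        cl = self._cluster({"CD45": "dim", "CD34": "positive", "CD19": "positive",
                            "CD10": "positive", "cCD3": "positive"}, tbl)
        cat, conf = rule_classify(cl, tbl)
        assert cat == "unclassified" and conf == 0.0

    def test_normal_marrow_categories(self, analyzed_normal):
        """Lymphoid/monocyte/granulocyte/NRBC clusters of a clear-cut normal
        marrow all carry a correct (possibly superclass) category after
        cross-tube integration."""
        res, truth = analyzed_normal
        from collections import Counter
        for tid, tr in res.tubes.items():
            tret = tr.retained.column("Time").astype(int)
            pop = truth.population_labels[tid][tret]
            for cl in tr.clusters:
                cat = tr.labels[cl.cluster_id][0]
                major = Counter(pop[cl.member_indices]).most_common(1)[0][0]
                assert is_category_consistent(cat, major), (tid, cat, major)

    def test_empty_cluster_list(self):
        assert classify_clusters([], TubeModel("rule_based", [])) == []


class TestCrossTube:
    def test_self_match_identity(self, analyzed_normal):
        res, _ = analyzed_normal
        tr = res.tubes["tube1"]
        matches = cross_tube_match(tr.clusters, tr.clusters, tr.retained,
                                   tr.retained, ["CD45", "FSC-A", "SSC-A"])
        for m, cl in zip(matches, tr.clusters):
            assert m.target == ("tube1", cl.cluster_id)
            assert m.score == pytest.approx(0.0, abs=1e-12)

    def test_truth_pairing_recovered(self, analyzed_normal):
        """Backbone anchors pair each population's cluster across tubes."""
        res, truth = analyzed_normal
        from collections import Counter
        s, d = res.tubes["tube1"], res.tubes["tube3"]
        matches = cross_tube_match(s.clusters, d.clusters, s.retained, d.retained,
                                   ["CD45", "FSC-A", "SSC-A"])
        s_ret = s.retained.column("Time").astype(int)
        d_ret = d.retained.column("Time").astype(int)
        s_pop = truth.population_labels["tube1"][s_ret]
        d_pop = truth.population_labels["tube3"][d_ret]

        def major(clusters, pop, cid):
            cl = next(c for c in clusters if c.cluster_id == cid)
            return Counter(pop[cl.member_indices]).most_common(1)[0][0]

        lymphoid = {"T_cell", "B_cell", "NK_cell"}
        for m in matches:
            src_cl = next(c for c in s.clusters if c.cluster_id == m.source[1])
            if src_cl.fraction < 0.05 or m.target is None:
                continue
            a = major(s.clusters, s_pop, m.source[1])
            b = major(d.clusters, d_pop, m.target[1])
            assert a == b or ({a, b} <= lymphoid), (a, b)

    def test_zero_threshold_matches_nothing(self, analyzed_normal):
        res, _ = analyzed_normal
        s, d = res.tubes["tube1"], res.tubes["tube3"]
        matches = cross_tube_match(s.clusters, d.clusters, s.retained, d.retained,
                                   ["CD45", "FSC-A", "SSC-A"], threshold=0.0)
        assert all(m.target is None for m in matches)

    def test_empty_shared_channels_rejected(self, analyzed_normal):
        res, _ = analyzed_normal
        tr = res.tubes["tube1"]
        with pytest.raises(ConfigurationError):
            cross_tube_match(tr.clusters, tr.clusters, tr.retained, tr.retained, [])


class TestIntegration:
    CLS = {
        "t1": {"P1": ("unclassified", 0.0), "P2": ("granulocyte", 1.0)},
        "t2": {"P1": ("blast_B", 1.0)},
        "t3": {"P1": ("blast_T", 1.0)},
    }

    def _match(self, src, tgt):
        return CrossTubeMatch(source=src, target=tgt, score=0.1,
                              shared_channels=["CD45"])

    def test_inherit_from_confident_counterpart(self):
        revised, warns = integrate_cross_tube(
            self.CLS, [self._match(("t1", "P1"), ("t2", "P1"))])
        assert revised["t1"]["P1"][0] == "blast_B"
        assert warns == []

    def test_no_matches_no_change(self):
        revised, warns = integrate_cross_tube(self.CLS, [])
        assert revised == self.CLS and warns == []

    def test_conflicting_counterparts_warn(self):
        revised, warns = integrate_cross_tube(
            self.CLS, [self._match(("t1", "P1"), ("t2", "P1")),
                       self._match(("t1", "P1"), ("t3", "P1"))])
        assert revised["t1"]["P1"][0] == "unclassified"
        assert len(warns) == 1 and "disagree" in warns[0]

    def test_low_confidence_counterpart_ignored(self):
        cls = {"t1": {"P1": ("unclassified", 0.0)},
               "t2": {"P1": ("blast_B", 0.5)}}
        revised, _ = integrate_cross_tube(cls, [self._match(("t1", "P1"), ("t2", "P1"))])
        assert revised["t1"]["P1"][0] == "unclassified"
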