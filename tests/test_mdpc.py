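"""Five-level calibration and density-phenotype clustering tests."""

import numpy as np
import pytest
from scipy.stats import gaussian_kde
from sklearn.metrics import adjusted_rand_score
from sklearn.mixture import GaussianMixture

from conftest import make_table
from leukoflow.errors import InsufficientDataError
from leukoflow.fcs import transform_fluorescence
from leukoflow.mdpc import (
    ChannelCalibration,
    ExpressionLevel,
    MDPCConfig,
    calibrate_channel,
    call_level,
    cluster_signature,
    mdpc_cluster,
)
from leukoflow.qc import run_qc
from leukoflow.simulate import PopulationTemplate, simulate_case


def _marker_table(X, markers):
    """Transformed-scale marker-only table (constant scatter/time)."""
    n = X.shape[0]
    vals = np.c_[np.full(n, 5e4), np.full(n, 4.75e4), np.full(n, 1.5e4),
                 np.arange(n), X]
    return make_table(vals, markers=markers, transform_state="transformed")


class TestCalibration:
    def test_bimodal_boundary_at_kde_valley(self):
        rng = np.random.default_rng(0)
        vals = np.r_[rng.normal(0, 0.3, 2000), rng.normal(4, 0.4, 1500)]
        cal = calibrate_channel(vals, marker="CD19")
        # oracle: the minimum of a kernel density estimate between the modes
        kde = gaussian_kde(vals)
        xs = np.linspace(0.5, 3.5, 200)
        valley = xs[np.argmin(kde(xs))]
        assert 0.5 < cal.cut_points[0] <= valley + 0.3
        assert call_level(0.0, cal) == ExpressionLevel.negative
        assert call_level(4.0, cal) >= ExpressionLevel.positive

    def test_unimodal_channel_reads_negative(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(0.3, 0.35, 3000)
        cal = calibrate_channel(vals, marker="CD117")
        levels = [call_level(v, cal) for v in np.percentile(vals, [5, 50, 95])]
        assert all(lv == ExpressionLevel.negative for lv in levels)

    def test_explicit_anchor_all_below_is_negative(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(1.0, 0.5, 1000)
        cal = calibrate_channel(vals, negative_anchor=5.0, marker="CD5")
        assert all(call_level(v, cal) == ExpressionLevel.negative for v in vals)

    def test_levels_monotone_in_mfi(self):
        rng = np.random.default_rng(3)
        vals = np.r_[rng.normal(0, 0.3, 1000), rng.normal(4, 0.4, 1000)]
        cal = calibrate_channel(vals, marker="CD33")
        grid = np.linspace(vals.min(), vals.max(), 500)
        levels = [int(call_level(v, cal)) for v in grid]
        assert all(b >= a for a, b in zip(levels, levels[1:]))

    def test_degenerate_input_rejected(self):
        with pytest.raises(InsufficientDataError):
            calibrate_channel(np.full(1000, 2.0), marker="CD10")
        with pytest.raises(InsufficientDataError):
            calibrate_channel(np.random.default_rng(0).normal(size=100))


class TestCallLevel:
    CAL = ChannelCalibration(marker="x", cut_points=(1.0, 2.0, 3.0, 4.0))

    @pytest.mark.parametrize("mfi,expected", [
        (0.5, ExpressionLevel.negative),
        (5.0, ExpressionLevel.bright),
        (2.0, ExpressionLevel.partial),   # boundary resolves upward
        (1.0, ExpressionLevel.dim),
        (4.0, ExpressionLevel.bright),
        (2.5, ExpressionLevel.partial),
    ])
    def test_interval_mapping(self, mfi, expected):
        assert call_level(mfi, self.CAL) == expected


class TestClustering:
    def _cals(self, tbl):
        return {m: calibrate_channel(tbl.column(m), marker=m) for m in tbl.markers}

    def test_two_separated_gaussians(self):
        rng = np.random.default_rng(4)
        n1, n2 = 1200, 800  # 60% / 40%
        X = np.zeros((n1 + n2, 2))
        X[:n1] = rng.normal([0.3, 0.3], 0.35, (n1, 2))
        X[n1:] = rng.normal([6.3, 0.3], 0.35, (n2, 2))
        tbl = _marker_table(X, ["CD19", "CD10"])
        clusters = mdpc_cluster(tbl, self._cals(tbl), MDPCConfig(use_scatter=False))
        assert len(clusters) == 2
        assert clusters[0].fraction == pytest.approx(0.6, abs=0.02)
        truth = np.r_[np.zeros(n1), np.ones(n2)]
        pred = np.empty(n1 + n2)
        for i, cl in enumerate(clusters):
            pred[cl.member_indices] = i
        assert adjusted_rand_score(truth, pred) >= 0.99

    def test_single_gaussian_single_cluster(self):
        rng = np.random.default_rng(5)
        X = rng.normal(2.0, 0.4, (1500, 2))
        tbl = _marker_table(X, ["CD19", "CD10"])
        clusters = mdpc_cluster(tbl, self._cals(tbl), MDPCConfig(use_scatter=False))
        assert len(clusters) == 1
        assert clusters[0].size == 1500

    def test_five_population_marrow_recovered(self):
        fiv = [
            PopulationTemplate("gran", "granulocyte", 0.40,
                               {"CD45": "positive", "CD13": "positive",
                                "CD33": "positive", "CD16": "positive"},
                               fsc_mean=65000, fsc_sd=9000,
                               ssc_mean=75000, ssc_sd=12000),
            PopulationTemplate("lymph", "lymphocyte", 0.25, {"CD45": "bright"},
                               fsc_mean=50000, fsc_sd=7000,
                               ssc_mean=14000, ssc_sd=3000),
            PopulationTemplate("mono", "monocyte", 0.12,
                               {"CD45": "positive", "CD14": "positive",
                                "CD64": "positive", "CD33": "bright",
                                "CD13": "positive"},
                               fsc_mean=75000, fsc_sd=9000,
                               ssc_mean=35000, ssc_sd=6000),
            PopulationTemplate("nrbc", "NRBC", 0.10, {},
                               fsc_mean=35000, fsc_sd=6000,
                               ssc_mean=7000, ssc_sd=2000),
            PopulationTemplate("blast", "blast_myeloid", 0.13,
                               {"CD45": "dim", "CD34": "positive",
                                "CD117": "positive", "CD13": "positive",
                                "CD33": "positive"},
                               fsc_mean=60000, fsc_sd=8000,
                               ssc_mean=18000, ssc_sd=4000),
        ]
        tables, truth = simulate_case(fiv, n_events=4000, seed=6)
        tbl = transform_fluorescence(tables["tube3"])
        clusters = mdpc_cluster(tbl, self._cals(tbl))
        assert len(clusters) == 5
        pred = np.empty(tbl.n_events)
        for i, cl in enumerate(clusters):
            pred[cl.member_indices] = i
        assert adjusted_rand_score(truth.population_labels["tube3"], pred) >= 0.9

    def test_partition_is_disjoint_and_exhaustive(self, analyzed_normal):
        res, _ = analyzed_normal
        for tr in res.tubes.values():
            seen = np.concatenate([c.member_indices for c in tr.clusters])
            assert len(seen) == len(set(seen)) == tr.retained.n_events

    def test_deterministic(self):
        rng = np.random.default_rng(7)
        X = np.r_[rng.normal([0.3, 0.3], 0.35, (600, 2)),
                  rng.normal([4.3, 4.3], 0.35, (400, 2))]
        tbl = _marker_table(X, ["CD19", "CD10"])
        cals = self._cals(tbl)
        c1 = mdpc_cluster(tbl, cals, MDPCConfig(use_scatter=False))
        c2 = mdpc_cluster(tbl, cals, MDPCConfig(use_scatter=False))
        for a, b in zip(c1, c2):
            np.testing.assert_array_equal(a.member_indices, b.member_indices)
            assert a.signature == b.signature

    def test_matches_gmm_oracle_on_small_mixtures(self):
        """On <= 500 events from k <= 3 separable spherical Gaussians the
        clustering must agree with a maximum-likelihood mixture fit with
        known k (the independent oracle)."""
        rng = np.random.default_rng(8)
        for k_true, centers in [(2, [(0.3, 0.3), (5.3, 0.5)]),
                                (3, [(0.3, 0.3), (5.3, 0.4), (2.8, 5.3)])]:
            sizes = [500 // k_true] * (k_true - 1) + [500 - (k_true - 1) * (500 // k_true)]
            X = np.vstack([rng.normal(c, 0.3, (s, 2))
                           for c, s in zip(centers, sizes)])
            tbl = _marker_table(X, ["CD19", "CD10"])
            clusters = mdpc_cluster(tbl, self._cals(tbl),
                                    MDPCConfig(use_scatter=False))
            pred = np.empty(len(X))
            for i, cl in enumerate(clusters):
                pred[cl.member_indices] = i
            gmm = GaussianMixture(n_components=k_true, covariance_type="spherical",
                                  n_init=5, random_state=0).fit(X)
            assert adjusted_rand_score(gmm.predict(X), pred) >= 0.99

    def test_too_few_events_rejected(self):
        X = np.random.default_rng(9).normal(size=(30, 2))
        tbl = _marker_table(X, ["CD19", "CD10"])
        with pytest.raises(InsufficientDataError):
            mdpc_cluster(tbl, {}, MDPCConfig(density_neighbors=50))


class TestSignature:
    def test_blast_template_signature(self, analyzed_ball):
        res, _ = analyzed_ball
        tr = res.tubes["tube1"]
        blast = max(tr.clusters, key=lambda c: c.fraction)  # 50% blasts dominate
        assert tr.labels[blast.cluster_id][0] == "blast_B"
        assert blast.signature["CD19"] >= ExpressionLevel.positive
        assert blast.signature["CD45"] == ExpressionLevel.dim

    def test_identical_mfi_identical_signature(self):
        cal = {"CD19": ChannelCalibration("CD19", (1, 2, 3, 4))}
        from leukoflow.mdpc import CellCluster
        a = CellCluster("P1", np.array([0]), 0.5, {"CD19": 2.5}, {"CD19": 0.1})
        b = CellCluster("P2", np.array([1]), 0.5, {"CD19": 2.5}, {"CD19": 0.1})
        assert cluster_signature(a, cal) == cluster_signature(b, cal)

    def test_zero_fluorescence_all_negative(self):
        cal = {"CD19": ChannelCalibration("CD19", (1, 2, 3, 4)),
               "CD10": ChannelCalibration("CD10", (1, 2, 3, 4))}
        from leukoflow.mdpc import CellCluster
        cl = CellCluster("P1", np.array([0]), 1.0,
                         {"CD19": 0.0, "CD10": 0.0}, {"CD19": 0.0, "CD10": 0.0})
        sig = cluster_signature(cl, cal)
        assert all(lv == ExpressionLevel.negative for lv in sig.values())
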