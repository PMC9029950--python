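"""Flow stability, doublet and debris filtering tests."""

import numpy as np
import pytest

from conftest import make_table
from leukoflow.errors import ConfigurationError, InsufficientDataError
from leukoflow.qc import (
    LinearSeparator,
    QCConfig,
    QCReport,
    check_flow_stability,
    filter_doublets,
    fit_singlet_separator,
    remove_debris,
    run_qc,
)
from leukoflow.simulate import DriftSpec, builtin_templates, simulate_case
from scipy.stats import theilslopes


def _scatter_table(rng, n=5000, fsc_mean=50000.0, fsc_sd=5000.0):
    vals = np.zeros((n, 4))
    fsc = rng.normal(fsc_mean, fsc_sd, n)
    vals[:, 0] = fsc
    vals[:, 1] = 0.95 * fsc + rng.normal(0, 500, n)
    vals[:, 2] = rng.normal(15000, 2000, n)
    vals[:, 3] = np.arange(n)
    return make_table(vals)


class TestFlowStability:
    def test_stationary_is_stable(self):
        t = _scatter_table(np.random.default_rng(0))
        res = check_flow_stability(t, window_events=500, deviation_k=5)
        assert res.stable and res.flagged_windows == []

    def test_constant_signal_is_stable(self):
        vals = np.zeros((2000, 4))
        vals[:, 0] = 42000.0
        vals[:, 1] = 40000.0
        vals[:, 3] = np.arange(2000)
        res = check_flow_stability(make_table(vals), window_events=500)
        assert res.stable
        assert np.allclose(res.moving_average, 42000.0)

    def test_middle_third_shift_flagged(self):
        rng = np.random.default_rng(1)
        t = _scatter_table(rng, n=9000, fsc_sd=3000.0)
        lo, hi = 3000, 6000
        t.values[lo:hi, 0] += 10 * 3000.0  # +10 event SDs
        res = check_flow_stability(t, window_events=500, deviation_k=4)
        assert not res.stable
        flagged = set()
        for a, b in res.flagged_windows:
            flagged.update(range(a, b))
        shifted = set(range(lo, hi))
        assert len(flagged & shifted) / len(shifted) >= 0.9
        assert len(flagged - shifted) <= 500  # at most one boundary window extra

    def test_missing_time_channel_rejected(self):
        vals = np.random.default_rng(2).uniform(0, 1, size=(200, 1))
        # a scatter-only table without a time channel
        from leukoflow.fcs import ChannelMeta, EventTable
        t = EventTable(
            values=np.c_[vals, vals, vals],
            channels=[ChannelMeta("FSC-A", is_scatter=True),
                      ChannelMeta("FSC-H", is_scatter=True),
                      ChannelMeta("SSC-A", is_scatter=True)])
        with pytest.raises(ConfigurationError, match="time channel"):
            check_flow_stability(t)


class TestSingletSeparator:
    def test_exact_proportional_data(self):
        rng = np.random.default_rng(3)
        vals = np.zeros((1000, 4))
        fsc = rng.uniform(20000, 80000, 1000)
        vals[:, 0] = fsc
        vals[:, 1] = 0.9 * fsc
        vals[:, 3] = np.arange(1000)
        sep = fit_singlet_separator(make_table(vals))
        assert sep.slope == pytest.approx(0.9, rel=1e-6)
        assert abs(sep.intercept) < 1.0

    def test_robust_to_doublets(self):
        rng = np.random.default_rng(4)
        t = _scatter_table(rng, n=4000)
        n_d = 200  # 5% doublets: FSC-A doubles, FSC-H does not
        t.values[:n_d, 0] *= 2
        sep = fit_singlet_separator(t)
        # oracle: fit on the uncontaminated singlets alone
        s = t.values[n_d:]
        slope_oracle, *_ = theilslopes(s[:, 1], s[:, 0])
        assert sep.slope == pytest.approx(slope_oracle, rel=0.05)

    def test_degenerate_data_rejected(self):
        vals = np.tile([50000.0, 47500.0, 15000.0, 0.0], (500, 1))
        vals[:, 3] = np.arange(500)
        with pytest.raises(InsufficientDataError):
            fit_singlet_separator(make_table(vals))

    def test_too_few_events_rejected(self):
        t = _scatter_table(np.random.default_rng(5), n=50)
        with pytest.raises(InsufficientDataError, match="100"):
            fit_singlet_separator(t)


class TestDoubletFilter:
    def test_event_on_the_line_is_singlet(self):
        sep = LinearSeparator(slope=1.0, intercept=0.0, margin=0.0)
        vals = np.array([[100.0, 100.0, 10.0, 0.0],   # exactly on the line
                         [100.0, 50.0, 10.0, 1.0]])   # far below
        labels = filter_doublets(make_table(vals), sep)
        assert labels[0] == "singlet" and labels[1] == "doublet"

    def test_injected_doublets_recovered(self, normal_case_artifacts):
        tables, truth = normal_case_artifacts
        t = tables["tube1"]
        art = truth.artifact_labels["tube1"]
        keep = art != "debris"   # debris is handled by its own stage
        sub = t.subset(keep)
        sep = fit_singlet_separator(sub)
        labels = filter_doublets(sub, sep)
        is_doublet = art[keep] == "doublet"
        recall = (labels[is_doublet] == "doublet").mean()
        fpr = (labels[~is_doublet] == "doublet").mean()
        assert recall >= 0.9
        assert fpr <= 0.02

    def test_infinite_margin_flags_nothing(self, normal_case_artifacts):
        tables, _ = normal_case_artifacts
        t = tables["tube1"]
        sep = fit_singlet_separator(t, margin_k=1e9)
        assert (filter_doublets(t, sep) == "singlet").all()


class TestDebrisRemoval:
    def test_no_low_mode_no_debris(self):
        t = _scatter_table(np.random.default_rng(6), n=2000)
        assert (remove_debris(t) == "cell").all()

    def test_injected_debris_recovered(self, normal_case_artifacts):
        tables, truth = normal_case_artifacts
        t = tables["tube1"]
        art = truth.artifact_labels["tube1"]
        keep = art != "doublet"
        labels = remove_debris(t.subset(keep))
        is_debris = art[keep] == "debris"
        assert (labels[is_debris] == "debris").mean() >= 0.9
        assert (labels[~is_debris] == "debris").mean() <= 0.02

    def test_ssc_only_difference_is_not_debris(self):
        rng = np.random.default_rng(7)
        vals = np.zeros((3000, 4))
        fsc = rng.normal(50000, 3000, 3000)
        vals[:, 0] = fsc
        vals[:, 1] = 0.95 * fsc
        vals[:1500, 2] = rng.normal(10000, 1500, 1500)
        vals[1500:, 2] = rng.normal(60000, 5000, 1500)
        vals[:, 3] = np.arange(3000)
        assert (remove_debris(make_table(vals)) == "cell").all()


class TestRunQC:
    def test_clean_table_nearly_untouched(self, normal_case):
        tables, _ = normal_case
        retained, report = run_qc(tables["tube1"])
        assert report.warnings == []
        assert report.retained_events >= 0.985 * report.total_events

    def test_artifact_counts_conserved(self, normal_case_artifacts):
        tables, _ = normal_case_artifacts
        for tube in tables.values():
            retained, rep = run_qc(tube)
            assert (rep.unstable_events + rep.doublet_events + rep.debris_events
                    + rep.retained_events == rep.total_events)
            assert retained.n_events == rep.retained_events

    def test_artifact_fractions_recovered(self, normal_case_artifacts):
        tables, _ = normal_case_artifacts
        _, rep = run_qc(tables["tube1"])
        # 5% doublets + 8% debris injected -> ~87% retained
        assert rep.retained_events / rep.total_events == pytest.approx(0.87, abs=0.02)

    def test_unstable_windows_excluded_and_warned(self, templates):
        tables, _ = simulate_case(
            templates["normal_marrow"], n_events=6000, seed=9,
            drift=DriftSpec(start=1 / 3, end=2 / 3, magnitude_sd=10))
        _, rep = run_qc(tables["tube1"])
        assert any("instability" in w for w in rep.warnings)
        assert rep.unstable_events >= 0.9 * 2000

    def test_idempotent_on_clean_data(self, normal_case):
        tables, _ = normal_case
        retained, _ = run_qc(tables["tube1"])
        again, rep2 = run_qc(retained)
        assert (retained.n_events - again.n_events) < 0.01 * retained.n_events

    def test_doublet_labels_invariant_to_event_order(self, normal_case_artifacts):
        tables, _ = normal_case_artifacts
        t = tables["tube1"]
        rng = np.random.default_rng(11)
        perm = rng.permutation(t.n_events)
        tp = t.subset(perm)
        sep, sep_p = fit_singlet_separator(t), fit_singlet_separator(tp)
        lab, lab_p = filter_doublets(t, sep), filter_doublets(tp, sep_p)
        np.testing.assert_array_equal(lab[perm], lab_p)

    def test_report_invariant_enforced(self):
        with pytest.raises(ValueError, match="sum"):
            QCReport(total_events=10, unstable_events=1, doublet_events=1,
                     debris_events=1, retained_events=10)
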