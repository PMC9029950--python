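"""Phase-1 data validation: flow stability, doublet and debris removal.

Produces the nucleated-singlet event set that every downstream phase
operates on, plus a conservation-checked QC report.  The three filters
run in a fixed order (stability -> doublets -> debris) so each event is
attributed to exactly one removal cause.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import theilslopes
from sklearn.mixture import GaussianMixture

from .errors import ConfigurationError, InsufficientDataError
from .fcs import EventTable
from .util import MAD_TO_SD, robust_scale

__all__ = [
    "StabilityResult",
    "LinearSeparator",
    "QCReport",
    "QCConfig",
    "check_flow_stability",
    "fit_singlet_separator",
    "filter_doublets",
    "remove_debris",
    "run_qc",
]


@dataclass
class StabilityResult:
    stable: bool
    flagged_windows: list[tuple[int, int]]   # [start, end) event-index ranges in time order
    moving_average: np.ndarray               # per-window FSC-A mean

    def __post_init__(self) -> None:
        assert (len(self.flagged_windows) == 0) == self.stable


@dataclass
class LinearSeparator:
    """FSC-H = slope * FSC-A + intercept; events more than ``margin`` below
    the line are doublets (area grows with coincident cells, height does not)."""

    slope: float
    intercept: float
    margin: float

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError("singlet separator slope must be positive")
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


@dataclass
class QCReport:
    total_events: int
    unstable_events: int
    doublet_events: int
    debris_events: int
    retained_events: int
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        counts = (
            self.unstable_events,
            self.doublet_events,
            self.debris_events,
            self.retained_events,
        )
        if any(c < 0 for c in counts):
            raise ValueError("QC counts must be non-negative")
        if sum(counts) != self.total_events:
            raise ValueError("QC counts do not sum to the total event count")

    def to_dict(self) -> dict:
        return {
            "total_events": self.total_events,
            "unstable_events": self.unstable_events,
            "doublet_events": self.doublet_events,
            "debris_events": self.debris_events,
            "retained_events": self.retained_events,
            "warnings": list(self.warnings),
        }


@dataclass
class QCConfig:
    window_events: int = 1000
    deviation_k: float = 4.0
    margin_k: float = 3.0
    debris_fsc_fraction: float = 0.25
    max_debris_clusters: int = 6
    exclude_unstable: bool = True


def check_flow_stability(
    table: EventTable, window_events: int = 1000, deviation_k: float = 4.0
) -> StabilityResult:
    """Flag acquisition windows whose FSC-A moving average departs from the run.

    Events are ordered by the time channel and cut into consecutive windows
    of ``window_events``.  A window is flagged when its FSC-A mean deviates
    from the robust center of all window means (median) by more than
    ``deviation_k`` times the robust spread (1.4826 x MAD).  The robust
    center/spread keep a genuine drift interval from masking itself by
    inflating the plain SD of window means.
    """
    if window_events < 50:
        raise ConfigurationError("window_events must be at least 50")
    if deviation_k <= 0:
        raise ConfigurationError("deviation_k must be positive")
    t_idx = table.time_index()  # raises ConfigurationError if absent
    order = np.argsort(table.values[:, t_idx], kind="stable")
    fsc = table.column("FSC-A")[order]
    n = fsc.size
    n_win = max(n // window_events, 1)
    bounds = [(i * window_events, (i + 1) * window_events) for i in range(n_win)]
    bounds[-1] = (bounds[-1][0], n)  # last window absorbs the remainder
    means = np.array([fsc[a:b].mean() for a, b in bounds])
    center = np.median(means)
    spread = MAD_TO_SD * np.median(np.abs(means - center))
    dev = np.abs(means - center)
    if spread == 0.0:
        flagged = [i for i in range(n_win) if dev[i] > 0.0]
    else:
        flagged = [i for i in range(n_win) if dev[i] > deviation_k * spread]
    windows = [bounds[i] for i in flagged]
    return StabilityResult(stable=not windows, flagged_windows=windows, moving_average=means)


def fit_singlet_separator(table: EventTable, margin_k: float = 3.0) -> LinearSeparator:
    """Robust line fit of FSC-H on FSC-A over the central bulk of events.

    Theil-Sen is used so a few percent of doublets (below the line) do not
    drag the fit; the margin is margin_k x 1.4826 x MAD of the residuals.
    """
    a = table.column("FSC-A")
    h = table.column("FSC-H")
    if a.size < 100:
        raise InsufficientDataError(f"singlet fit needs >= 100 events, got {a.size}")
    lo, hi = np.percentile(a, [5, 95])
    bulk = (a >= lo) & (a <= hi)
    if bulk.sum() < 50 or np.ptp(a[bulk]) == 0:
        raise InsufficientDataError("insufficient FSC-A variance for a singlet fit")
    # Theil-Sen is O(n^2) in pairwise slopes; an evenly spaced subsample of
    # the bulk keeps it cheap without losing robustness
    bulk_idx = np.flatnonzero(bulk)
    if bulk_idx.size > 2000:
        bulk_idx = bulk_idx[np.linspace(0, bulk_idx.size - 1, 2000).astype(int)]
    slope, intercept, *_ = theilslopes(h[bulk_idx], a[bulk_idx])
    if slope <= 0:
        raise InsufficientDataError("non-positive FSC-H/FSC-A slope; not a singlet cloud")
    resid = h - (slope * a + intercept)
    scale = robust_scale(resid[bulk])
    return LinearSeparator(slope=float(slope), intercept=float(intercept),
                           margin=margin_k * scale)


def filter_doublets(table: EventTable, sep: LinearSeparator) -> np.ndarray:
    """Label every event "singlet" or "doublet" against the fitted separator.

    Doublets sit below the singlet line in FSC-H (area roughly doubles,
    height does not).  Events exactly on the boundary are singlets.
    """
    a = table.column("FSC-A")
    h = table.column("FSC-H")
    doublet = h < (sep.slope * a + sep.intercept - sep.margin)
    return np.where(doublet, "doublet", "singlet")


def remove_debris(
    table: EventTable,
    max_clusters: int = 6,
    fsc_fraction: float = 0.25,
    warnings: list[str] | None = None,
) -> np.ndarray:
    """Label events "cell" or "debris" from the (FSC-A, SSC-A) projection.

    A Gaussian mixture (components chosen by BIC) clusters the scatter
    plane; the lowest-FSC-A cluster(s) are debris when their median FSC-A
    falls below ``fsc_fraction`` of the median FSC-A of the remaining
    (nucleated) events.  If the mixture fit fails, a fixed FSC-A
    percentile threshold is used and a warning recorded.
    """
    a = table.column("FSC-A")
    s = table.column("SSC-A")
    X = np.column_stack([a, s])
    scale = np.maximum(X.std(axis=0), 1e-9)
    Xs = (X - X.mean(axis=0)) / scale
    labels = None
    try:
        best_bic, best = np.inf, None
        n_max = min(max_clusters, len(X))
        for k in range(1, n_max + 1):
            gm = GaussianMixture(n_components=k, random_state=0, n_init=1,
                                 covariance_type="full", reg_covar=1e-6)
            gm.fit(Xs)
            bic = gm.bic(Xs)
            if bic < best_bic - 1e-9:
                best_bic, best = bic, gm
        labels = best.predict(Xs)
    except Exception:
        if warnings is not None:
            warnings.append(
                "debris clustering failed to converge; fell back to a fixed "
                "FSC-A percentile threshold"
            )
        thr = np.percentile(a, 5)
        return np.where(a < fsc_fraction * np.median(a[a >= thr]), "debris", "cell")

    ks = np.unique(labels)
    med_fsc = {k: float(np.median(a[labels == k])) for k in ks}
    # iteratively peel off the lowest-FSC-A cluster while it sits far below
    # the median FSC-A of everything else
    debris_ks: set[int] = set()
    while True:
        remaining = [k for k in ks if k not in debris_ks]
        if len(remaining) <= 1:
            break
        lowest = min(remaining, key=lambda k: med_fsc[k])
        rest_mask = np.isin(labels, [k for k in remaining if k != lowest])
        if med_fsc[lowest] < fsc_fraction * np.median(a[rest_mask]):
            debris_ks.add(lowest)
        else:
            break
    debris = np.isin(labels, sorted(debris_ks))
    return np.where(debris, "debris", "cell")


def run_qc(table: EventTable, config: QCConfig | None = None) -> tuple[EventTable, QCReport]:
    """Stability -> doublet -> debris filtering with conservation accounting."""
    cfg = config or QCConfig()
    warnings: list[str] = []
    n_total = table.n_events

    stab = check_flow_stability(table, cfg.window_events, cfg.deviation_k)
    t_idx = table.time_index()
    order = np.argsort(table.values[:, t_idx], kind="stable")
    unstable_mask = np.zeros(n_total, dtype=bool)
    if not stab.stable:
        warnings.append(
            f"flow instability: {len(stab.flagged_windows)} acquisition window(s) "
            "deviate from the running FSC-A average"
        )
        if cfg.exclude_unstable:
            for a, b in stab.flagged_windows:
                unstable_mask[order[a:b]] = True
    n_unstable = int(unstable_mask.sum())
    stable_tbl = table.subset(~unstable_mask)

    sep = fit_singlet_separator(stable_tbl, cfg.margin_k)
    dlab = filter_doublets(stable_tbl, sep)
    n_doublet = int((dlab == "doublet").sum())
    if n_doublet > 0.1 * n_total:
        warnings.append(
            f"high doublet rate: {n_doublet / n_total:.1%} of events below the singlet line"
        )
    singlet_tbl = stable_tbl.subset(dlab == "singlet")

    blab = remove_debris(singlet_tbl, cfg.max_debris_clusters,
                         cfg.debris_fsc_fraction, warnings)
    n_debris = int((blab == "debris").sum())
    if n_debris > 0.2 * n_total:
        warnings.append(
            f"high debris rate: {n_debris / n_total:.1%} of events in the low-FSC-A cluster"
        )
    retained = singlet_tbl.subset(blab == "cell")

    report = QCReport(
        total_events=n_total,
        unstable_events=n_unstable,
        doublet_events=n_doublet,
        debris_events=n_debris,
        retained_events=retained.n_events,
        warnings=warnings,
    )
    return retained, report
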