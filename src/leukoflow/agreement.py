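"""Inter-rater agreement statistics for AI-vs-manual validation.

Consistency (observed agreement), unweighted and linearly weighted
Cohen's kappa on possibly non-square confusion tables (the label sets of
the two raters are unioned and zero-filled before kappa, which is how a
rater-only category such as an AI "flag for review" column is handled),
Bland-Altman limits of agreement, Pearson correlation and the paired t
test.  Two published AI-vs-manual validation tables ship as package data
and serve as worked examples throughout the docs and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionTable",
    "AgreementStats",
    "BlandAltmanResult",
    "CorrelationResult",
    "consistency",
    "cohen_kappa",
    "bland_altman",
    "pearson_r",
    "paired_t",
    "load_example_diagnosis_table",
    "load_example_antigen_tables",
]


@dataclass
class ConfusionTable:
    """Manual (rows) vs AI (columns) cross-tabulation of category calls."""

    row_labels: list[str]
    col_labels: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("counts shape does not match label lists")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(set(self.row_labels)) != len(self.row_labels) or \
                len(set(self.col_labels)) != len(self.col_labels):
            raise ValueError("labels must be unique")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_square(self) -> "ConfusionTable":
        """Embed into the square union of row and column label sets (zero-fill)."""
        labels = list(self.row_labels)
        labels += [l for l in self.col_labels if l not in labels]
        sq = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for i, rl in enumerate(self.row_labels):
            for j, cl in enumerate(self.col_labels):
                sq[labels.index(rl), labels.index(cl)] = self.counts[i, j]
        return ConfusionTable(row_labels=labels, col_labels=labels, counts=sq)

    @classmethod
    def from_pairs(cls, manual, ai) -> "ConfusionTable":
        """Cross-tabulate two equal-length rating sequences."""
        manual = list(manual)
        ai = list(ai)
        if len(manual) != len(ai):
            raise ValueError("rating sequences differ in length")
        rows = sorted(set(manual))
        cols = sorted(set(ai))
        counts = np.zeros((len(rows), len(cols)), dtype=np.int64)
        for m, a in zip(manual, ai):
            counts[rows.index(m), cols.index(a)] += 1
        return cls(row_labels=rows, col_labels=cols, counts=counts)

    def to_pairs(self) -> tuple[list[str], list[str]]:
        """Expand back to per-case (manual, ai) rating pairs."""
        manual, ai = [], []
        for i, rl in enumerate(self.row_labels):
            for j, cl in enumerate(self.col_labels):
                manual += [rl] * int(self.counts[i, j])
                ai += [cl] * int(self.counts[i, j])
        return manual, ai

    @classmethod
    def from_csv(cls, path) -> "ConfusionTable":
        df = pd.read_csv(path, index_col=0)
        return cls(row_labels=[str(x) for x in df.index],
                   col_labels=[str(x) for x in df.columns],
                   counts=df.to_numpy())

    def to_csv(self, path) -> None:
        pd.DataFrame(self.counts, index=self.row_labels,
                     columns=self.col_labels).to_csv(path)


@dataclass
class AgreementStats:
    total_consistency: float
    per_row_consistency: dict[str, float]
    kappa: float | None = None


@dataclass
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float


@dataclass
class CorrelationResult:
    r: float
    p_value: float


def consistency(table: ConfusionTable) -> AgreementStats:
    """Observed agreement: diagonal mass over n, total and per manual category."""
    if table.n == 0:
        raise ValueError("empty confusion table")
    sq = table.to_square()
    diag = float(np.trace(sq.counts))
    per_row: dict[str, float] = {}
    for i, rl in enumerate(table.row_labels):
        row_total = int(table.counts[i].sum())
        if row_total == 0:
            continue
        j = sq.row_labels.index(rl)
        per_row[rl] = float(sq.counts[j, j]) / row_total
    return AgreementStats(total_consistency=diag / table.n, per_row_consistency=per_row)


def cohen_kappa(table: ConfusionTable, weighted: bool = False) -> float:
    """Chance-corrected agreement kappa = (po - pe) / (1 - pe).

    The table is first embedded into the square union of the two raters'
    label sets; unweighted by default, with linear weights behind a flag.
    """
    sq = table.to_square()
    M = sq.counts.astype(float)
    n = M.sum()
    if n == 0:
        raise ValueError("empty confusion table")
    p = M / n
    r = p.sum(axis=1)
    c = p.sum(axis=0)
    if weighted:
        k = len(sq.row_labels)
        idx = np.arange(k)
        w = np.abs(idx[:, None] - idx[None, :]) / max(k - 1, 1)
        po = float((w * p).sum())
        pe = float((w * np.outer(r, c)).sum())
        if pe == 0:
            raise ValueError("kappa undefined: all expected mass on the diagonal")
        return 1.0 - po / pe
    po = float(np.trace(p))
    pe = float(r @ c)
    if pe == 1.0:
        raise ValueError("kappa undefined: all mass concentrated in one cell pair")
    return (po - pe) / (1.0 - pe)


def bland_altman(pairs) -> BlandAltmanResult:
    """Limits of agreement of paired (ai, manual) measurements: bias +/- 1.96 SD.

    SD uses the n-1 (sample) denominator.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 (ai, manual) pairs")
    d = arr[:, 0] - arr[:, 1]
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd, loa_high=bias + 1.96 * sd)


def pearson_r(pairs) -> CorrelationResult:
    """Product-moment correlation of paired measurements with two-tailed p."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 pairs")
    x, y = arr[:, 0], arr[:, 1]
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return CorrelationResult(r=float(res.statistic), p_value=float(res.pvalue))


def paired_t(pairs) -> tuple[float, float]:
    """Paired t test on the differences; returns (t, two-tailed p)."""
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 2:
        raise ValueError("need at least 2 pairs")
    d = arr[:, 0] - arr[:, 1]
    if np.allclose(d.std(ddof=1), 0) and not np.allclose(d.mean(), 0):
        raise ValueError("zero-variance nonzero differences: t undefined")
    res = stats.ttest_rel(arr[:, 0], arr[:, 1])
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Bundled worked-example data (published AI-vs-manual validation tables)
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("leukoflow").joinpath("data", name)


def load_example_diagnosis_table() -> ConfusionTable:
    """294-case diagnostic cross-tabulation (manual rows, AI columns).

    The AI has an extra "Abnormal" (flag-for-review) column with no manual
    counterpart, making the table non-square.
    """
    with resources.as_file(_data_path("diagnosis_confusion.csv")) as p:
        return ConfusionTable.from_csv(p)


def load_example_antigen_tables() -> dict[str, ConfusionTable]:
    """Per-antigen 3x3 (Pos/Partial/Neg) phenotype tables over 200 leukemia cases.

    Returns marker -> ConfusionTable, 25 antigens; pooling all counts gives
    the overall phenotype-agreement table.
    """
    with resources.as_file(_data_path("antigen_confusion.csv")) as p:
        df = pd.read_csv(p)
    levels = ["Pos", "Partial", "Neg"]
    out: dict[str, ConfusionTable] = {}
    for _, row in df.iterrows():
        counts = np.array([
            [row["pos_pos"], row["pos_partial"], row["pos_neg"]],
            [row["partial_pos"], row["partial_partial"], row["partial_neg"]],
            [row["neg_pos"], row["neg_partial"], row["neg_neg"]],
        ])
        out[str(row["marker"])] = ConfusionTable(
            row_labels=levels, col_labels=levels, counts=counts)
    return out
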