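"""Small numerical helpers used across modules."""

from __future__ import annotations

import numpy as np

# Consistency constant: 1.4826 * MAD estimates the SD of a normal sample.
MAD_TO_SD = 1.4826


def robust_scale(x: np.ndarray) -> float:
    """MAD-based robust SD estimate of a 1-D sample."""
    x = np.asarray(x, dtype=float)
    med = np.median(x)
    return MAD_TO_SD * float(np.median(np.abs(x - med)))


def robust_zscore(x: np.ndarray, ref: np.ndarray | None = None) -> np.ndarray:
    """Center by median and scale by MAD of ``ref`` (default: x itself).

    Falls back to the plain SD when the MAD is zero, and to a unit scale
    when the sample is constant.
    """
    x = np.asarray(x, dtype=float)
    ref = x if ref is None else np.asarray(ref, dtype=float)
    med = np.median(ref)
    scale = robust_scale(ref)
    if scale == 0.0:
        scale = float(np.std(ref))
    if scale == 0.0:
        scale = 1.0
    return (x - med) / scale
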