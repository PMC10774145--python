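"""dF/F extraction from raw and neuropil fluorescence traces.

The pipeline mirrors standard two-photon practice: subtract a scaled
neuropil trace (F = F_cell - c * F_neuropil), estimate a slowly drifting
baseline F0 as a moving average of the rolling 10th percentile over a
1,000-frame (~3 min) window, and normalize, dF/F = (F - F0) / F0.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.ndimage import uniform_filter1d


class DffResult(NamedTuple):
    dff: np.ndarray       # same shape as the input traces
    f0: np.ndarray        # baseline estimate
    valid: np.ndarray     # per-cell flag; False where F0 <= 0 somewhere


def rolling_percentile(
    trace: np.ndarray,
    window: int,
    percentile: float,
    stride: int = 1,
) -> np.ndarray:
    """Centered rolling percentile of a 1-D or (cells, frames) trace.

    With ``stride > 1`` the percentile is evaluated exactly at anchor frames
    every ``stride`` frames and linearly interpolated in between; baseline
    drift is slow compared to any practical stride, and the strided estimate
    makes thousand-cell recordings tractable.
    """
    x = np.atleast_2d(np.asarray(trace, dtype=float))
    n = x.shape[1]
    half = window // 2
    anchors = np.arange(0, n, max(stride, 1))
    if anchors[-1] != n - 1:
        anchors = np.append(anchors, n - 1)
    vals = np.empty((x.shape[0], anchors.size))
    for k, a in enumerate(anchors):
        lo, hi = max(0, a - half), min(n, a + half + 1)
        vals[:, k] = np.percentile(x[:, lo:hi], percentile, axis=1)
    frames = np.arange(n)
    out = np.empty_like(x)
    for i in range(x.shape[0]):
        out[i] = np.interp(frames, anchors, vals[i])
    return out.reshape(np.asarray(trace).shape)


def dff(
    f_cell: np.ndarray,
    f_neuropil: np.ndarray,
    c: float = 0.7,
    window: int = 1000,
    percentile: float = 10.0,
    stride: int = 50,
    presmooth: int = 30,
) -> DffResult:
    """Neuropil-subtracted, baseline-normalized fluorescence.

    Parameters
    ----------
    f_cell, f_neuropil
        Traces of equal shape, 1-D ``(frames,)`` or 2-D ``(cells, frames)``.
    c
        Neuropil subtraction coefficient in [0, 1].
    window
        Frames in the rolling-percentile window (default 1,000).
    stride
        Anchor spacing for the strided percentile; ``1`` computes the exact
        rolling percentile at every frame.
    presmooth
        Frames of rolling-mean low-pass applied before the percentile is
        taken (``1`` disables it).  A low percentile of a noisy trace sits
        well below the true baseline (the 10th percentile of pure noise is
        -1.28 sigma), which would inflate every dF/F amplitude; the
        baseline drift being slow, low-passing first removes most of that
        bias without tracking the transients.

    Cells whose baseline estimate touches zero or goes negative are flagged
    invalid rather than silently clipped; their dF/F is NaN.
    """
    f_cell = np.asarray(f_cell, dtype=float)
    f_neuropil = np.asarray(f_neuropil, dtype=float)
    if f_cell.shape != f_neuropil.shape:
        raise ValueError("cell and neuropil traces must have equal shape")
    if not 0.0 <= c <= 1.0:
        raise ValueError("neuropil coefficient must lie in [0, 1]")
    squeeze = f_cell.ndim == 1
    f = np.atleast_2d(f_cell - c * f_neuropil)
    smooth = (
        uniform_filter1d(f, size=min(presmooth, f.shape[1]), axis=1, mode="nearest")
        if presmooth > 1
        else f
    )
    p = rolling_percentile(smooth, window, percentile, stride=stride)
    f0 = uniform_filter1d(p, size=min(window, f.shape[1]), axis=1, mode="nearest")
    valid = (f0 > 0).all(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (f - f0) / f0
    out[~valid] = np.nan
    if squeeze:
        return DffResult(out[0], f0[0], valid)
    return DffResult(out, f0, valid)
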