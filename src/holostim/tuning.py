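"""Orientation tuning metrics from drifting-grating responses.

Gratings drift in eight directions of motion; orientation tuning is obtained
by averaging responses to opposite directions, giving four orientations
(0, 45, 90, 135 degrees).  The orientation selectivity index is
OSI = (PO - OO) / (PO + OO), where PO is the peak response of the folded
curve and OO the response at the orthogonal orientation.
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy import stats

from holostim.fields import fold_orientation


class TuningResult(NamedTuple):
    tuning_curve: np.ndarray  # mean response per direction (length n_directions)
    folded_curve: np.ndarray  # mean response per orientation (length n_dir // 2)
    po: float                 # preferred orientation, degrees
    oo: float                 # orthogonal orientation, degrees
    osi: float
    p_visual: float


def fold_directions(direction_curve: np.ndarray) -> np.ndarray:
    """Average responses to opposite drift directions into orientations."""
    c = np.asarray(direction_curve, dtype=float)
    if c.shape[-1] % 2:
        raise ValueError("need an even number of directions to fold")
    half = c.shape[-1] // 2
    return 0.5 * (c[..., :half] + c[..., half:])


def osi_from_folded(folded: np.ndarray) -> tuple[float, float, float]:
    """(osi, po_deg, oo_deg) from a folded orientation curve.

    Responses are rectified at zero before the index is formed so that
    OSI stays within [0, 1] even for negative dF/F responses; a flat or
    all-zero curve maps to OSI 0.
    """
    folded = np.asarray(folded, dtype=float)
    n = folded.shape[-1]
    step = 180.0 / n
    k = int(np.argmax(folded))
    po = k * step
    k_orth = (k + n // 2) % n
    oo = k_orth * step
    r = np.maximum(folded, 0.0)
    denom = r[k] + r[k_orth]
    osi = 0.0 if denom == 0 else float((r[k] - r[k_orth]) / denom)
    return osi, float(po), float(oo)


def tuning_and_osi(
    responses: np.ndarray,
    blank: np.ndarray | None = None,
) -> TuningResult:
    """Tuning curve, preferred orientation and OSI from per-trial responses.

    Parameters
    ----------
    responses
        Array of shape ``(n_trials, n_directions)`` of per-trial responses,
        one column per drift direction (equally spaced over 360 degrees).
    blank
        Optional per-trial responses to the gray-screen condition, included
        in the visual-responsiveness test.

    The visual-responsiveness p-value is a one-way ANOVA across the direction
    conditions (plus blank when given).
    """
    responses = np.asarray(responses, dtype=float)
    if responses.ndim != 2 or responses.shape[0] < 2:
        raise ValueError("need >= 2 trials per direction, shaped (trials, directions)")
    curve = responses.mean(axis=0)
    folded = fold_directions(curve)
    osi, po, oo = osi_from_folded(folded)
    groups = [responses[:, j] for j in range(responses.shape[1])]
    if blank is not None and len(blank):
        groups.append(np.asarray(blank, dtype=float))
    p_visual = float(stats.f_oneway(*groups).pvalue)
    return TuningResult(curve, folded, po, oo, osi, p_visual)


def relative_tuning_split(
    cell_po,
    ensemble_po: float,
    cell_osi=None,
    osi_threshold: float = 0.25,
    visually_responsive=None,
):
    """Label cells by orientation offset to the stimulated ensemble.

    Offsets are folded into [0, 90] and snapped to the nearest of
    {0 (iso), 45, 90 (ortho)}.  Cells failing the tuned-cell filter
    (OSI > threshold and, if provided, visual responsiveness) are labeled
    ``'untuned'`` and reported separately rather than forced into a bin.
    """
    delta = fold_orientation(np.asarray(cell_po, dtype=float) - ensemble_po)
    labels = np.select([delta < 22.5, delta < 67.5], [0, 45], default=90).astype(object)
    if cell_osi is not None:
        untuned = np.asarray(cell_osi, dtype=float) <= osi_threshold
        if visually_responsive is not None:
            untuned |= ~np.asarray(visually_responsive, dtype=bool)
        labels[untuned] = "untuned"
    return labels
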