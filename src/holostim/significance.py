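"""Per-cell modulation significance with bootstrap CIs and FDR control.

A nontargeted cell is called activated (suppressed) by an ensemble when the
99% bootstrap confidence interval of its mean trial response excludes zero
and the call survives false-discovery-rate control at 1% across cells
(Benjamini-Hochberg on the bootstrap sign-crossing p-values).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from statsmodels.stats.multitest import multipletests


class SignificanceResult(NamedTuple):
    label: np.ndarray        # 'activated' | 'suppressed' | 'neither' per cell
    ci_low: np.ndarray
    ci_high: np.ndarray
    p_value: np.ndarray
    insufficient: np.ndarray  # True where too few trials to test


def modulation_significance(
    responses: list[np.ndarray] | np.ndarray,
    ci_level: float = 0.99,
    fdr_q: float = 0.01,
    n_bootstrap: int = 2000,
    min_trials: int = 10,
    seed: int = 0,
) -> SignificanceResult:
    """Classify each cell's ensemble response as activated/suppressed/neither.

    Parameters
    ----------
    responses
        Per-cell arrays of per-trial responses (a ragged list, or a 2-D
        array ``(cells, trials)``).
    ci_level, fdr_q
        Percentile-CI coverage (default 99%) and BH false-discovery rate
        (default 1%).
    min_trials
        Cells with fewer trials are labeled 'neither' and flagged
        insufficient rather than tested.

    The bootstrap resamples trials with replacement (seeded); the p-value is
    the two-sided sign-crossing fraction with the +1 small-sample correction.
    """
    if isinstance(responses, np.ndarray) and responses.ndim == 2:
        responses = list(responses)
    n_cells = len(responses)
    rng = np.random.default_rng(seed)
    alpha = 1.0 - ci_level
    ci_low = np.full(n_cells, np.nan)
    ci_high = np.full(n_cells, np.nan)
    pval = np.full(n_cells, 1.0)
    insufficient = np.zeros(n_cells, dtype=bool)
    means = np.zeros(n_cells)

    for i, r in enumerate(responses):
        r = np.asarray(r, dtype=float)
        r = r[np.isfinite(r)]
        if r.size < min_trials:
            insufficient[i] = True
            continue
        means[i] = r.mean()
        idx = rng.integers(0, r.size, size=(n_bootstrap, r.size))
        boot = r[idx].mean(axis=1)
        ci_low[i] = np.percentile(boot, 100 * alpha / 2)
        ci_high[i] = np.percentile(boot, 100 * (1 - alpha / 2))
        n_le = np.count_nonzero(boot <= 0)
        n_ge = np.count_nonzero(boot >= 0)
        pval[i] = min(1.0, 2.0 * (min(n_le, n_ge) + 1) / (n_bootstrap + 1))

    label = np.full(n_cells, "neither", dtype=object)
    testable = ~insufficient
    if testable.any():
        reject = np.zeros(n_cells, dtype=bool)
        reject[testable] = multipletests(
            pval[testable], alpha=fdr_q, method="fdr_bh"
        )[0]
        excludes = (ci_low > 0) | (ci_high < 0)
        sig = reject & excludes & testable
        label[sig & (means > 0)] = "activated"
        label[sig & (means < 0)] = "suppressed"
    return SignificanceResult(label, ci_low, ci_high, pval, insufficient)
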