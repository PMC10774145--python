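"""Sum-of-two-Gaussians (center-surround) fits of the spatial response.

The distance-resolved response of nontargeted cells is summarized by

    f(d) = A1 exp(-(d / sigma1)^2) + A2 exp(-(d / sigma2)^2),

typically with a narrow positive center (A1 > 0) and a broad negative
surround (A2 < 0).  The derived quantities are the zero crossing -- the
distance where activation gives way to suppression -- and the ratio of
maximum activation to maximum suppression.  Note the fit convention has no
factor 1/2 in the exponent, unlike the model's wiring kernels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit


@dataclass
class DoGFit:
    a1: float
    sigma1: float
    a2: float
    sigma2: float
    zero_crossing: float | None = None
    act_supp_ratio: float | None = None

    def __call__(self, d):
        d = np.asarray(d, dtype=float)
        return self.a1 * np.exp(-((d / self.sigma1) ** 2)) + self.a2 * np.exp(
            -((d / self.sigma2) ** 2)
        )


@dataclass
class RegimeBox:
    """Rectangle of (zero crossing, activation/suppression ratio) values."""

    crossing_min: float
    crossing_max: float
    ratio_min: float
    ratio_max: float

    def __post_init__(self) -> None:
        if self.crossing_min > self.crossing_max or self.ratio_min > self.ratio_max:
            raise ValueError("regime box bounds are not ordered")

    def contains(self, crossing: float | None, ratio: float | None) -> bool:
        if crossing is None or ratio is None or not np.isfinite(ratio):
            return False
        return (
            self.crossing_min <= crossing <= self.crossing_max
            and self.ratio_min <= ratio <= self.ratio_max
        )


def _model(d, a1, s1, a2, s2):
    return a1 * np.exp(-((d / s1) ** 2)) + a2 * np.exp(-((d / s2) ** 2))


class FitError(RuntimeError):
    pass


def fit_dog(
    distances,
    responses=None,
    fix_a2_zero: bool = False,
    max_sigma: float | None = None,
) -> DoGFit:
    """Least-squares center-surround fit of (distance, response) data.

    Accepts either a :class:`holostim.spatial.DistanceCurve` (binned means
    are fitted at the bin centers) or raw distance/response arrays.  The fit
    is multi-started over a grid of initial length scales to avoid local
    minima; sign conventions are free (the data decide center vs surround).
    """
    if responses is None:  # DistanceCurve input
        curve = distances
        ok = np.isfinite(curve.mean)
        d = curve.bin_centers[ok]
        y = curve.mean[ok]
    else:
        d = np.asarray(distances, dtype=float)
        y = np.asarray(responses, dtype=float)
        ok = np.isfinite(d) & np.isfinite(y)
        d, y = d[ok], y[ok]
    if d.size < (3 if fix_a2_zero else 6):
        raise FitError("too few points for a stable center-surround fit")
    if max_sigma is None:
        max_sigma = 10 * max(d.max(), 1.0)
    amp = max(np.abs(y).max(), 1e-12)

    best = None
    best_cost = np.inf
    s1_grid = (10.0, 25.0, 50.0)
    s2_grid = (80.0, 150.0, 300.0)
    for s1 in s1_grid:
        for s2 in s2_grid:
            try:
                if fix_a2_zero:
                    popt, _ = curve_fit(
                        lambda dd, a1, ss1: _model(dd, a1, ss1, 0.0, 1.0),
                        d,
                        y,
                        p0=[y[np.argmin(d)], s1],
                        bounds=([-10 * amp, 1e-3], [10 * amp, max_sigma]),
                        maxfev=20000,
                    )
                    params = (popt[0], popt[1], 0.0, max_sigma)
                else:
                    popt, _ = curve_fit(
                        _model,
                        d,
                        y,
                        p0=[max(y.max(), amp * 0.1), s1, min(y.min(), 0.0), s2],
                        bounds=(
                            [-10 * amp, 1e-3, -10 * amp, 1e-3],
                            [10 * amp, max_sigma, 10 * amp, max_sigma],
                        ),
                        maxfev=20000,
                    )
                    params = tuple(popt)
            except RuntimeError:
                continue
            resid = y - _model(d, *params)
            cost = float((resid**2).sum())
            if cost < best_cost:
                best_cost, best = cost, params
    if best is None:
        raise FitError(
            f"center-surround fit failed to converge from {len(s1_grid) * len(s2_grid)}"
            " starting points"
        )
    a1, s1, a2, s2 = best
    # order components so sigma1 <= sigma2 (narrow center first)
    if s1 > s2:
        a1, s1, a2, s2 = a2, s2, a1, s1
    fit = DoGFit(a1, s1, a2, s2)
    fit.zero_crossing, fit.act_supp_ratio = dog_summary(fit)
    return fit


def dog_summary(fit: DoGFit, d_max: float = 1000.0) -> tuple[float | None, float]:
    """(zero crossing, max activation / |max suppression|) of a fitted curve.

    With a positive narrow center and negative broad surround the crossing
    has the closed form d* = sqrt(ln(A1/|A2|) / (1/sigma1^2 - 1/sigma2^2)).
    When the components do not change sign there is no crossing (None); the
    ratio is infinite when the curve never goes negative.
    """
    crossing = None
    if fit.a1 * fit.a2 < 0 and fit.sigma1 != fit.sigma2:
        num = np.log(abs(fit.a1) / abs(fit.a2))
        den = 1.0 / fit.sigma1**2 - 1.0 / fit.sigma2**2
        if num / den > 0:
            crossing = float(np.sqrt(num / den))
            if fit(0.0) < 0:  # center negative: crossing is suppression->activation
                crossing = float(crossing)
    d = np.linspace(0.0, d_max, 4001)
    vals = fit(d)
    peak = float(vals.max())
    trough = float(vals.min())
    ratio = np.inf if trough >= 0 else peak / abs(trough)
    return crossing, ratio


def zero_crossing_brentq(fit: DoGFit, lo: float = 1e-6, hi: float = 1000.0):
    """Numeric root of f(d) = 0, used as an independent check of the closed form."""
    d = np.linspace(lo, hi, 20001)
    vals = fit(d)
    sign_change = np.where(np.sign(vals[:-1]) != np.sign(vals[1:]))[0]
    if not len(sign_change):
        return None
    i = sign_change[0]
    return float(brentq(fit, d[i], d[i + 1], xtol=1e-12))


def data_regime_box(
    distances,
    responses,
    bin_widths=tuple(range(5, 21)),
    max_distance: float | None = None,
) -> RegimeBox:
    """Smallest rectangle of (crossing, ratio) over a range of bin widths.

    For each bin width the raw (distance, response) pairs are binned, fitted
    and summarized; the box spans the min/max of the per-width crossings and
    ratios.  Widths whose fit fails (or yields no crossing) are skipped with
    a warning rather than aborting the box.
    """
    import warnings

    from holostim.spatial import distance_response_curve
    import pandas as pd

    pairs = pd.DataFrame({"min_dist": distances, "response": responses})
    crossings, ratios = [], []
    for w in bin_widths:
        try:
            curve = distance_response_curve(pairs, bin_width=float(w), max_distance=max_distance)
            fit = fit_dog(curve)
            crossing, ratio = dog_summary(fit)
        except FitError:
            warnings.warn(f"center-surround fit failed at bin width {w} um; skipped")
            continue
        if crossing is None or not np.isfinite(ratio):
            warnings.warn(f"no zero crossing at bin width {w} um; skipped")
            continue
        crossings.append(crossing)
        ratios.append(ratio)
    if not crossings:
        raise FitError("no bin width produced a valid crossing/ratio pair")
    return RegimeBox(min(crossings), max(crossings), min(ratios), max(ratios))
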