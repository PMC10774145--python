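"""Physiological point-spread function (PPSF) fits.

The PPSF quantifies how the photostimulation response falls off as the
hologram is digitally offset from the target, radially and axially.  The
response-versus-offset samples are fitted with a Gaussian aligned to its
peak; resolution is reported as the full width at half maximum
FWHM = 2 sqrt(2 ln 2) sigma (and HWHM = FWHM / 2).
"""

from __future__ import annotations

from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PpsfFit(NamedTuple):
    sigma: float
    fwhm: float
    hwhm: float
    center: float
    amplitude: float
    baseline: float


def _gauss(x, amp, mu, sigma, base):
    return base + amp * np.exp(-((x - mu) ** 2) / (2 * sigma**2))


def ppsf_fit(offsets, responses) -> PpsfFit:
    """Fit one axis of the PPSF with a peak-aligned Gaussian.

    ``offsets`` are hologram displacements (um) spanning the peak;
    ``responses`` the evoked fluorescence at each offset.  Raises if the
    fit cannot converge.
    """
    x = np.asarray(offsets, dtype=float)
    y = np.asarray(responses, dtype=float)
    if x.size < 4:
        raise ValueError("need at least four offsets to fit the PPSF")
    amp0 = y.max() - y.min()
    mu0 = float(x[np.argmax(y)])
    sigma0 = max((x.max() - x.min()) / 4.0, 1e-3)
    try:
        popt, _ = curve_fit(
            _gauss,
            x,
            y,
            p0=[amp0, mu0, sigma0, y.min()],
            bounds=([0, x.min() - 50, 1e-3, -np.inf], [np.inf, x.max() + 50, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as err:
        raise RuntimeError(f"PPSF Gaussian fit did not converge: {err}") from err
    amp, mu, sigma, base = popt
    fwhm = FWHM_PER_SIGMA * sigma
    return PpsfFit(float(sigma), float(fwhm), float(fwhm / 2), float(mu), float(amp), float(base))
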