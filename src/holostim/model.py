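"""Linearized neural-field model with joint space- and feature-dependent wiring.

The model describes perturbations of excitatory (E) and inhibitory (I) rate
fields on a periodic square domain, linearized around the uniform
steady state reached while the animal views a gray screen.  Connectivity is
separable into a spatial profile ``g(r)`` (a broad plus an optional narrow
Gaussian) and an orientation profile ``h(dtheta)`` (baseline plus
like-to-like peak).  Photostimulation enters as point masses of added rate at
the targeted locations, and the steady-state response is solved exactly in
Fourier space or approximated by the synaptic pathway expansion

    dr_e ~ (W_ee + W_ee * W_ee) * r_stim + W_ei * W_ie * r_stim,

i.e. a monosynaptic and a disynaptic excitatory term plus the disynaptic
E->I->E inhibitory pathway (asterisks denote spatial convolution).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from holostim.config import FeatureKernelParams, ModelConfig, ParameterError
from holostim.fields import (
    FieldState,
    fold_orientation,
    periodic_distance_grid,
)


class StabilityError(RuntimeError):
    """Exact inversion requested but some Fourier mode has spectral radius >= 1."""


def spatial_kernel(r, sigma_broad: float, sigma_narrow: float, kappa: float):
    """Two-scale spatial wiring density (per um^2) at distance ``r``.

    A mixture of a broad and a narrow 2-D Gaussian, each normalized to unit
    mass over the plane:

        g(r) = (1-kappa)/(2 pi sb^2) exp(-r^2/(2 sb^2))
             +     kappa/(2 pi sn^2) exp(-r^2/(2 sn^2))
    """
    if sigma_broad <= 0 or sigma_narrow <= 0:
        raise ParameterError("spatial kernel sigmas must be > 0")
    if not 0.0 <= kappa <= 1.0:
        raise ParameterError("kappa must lie in [0, 1]")
    r = np.asarray(r, dtype=float)
    broad = (1.0 - kappa) / (2 * np.pi * sigma_broad**2) * np.exp(
        -(r**2) / (2 * sigma_broad**2)
    )
    narrow = kappa / (2 * np.pi * sigma_narrow**2) * np.exp(
        -(r**2) / (2 * sigma_narrow**2)
    )
    return broad + narrow


def feature_kernel(delta_theta, params: FeatureKernelParams):
    """Orientation wiring weight h(dtheta) = r0 + rp exp(-dtheta^2/(2 sigma^2)).

    ``delta_theta`` must already be folded into [0, 90] degrees; the caller is
    responsible for the folding (see :func:`holostim.fields.fold_orientation`).
    """
    d = np.asarray(delta_theta, dtype=float)
    if np.any(d < 0) or np.any(d > 90):
        raise ValueError("delta_theta must lie in [0, 90] degrees; fold it first")
    return params.r0 + params.rp * np.exp(-(d**2) / (2 * params.sigma_theta**2))


@dataclass
class Connectivity:
    """Discretized translation-invariant operators W_ee, W_ei, W_ie.

    Each kernel is an ``(n, n, n_orientations)`` array indexed by spatial and
    orientation displacement (wraparound convention: index 0 is zero
    displacement).  Kernels are normalized so that the discrete sum over
    space (weighted by cell area) and orientation equals the signed effective
    weight ``w``; W_ei carries the negative sign of inhibition.
    """

    config: ModelConfig
    kernels: Mapping[str, np.ndarray]

    def __post_init__(self) -> None:
        self._ffts: dict[str, np.ndarray] = {}

    def fft(self, name: str) -> np.ndarray:
        """Fourier transform of a kernel including the convolution area factor."""
        if name not in self._ffts:
            self._ffts[name] = (
                np.fft.fftn(self.kernels[name]) * self.config.grid_spacing**2
            )
        return self._ffts[name]

    def weight(self, name: str) -> float:
        return float(self.kernels[name].sum() * self.config.grid_spacing**2)


def _lattice_delta_theta(config: ModelConfig) -> np.ndarray:
    step = 180.0 / config.n_orientations
    return fold_orientation(np.arange(config.n_orientations) * step)


def _make_kernel(
    config: ModelConfig,
    w: float,
    sigma_broad: float,
    sigma_narrow: float,
    kappa: float,
    feature: FeatureKernelParams,
) -> np.ndarray:
    r = periodic_distance_grid(config)
    g = spatial_kernel(r, sigma_broad, sigma_narrow, kappa)
    h = feature_kernel(_lattice_delta_theta(config), feature)
    kern = g[:, :, None] * h[None, None, :]
    total = kern.sum() * config.grid_spacing**2
    return w * kern / total


def build_connectivity(config: ModelConfig) -> Connectivity:
    """Build the three operators entering the E-cell response.

    Spatial profiles are attached to the presynaptic population: projections
    out of E cells (W_ee, W_ie) use the excitatory broad/narrow mixture,
    projections out of I cells (W_ei) use the inhibitory profile.  The
    inhibitory pathway weight w_eie = w_ei * w_ie only enters the E response
    through its product, so it is carried entirely by W_ei (negative) while
    W_ie has unit gain.
    """
    kernels = {
        "ee": _make_kernel(
            config,
            config.w_ee,
            config.sigma_e_broad,
            config.sigma_e_narrow,
            config.kappa_e,
            config.feature_ee,
        ),
        "ei": _make_kernel(
            config,
            -config.w_eie,
            config.sigma_i_broad,
            config.sigma_i_narrow,
            config.kappa_i,
            config.feature_ei,
        ),
        "ie": _make_kernel(
            config,
            1.0,
            config.sigma_e_broad,
            config.sigma_e_narrow,
            config.kappa_e,
            config.feature_ie,
        ),
    }
    return Connectivity(config=config, kernels=kernels)


def stim_field(targets, config: ModelConfig) -> FieldState:
    """Photostimulation input: point masses of ``stim_amplitude`` added rate.

    ``targets`` is an iterable of ``(x_um, y_um, theta_deg)``.  Each target's
    mass lands on the nearest grid node and nearest orientation level
    (density ``amplitude / cell_area`` so that the integrated mass per target
    equals the amplitude); coincident targets accumulate.
    """
    field = FieldState.zeros(config)
    n = config.n_grid
    levels = config.orientation_levels
    step = 180.0 / config.n_orientations
    for x, y, theta in targets:
        if not (0 <= x <= config.domain_size and 0 <= y <= config.domain_size):
            raise ValueError(f"target ({x}, {y}) outside the model domain")
        i = int(round(x / config.grid_spacing)) % n
        j = int(round(y / config.grid_spacing)) % n
        k = int(round((theta % 180.0) / step)) % len(levels)
        field.values[i, j, k] += config.stim_amplitude / field.cell_area
    return field


def _mode_blocks(conn: Connectivity):
    return conn.fft("ee"), conn.fft("ei"), conn.fft("ie")


def spectral_radius(conn: Connectivity) -> tuple[float, tuple[int, ...]]:
    """Largest per-Fourier-mode modulus among eigenvalues of the 2x2 blocks.

    With W_ii = 0 the block is [[W_ee, W_ei], [W_ie, 0]] and the eigenvalues
    are (a +- sqrt(a^2 + 4 b c)) / 2 for a = W_ee, b c = W_ei W_ie.
    """
    a, b, c = _mode_blocks(conn)
    disc = np.sqrt((a**2 + 4 * b * c).astype(complex))
    lam = np.maximum(np.abs((a + disc) / 2), np.abs((a - disc) / 2))
    idx = np.unravel_index(int(np.argmax(lam)), lam.shape)
    return float(lam[idx]), idx


def solve_linear_response(
    conn: Connectivity, r_stim: FieldState, config: ModelConfig | None = None
) -> FieldState:
    """Steady-state E-rate perturbation for a given stimulation field.

    In ``exact`` mode the response is solved per Fourier mode from the 2x2
    population block, dr_e = (a + b c) s / ((1 - a) - b c); in ``expansion``
    mode the second-order pathway expansion is used.  The solution is linear
    in ``r_stim`` in both modes.
    """
    config = config or conn.config
    a, b, c = _mode_blocks(conn)
    s = np.fft.fftn(r_stim.values)
    if config.expansion_order == "exact":
        rho, mode = spectral_radius(conn)
        if rho >= 1.0:
            raise StabilityError(
                f"spectral radius {rho:.3f} >= 1 at Fourier mode {mode}; "
                "the linear inversion is invalid for these weights"
            )
        num = (a + b * c) * s
        den = (1.0 - a) - b * c
        out = np.fft.ifftn(num / den)
    else:
        out = np.fft.ifftn((a + a * a + b * c) * s)
    return r_stim.copy_with(np.real(out))


@dataclass
class PathwayResponse:
    """Second-order decomposition of the E response into synaptic pathways."""

    mono_ee: FieldState
    di_eee: FieldState
    di_eie: FieldState
    total: FieldState


def decompose_pathways(
    conn: Connectivity, r_stim: FieldState, config: ModelConfig | None = None
) -> PathwayResponse:
    """Split the expansion-mode response into its three synaptic pathways.

    ``mono_ee`` is the direct E->E term, ``di_eee`` the disynaptic E->E->E
    term, ``di_eie`` the (negative) disynaptic E->I->E term; their sum is the
    expansion-mode response.
    """
    a, b, c = _mode_blocks(conn)
    s = np.fft.fftn(r_stim.values)
    mono = r_stim.copy_with(np.real(np.fft.ifftn(a * s)))
    di_e = r_stim.copy_with(np.real(np.fft.ifftn(a * a * s)))
    di_i = r_stim.copy_with(np.real(np.fft.ifftn(b * c * s)))
    total = r_stim.copy_with(mono.values + di_e.values + di_i.values)
    return PathwayResponse(mono_ee=mono, di_eee=di_e, di_eie=di_i, total=total)


def _snap_theta_index(theta, config: ModelConfig) -> np.ndarray:
    step = 180.0 / config.n_orientations
    return (np.round((np.asarray(theta, dtype=float) % 180.0) / step).astype(int)
            % config.n_orientations)


def embed_coordinates(xy: np.ndarray, fov_size: float, config: ModelConfig) -> np.ndarray:
    """Center an FOV's (x, y) coordinates inside the (larger) model domain."""
    xy = np.asarray(xy, dtype=float)
    offset = (config.domain_size - fov_size) / 2.0
    out = xy + offset
    if np.any(out < 0) or np.any(out > config.domain_size):
        raise ValueError("cell coordinates fall outside the model domain after embedding")
    return out


def predict_cell_responses(
    population: pd.DataFrame,
    ensemble,
    config: ModelConfig,
    fov_size: float | None = None,
) -> np.ndarray:
    """Model-predicted rate change at each recorded cell.

    ``population`` needs columns ``x``, ``y`` and ``po`` (preferred
    orientation, degrees); planes are collapsed because the model is 2-D.
    ``ensemble`` is anything with ``target_xyz`` and ``ensemble_po``
    attributes (an :class:`holostim.ensembles.Ensemble`) or an ``(m, 2|3)``
    array of target coordinates plus per-target orientation via ``target_po``.

    Returns the response field sampled by bilinear interpolation at each
    cell's location and nearest orientation level; deterministic.
    """
    if fov_size is None:
        fov_size = float(max(population["x"].max(), population["y"].max()))
        fov_size = max(fov_size, 1.0)
    if hasattr(ensemble, "target_xyz"):
        txy = np.asarray(ensemble.target_xyz, dtype=float)[:, :2]
        tpo = np.full(len(txy), ensemble.ensemble_po)
    else:
        txy = np.asarray(ensemble, dtype=float)[:, :2]
        tpo = np.zeros(len(txy))
    txy = embed_coordinates(txy, fov_size, config)
    cxy = embed_coordinates(population[["x", "y"]].to_numpy(), fov_size, config)

    conn = build_connectivity(config)
    stim = stim_field(
        [(x, y, t) for (x, y), t in zip(txy, tpo)], config
    )
    resp = solve_linear_response(conn, stim, config)

    n = config.n_grid
    dxy = cxy / config.grid_spacing
    i0 = np.floor(dxy[:, 0]).astype(int) % n
    j0 = np.floor(dxy[:, 1]).astype(int) % n
    fi = dxy[:, 0] - np.floor(dxy[:, 0])
    fj = dxy[:, 1] - np.floor(dxy[:, 1])
    k = _snap_theta_index(population["po"].to_numpy(), config)
    v = resp.values
    i1 = (i0 + 1) % n
    j1 = (j0 + 1) % n
    out = (
        v[i0, j0, k] * (1 - fi) * (1 - fj)
        + v[i1, j0, k] * fi * (1 - fj)
        + v[i0, j1, k] * (1 - fi) * fj
        + v[i1, j1, k] * fi * fj
    )
    return out
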