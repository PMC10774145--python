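"""Configuration dataclasses and their YAML/JSON (de)serialization.

All tunable quantities of the model, the analysis and the synthetic-data
generator live here so that every run is reproducible from a single config
file.  Units are micrometres for space, degrees for orientation, frames or
seconds (as stated) for time.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import yaml


class ParameterError(ValueError):
    """Raised when a configuration value violates its documented invariant."""


@dataclass(frozen=True)
class FeatureKernelParams:
    """Orientation-dependent wiring profile h(dtheta) = r0 + rp * exp(-dtheta^2 / (2 sigma^2)).

    ``r0`` is the untuned baseline, ``rp`` the like-to-like peak on top of it
    and ``sigma_theta`` the tuning width in degrees.  ``dtheta`` is the
    orientation difference folded into [0, 90] degrees.
    """

    r0: float = 0.0
    rp: float = 1.0
    sigma_theta: float = 20.0

    def __post_init__(self) -> None:
        if self.r0 < 0 or self.rp < 0:
            raise ParameterError("feature kernel weights r0, rp must be >= 0")
        if self.sigma_theta <= 0:
            raise ParameterError("feature kernel sigma_theta must be > 0")

    @classmethod
    def untuned(cls) -> "FeatureKernelParams":
        """Flat profile h = 1: no orientation dependence."""
        return cls(r0=1.0, rp=0.0, sigma_theta=30.0)


# Defaults below parameterize the broad/narrow sum-of-Gaussians spatial
# wiring and the effective pathway weights.  Broad scales follow anatomical
# tracing estimates (E ~110 um, I ~90 um); the narrow E scale (<50 um) and
# the feature kernels are calibrated so that the model sits in the
# experimentally observed regime (see docs/methods.md).
@dataclass(frozen=True)
class ModelConfig:
    """Parameters of the linearized neural-field model on a periodic square."""

    domain_size: float = 1400.0
    grid_spacing: float = 4.0
    n_orientations: int = 4
    w_ee: float = 0.3
    w_eie: float = 0.6
    sigma_e_broad: float = 110.0
    sigma_i_broad: float = 90.0
    sigma_e_narrow: float = 15.0
    sigma_i_narrow: float = 15.0
    kappa_e: float = 0.3
    kappa_i: float = 0.0
    feature_ee: FeatureKernelParams = field(
        default_factory=lambda: FeatureKernelParams(0.0, 1.0, 20.0)
    )
    feature_ei: FeatureKernelParams = field(
        default_factory=lambda: FeatureKernelParams(0.0, 1.0, 25.0)
    )
    feature_ie: FeatureKernelParams = field(
        default_factory=lambda: FeatureKernelParams(0.0, 1.0, 25.0)
    )
    stim_amplitude: float = 10.0
    expansion_order: Literal["expansion", "exact"] = "expansion"

    def __post_init__(self) -> None:
        if self.domain_size <= 0 or self.grid_spacing <= 0:
            raise ParameterError("domain_size and grid_spacing must be > 0")
        n = self.domain_size / self.grid_spacing
        if abs(n - round(n)) > 1e-9:
            raise ParameterError("grid_spacing must divide domain_size")
        if self.n_orientations < 2:
            raise ParameterError("n_orientations must be >= 2")
        for name in ("sigma_e_broad", "sigma_i_broad", "sigma_e_narrow", "sigma_i_narrow"):
            if getattr(self, name) <= 0:
                raise ParameterError(f"{name} must be > 0")
        for name in ("kappa_e", "kappa_i"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.expansion_order not in ("expansion", "exact"):
            raise ParameterError("expansion_order must be 'expansion' or 'exact'")
        if self.kappa_e > 0 and self.grid_spacing > self.sigma_e_narrow:
            raise ParameterError(
                "grid_spacing exceeds sigma_e_narrow: the narrow wiring scale "
                "cannot be resolved on this grid"
            )

    @property
    def n_grid(self) -> int:
        return int(round(self.domain_size / self.grid_spacing))

    @property
    def orientation_levels(self):
        """Orientation preference levels in degrees, e.g. {0, 45, 90, 135}."""
        import numpy as np

        return np.arange(self.n_orientations) * (180.0 / self.n_orientations)

    def replace(self, **kwargs) -> "ModelConfig":
        return dataclasses.replace(self, **kwargs)


@dataclass(frozen=True)
class DoGProfile:
    """Center-surround spatial response f(d) = A1 exp(-(d/s1)^2) + A2 exp(-(d/s2)^2)."""

    a1: float = 0.2
    sigma1: float = 20.0
    a2: float = -0.02
    sigma2: float = 150.0

    def __post_init__(self) -> None:
        if self.sigma1 <= 0 or self.sigma2 <= 0:
            raise ParameterError("DoG length scales must be > 0")

    def __call__(self, d):
        import numpy as np

        d = np.asarray(d, dtype=float)
        return self.a1 * np.exp(-((d / self.sigma1) ** 2)) + self.a2 * np.exp(
            -((d / self.sigma2) ** 2)
        )


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the trace-level analysis pipeline."""

    neuropil_coefficient: float = 0.7
    baseline_window_frames: int = 1000
    baseline_percentile: float = 10.0
    baseline_stride: int = 50
    pre_frames: int = 3          # baseline frames averaged before stimulation
    window_extra_frames: int = 1  # analysis window = stim frames + this many
    bin_width_um: float = 15.0
    max_distance_um: float = 300.0
    osi_tuned_threshold: float = 0.25
    visual_alpha: float = 0.05
    run_speed_max_cms: float = 6.0
    reg_shift_max_um: float = 4.7
    off_target_radial_um: float = 15.0
    off_target_adjacent_um: float = 30.0
    min_repetitions: int = 10
    ci_level: float = 0.99
    fdr_q: float = 0.01
    n_bootstrap: int = 2000
    distance_metric: Literal["3d", "2d"] = "3d"

    def __post_init__(self) -> None:
        if not 0.0 <= self.neuropil_coefficient <= 1.0:
            raise ParameterError("neuropil coefficient must lie in [0, 1]")
        if self.baseline_window_frames < 2:
            raise ParameterError("baseline window must span at least 2 frames")
        if self.bin_width_um <= 0:
            raise ParameterError("bin width must be > 0")


@dataclass(frozen=True)
class EnsembleSpec:
    """Target windows and cost weights for the discrete ensemble optimizer."""

    n_ensembles: int = 3
    ensemble_size: int = 10
    target_spread_window: tuple[float, float] = (100.0, 200.0)
    target_ensemble_osi_window: tuple[float, float] = (0.0, 1.0)
    target_mean_osi_window: tuple[float, float] = (0.0, 1.0)
    min_within_pair_distance: float = 30.0
    weight_overlap: float = 5.0        # (1) ensembles maximally distinct
    weight_reuse: float = 1.0          # (2) penalize repeated use of a cell
    weight_power: float = 0.2          # (3) prefer cells stimmable at low power
    weight_visual: float = 0.5         # (4) prefer visually responsive cells
    weight_spacing: float = 1.0        # (6) spread cells out within an ensemble
    weight_spread: float = 10.0        # (7) desired spatial spread
    weight_ensemble_osi: float = 10.0  # (8) desired ensemble OSI
    weight_mean_osi: float = 10.0      # (9) desired mean member OSI
    n_restarts: int = 20
    max_iterations: int = 5000
    stall_iterations: int = 500
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.ensemble_size < 3:
            raise ParameterError("ensembles must contain at least three targets")
        for name in (
            "target_spread_window",
            "target_ensemble_osi_window",
            "target_mean_osi_window",
        ):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ParameterError(f"{name} is not well ordered")
        for f_ in dataclasses.fields(self):
            if f_.name.startswith("weight_") and getattr(self, f_.name) < 0:
                raise ParameterError("cost weights must be >= 0")


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions emulated by the synthetic-data generator.

    Defaults mirror the experimental recordings: three 800 x 800 um planes
    spaced 30 um apart imaged at ~6 Hz, drifting-grating tuning blocks over
    eight directions, and ten-target photostimulation trials (1 s of
    stimulation, ten pulses at 10 Hz recorded as metadata).
    """

    n_cells_per_plane: int = 500
    n_planes: int = 3
    fov_size: float = 800.0
    plane_spacing: float = 30.0
    frame_rate_hz: float = 6.0
    opsin_fraction: float = 0.4
    osi_beta: tuple[float, float] = (2.0, 2.0)
    visual_fraction: float = 0.6
    ground_truth: DoGProfile | ModelConfig = field(default_factory=DoGProfile)
    feature_modulation: tuple[float, float, float] = (1.0, 1.0, 1.0)  # iso/45/ortho
    n_ensembles: int = 10
    ensemble_size: int = 10
    spread_range: tuple[float, float] = (80.0, 400.0)
    n_trials_per_ensemble: int = 16
    n_tuning_trials: int = 8
    stim_duration_s: float = 1.0
    n_pulses: int = 10
    pulse_rate_hz: float = 10.0
    pre_frames: int = 5
    post_frames: int = 4
    direct_amplitude: float = 1.0
    ppsf_hwhm_radial: float = 8.0
    ppsf_hwhm_axial: float = 18.0
    snr: float = 5.0
    noise_reference_dff: float = 0.2
    neuropil_contamination: float = 0.7
    calcium_tau_s: float = 1.5
    running_trial_fraction: float = 0.1
    shift_fail_fraction: float = 0.03
    weak_trial_fraction: float = 0.05
    target_success_prob: float = 0.92
    artifact_fraction: float = 0.01
    unmatched_fraction: float = 0.02
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "opsin_fraction",
            "visual_fraction",
            "running_trial_fraction",
            "shift_fail_fraction",
            "weak_trial_fraction",
            "target_success_prob",
            "artifact_fraction",
            "unmatched_fraction",
            "neuropil_contamination",
        ):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ParameterError(f"{name} must lie in [0, 1]")
        if self.snr <= 0:
            raise ParameterError("snr must be > 0")

    def replace(self, **kwargs) -> "GeneratorConfig":
        return dataclasses.replace(self, **kwargs)


# ---------------------------------------------------------------------------
# (De)serialization


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        out = {"__type__": type(obj).__name__}
        for f_ in dataclasses.fields(obj):
            out[f_.name] = _to_plain(getattr(obj, f_.name))
        return out
    if isinstance(obj, tuple):
        return list(obj)
    return obj


_TYPES = {}


def _register(cls):
    _TYPES[cls.__name__] = cls
    return cls


for _cls in (
    FeatureKernelParams,
    ModelConfig,
    DoGProfile,
    AnalysisConfig,
    EnsembleSpec,
    GeneratorConfig,
):
    _register(_cls)


def _from_plain(data):
    if isinstance(data, dict) and "__type__" in data:
        cls = _TYPES[data["__type__"]]
        kwargs = {}
        for f_ in dataclasses.fields(cls):
            if f_.name not in data:
                continue
            v = _from_plain(data[f_.name])
            if isinstance(v, list):
                v = tuple(v)
            kwargs[f_.name] = v
        return cls(**kwargs)
    return data


def save_config(cfg, path: str | Path) -> None:
    """Write any holostim config dataclass to YAML (or JSON if suffix is .json)."""
    path = Path(path)
    plain = _to_plain(cfg)
    if path.suffix == ".json":
        path.write_text(json.dumps(plain, indent=2))
    else:
        path.write_text(yaml.safe_dump(plain, sort_keys=False))


def load_config(path: str | Path):
    """Load a config dataclass previously written by :func:`save_config`."""
    path = Path(path)
    text = path.read_text()
    plain = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return _from_plain(plain)
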