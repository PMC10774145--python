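"""Synthetic read/write experiments with known ground truth.

The generator emulates the structure of the real recordings -- three
800 x 800 um imaging planes 30 um apart at ~6 Hz, salt-and-pepper
orientation preferences, drifting-grating tuning blocks over eight
directions, and ten-target photostimulation trials -- while every response
is drawn from a known ground truth (a center-surround distance profile or
the neural-field model itself).  That makes every stage of the analysis
pipeline testable end to end without any recorded data.

All randomness flows from one root seed through named substreams
(positions, tuning, design, behavior, noise), so identical configs produce
byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

import json

import numpy as np
import pandas as pd

from holostim.config import DoGProfile, GeneratorConfig, ModelConfig
from holostim.ensembles import Ensemble, ensembles_to_frame, mean_pairwise_spread
from holostim.fields import fold_orientation
from holostim.model import predict_cell_responses
from holostim.spatial import min_target_distance

_SUBSTREAMS = ("positions", "tuning", "design", "behavior", "noise")


def _rngs(seed: int) -> dict[str, np.random.Generator]:
    root = np.random.SeedSequence(seed)
    children = root.spawn(len(_SUBSTREAMS))
    return {name: np.random.default_rng(s) for name, s in zip(_SUBSTREAMS, children)}


def _direction_grid(n: int = 8) -> np.ndarray:
    return np.arange(n) * (360.0 / n)


def tuning_curve_from_osi(po: float, osi: float, amp: float, n_directions: int = 8,
                          sigma_theta: float = 25.0) -> np.ndarray:
    """Ground-truth direction tuning curve with a prescribed OSI.

    The folded curve has peak ``amp`` at the preferred orientation and
    baseline ``amp * (1 - osi) / (1 + osi)`` at the orthogonal one, which
    reproduces ``osi`` exactly under the (PO - OO)/(PO + OO) definition.
    Opposite drift directions respond identically (no direction
    selectivity).
    """
    b = (1.0 - osi) / (1.0 + osi)
    dirs = _direction_grid(n_directions)
    delta = fold_orientation(dirs - po)
    shape = b + (1.0 - b) * (
        np.exp(-(delta**2) / (2 * sigma_theta**2))
        - np.exp(-(90.0**2) / (2 * sigma_theta**2))
    ) / (1.0 - np.exp(-(90.0**2) / (2 * sigma_theta**2)))
    return amp * shape


def generate_fov(config: GeneratorConfig, fov_id: int = 0) -> pd.DataFrame:
    """Cell table for one synthetic field of view.

    Positions are uniform within each plane; orientation preferences are
    drawn uniformly from {0, 45, 90, 135} independent of position
    (salt-and-pepper map); OSIs follow the configured beta distribution.
    """
    rngs = _rngs(config.random_seed)
    rp, rt = rngs["positions"], rngs["tuning"]
    n = config.n_cells_per_plane * config.n_planes
    plane = np.repeat(np.arange(config.n_planes), config.n_cells_per_plane)
    x = rp.uniform(0, config.fov_size, n)
    y = rp.uniform(0, config.fov_size, n)
    z = plane * config.plane_spacing
    po = rt.choice([0.0, 45.0, 90.0, 135.0], size=n)
    osi = rt.beta(*config.osi_beta, size=n)
    visual = rt.random(n) < config.visual_fraction
    amp = np.where(visual, rt.uniform(0.3, 0.8, n), rt.uniform(0.0, 0.04, n))
    opsin = rt.random(n) < config.opsin_fraction
    power = rt.uniform(12.5, 100.0, n)
    matched = rt.random(n) >= config.unmatched_fraction
    artifact = rt.random(n) < config.artifact_fraction
    return pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "fov_id": fov_id,
            "plane": plane,
            "x": x,
            "y": y,
            "z": z.astype(float),
            "opsin_positive": opsin,
            "power": power,
            "matched": matched,
            "artifact_occluded": artifact,
            "po_true": po,
            "osi_true": osi,
            "amp_visual": amp,
            "visually_responsive_true": visual,
        }
    )


def _pick_ensemble(
    cells: pd.DataFrame,
    rng: np.random.Generator,
    size: int,
    target_spread: float,
    min_pair: float,
    mode: str,
) -> np.ndarray | None:
    pool = cells[cells["opsin_positive"] & cells["matched"]]
    if mode == "cotuned":
        po = rng.choice([0.0, 45.0, 90.0, 135.0])
        # member OSI well above the 0.5 mean-OSI threshold so the ensemble
        # OSI of the mean curve clears the 0.7 cotuned criterion
        pool = pool[(pool["po_true"] == po) & (pool["osi_true"] > 0.7)]
    elif mode == "untuned":
        pool = pool[pool["osi_true"] < 0.45]
    xyz = pool[["x", "y", "z"]].to_numpy(float)
    ids = pool.index.to_numpy()
    if len(pool) < size:
        return None
    best, best_err = None, np.inf
    for attempt in range(60):
        center = xyz[rng.integers(len(ids))][:2]
        # grow the candidate radius until enough cells are available, so
        # sparse pools still yield an ensemble (its realized spread may then
        # exceed the request; the recorded spread is always the actual one)
        radius = max(target_spread / 0.9, min_pair * 2.5)
        r2d = np.hypot(xyz[:, 0] - center[0], xyz[:, 1] - center[1])
        near = np.where(r2d <= radius)[0]
        while len(near) < 3 * size and radius < 2000.0:
            radius *= 1.4
            near = np.where(r2d <= radius)[0]
        if len(near) < size:
            continue
        order = rng.permutation(near)
        picked: list[int] = []
        for j in order:
            if len(picked) == size:
                break
            cand = xyz[picked + [j]]
            diff = cand[:, None, :] - cand[None, :, :]
            d = np.sqrt((diff**2).sum(-1))
            iu = np.triu_indices(len(cand), 1)
            if len(cand) == 1 or (d[iu] >= min_pair).all():
                picked.append(int(j))
        if len(picked) < size:
            continue
        spread = mean_pairwise_spread(xyz[picked])
        err = abs(spread - target_spread)
        if err < best_err:
            best_err, best = err, np.array(picked)
    return ids[best] if best is not None else None


def design_ensembles(cells: pd.DataFrame, config: GeneratorConfig,
                     tuning_modes: tuple[str, ...] = ("random",)) -> list[Ensemble]:
    """Draw stimulation ensembles spanning the configured spread range."""
    rng = _rngs(config.random_seed)["design"]
    lo, hi = config.spread_range
    spreads = np.linspace(lo, hi, config.n_ensembles)
    ensembles = []
    for k in range(config.n_ensembles):
        mode = tuning_modes[k % len(tuning_modes)]
        members = None
        for attempt in range(10):
            members = _pick_ensemble(
                cells, rng, config.ensemble_size, spreads[k], 30.0, mode
            )
            if members is not None:
                break
        if members is None:
            raise RuntimeError(
                f"could not design ensemble {k} (mode={mode}, spread={spreads[k]:.0f})"
            )
        sub = cells.loc[members]
        curves = np.stack(
            [
                tuning_curve_from_osi(r["po_true"], r["osi_true"], r["amp_visual"])
                for _, r in sub.iterrows()
            ]
        )
        from holostim.ensembles import ensemble_osi as _eosi

        e_osi, e_po, m_osi = _eosi(curves)
        ensembles.append(
            Ensemble(
                ensemble_id=k,
                target_ids=sub["cell_id"].tolist(),
                target_xyz=sub[["x", "y", "z"]].to_numpy(float),
                spread=mean_pairwise_spread(sub[["x", "y", "z"]].to_numpy(float)),
                ensemble_osi=e_osi,
                mean_osi=m_osi,
                ensemble_po=e_po,
            )
        )
    return ensembles


def generate_ground_truth_response(
    cells: pd.DataFrame,
    ensemble: Ensemble,
    config: GeneratorConfig,
) -> np.ndarray:
    """Expected (noise-free) response of every cell to one ensemble.

    Network effect: the configured distance profile evaluated at the 3-D
    minimal target distance, times the relative-tuning modulation weight;
    or, in model mode, the neural-field prediction.  On top of that, targets
    respond with the direct amplitude and cells inside the off-target zone
    receive a direct-activation surrogate with the PPSF's radial/axial
    falloff (so the off-target exclusion logic has real work to do).
    """
    xyz = cells[["x", "y", "z"]].to_numpy(float)
    md = min_target_distance(xyz, ensemble.target_xyz, metric="3d")
    if isinstance(config.ground_truth, ModelConfig):
        pop = cells.rename(columns={"po_true": "po"})[["x", "y", "po"]]
        network = predict_cell_responses(
            pop, ensemble, config.ground_truth, fov_size=config.fov_size
        )
    else:
        delta = fold_orientation(cells["po_true"].to_numpy(float) - ensemble.ensemble_po)
        w_iso, w_mid, w_ortho = config.feature_modulation
        mod = np.select([delta < 22.5, delta < 67.5], [w_iso, w_mid], default=w_ortho)
        network = config.ground_truth(md) * mod

    # Direct-activation surrogate with PPSF falloff (radial/axial HWHM),
    # confined to the off-target zone those cells are excluded for (stray
    # light beyond the zone is treated as negligible so that the network
    # ground truth stays exactly the configured profile for analyzed cells).
    direct = np.zeros(len(cells))
    plane_spacing = config.plane_spacing
    for tx, ty, tz in ensemble.target_xyz:
        r = np.hypot(xyz[:, 0] - tx, xyz[:, 1] - ty)
        dz = np.abs(xyz[:, 2] - tz)
        in_zone = ((dz < 0.5 * plane_spacing) & (r < 15.0)) | (
            (np.abs(dz - plane_spacing) < 0.5 * plane_spacing) & (r < 30.0)
        )
        d = config.direct_amplitude * np.exp(
            -np.log(2) * (r / config.ppsf_hwhm_radial) ** 2
            - np.log(2) * (dz / config.ppsf_hwhm_axial) ** 2
        )
        direct = np.maximum(direct, np.where(in_zone, d, 0.0))
    is_target = cells["cell_id"].isin(ensemble.target_ids).to_numpy()
    direct[is_target] = config.direct_amplitude
    return network + direct


class Recording(NamedTuple):
    f_cell: np.ndarray      # (cells, frames) raw fluorescence
    f_neuropil: np.ndarray  # (cells, frames)
    run_speed: np.ndarray   # (frames,) cm/s
    trials: pd.DataFrame
    frame_rate_hz: float


@dataclass
class SyntheticExperiment:
    cells: pd.DataFrame
    ensembles: list[Ensemble]
    expected: np.ndarray          # (n_ensembles, n_cells) ground-truth responses
    recording: Recording
    config: GeneratorConfig

    @property
    def ensembles_frame(self) -> pd.DataFrame:
        df = ensembles_to_frame(self.ensembles)
        df["fov_id"] = 0
        return df


def _trial_frames(config: GeneratorConfig) -> tuple[int, int, int]:
    n_stim = int(round(config.stim_duration_s * config.frame_rate_hz))
    return config.pre_frames, n_stim, config.post_frames


def _event_kernel(n_stim: int, n_tail: int, window: int, tau_frames: float) -> np.ndarray:
    """Within-trial calcium kernel, normalized so its analysis-window mean is 1."""
    t = np.arange(n_stim + n_tail, dtype=float)
    k = np.exp(-t / tau_frames)
    k /= k[:window].mean()
    return k


def generate_recording(
    cells: pd.DataFrame,
    ensembles: list[Ensemble],
    expected: np.ndarray,
    config: GeneratorConfig,
) -> Recording:
    """Trace matrices and the trial table for one synthetic session.

    The session is a drifting-grating tuning block (eight directions plus
    blanks) followed by interleaved photostimulation trials.  Responses are
    injected as exponential-decay calcium transients (tau ~1.5 s, GCaMP6s
    like) truncated at the trial boundary and calibrated so that the mean
    over the analysis window equals the prescribed response amplitude.
    Running speed, registration shifts and per-target success flags are
    drawn so the exclusion rules fire at the configured rates.
    """
    rngs = _rngs(config.random_seed)
    rb, rn = rngs["behavior"], rngs["noise"]
    n_cells = len(cells)
    pre, n_stim, post = _trial_frames(config)
    trial_len = pre + n_stim + post
    window = n_stim + 1  # analysis window: stimulus frames plus one
    tau_frames = config.calcium_tau_s * config.frame_rate_hz
    kern = _event_kernel(n_stim, post, window, tau_frames)

    dirs = _direction_grid()
    grating_plan = [(d, None) for d in np.tile(dirs, config.n_tuning_trials)]
    grating_plan += [(np.nan, None)] * config.n_tuning_trials  # blanks
    rngs["design"].shuffle(grating_plan)
    stim_plan = [(np.nan, e.ensemble_id) for e in ensembles] * config.n_trials_per_ensemble
    rngs["design"].shuffle(stim_plan)
    plan = grating_plan + stim_plan
    n_frames = trial_len * len(plan)

    curves = np.stack(
        [
            tuning_curve_from_osi(r["po_true"], r["osi_true"], r["amp_visual"])
            for _, r in cells.iterrows()
        ]
    )
    target_idx = {
        e.ensemble_id: cells["cell_id"].isin(e.target_ids).to_numpy().nonzero()[0]
        for e in ensembles
    }

    sig = np.zeros((n_cells, n_frames), dtype=np.float32)
    run_speed = np.abs(rb.normal(1.0, 0.8, n_frames)).clip(0, 5.5)
    trials = []
    for t_i, (direction, eid) in enumerate(plan):
        f0 = t_i * trial_len
        stim_start = f0 + pre
        kind = "stim" if eid is not None else ("blank" if np.isnan(direction) else "grating")
        amp = np.zeros(n_cells)
        n_targets = n_ok = 0
        success = ""
        if kind == "grating":
            j = int(np.where(dirs == direction)[0][0])
            amp = curves[:, j]
        elif kind == "stim":
            e = ensembles[int(eid)]
            tidx = target_idx[e.ensemble_id]
            n_targets = len(tidx)
            p_ok = (
                0.3
                if rb.random() < config.weak_trial_fraction
                else config.target_success_prob
            )
            ok = rb.random(n_targets) < p_ok
            n_ok = int(ok.sum())
            success = ";".join("1" if s else "0" for s in ok)
            # a failed target loses its own direct response; trials where
            # too many targets fail are removed by the exclusion rules
            amp = expected[int(eid)].copy()
            amp[tidx[~ok]] = 0.0
        if kind == "stim" and rb.random() < config.running_trial_fraction:
            run_speed[stim_start : f0 + trial_len] = rb.uniform(7.0, 15.0)
        reg_shift = (
            rb.uniform(5.0, 8.0)
            if (kind == "stim" and rb.random() < config.shift_fail_fraction)
            else rb.uniform(0.0, 2.0)
        )
        span = min(len(kern), f0 + trial_len - stim_start)
        sig[:, stim_start : stim_start + span] += np.outer(amp, kern[:span]).astype(
            np.float32
        )
        trials.append(
            {
                "trial_id": t_i,
                "fov_id": 0,
                "kind": kind,
                "direction": direction,
                "ensemble_id": -1 if eid is None else int(eid),
                "start_frame": f0,
                "stim_frame": stim_start,
                "n_pre": pre,
                "n_stim": n_stim,
                "run_speed_max": float(run_speed[f0 : f0 + trial_len].max()),
                "reg_shift_um": reg_shift,
                "n_targets": n_targets,
                "n_targets_ok": n_ok,
                "success_flags": success,
                "n_pulses": config.n_pulses if kind == "stim" else 0,
                "pulse_rate_hz": config.pulse_rate_hz if kind == "stim" else 0.0,
            }
        )

    # Trace SNR is referenced to the single-action-potential transient scale
    # (~0.2 dF/F for GCaMP6s); at the default snr=5 the per-frame noise SD is
    # 0.04 dF/F, typical of 6 Hz two-photon recordings.
    noise_sd = config.noise_reference_dff / config.snr
    frames = np.arange(n_frames)
    drift = 0.05 * np.sin(2 * np.pi * frames / 2500.0)
    f0_cell = rn.uniform(80.0, 120.0, n_cells)[:, None]
    neuro_base = 20.0 * (1.0 + 0.3 * drift + 0.02 * rn.standard_normal((n_cells, n_frames)))
    dff_true = sig + noise_sd * rn.standard_normal((n_cells, n_frames)).astype(np.float32)
    f_cell = f0_cell * (1.0 + dff_true + drift) + config.neuropil_contamination * neuro_base
    return Recording(
        f_cell=f_cell.astype(np.float32),
        f_neuropil=neuro_base.astype(np.float32),
        run_speed=run_speed,
        trials=pd.DataFrame(trials),
        frame_rate_hz=config.frame_rate_hz,
    )


def simulate(
    config: GeneratorConfig,
    outdir: str | Path | None = None,
    tuning_modes: tuple[str, ...] = ("random",),
) -> SyntheticExperiment:
    """Full synthetic experiment; optionally written to disk.

    When ``outdir`` is given, writes ``cells.csv``, ``ensembles.csv``,
    ``trials.csv``, ``traces.h5`` (datasets /F, /Fneu, /run_speed, attribute
    ``frame_rate_hz``) and ``truth.json`` + ``truth_responses.csv`` with the
    ground-truth record used by round-trip tests.
    """
    cells = generate_fov(config)
    ensembles = design_ensembles(cells, config, tuning_modes=tuning_modes)
    expected = np.stack(
        [generate_ground_truth_response(cells, e, config) for e in ensembles]
    )
    rec = generate_recording(cells, ensembles, expected, config)
    exp = SyntheticExperiment(cells, ensembles, expected, rec, config)
    if outdir is not None:
        from holostim import io as hio

        hio.write_experiment(exp, outdir)
        truth = {
            "ground_truth": type(config.ground_truth).__name__,
            "params": (
                {
                    "a1": config.ground_truth.a1,
                    "sigma1": config.ground_truth.sigma1,
                    "a2": config.ground_truth.a2,
                    "sigma2": config.ground_truth.sigma2,
                }
                if isinstance(config.ground_truth, DoGProfile)
                else "model"
            ),
            "feature_modulation": list(config.feature_modulation),
            "random_seed": config.random_seed,
            "ensemble_classes": [
                [e.spatial_class, e.tuning_class] for e in ensembles
            ],
        }
        Path(outdir, "truth.json").write_text(json.dumps(truth, indent=2))
        resp = pd.DataFrame(
            expected.T, columns=[f"ensemble_{e.ensemble_id}" for e in ensembles]
        )
        resp.insert(0, "cell_id", cells["cell_id"])
        resp.to_csv(Path(outdir, "truth_responses.csv"), index=False)
    return exp
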