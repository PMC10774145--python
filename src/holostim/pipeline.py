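"""End-to-end orchestration and in-silico circuit experiments.

``run_end_to_end`` drives the full chain simulate -> dF/F -> tuning ->
exclusions -> distance curves -> center-surround fit and returns a report
whose every number is traceable to a pipeline operation.  The experiment
functions reproduce the model analyses: the (w_ee, kappa) sweep of the
zero crossing and activation/suppression ratio against the experimentally
observed regime, the ensemble-spread dependence of the synaptic pathways,
and the iso/ortho distance curves under different feature-wiring modes.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from holostim.config import (
    AnalysisConfig,
    DoGProfile,
    FeatureKernelParams,
    GeneratorConfig,
    ModelConfig,
)
from holostim.dog import DoGFit, RegimeBox, dog_summary, fit_dog
from holostim.ensembles import Ensemble
from holostim.exclusions import apply_exclusions
from holostim.fields import min_distance_grid
from holostim.model import (
    build_connectivity,
    decompose_pathways,
    solve_linear_response,
    stim_field,
)
from holostim.spatial import distance_response_curve, min_target_distance
from holostim.synth import SyntheticExperiment, simulate
from holostim.traces import dff
from holostim.tuning import relative_tuning_split, tuning_and_osi


# ---------------------------------------------------------------------------
# trace-level analysis


def trial_responses(
    dff_mat: np.ndarray, trials: pd.DataFrame, cfg: AnalysisConfig
) -> np.ndarray:
    """Per-trial response of every cell: analysis-window mean minus baseline.

    The analysis window spans the stimulus frames plus ``window_extra``
    frames; the baseline is the mean over the ``pre_frames`` frames
    immediately before stimulus onset.  Returns ``(n_trials, n_cells)``.
    """
    out = np.zeros((len(trials), dff_mat.shape[0]))
    for i, (_, tr) in enumerate(trials.iterrows()):
        s = int(tr["stim_frame"])
        w = int(tr["n_stim"]) + cfg.window_extra_frames
        base = dff_mat[:, max(0, s - cfg.pre_frames) : s].mean(axis=1)
        out[i] = dff_mat[:, s : s + w].mean(axis=1) - base
    return out


def recompute_tuning(
    responses: np.ndarray, trials: pd.DataFrame, cfg: AnalysisConfig
) -> pd.DataFrame:
    """Offline tuning of each cell from the grating-block trial responses."""
    gr = trials[trials["kind"] == "grating"]
    bl = trials[trials["kind"] == "blank"]
    dirs = np.sort(gr["direction"].unique())
    n_cells = responses.shape[1]
    per_dir = [responses[gr.index[gr["direction"] == d].to_numpy(), :] for d in dirs]
    n_trials = min(r.shape[0] for r in per_dir)
    stack = np.stack([r[:n_trials] for r in per_dir], axis=2)  # (trials, cells, dirs)
    blank = responses[bl.index.to_numpy(), :] if len(bl) else None
    rows = []
    for c in range(n_cells):
        res = tuning_and_osi(
            stack[:, c, :], blank=blank[:, c] if blank is not None else None
        )
        rows.append(
            {
                "po": res.po,
                "oo": res.oo,
                "osi": res.osi,
                "p_visual": res.p_visual,
                "visually_responsive": res.p_visual < cfg.visual_alpha,
            }
        )
    return pd.DataFrame(rows)


def build_pair_table(
    result,
    responses: np.ndarray,
    trials: pd.DataFrame,
    cells: pd.DataFrame,
    ensembles: Iterable[Ensemble],
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """(cell, ensemble) response table with distances and tuning labels.

    Averages the per-trial responses of each included (trial, cell) pair
    over an ensemble's kept trials, attaches the minimal 3-D target
    distance and the relative-tuning label, and drops pairs with fewer
    included repetitions than ``cfg.min_repetitions``.
    """
    trial_rows = {tid: i for i, tid in enumerate(trials["trial_id"])}
    cell_rows = {cid: i for i, cid in enumerate(cells["cell_id"])}
    pairs = result.pairs
    r_idx = pairs["trial_id"].map(trial_rows).to_numpy()
    c_idx = pairs["cell_id"].map(cell_rows).to_numpy()
    df = pairs.copy()
    df["response"] = responses[r_idx, c_idx]
    agg = (
        df.groupby(["ensemble_id", "cell_id"])["response"]
        .agg(["mean", "count"])
        .reset_index()
        .rename(columns={"mean": "response", "count": "n_trials"})
    )
    agg = agg[agg["n_trials"] >= cfg.min_repetitions]

    ens_by_id = {e.ensemble_id: e for e in ensembles}
    xyz = cells.set_index("cell_id")[["x", "y", "z"]]
    po = cells.set_index("cell_id")["po"]
    osi = cells.set_index("cell_id")["osi"]
    vis = cells.set_index("cell_id")["visually_responsive"]
    out = []
    for eid, sub in agg.groupby("ensemble_id"):
        e = ens_by_id[int(eid)]
        cxyz = xyz.loc[sub["cell_id"]].to_numpy(float)
        sub = sub.copy()
        sub["min_dist"] = min_target_distance(
            cxyz, e.target_xyz, metric=cfg.distance_metric
        )
        sub["delta_theta"] = relative_tuning_split(
            po.loc[sub["cell_id"]].to_numpy(float),
            e.ensemble_po,
            cell_osi=osi.loc[sub["cell_id"]].to_numpy(float),
            osi_threshold=cfg.osi_tuned_threshold,
            visually_responsive=vis.loc[sub["cell_id"]].to_numpy(bool),
        )
        out.append(sub)
    return pd.concat(out, ignore_index=True) if out else agg


def analyze_experiment(
    exp: SyntheticExperiment, cfg: AnalysisConfig | None = None
) -> dict:
    """Full analysis of one (synthetic) experiment; returns the run report."""
    cfg = cfg or AnalysisConfig()
    rec = exp.recording
    d = dff(
        rec.f_cell,
        rec.f_neuropil,
        c=cfg.neuropil_coefficient,
        window=cfg.baseline_window_frames,
        percentile=cfg.baseline_percentile,
        stride=cfg.baseline_stride,
    )
    dmat = np.nan_to_num(d.dff, nan=0.0)
    responses = trial_responses(dmat, rec.trials, cfg)
    tuning = recompute_tuning(responses, rec.trials, cfg)
    cells = pd.concat([exp.cells.reset_index(drop=True), tuning], axis=1)

    result = apply_exclusions(rec.trials, cells, exp.ensembles_frame, cfg)
    report: dict = {"audit": result.audit, "n_cells_valid": int(d.valid.sum())}
    if not len(result.cells):
        report["status"] = "empty_after_exclusions"
        return report
    pair_table = build_pair_table(result, responses, rec.trials, cells,
                                  exp.ensembles, cfg)
    report["status"] = "ok"
    report["n_pairs"] = int(len(pair_table))
    curve = distance_response_curve(
        pair_table, bin_width=cfg.bin_width_um, max_distance=cfg.max_distance_um
    )
    report["curve"] = curve.to_frame()
    report["curves_by_tuning"] = {
        k: v.to_frame()
        for k, v in distance_response_curve(
            pair_table,
            bin_width=cfg.bin_width_um,
            max_distance=cfg.max_distance_um,
            grouping="delta_theta",
        ).items()
    }
    fit = fit_dog(pair_table["min_dist"], pair_table["response"])
    crossing, ratio = dog_summary(fit)
    report["fit"] = {
        "a1": fit.a1,
        "sigma1": fit.sigma1,
        "a2": fit.a2,
        "sigma2": fit.sigma2,
        "zero_crossing_um": crossing,
        "act_supp_ratio": ratio,
    }
    report["pair_table"] = pair_table
    return report


def run_end_to_end(
    gen_config: GeneratorConfig,
    analysis_config: AnalysisConfig | None = None,
    outdir=None,
    tuning_modes: tuple[str, ...] = ("random",),
) -> dict:
    """simulate -> exclude -> curves -> fit, with ground-truth comparison."""
    exp = simulate(gen_config, outdir=outdir, tuning_modes=tuning_modes)
    report = analyze_experiment(exp, analysis_config)
    report["generator"] = {"seed": gen_config.random_seed}
    if isinstance(gen_config.ground_truth, DoGProfile) and report.get("fit"):
        gt = gen_config.ground_truth
        truth_fit = DoGFit(gt.a1, gt.sigma1, gt.a2, gt.sigma2)
        crossing, ratio = dog_summary(truth_fit)
        report["truth"] = {
            "a1": gt.a1,
            "sigma1": gt.sigma1,
            "a2": gt.a2,
            "sigma2": gt.sigma2,
            "zero_crossing_um": crossing,
            "act_supp_ratio": ratio,
        }
    return report


# ---------------------------------------------------------------------------
# model experiments


def _untuned(config: ModelConfig) -> ModelConfig:
    u = FeatureKernelParams.untuned()
    return config.replace(feature_ee=u, feature_ei=u, feature_ie=u)


def spiral_targets(
    spread: float, n_targets: int = 10, center: tuple[float, float] | None = None,
    config: ModelConfig | None = None,
) -> np.ndarray:
    """Deterministic golden-angle spiral of targets with exact mean spread."""
    k = np.arange(1, n_targets + 1)
    pts = np.stack(
        [np.sqrt(k) * np.cos(k * 2.399963), np.sqrt(k) * np.sin(k * 2.399963)], axis=1
    )
    d = pts[:, None, :] - pts[None, :, :]
    mean_pair = np.sqrt((d**2).sum(-1))[np.triu_indices(n_targets, 1)].mean()
    pts *= spread / mean_pair
    if center is None:
        size = config.domain_size if config is not None else 1400.0
        center = (size / 2, size / 2)
    return pts + np.asarray(center)


def _grid_curve(values2d: np.ndarray, md: np.ndarray, bin_width: float,
                max_dist: float) -> tuple[np.ndarray, np.ndarray]:
    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    idx = np.digitize(md.ravel(), edges) - 1
    v = values2d.ravel()
    means = np.array([
        v[idx == b].mean() if np.any(idx == b) else np.nan
        for b in range(len(edges) - 1)
    ])
    return 0.5 * (edges[:-1] + edges[1:]), means


def point_response_profile(
    config: ModelConfig, bin_width: float = 2.0, max_dist: float = 400.0
) -> tuple[np.ndarray, np.ndarray]:
    """Orientation-averaged response profile to a single point stimulus."""
    conn = build_connectivity(config)
    c = config.domain_size / 2
    stim = stim_field([(c, c, 0.0)], config)
    resp = solve_linear_response(conn, stim, config)
    md = min_distance_grid(np.array([[c, c]]), config)
    return _grid_curve(resp.values.mean(axis=2), md, bin_width, max_dist)


def profile_summary(r: np.ndarray, p: np.ndarray) -> tuple[float | None, float]:
    """(zero crossing, max activation / |max suppression|) of a profile."""
    ok = np.isfinite(p)
    r, p = r[ok], p[ok]
    crossing = None
    sign_change = np.where((p[:-1] > 0) & (p[1:] <= 0))[0]
    if len(sign_change):
        i = sign_change[0]
        # linear interpolation between bin centers
        f = p[i] / (p[i] - p[i + 1])
        crossing = float(r[i] + f * (r[i + 1] - r[i]))
    trough = p.min()
    peak = max(float(p.max()), 0.0)  # all-suppressed profiles have no activation
    ratio = np.inf if trough >= 0 else peak / abs(trough)
    return crossing, ratio


def reference_regime_box(
    fit: DoGFit, crossing_halfwidth: float = 7.5, ratio_factor: float = 1.5
) -> RegimeBox:
    """Rectangle around a reference fit's (crossing, ratio) point."""
    crossing, ratio = dog_summary(fit)
    if crossing is None or not np.isfinite(ratio):
        raise ValueError("reference fit has no crossing or no suppression")
    return RegimeBox(
        crossing - crossing_halfwidth,
        crossing + crossing_halfwidth,
        ratio / ratio_factor,
        ratio * ratio_factor,
    )


def sweep_regime_locus(
    config: ModelConfig,
    w_ee_values: Iterable[float] | None = None,
    kappa_values: Iterable[float] = (0.0, 0.15, 0.3, 0.45),
    box: RegimeBox | None = None,
    untuned: bool = True,
) -> pd.DataFrame:
    """(zero crossing, ratio) locus over the (w_ee, kappa) parameter grid.

    For each parameter pair the single-point response profile is summarized
    by its zero crossing and activation/suppression ratio; when a regime
    ``box`` is supplied an ``in_box`` flag records whether the locus point
    falls inside the experimentally observed rectangle.
    """
    if w_ee_values is None:
        w_ee_values = np.linspace(0.05, 1.25, 16)
    base = _untuned(config) if untuned else config
    rows = []
    for kappa in kappa_values:
        for w_ee in w_ee_values:
            cfg = base.replace(w_ee=float(w_ee), kappa_e=float(kappa))
            r, p = point_response_profile(cfg)
            crossing, ratio = profile_summary(r, p)
            rows.append(
                {
                    "w_ee": float(w_ee),
                    "kappa": float(kappa),
                    "zero_crossing_um": crossing,
                    "act_supp_ratio": ratio,
                    "in_box": box.contains(crossing, ratio) if box else None,
                }
            )
    return pd.DataFrame(rows)


def spread_pathway_experiment(
    config: ModelConfig,
    spreads: Iterable[float] = (60.0, 100.0, 150.0, 250.0, 400.0),
    n_targets: int = 10,
    untuned: bool = True,
) -> dict:
    """Surround suppression and pathway magnitudes versus ensemble spread.

    For ten-target spiral ensembles at each spread, records the mean
    response over nodes 50-150 um from the nearest target and the L2 norm
    of each synaptic pathway's field (the total signed mass of a pathway is
    spread-invariant, so the L2 norm is used as the magnitude).  Returns the
    per-spread table plus regression slopes of the excitatory (mono + di)
    and inhibitory pathway magnitudes against spread.
    """
    cfg = _untuned(config) if untuned else config
    conn = build_connectivity(cfg)
    dx2 = cfg.grid_spacing**2
    rows = []
    for spread in spreads:
        pts = spiral_targets(spread, n_targets, config=cfg)
        stim = stim_field([(x, y, 0.0) for x, y in pts], cfg)
        pw = decompose_pathways(conn, stim, cfg)
        md = min_distance_grid(pts, cfg)
        tot = pw.total.values.mean(axis=2)
        mask = (md >= 50) & (md <= 150)
        exc = (pw.mono_ee.values + pw.di_eee.values).mean(axis=2)
        inh = pw.di_eie.values.mean(axis=2)
        rows.append(
            {
                "spread_um": float(spread),
                "suppression_50_150": float(tot[mask].mean()),
                "l2_excitatory": float(np.sqrt((exc**2).sum() * dx2)),
                "l2_inhibitory": float(np.sqrt((inh**2).sum() * dx2)),
            }
        )
    df = pd.DataFrame(rows)
    slope_exc = float(np.polyfit(df["spread_um"], df["l2_excitatory"], 1)[0])
    slope_inh = float(np.polyfit(df["spread_um"], df["l2_inhibitory"], 1)[0])
    return {"table": df, "slope_excitatory": slope_exc, "slope_inhibitory": slope_inh}


_MODES = ("spatial", "tuned_ee", "full")


def tuning_mode_experiment(
    config: ModelConfig,
    spread: float = 300.0,
    modes: Iterable[str] = _MODES,
    n_targets: int = 10,
    bin_width: float = 15.0,
    max_dist: float = 300.0,
) -> Mapping[str, dict]:
    """Iso/45/ortho distance curves under different feature-wiring modes.

    Modes: ``spatial`` has no orientation dependence anywhere; ``tuned_ee``
    keeps the configured like-to-like E->E kernel but untuned E->I and
    I->E; ``full`` uses all configured feature kernels.  The stimulated
    ensemble is cotuned (all targets at 0 degrees).
    """
    u = FeatureKernelParams.untuned()
    out: dict[str, dict] = {}
    pts = spiral_targets(spread, n_targets, config=config)
    md = min_distance_grid(pts, config)
    k_iso = 0
    k_mid = 1
    k_ortho = config.n_orientations // 2
    for mode in modes:
        if mode == "spatial":
            cfg = _untuned(config)
        elif mode == "tuned_ee":
            cfg = config.replace(feature_ei=u, feature_ie=u)
        elif mode == "full":
            cfg = config
        else:
            raise ValueError(f"unknown mode {mode!r}")
        conn = build_connectivity(cfg)
        stim = stim_field([(x, y, 0.0) for x, y in pts], cfg)
        resp = solve_linear_response(conn, stim, cfg)
        pw = decompose_pathways(conn, stim, cfg)
        bins, iso = _grid_curve(resp.values[:, :, k_iso], md, bin_width, max_dist)
        _, mid = _grid_curve(resp.values[:, :, k_mid], md, bin_width, max_dist)
        _, ortho = _grid_curve(resp.values[:, :, k_ortho], md, bin_width, max_dist)
        exc = pw.mono_ee.values + pw.di_eee.values
        inh = pw.di_eie.values
        out[mode] = {
            "bins": bins,
            "iso": iso,
            "mid": mid,
            "ortho": ortho,
            "l2_excitatory": float(np.sqrt((exc**2).sum() * config.grid_spacing**2)),
            "l2_inhibitory": float(np.sqrt((inh**2).sum() * config.grid_spacing**2)),
        }
    return out


def report_to_json(report: dict) -> dict:
    """Strip a run report down to JSON-serializable content."""
    out = {}
    for k, v in report.items():
        if isinstance(v, pd.DataFrame):
            out[k] = v.to_dict(orient="list")
        elif isinstance(v, dict):
            out[k] = {
                kk: (vv.to_dict(orient="list") if isinstance(vv, pd.DataFrame) else vv)
                for kk, vv in v.items()
            }
        else:
            out[k] = v
    return out
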