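"""Exclusion rules turning raw trial tables into the analysis dataset.

Rules are applied in the order FOV -> ensemble -> trial -> cell, with an
audit log counting removals per rule:

* FOV: fewer than 5% visually responsive cells; more than 50% of trials
  while the animal ran; fewer than 250 detected cells.
* Ensemble: more than 33% of targets not detected; more than 50% of
  attempted stimulation trials failed; fewer than ten successful
  repetitions.
* Trial: running above 6 cm/s; 50% or more of targets failed to respond
  (below 0.25 z-scored fluorescence); registration shift above 4.7 um.
* Cell (per trial): inside an off-target zone (or itself a target);
  stimulated in the immediately preceding trial; occluded by the
  stimulation artifact; not matched to a detected source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from holostim.config import AnalysisConfig
from holostim.spatial import off_target_mask

FOV_MIN_VISUAL_FRACTION = 0.05
FOV_MAX_RUNNING_FRACTION = 0.5
FOV_MIN_CELLS = 250
ENSEMBLE_MAX_UNDETECTED = 1.0 / 3.0
ENSEMBLE_MAX_FAILED_TRIALS = 0.5
TRIAL_MAX_TARGET_FAILURES = 0.5

_CELL_RULES = ("cell_off_target", "cell_prev_stimulated", "cell_artifact", "cell_unmatched")


class SchemaError(KeyError):
    """A required flag column is missing from an input table."""


def _require(df: pd.DataFrame, cols, table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{table} table lacks required columns: {missing}")


@dataclass
class ExclusionResult:
    trials: pd.DataFrame
    cells: pd.DataFrame
    ensembles: pd.DataFrame
    pairs: pd.DataFrame
    audit: dict = field(default_factory=dict)


def _member_ids(row) -> list:
    return [type(row["first_member_dtype"])(x) for x in row]


def _parse_members(ensembles: pd.DataFrame, cells: pd.DataFrame) -> dict:
    dtype = cells["cell_id"].dtype.type
    out = {}
    for _, row in ensembles.iterrows():
        out[row["ensemble_id"]] = [dtype(tok) for tok in str(row["member_ids"]).split(";")]
    return out


class _EnsembleView:
    """Adapter exposing target_ids / target_xyz for off_target_mask."""

    def __init__(self, target_ids, cells: pd.DataFrame):
        self.target_ids = list(target_ids)
        sub = cells.set_index("cell_id").reindex(self.target_ids)
        self.target_xyz = sub[["x", "y", "z"]].to_numpy(float)
        self.matched = sub["matched"].to_numpy(bool) if "matched" in sub else None


def _trial_ok(trials: pd.DataFrame, cfg: AnalysisConfig) -> pd.DataFrame:
    """Per-trial pass/fail for each trial-level rule (stim trials)."""
    run_bad = trials["run_speed_max"].to_numpy(float) > cfg.run_speed_max_cms
    frac_fail = 1.0 - trials["n_targets_ok"].to_numpy(float) / trials[
        "n_targets"
    ].to_numpy(float)
    fail_bad = frac_fail >= TRIAL_MAX_TARGET_FAILURES
    shift_bad = trials["reg_shift_um"].to_numpy(float) > cfg.reg_shift_max_um
    return pd.DataFrame(
        {
            "trial_running": run_bad,
            "trial_target_failures": fail_bad,
            "trial_registration_shift": shift_bad,
        },
        index=trials.index,
    )


def apply_exclusions(
    trials: pd.DataFrame,
    cells: pd.DataFrame,
    ensembles: pd.DataFrame,
    config: AnalysisConfig | None = None,
) -> ExclusionResult:
    """Filter FOVs, ensembles, trials and (cell, trial) pairs; audit removals.

    Returns an :class:`ExclusionResult` whose ``pairs`` table holds one row
    per included (trial, cell) combination (columns ``trial_id``,
    ``ensemble_id``, ``cell_id``, ``fov_id``) ready to be joined with
    responses; ``audit`` counts removals per rule (FOVs, ensembles and trials
    in their own units, cell rules in (cell, trial) pairs).  Applying the
    function to its own output is a no-op.
    """
    cfg = config or AnalysisConfig()
    _require(cells, ["cell_id", "fov_id", "plane", "x", "y", "z", "matched",
                     "artifact_occluded", "visually_responsive"], "cells")
    _require(trials, ["trial_id", "fov_id", "ensemble_id", "kind",
                      "run_speed_max", "reg_shift_um", "n_targets",
                      "n_targets_ok"], "trials")
    _require(ensembles, ["ensemble_id", "fov_id", "member_ids"], "ensembles")

    audit: dict[str, int] = {}
    trials = trials.sort_values(["fov_id", "start_frame" if "start_frame" in trials else "trial_id"])
    stim = trials[trials["kind"] == "stim"].copy()

    # ---- FOV level -------------------------------------------------------
    fov_ids = sorted(cells["fov_id"].unique())
    bad_fovs: set = set()
    low_vis = running = few = 0
    for fov in fov_ids:
        fc = cells[cells["fov_id"] == fov]
        ft = trials[trials["fov_id"] == fov]
        vis_frac = fc["visually_responsive"].mean() if len(fc) else 0.0
        run_frac = (
            (ft["run_speed_max"] > cfg.run_speed_max_cms).mean() if len(ft) else 0.0
        )
        if vis_frac < FOV_MIN_VISUAL_FRACTION:
            low_vis += 1
            bad_fovs.add(fov)
        if run_frac > FOV_MAX_RUNNING_FRACTION:
            running += 1
            bad_fovs.add(fov)
        if len(fc) < FOV_MIN_CELLS:
            few += 1
            bad_fovs.add(fov)
    audit["fov_low_visual"] = low_vis
    audit["fov_running"] = running
    audit["fov_few_cells"] = few
    cells = cells[~cells["fov_id"].isin(bad_fovs)]
    ensembles = ensembles[~ensembles["fov_id"].isin(bad_fovs)]
    stim = stim[~stim["fov_id"].isin(bad_fovs)]

    # ---- Ensemble level --------------------------------------------------
    members = _parse_members(ensembles, cells) if len(cells) else {}
    views = {eid: _EnsembleView(m, cells) for eid, m in members.items()}
    trial_flags = _trial_ok(stim, cfg)
    trial_bad_own = trial_flags.any(axis=1)
    undetected = failed = few_reps = 0
    bad_ens: set = set()
    for eid, view in views.items():
        etrials = stim["ensemble_id"] == eid
        n_attempted = int(etrials.sum())
        frac_undet = (
            float(np.mean(~view.matched)) if view.matched is not None else 0.0
        )
        frac_fail = (
            1.0
            - stim.loc[etrials, "n_targets_ok"].sum()
            / stim.loc[etrials, "n_targets"].sum()
            if n_attempted
            else 1.0
        )
        fail_trial_frac = (
            trial_flags.loc[etrials[etrials].index, "trial_target_failures"].mean()
            if n_attempted
            else 1.0
        )
        n_good = int((etrials & ~trial_bad_own).sum())
        if frac_undet > ENSEMBLE_MAX_UNDETECTED:
            undetected += 1
            bad_ens.add(eid)
        if fail_trial_frac > ENSEMBLE_MAX_FAILED_TRIALS or frac_fail > ENSEMBLE_MAX_FAILED_TRIALS:
            failed += 1
            bad_ens.add(eid)
        if n_good < cfg.min_repetitions:
            few_reps += 1
            bad_ens.add(eid)
    audit["ensemble_undetected"] = undetected
    audit["ensemble_failed_trials"] = failed
    audit["ensemble_few_repetitions"] = few_reps
    ensembles = ensembles[~ensembles["ensemble_id"].isin(bad_ens)]
    cascade = stim["ensemble_id"].isin(bad_ens)
    audit["trial_cascade_ensemble"] = int(cascade.sum())
    stim = stim[~cascade]
    trial_flags = trial_flags.loc[stim.index]

    # ---- Trial level -----------------------------------------------------
    for rule in ("trial_running", "trial_target_failures", "trial_registration_shift"):
        audit[rule] = int(trial_flags[rule].sum())
    stim = stim[~trial_flags.any(axis=1)]

    # ---- Cell level (per kept trial) ------------------------------------
    ot_masks = {
        eid: off_target_mask(
            cells[cells["fov_id"] == ensembles.set_index("ensemble_id").loc[eid, "fov_id"]],
            view,
            radial_um=cfg.off_target_radial_um,
            adjacent_um=cfg.off_target_adjacent_um,
        )
        for eid, view in views.items()
        if eid in set(ensembles["ensemble_id"])
    }
    counts = dict.fromkeys(_CELL_RULES, 0)
    rows = []
    for fov in sorted(stim["fov_id"].unique()):
        fc = cells[cells["fov_id"] == fov]
        cid = fc["cell_id"].to_numpy()
        unmatched = ~fc["matched"].to_numpy(bool)
        artifact = fc["artifact_occluded"].to_numpy(bool)
        ftr = stim[stim["fov_id"] == fov]
        prev_targets: set = set()
        for _, tr in ftr.iterrows():
            eid = tr["ensemble_id"]
            off = ot_masks[eid]
            prev = fc["cell_id"].isin(prev_targets).to_numpy()
            reason = np.full(len(fc), 0)  # 0 keep, else 1-based rule index
            for k, mask in enumerate((off, prev, artifact, unmatched), start=1):
                reason = np.where((reason == 0) & mask, k, reason)
            for k, rule in enumerate(_CELL_RULES, start=1):
                counts[rule] += int((reason == k).sum())
            keep = reason == 0
            rows.append(
                pd.DataFrame(
                    {
                        "trial_id": tr["trial_id"],
                        "ensemble_id": eid,
                        "fov_id": fov,
                        "cell_id": cid[keep],
                    }
                )
            )
            prev_targets = set(members[eid])
    audit.update(counts)
    pairs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["trial_id", "ensemble_id", "fov_id", "cell_id"])
    )
    return ExclusionResult(
        trials=stim.reset_index(drop=True),
        cells=cells.reset_index(drop=True),
        ensembles=ensembles.reset_index(drop=True),
        pairs=pairs,
        audit=audit,
    )
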