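"""Reading and writing the on-disk experiment layout.

An experiment directory holds ``cells.csv``, ``ensembles.csv``,
``trials.csv`` and ``traces.h5`` (datasets ``/F``, ``/Fneu``,
``/run_speed``; attribute ``frame_rate_hz``).  Response fields are written
to HDF5 with the grid metadata as attributes.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from holostim.ensembles import Ensemble
from holostim.fields import FieldState


def write_experiment(exp, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    exp.cells.to_csv(out / "cells.csv", index=False)
    exp.ensembles_frame.to_csv(out / "ensembles.csv", index=False)
    exp.recording.trials.to_csv(out / "trials.csv", index=False)
    with h5py.File(out / "traces.h5", "w") as h5:
        h5.create_dataset("F", data=exp.recording.f_cell, compression="gzip")
        h5.create_dataset("Fneu", data=exp.recording.f_neuropil, compression="gzip")
        h5.create_dataset("run_speed", data=exp.recording.run_speed)
        h5.attrs["frame_rate_hz"] = exp.recording.frame_rate_hz


def read_traces(path: str | Path):
    with h5py.File(path, "r") as h5:
        return (
            h5["F"][...],
            h5["Fneu"][...],
            h5["run_speed"][...] if "run_speed" in h5 else None,
            float(h5.attrs["frame_rate_hz"]),
        )


def read_experiment(directory: str | Path):
    d = Path(directory)
    cells = pd.read_csv(d / "cells.csv")
    ensembles = pd.read_csv(d / "ensembles.csv")
    trials = pd.read_csv(d / "trials.csv")
    f, fneu, run_speed, rate = read_traces(d / "traces.h5")
    return cells, ensembles, trials, f, fneu, run_speed, rate


def ensembles_from_frame(df: pd.DataFrame, cells: pd.DataFrame) -> list[Ensemble]:
    """Rebuild Ensemble objects from the ensembles.csv schema."""
    out = []
    lookup = cells.set_index("cell_id")
    for _, row in df.iterrows():
        ids = [type(cells["cell_id"].iloc[0])(tok) for tok in str(row["member_ids"]).split(";")]
        xyz = lookup.loc[ids, ["x", "y", "z"]].to_numpy(float)
        out.append(
            Ensemble(
                ensemble_id=int(row["ensemble_id"]),
                target_ids=ids,
                target_xyz=xyz,
                spread=float(row["spread_um"]),
                ensemble_osi=float(row["ensemble_osi"]),
                mean_osi=float(row["mean_osi"]),
                ensemble_po=float(row["ensemble_po"]),
                spatial_class=str(row.get("spatial_class", "")) or "",
                tuning_class=str(row.get("tuning_class", "")) or "",
            )
        )
    return out


def write_field(field: FieldState, path: str | Path, pathways=None) -> None:
    """Response field (and optional pathway decomposition) to HDF5."""
    with h5py.File(path, "w") as h5:
        h5.create_dataset("delta_r", data=field.values, compression="gzip")
        h5.attrs["grid_spacing"] = field.grid_spacing
        h5.attrs["domain_size"] = field.domain_size
        h5.attrs["theta_levels"] = field.theta_levels
        if pathways is not None:
            grp = h5.create_group("pathways")
            for name in ("mono_ee", "di_eee", "di_eie"):
                grp.create_dataset(
                    name, data=getattr(pathways, name).values, compression="gzip"
                )


def read_field(path: str | Path) -> FieldState:
    with h5py.File(path, "r") as h5:
        return FieldState(
            h5["delta_r"][...],
            float(h5.attrs["grid_spacing"]),
            float(h5.attrs["domain_size"]),
            np.asarray(h5.attrs["theta_levels"]),
        )


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
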