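"""Distance metrics, off-target zones and distance-resolved response curves."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


def min_target_distance(
    cell_xyz,
    target_xyz,
    metric: str = "3d",
) -> float | np.ndarray:
    """Minimal distance from cell(s) to any attempted target (um).

    Distances are Euclidean in 3-D by default (imaging planes are 30 um
    apart, so a cell directly above a target one plane away is 30 um from
    it); ``metric='2d'`` ignores the axial coordinate.
    """
    cells = np.atleast_2d(np.asarray(cell_xyz, dtype=float))
    targets = np.atleast_2d(np.asarray(target_xyz, dtype=float))
    if metric == "2d":
        cells = cells[:, :2]
        targets = targets[:, :2]
    elif metric != "3d":
        raise ValueError("metric must be '3d' or '2d'")
    diff = cells[:, None, :] - targets[None, :, :]
    d = np.sqrt((diff**2).sum(-1)).min(axis=1)
    return float(d[0]) if np.asarray(cell_xyz).ndim == 1 else d


def off_target_mask(
    cells: pd.DataFrame,
    ensemble,
    radial_um: float = 15.0,
    adjacent_um: float = 30.0,
) -> np.ndarray:
    """Flag cells at risk of stray-light activation by an ensemble's hologram.

    A cell is off-target if its in-plane radial distance to any target on
    the same imaging plane is below ``radial_um``, or below ``adjacent_um``
    to a target exactly one plane away.  Targets themselves are always
    flagged (they are excluded from nontarget analyses).

    ``cells`` needs columns ``cell_id``, ``plane``, ``x``, ``y``; ``ensemble``
    provides ``target_ids``, ``target_xyz`` and (via the table) target planes.
    """
    cxy = cells[["x", "y"]].to_numpy(float)
    cplane = cells["plane"].to_numpy(int)
    target_ids = set(ensemble.target_ids)
    txyz = np.atleast_2d(np.asarray(ensemble.target_xyz, dtype=float))
    if txyz.shape[1] < 3:
        raise ValueError("off_target_mask needs 3-D target coordinates")
    # infer target plane from z assuming uniform plane spacing in the table
    planes = np.unique(cells["plane"])
    zs = np.array([cells.loc[cells["plane"] == p, "z"].iloc[0] for p in planes])
    tplane = np.array([planes[np.argmin(np.abs(zs - z))] for z in txyz[:, 2]])

    excluded = cells["cell_id"].isin(target_ids).to_numpy()
    for (tx, ty, _tz), tp in zip(txyz, tplane):
        radial = np.hypot(cxy[:, 0] - tx, cxy[:, 1] - ty)
        dplane = np.abs(cplane - tp)
        excluded |= (dplane == 0) & (radial < radial_um)
        excluded |= (dplane == 1) & (radial < adjacent_um)
    return excluded


@dataclass
class DistanceCurve:
    """Binned mean response versus minimal distance to the ensemble."""

    bin_edges: np.ndarray
    mean: np.ndarray
    sem: np.ndarray
    n: np.ndarray
    group: str | None = None

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_center_um": self.bin_centers,
                "group": self.group if self.group is not None else "all",
                "mean": self.mean,
                "sem": self.sem,
                "n": self.n,
            }
        )


def _bin_one(df: pd.DataFrame, edges: np.ndarray, group: str | None) -> DistanceCurve:
    idx = np.digitize(df["min_dist"].to_numpy(float), edges) - 1
    k = len(edges) - 1
    mean = np.full(k, np.nan)
    sem = np.full(k, np.nan)
    n = np.zeros(k, dtype=int)
    resp = df["response"].to_numpy(float)
    for b in range(k):
        v = resp[idx == b]
        n[b] = v.size
        if v.size:
            mean[b] = v.mean()
        if v.size > 1:
            sem[b] = v.std(ddof=1) / np.sqrt(v.size)
    return DistanceCurve(edges, mean, sem, n, group=group)


def distance_response_curve(
    pairs: pd.DataFrame,
    bin_width: float = 15.0,
    max_distance: float | None = None,
    grouping: str | None = None,
):
    """Bin per-(cell, ensemble) responses by minimal target distance.

    ``pairs`` is a long table with at least ``min_dist`` and ``response``
    columns (one row per included cell x ensemble combination).  Bins are
    contiguous with edges {0, 15, 30, ...}; empty bins are reported as
    missing, not zero.  With ``grouping`` set to a column name (e.g. a
    relative-tuning label) one curve per group value is returned as a dict.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if max_distance is None:
        max_distance = float(pairs["min_dist"].max())
    edges = np.arange(0.0, max_distance + bin_width, bin_width)
    if grouping is None:
        return _bin_one(pairs, edges, None)
    return {
        str(g): _bin_one(sub, edges, str(g))
        for g, sub in pairs.groupby(grouping, sort=True)
    }
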