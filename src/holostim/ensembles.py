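"""Ensemble metrics, classification and the discrete design optimizer.

An ensemble is a set of (typically ten) opsin-positive cells stimulated
together by one multi-target hologram.  Ensembles are characterized by their
spatial spread (mean pairwise 3-D distance among targets), their ensemble
OSI (the OSI of the elementwise mean tuning curve) and the mean of their
members' individual OSIs; those metrics drive the compact/diffuse and
cotuned/untuned classifications used throughout the analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from holostim.config import EnsembleSpec
from holostim.tuning import fold_directions, osi_from_folded

SPREAD_COMPACT_UM = 200.0
COTUNED_ENSEMBLE_OSI = 0.7
UNTUNED_ENSEMBLE_OSI = 0.3
MEAN_OSI_SPLIT = 0.5


def mean_pairwise_spread(points) -> float:
    """Mean pairwise Euclidean 3-D distance among target centers (um)."""
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    if pts.shape[0] < 2:
        raise ValueError("spread needs at least two points")
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(pts.shape[0], 1)
    return float(d[iu].mean())


def ensemble_osi(tuning_curves) -> tuple[float, float, float]:
    """(ensemble_osi, ensemble_po, mean_osi) from member direction curves.

    The ensemble OSI is the OSI of the elementwise mean tuning curve; the
    mean OSI is the arithmetic mean of the members' individual OSIs.
    """
    curves = np.atleast_2d(np.asarray(tuning_curves, dtype=float))
    mean_curve = curves.mean(axis=0)
    ens_osi, ens_po, _ = osi_from_folded(fold_directions(mean_curve))
    member = [osi_from_folded(fold_directions(c))[0] for c in curves]
    return ens_osi, ens_po, float(np.mean(member))


@dataclass
class Ensemble:
    """One designed stimulation ensemble with its derived metrics."""

    ensemble_id: int
    target_ids: list
    target_xyz: np.ndarray
    spread: float
    ensemble_osi: float
    mean_osi: float
    ensemble_po: float
    spatial_class: str = field(default="", compare=False)
    tuning_class: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        self.target_xyz = np.asarray(self.target_xyz, dtype=float)
        if len(self.target_ids) < 3:
            raise ValueError("an ensemble must contain at least three targets")
        if not self.spatial_class or not self.tuning_class:
            self.spatial_class, self.tuning_class = classify_ensemble(self)


def classify_ensemble(ens) -> tuple[str, str]:
    """(spatial_class, tuning_class) from the spread and OSI metrics.

    Compact means spread < 200 um, diffuse otherwise.  Cotuned requires
    ensemble OSI > 0.7 and mean OSI > 0.5; untuned requires ensemble
    OSI < 0.3 and mean OSI < 0.5; anything in between is mixed.
    """
    spatial = "compact" if ens.spread < SPREAD_COMPACT_UM else "diffuse"
    if ens.ensemble_osi > COTUNED_ENSEMBLE_OSI and ens.mean_osi > MEAN_OSI_SPLIT:
        tuning = "cotuned"
    elif ens.ensemble_osi < UNTUNED_ENSEMBLE_OSI and ens.mean_osi < MEAN_OSI_SPLIT:
        tuning = "untuned"
    else:
        tuning = "mixed"
    return spatial, tuning


def _window_center(window) -> float:
    return 0.5 * (window[0] + window[1])


class _Pool:
    """Pre-extracted candidate arrays for fast cost evaluation."""

    def __init__(self, candidates: pd.DataFrame):
        required = {"cell_id", "x", "y", "z"}
        missing = required - set(candidates.columns)
        if missing:
            raise ValueError(f"candidate table lacks columns: {sorted(missing)}")
        self.df = candidates.reset_index(drop=True)
        self.xyz = self.df[["x", "y", "z"]].to_numpy(float)
        tc_cols = [c for c in self.df.columns if c.startswith("tc_")]
        if tc_cols:
            self.curves = self.df[tc_cols].to_numpy(float)
            self.member_osi = np.array(
                [osi_from_folded(fold_directions(c))[0] for c in self.curves]
            )
        else:
            self.curves = np.ones((len(self.df), 8))
            self.member_osi = np.zeros(len(self.df))
        self.power = (
            self.df["power"].to_numpy(float)
            if "power" in self.df
            else np.zeros(len(self.df))
        )
        self.visual = (
            self.df["visually_responsive"].to_numpy(bool)
            if "visually_responsive" in self.df
            else np.ones(len(self.df), bool)
        )
        self.n = len(self.df)


def _feasible(pool: _Pool, members: np.ndarray, min_dist: float) -> bool:
    pts = pool.xyz[members]
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(members), 1)
    return bool((d[iu] >= min_dist).all())


def _ensemble_cost(pool: _Pool, members: np.ndarray, spec: EnsembleSpec) -> float:
    pts = pool.xyz[members]
    spread = mean_pairwise_spread(pts)
    ens_osi, _, mean_osi = ensemble_osi(pool.curves[members])
    cost = 0.0
    sc = _window_center(spec.target_spread_window)
    cost += spec.weight_spread * ((spread - sc) / max(sc, 1.0)) ** 2
    cost += spec.weight_ensemble_osi * (
        ens_osi - _window_center(spec.target_ensemble_osi_window)
    ) ** 2
    cost += spec.weight_mean_osi * (
        mean_osi - _window_center(spec.target_mean_osi_window)
    ) ** 2
    # (6) soft reward for spacing members out: penalize pairs closer than
    # twice the hard minimum
    diff = pts[:, None, :] - pts[None, :, :]
    d = np.sqrt((diff**2).sum(-1))
    iu = np.triu_indices(len(members), 1)
    soft = 2 * spec.min_within_pair_distance
    crowd = np.clip(soft - d[iu], 0.0, None) / soft
    cost += spec.weight_spacing * float((crowd**2).mean())
    cost += spec.weight_power * float(pool.power[members].mean())
    cost -= spec.weight_visual * float(pool.visual[members].mean())
    return cost


def _total_cost(pool: _Pool, assign: list[np.ndarray], spec: EnsembleSpec) -> float:
    cost = sum(_ensemble_cost(pool, m, spec) for m in assign)
    # (1) distinctness: Jaccard overlap between every ensemble pair
    sets = [set(m.tolist()) for m in assign]
    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            inter = len(sets[i] & sets[j])
            union = len(sets[i] | sets[j])
            cost += spec.weight_overlap * inter / union
    # (2) reuse of individual cells across ensembles
    counts = np.bincount(np.concatenate(assign), minlength=pool.n)
    cost += spec.weight_reuse * float(((counts - 1).clip(0) ** 2).sum())
    return cost


def _random_feasible(
    pool: _Pool, rng: np.random.Generator, spec: EnsembleSpec
) -> np.ndarray | None:
    for _ in range(300):
        order = rng.permutation(pool.n)
        picked: list[int] = []
        for idx in order:
            if len(picked) == spec.ensemble_size:
                break
            trial = np.array(picked + [idx])
            if _feasible(pool, trial, spec.min_within_pair_distance):
                picked.append(int(idx))
        if len(picked) == spec.ensemble_size:
            return np.array(sorted(picked))
    return None


def _to_ensembles(pool: _Pool, assign: list[np.ndarray]) -> list[Ensemble]:
    out = []
    for eid, members in enumerate(assign):
        members = np.sort(members)
        ens_osi, ens_po, mean_osi = ensemble_osi(pool.curves[members])
        out.append(
            Ensemble(
                ensemble_id=eid,
                target_ids=pool.df["cell_id"].to_numpy()[members].tolist(),
                target_xyz=pool.xyz[members],
                spread=mean_pairwise_spread(pool.xyz[members]),
                ensemble_osi=ens_osi,
                mean_osi=mean_osi,
                ensemble_po=ens_po,
            )
        )
    return out


def optimize_ensembles(
    candidates: pd.DataFrame,
    spec: EnsembleSpec,
    return_cost: bool = False,
):
    """Select stimulation ensembles from a candidate pool by greedy swaps.

    The search runs ``spec.n_restarts`` random restarts; each restart builds
    a feasible random assignment (hard constraint: no two members of one
    ensemble within ``min_within_pair_distance``) and then repeatedly swaps a
    single member for an unused-or-reusable candidate, accepting only
    cost-decreasing moves, until the iteration cap or a stall.  The weighted
    cost combines the nine design criteria (distinctness, reuse, power,
    visual responsiveness, spacing, spread window, ensemble-OSI window,
    mean-OSI window); ties are broken by candidate order and all randomness
    flows from ``spec.random_seed``.
    """
    pool = _Pool(candidates)
    if pool.n < spec.ensemble_size:
        raise ValueError("candidate pool smaller than one ensemble")
    rng = np.random.default_rng(spec.random_seed)
    best_assign = None
    best_cost = np.inf
    for _ in range(spec.n_restarts):
        assign = []
        for _k in range(spec.n_ensembles):
            m = _random_feasible(pool, rng, spec)
            if m is None:
                raise ValueError(
                    "infeasible hard constraint: cannot place "
                    f"{spec.ensemble_size} cells >= {spec.min_within_pair_distance} um apart"
                )
            assign.append(m)
        cost = _total_cost(pool, assign, spec)
        stall = 0
        for _it in range(spec.max_iterations):
            if stall >= spec.stall_iterations:
                break
            e = int(rng.integers(spec.n_ensembles))
            slot = int(rng.integers(spec.ensemble_size))
            cand = int(rng.integers(pool.n))
            if cand in assign[e]:
                stall += 1
                continue
            proposal = assign[e].copy()
            proposal[slot] = cand
            if not _feasible(pool, proposal, spec.min_within_pair_distance):
                stall += 1
                continue
            new_assign = list(assign)
            new_assign[e] = proposal
            new_cost = _total_cost(pool, new_assign, spec)
            if new_cost < cost:
                assign, cost = new_assign, new_cost
                stall = 0
            else:
                stall += 1
        if cost < best_cost:
            best_cost, best_assign = cost, [m.copy() for m in assign]
    result = _to_ensembles(pool, best_assign)
    if return_cost:
        return result, float(best_cost)
    return result


def ensembles_to_frame(ensembles: list[Ensemble]) -> pd.DataFrame:
    """Flatten Ensemble objects into the ensembles.csv table schema."""
    rows = []
    for e in ensembles:
        rows.append(
            {
                "ensemble_id": e.ensemble_id,
                "member_ids": ";".join(str(i) for i in e.target_ids),
                "spread_um": e.spread,
                "ensemble_osi": e.ensemble_osi,
                "mean_osi": e.mean_osi,
                "ensemble_po": e.ensemble_po,
                "spatial_class": e.spatial_class,
                "tuning_class": e.tuning_class,
            }
        )
    return pd.DataFrame(rows)
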