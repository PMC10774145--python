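"""Ensemble metrics, classification and the swap-based design optimizer."""

import itertools

import numpy as np
import pandas as pd
import pytest

from holostim.config import EnsembleSpec
from holostim.ensembles import (
    classify_ensemble,
    ensemble_osi,
    mean_pairwise_spread,
    optimize_ensembles,
)
from holostim.synth import tuning_curve_from_osi


class TestSpread:
    def test_two_points(self):
        assert mean_pairwise_spread([[0, 0, 0], [100, 0, 0]]) == pytest.approx(100.0)

    def test_coincident_points(self):
        assert mean_pairwise_spread([[5, 5, 5]] * 4) == 0.0

    def test_equilateral_triangle(self):
        h = 60 * np.sqrt(3) / 2
        pts = [[0, 0, 0], [60, 0, 0], [30, h, 0]]
        assert mean_pairwise_spread(pts) == pytest.approx(60.0)

    def test_uses_three_dimensions(self):
        assert mean_pairwise_spread([[0, 0, 0], [0, 0, 30]]) == pytest.approx(30.0)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mean_pairwise_spread([[0, 0, 0]])


class TestEnsembleOsi:
    def test_identical_members_match_member_osi(self):
        curve = tuning_curve_from_osi(45.0, 0.8, 1.0)
        e_osi, e_po, m_osi = ensemble_osi([curve] * 5)
        assert e_osi == pytest.approx(0.8, abs=1e-9)
        assert m_osi == pytest.approx(0.8, abs=1e-9)
        assert e_po == 45.0

    def test_orthogonal_members_cancel(self):
        c0 = tuning_curve_from_osi(0.0, 1.0, 1.0)
        c90 = tuning_curve_from_osi(90.0, 1.0, 1.0)
        e_osi, _, m_osi = ensemble_osi([c0, c90])
        assert e_osi == pytest.approx(0.0, abs=1e-9)
        assert m_osi == pytest.approx(1.0, abs=1e-9)

    def test_osi_formula_on_folded_values(self):
        # folded responses 1.0 at pref, 0.5 at ortho -> OSI 1/3
        curve = np.array([1.0, 0.75, 0.5, 0.75] * 2)
        e_osi, _, _ = ensemble_osi([curve])
        assert e_osi == pytest.approx(1.0 / 3.0)


class _E:
    def __init__(self, spread, ens_osi, mean_osi):
        self.spread = spread
        self.ensemble_osi = ens_osi
        self.mean_osi = mean_osi


class TestClassification:
    @pytest.mark.parametrize(
        "spread,eosi,mosi,expected",
        [
            (150, 0.8, 0.6, ("compact", "cotuned")),
            (250, 0.2, 0.3, ("diffuse", "untuned")),
            (250, 0.5, 0.9, ("diffuse", "mixed")),
            (199.9, 0.5, 0.1, ("compact", "mixed")),
            (150, 0.8, 0.4, ("compact", "mixed")),  # high ens OSI, low mean OSI
            (150, 0.2, 0.6, ("compact", "mixed")),  # low ens OSI, high mean OSI
        ],
    )
    def test_threshold_table(self, spread, eosi, mosi, expected):
        assert classify_ensemble(_E(spread, eosi, mosi)) == expected


def _pool(n=120, seed=5, jitter=True):
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {
            "cell_id": np.arange(n),
            "x": rng.uniform(0, 700, n),
            "y": rng.uniform(0, 700, n),
            "z": rng.choice([0.0, 30.0, 60.0], n),
            "power": rng.uniform(10, 100, n),
            "visually_responsive": rng.random(n) < 0.6,
        }
    )
    po = rng.choice([0.0, 45.0, 90.0, 135.0], n)
    osi = rng.beta(2, 2, n)
    curves = np.stack(
        [tuning_curve_from_osi(p, o, 1.0) for p, o in zip(po, osi)]
    )
    for j in range(curves.shape[1]):
        df[f"tc_{j}"] = curves[:, j]
    return df


def _fast_spec(**kw):
    base = dict(n_restarts=3, max_iterations=800, stall_iterations=200)
    base.update(kw)
    return EnsembleSpec(**base)


class TestOptimizer:
    def test_hard_constraint_always_satisfied(self):
        spec = _fast_spec(n_ensembles=3, random_seed=4)
        ensembles = optimize_ensembles(_pool(), spec)
        for e in ensembles:
            d = e.target_xyz[:, None, :] - e.target_xyz[None, :, :]
            dist = np.sqrt((d**2).sum(-1))
            iu = np.triu_indices(len(e.target_ids), 1)
            assert dist[iu].min() >= spec.min_within_pair_distance

    def test_deterministic_given_seed(self):
        spec = _fast_spec(n_ensembles=2, random_seed=9)
        a = optimize_ensembles(_pool(), spec)
        b = optimize_ensembles(_pool(), spec)
        assert [e.target_ids for e in a] == [e.target_ids for e in b]

    def test_seed_robustness_of_cost_on_large_pool(self):
        # different seeds land within 10% of each other's cost (500-cell pool)
        pool = _pool(n=500, seed=7)
        costs = []
        for seed in (0, 1):
            spec = _fast_spec(n_ensembles=2, random_seed=seed,
                              target_spread_window=(150.0, 250.0))
            _, cost = optimize_ensembles(pool, spec, return_cost=True)
            costs.append(cost)
        ref = max(abs(c) for c in costs)
        assert abs(costs[0] - costs[1]) <= 0.1 * ref

    def test_single_feasible_assignment_is_returned(self):
        # pool of exactly ensemble_size cells, all pairwise-far: unique answer
        pts = np.array(list(itertools.product([0, 300, 600], repeat=2)))[:5]
        df = pd.DataFrame(
            {
                "cell_id": np.arange(5),
                "x": pts[:, 0].astype(float),
                "y": pts[:, 1].astype(float),
                "z": 0.0,
            }
        )
        spec = _fast_spec(n_ensembles=1, ensemble_size=5, random_seed=0)
        (ens,) = optimize_ensembles(df, spec)
        assert sorted(ens.target_ids) == [0, 1, 2, 3, 4]

    def test_infeasible_pool_raises(self):
        df = pd.DataFrame(
            {
                "cell_id": np.arange(10),
                "x": np.linspace(0, 9, 10),  # all within 10 um
                "y": 0.0,
                "z": 0.0,
            }
        )
        with pytest.raises(ValueError, match="infeasible|pool"):
            optimize_ensembles(df, _fast_spec(n_ensembles=1, ensemble_size=5))

    def test_windows_met_on_feasible_pool_vs_rejection_oracle(self):
        # Rejection-sampling oracle: verify the pool admits assignments in the
        # requested windows, then check the optimizer finds one.
        pool = _pool(n=200, seed=3)
        spec = _fast_spec(
            n_ensembles=1,
            random_seed=2,
            target_spread_window=(250.0, 350.0),
            weight_spread=50.0,
        )
        rng = np.random.default_rng(0)
        xyz = pool[["x", "y", "z"]].to_numpy()
        feasible = False
        for _ in range(3000):
            idx = rng.choice(len(pool), 10, replace=False)
            d = xyz[idx][:, None] - xyz[idx][None]
            dist = np.sqrt((d**2).sum(-1))
            iu = np.triu_indices(10, 1)
            if dist[iu].min() < 30:
                continue
            s = dist[iu].mean()
            if 250 <= s <= 350:
                feasible = True
                break
        assert feasible, "oracle could not find a feasible assignment"
        (ens,) = optimize_ensembles(pool, spec)
        assert 250 <= ens.spread <= 350

    def test_compact_cotuned_request_yields_compact_cotuned(self):
        # candidates rich in high-OSI cells at every orientation
        rng = np.random.default_rng(12)
        n = 250
        po = rng.choice([0.0, 45.0, 90.0, 135.0], n)
        osi = rng.uniform(0.6, 0.95, n)
        df = pd.DataFrame(
            {
                "cell_id": np.arange(n),
                "x": rng.uniform(0, 600, n),
                "y": rng.uniform(0, 600, n),
                "z": rng.choice([0.0, 30.0, 60.0], n),
            }
        )
        curves = np.stack([tuning_curve_from_osi(p, o, 1.0) for p, o in zip(po, osi)])
        # cotuned pool: bias toward one orientation
        curves[po != 0.0] *= 0.4
        for j in range(curves.shape[1]):
            df[f"tc_{j}"] = curves[:, j]
        spec = _fast_spec(
            n_ensembles=3,
            random_seed=1,
            target_spread_window=(100.0, 190.0),
            target_ensemble_osi_window=(0.75, 1.0),
            target_mean_osi_window=(0.6, 1.0),
            weight_spread=30.0,
            weight_ensemble_osi=30.0,
            weight_mean_osi=30.0,
        )
        ensembles = optimize_ensembles(df, spec)
        from holostim.ensembles import classify_ensemble

        labels = [classify_ensemble(e) for e in ensembles]
        good = sum(lab == ("compact", "cotuned") for lab in labels)
        assert good >= 0.9 * len(labels)
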