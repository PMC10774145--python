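"""Neural-field model: kernels, solver oracles and symmetry properties."""

import numpy as np
import pytest

from holostim.config import FeatureKernelParams, ModelConfig, ParameterError
from holostim.fields import FieldState, fold_orientation
from holostim.model import (
    StabilityError,
    build_connectivity,
    decompose_pathways,
    feature_kernel,
    predict_cell_responses,
    solve_linear_response,
    spatial_kernel,
    spectral_radius,
    stim_field,
)


class TestSpatialKernel:
    def test_pure_broad_peak_value(self):
        # single Gaussian at r=0: 1/(2 pi sigma^2)
        val = spatial_kernel(0.0, 100.0, 10.0, 0.0)
        assert val == pytest.approx(1.0 / (2 * np.pi * 100.0**2), rel=1e-12)

    def test_narrow_gaussian_ratio_at_one_sigma(self):
        v0 = spatial_kernel(0.0, 100.0, 10.0, 1.0)
        v1 = spatial_kernel(10.0, 100.0, 10.0, 1.0)
        assert v1 / v0 == pytest.approx(np.exp(-0.5), rel=1e-12)

    def test_integrates_to_one_over_plane(self):
        # fine grid out to +-6 sigma_broad
        h = 1.0
        x = np.arange(-600, 600 + h, h)
        xx, yy = np.meshgrid(x, x)
        r = np.hypot(xx, yy)
        total = spatial_kernel(r, 100.0, 10.0, 0.3).sum() * h * h
        assert total == pytest.approx(1.0, abs=1e-3)

    def test_rejects_bad_sigma(self):
        with pytest.raises(ParameterError):
            spatial_kernel(1.0, -5.0, 10.0, 0.2)


class TestFeatureKernel:
    def test_peak_is_r0_plus_rp(self):
        p = FeatureKernelParams(r0=0.1, rp=0.9, sigma_theta=30.0)
        assert feature_kernel(0.0, p) == pytest.approx(1.0)

    def test_untuned_limit_is_flat(self):
        p = FeatureKernelParams(r0=0.7, rp=0.0, sigma_theta=30.0)
        vals = feature_kernel(np.array([0.0, 30.0, 90.0]), p)
        assert np.allclose(vals, 0.7)

    def test_orthogonal_value(self):
        p = FeatureKernelParams(r0=0.1, rp=0.9, sigma_theta=30.0)
        assert feature_kernel(90.0, p) == pytest.approx(0.1 + 0.9 * np.exp(-4.5), rel=1e-9)

    def test_monotone_nonincreasing(self):
        p = FeatureKernelParams(r0=0.2, rp=0.8, sigma_theta=25.0)
        v = feature_kernel(np.linspace(0, 90, 50), p)
        assert np.all(np.diff(v) <= 1e-15)

    def test_requires_folded_input(self):
        with pytest.raises(ValueError):
            feature_kernel(120.0, FeatureKernelParams())


class TestConnectivity:
    def test_discrete_mass_equals_effective_weight(self, small_model_config):
        conn = build_connectivity(small_model_config)
        assert conn.weight("ee") == pytest.approx(small_model_config.w_ee, abs=1e-6)
        assert conn.weight("ei") == pytest.approx(-small_model_config.w_eie, abs=1e-6)
        assert conn.weight("ie") == pytest.approx(1.0, abs=1e-6)

    def test_separability(self, small_model_config):
        # kernel(x, dtheta) = spatial part * feature part everywhere
        conn = build_connectivity(small_model_config)
        k = conn.kernels["ee"]
        spatial = k[:, :, 0]
        ratio = k[5, 3, :] / k[5, 3, 0]
        assert np.allclose(k, spatial[:, :, None] * ratio[None, None, :])

    def test_untuned_config_theta_independent(self, small_model_config):
        cfg = small_model_config.replace(
            feature_ee=FeatureKernelParams.untuned(),
            feature_ei=FeatureKernelParams.untuned(),
            feature_ie=FeatureKernelParams.untuned(),
        )
        conn = build_connectivity(cfg)
        k = conn.kernels["ee"]
        assert np.allclose(k - k[:, :, :1], 0.0)

    def test_unresolvable_narrow_scale_rejected(self):
        with pytest.raises(ParameterError):
            ModelConfig(grid_spacing=20.0, sigma_e_narrow=15.0, kappa_e=0.3)


class TestStimField:
    def test_single_target_mass(self, small_model_config):
        f = stim_field([(100.0, 100.0, 0.0)], small_model_config)
        assert f.integral() == pytest.approx(10.0)

    def test_ten_targets_mass(self, small_model_config):
        targets = [(16.0 * i, 32.0, 45.0) for i in range(10)]
        f = stim_field(targets, small_model_config)
        assert f.integral() == pytest.approx(100.0)

    def test_snapping_to_nearest_node(self):
        cfg = ModelConfig(domain_size=64.0, grid_spacing=4.0, kappa_e=0.0)
        f = stim_field([(3.0, 3.0, 0.0)], cfg)
        assert f.values[1, 1, 0] > 0  # node at (4, 4)
        assert f.values[0, 0, 0] == 0

    def test_empty_target_list_is_zero_field(self, small_model_config):
        f = stim_field([], small_model_config)
        assert f.integral() == 0.0

    def test_outside_domain_rejected(self, small_model_config):
        with pytest.raises(ValueError):
            stim_field([(9999.0, 0.0, 0.0)], small_model_config)


def _dense_operator(conn, config):
    """Real-space dense matrix of the full 2-population operator."""
    n = config.n_grid
    nt = config.n_orientations
    dim = n * n * nt
    blocks = {}
    for name in ("ee", "ei", "ie"):
        k = conn.kernels[name] * config.grid_spacing**2
        mat = np.zeros((dim, dim))
        for i in range(n):
            for j in range(n):
                for t in range(nt):
                    row = (i * n + j) * nt + t
                    shifted = np.roll(np.roll(np.roll(k, i, 0), j, 1), t, 2)
                    mat[row] = shifted.reshape(-1)
        blocks[name] = mat
    zero = np.zeros((dim, dim))
    return np.block([[blocks["ee"], blocks["ei"]], [blocks["ie"], zero]])


class TestSolver:
    def test_zero_stim_gives_zero_response(self, small_model_config):
        conn = build_connectivity(small_model_config)
        f = FieldState.zeros(small_model_config)
        r = solve_linear_response(conn, f, small_model_config)
        assert np.allclose(r.values, 0.0)

    def test_linearity(self, small_model_config):
        conn = build_connectivity(small_model_config)
        f1 = stim_field([(64.0, 64.0, 0.0)], small_model_config)
        f2 = stim_field([(128.0, 192.0, 90.0)], small_model_config)
        both = f1 + f2
        r1 = solve_linear_response(conn, f1, small_model_config)
        r2 = solve_linear_response(conn, f2, small_model_config)
        r12 = solve_linear_response(conn, both, small_model_config)
        assert np.allclose(r12.values, r1.values + r2.values, atol=1e-10)
        r2x = solve_linear_response(conn, 2.0 * f1, small_model_config)
        assert np.allclose(r2x.values, 2 * r1.values, atol=1e-12)

    @pytest.mark.parametrize("mode", ["expansion", "exact"])
    def test_fourier_matches_dense_oracle(self, mode):
        cfg = ModelConfig(
            domain_size=128.0,
            grid_spacing=8.0,
            n_orientations=4,
            sigma_e_broad=40.0,
            sigma_i_broad=30.0,
            sigma_e_narrow=10.0,
            sigma_i_narrow=10.0,
            expansion_order=mode,
        )
        conn = build_connectivity(cfg)
        stim = stim_field([(64.0, 64.0, 0.0), (32.0, 96.0, 45.0)], cfg)
        resp = solve_linear_response(conn, stim, cfg)

        w = _dense_operator(conn, cfg)
        s = np.concatenate([stim.values.reshape(-1), np.zeros(stim.values.size)])
        if mode == "exact":
            full = np.linalg.solve(np.eye(len(w)) - w, w @ s)
        else:
            full = w @ s + w @ (w @ s)
        dense = full[: stim.values.size].reshape(stim.values.shape)
        rel = np.linalg.norm(resp.values - dense) / np.linalg.norm(dense)
        assert rel < 1e-8

    def test_expansion_error_scales_linearly_in_weights(self, small_model_config):
        # || exact - expansion || / || exact || = O(eps) as weights shrink
        rels = []
        for eps in (0.5, 0.25, 0.125):
            cfg = small_model_config.replace(
                w_ee=small_model_config.w_ee * eps,
                w_eie=small_model_config.w_eie * eps,
            )
            conn = build_connectivity(cfg)
            stim = stim_field([(128.0, 128.0, 0.0)], cfg)
            exact = solve_linear_response(conn, stim, cfg.replace(expansion_order="exact"))
            approx = solve_linear_response(conn, stim, cfg)
            rels.append(
                np.linalg.norm(exact.values - approx.values)
                / np.linalg.norm(exact.values)
            )
        assert rels[0] > rels[1] > rels[2]
        # halving eps should roughly halve the relative error (O(eps))
        assert rels[1] / rels[0] < 0.7
        assert rels[2] / rels[1] < 0.7

    def test_translation_equivariance(self, small_model_config):
        cfg = small_model_config
        conn = build_connectivity(cfg)
        shift_nodes = 3
        dx = shift_nodes * cfg.grid_spacing
        r1 = solve_linear_response(conn, stim_field([(64.0, 96.0, 0.0)], cfg), cfg)
        r2 = solve_linear_response(
            conn, stim_field([(64.0 + dx, 96.0, 0.0)], cfg), cfg
        )
        assert np.allclose(np.roll(r1.values, shift_nodes, axis=0), r2.values, atol=1e-12)

    def test_untuned_symmetry_across_theta(self, small_model_config):
        cfg = small_model_config.replace(
            feature_ee=FeatureKernelParams.untuned(),
            feature_ei=FeatureKernelParams.untuned(),
            feature_ie=FeatureKernelParams.untuned(),
        )
        conn = build_connectivity(cfg)
        # stimulate every orientation level equally -> response flat in theta
        targets = [(128.0, 128.0, t) for t in (0.0, 45.0, 90.0, 135.0)]
        r = solve_linear_response(conn, stim_field(targets, cfg), cfg)
        assert np.allclose(r.values - r.values[:, :, :1], 0.0, atol=1e-12)

    def test_unstable_weights_raise_in_exact_mode(self, small_model_config):
        cfg = small_model_config.replace(w_ee=3.0, expansion_order="exact")
        conn = build_connectivity(cfg)
        rho, _ = spectral_radius(conn)
        assert rho >= 1.0
        with pytest.raises(StabilityError):
            solve_linear_response(conn, stim_field([(64.0, 64.0, 0.0)], cfg), cfg)


class TestPathways:
    def test_total_equals_sum_and_solver(self, small_model_config):
        conn = build_connectivity(small_model_config)
        stim = stim_field([(64.0, 64.0, 0.0)], small_model_config)
        pw = decompose_pathways(conn, stim, small_model_config)
        assert np.allclose(
            pw.total.values,
            pw.mono_ee.values + pw.di_eee.values + pw.di_eie.values,
        )
        resp = solve_linear_response(conn, stim, small_model_config)
        assert np.allclose(pw.total.values, resp.values, atol=1e-14)

    def test_no_inhibition_means_no_di_eie(self, small_model_config):
        cfg = small_model_config.replace(w_eie=0.0)
        conn = build_connectivity(cfg)
        pw = decompose_pathways(conn, stim_field([(64.0, 64.0, 0.0)], cfg), cfg)
        assert np.allclose(pw.di_eie.values, 0.0)

    def test_mono_term_is_broad_gaussian_for_point_stim(self):
        # kappa=0, untuned: mono pathway = w * g_broad centered on the target
        cfg = ModelConfig(
            domain_size=512.0,
            grid_spacing=8.0,
            kappa_e=0.0,
            sigma_e_broad=60.0,
            feature_ee=FeatureKernelParams.untuned(),
            feature_ei=FeatureKernelParams.untuned(),
            feature_ie=FeatureKernelParams.untuned(),
        )
        conn = build_connectivity(cfg)
        stim = stim_field([(256.0, 256.0, 0.0)], cfg)
        pw = decompose_pathways(conn, stim, cfg)
        prof = pw.mono_ee.values.sum(axis=2)
        i0 = 32
        line = prof[i0, i0:]
        r = np.arange(len(line)) * cfg.grid_spacing
        expected = np.exp(-(r**2) / (2 * cfg.sigma_e_broad**2))
        assert np.allclose(line / line[0], expected, atol=0.02)

    def test_di_eie_is_nonpositive_everywhere(self, small_model_config):
        conn = build_connectivity(small_model_config)
        pw = decompose_pathways(
            conn, stim_field([(64.0, 64.0, 0.0)], small_model_config), small_model_config
        )
        assert pw.di_eie.values.max() <= 1e-15


class TestPredictCellResponses:
    def _population(self, n=50, seed=0):
        import pandas as pd

        rng = np.random.default_rng(seed)
        return pd.DataFrame(
            {
                "x": rng.uniform(0, 400, n),
                "y": rng.uniform(0, 400, n),
                "po": rng.choice([0.0, 45.0, 90.0, 135.0], n),
            }
        )

    def test_untuned_network_ignores_cell_preference(self, small_model_config):
        cfg = small_model_config.replace(
            domain_size=512.0,
            grid_spacing=16.0,
            feature_ee=FeatureKernelParams.untuned(),
            feature_ei=FeatureKernelParams.untuned(),
            feature_ie=FeatureKernelParams.untuned(),
        )
        pop = self._population()
        targets = np.array([[200.0, 200.0], [240.0, 200.0], [200.0, 260.0]])
        base = predict_cell_responses(pop, targets, cfg, fov_size=400.0)
        rotated = pop.assign(po=(pop["po"] + 45.0) % 180.0)
        other = predict_cell_responses(rotated, targets, cfg, fov_size=400.0)
        assert np.allclose(base, other, atol=1e-12)

    def test_cells_at_targets_receive_peak_mono_drive(self):
        cfg = ModelConfig(domain_size=512.0, grid_spacing=8.0)
        import pandas as pd

        targets = np.array([[200.0, 200.0]])
        pop = pd.DataFrame(
            {"x": [200.0, 280.0, 120.0], "y": [200.0, 200.0, 330.0], "po": [0.0, 0.0, 0.0]}
        )
        out = predict_cell_responses(pop, targets, cfg, fov_size=400.0)
        assert out[0] > out[1] and out[0] > out[2]

    def test_fold_orientation_roundtrip(self):
        assert fold_orientation(135.0) == 45.0
        assert fold_orientation(-45.0) == 45.0
        assert fold_orientation(270.0) == 90.0
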