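import numpy as np
import pytest

from v1gamma import (
    ModelParams,
    SimSpec,
    StimulusSpec,
    build_hc_kernel,
    center_index,
    compute_mua,
    extract_lfp,
    lgn_drive,
    rectify,
    simulate,
)
from v1gamma.network import Trajectory, activation_mask, grid_coordinates


class TestRectify:
    @pytest.mark.parametrize("x, expected", [(2.5, 2.5), (-3.0, 0.0), (0.0, 0.0)])
    def test_scalar_branches(self, x, expected):
        assert rectify(np.float64(x)) == expected

    def test_elementwise(self):
        out = rectify(np.array([-1.0, 0.0, 2.0]))
        assert np.array_equal(out, [0.0, 0.0, 2.0])


class TestKernel:
    def test_diagonal_excluded(self, table1_params):
        k = build_hc_kernel(table1_params.replace(w_ee_hc=1.0), "E")
        assert np.all(np.diag(k) == 0.0)

    def test_gaussian_decay_values(self):
        # direct evaluation of W exp(-d^2/(2 sigma^2)) / sigma
        p = ModelParams(w_ee_hc=1.0, sigma_hc=4.0, grid_rows=1, grid_cols=25)
        k = build_hc_kernel(p, "E")
        assert k[0, 4] == pytest.approx(np.exp(-0.5) / 4.0, rel=1e-12)  # dist 4
        assert k[0, 24] == pytest.approx(np.exp(-576.0 / 32.0) / 4.0, rel=1e-12)
        p20 = ModelParams(w_ee_hc=1.0, sigma_hc=4.0, grid_rows=1, grid_cols=21)
        assert build_hc_kernel(p20, "E")[0, 20] == pytest.approx(
            np.exp(-12.5) / 4.0, rel=1e-12
        )

    def test_target_selects_amplitude(self, table1_params):
        p = table1_params.replace(w_ee_hc=0.5, w_ie_hc=2.0)
        k_e = build_hc_kernel(p, "E")
        k_i = build_hc_kernel(p, "I")
        assert np.allclose(k_i, 4.0 * k_e)
        with pytest.raises(ValueError):
            build_hc_kernel(p, "G")

    def test_symmetric_and_distance_monotone(self, table1_params):
        k = build_hc_kernel(table1_params.replace(w_ee_hc=1.0), "E")
        assert np.allclose(k, k.T)
        c = center_index(table1_params)
        coords = grid_coordinates(table1_params)
        d = np.linalg.norm(coords - coords[c], axis=1)
        order = np.argsort(d)
        assert np.all(np.diff(k[c][order][1:]) <= 1e-15)


class TestCenterAndZone:
    def test_odd_grid_center(self, table1_params):
        # 1-based (8, 8) on a 15x15 grid
        assert center_index(table1_params) == 7 * 15 + 7

    def test_even_grid_floor_convention(self):
        p = ModelParams(grid_rows=4, grid_cols=4)
        # floor((4+1)/2) = 2 (1-based) -> 0-based row/col 1
        assert center_index(p) == 1 * 4 + 1

    def test_activation_zone_radius(self, table1_params):
        mask0 = activation_mask(table1_params, StimulusSpec(radius=0.0))
        assert mask0.sum() == 1 and mask0[center_index(table1_params)]
        mask1 = activation_mask(table1_params, StimulusSpec(radius=1.0))
        assert mask1.sum() == 5  # centre plus 4-neighbourhood
        full = activation_mask(table1_params, StimulusSpec.full_field())
        assert full.all()


class TestLgnDrive:
    def test_sample_statistics(self, table1_params):
        stim = StimulusSpec(radius=3.0, rate_in=40.0, rate_out=0.0, noise_sd=1.0)
        sim = SimSpec(duration=0.5, discard=0.0, repeats=1, seed=0)
        rng = np.random.default_rng(7)
        r_e, _ = lgn_drive(stim, table1_params, sim, rng)
        mask = activation_mask(table1_params, stim)
        inside = r_e[:, mask].ravel()
        outside = r_e[:, ~mask].ravel()
        assert inside.mean() == pytest.approx(40.0, abs=0.02)
        assert inside.std() == pytest.approx(1.0, rel=0.01)
        assert outside.mean() == pytest.approx(0.0, abs=0.02)
        assert outside.std() == pytest.approx(1.0, rel=0.01)

    def test_e_and_i_streams_independent(self, table1_params):
        stim = StimulusSpec.full_field()
        sim = SimSpec(duration=0.2, discard=0.0, repeats=1, seed=0)
        r_e, r_i = lgn_drive(stim, table1_params, sim, np.random.default_rng(1))
        corr = np.corrcoef(r_e.ravel(), r_i.ravel())[0, 1]
        assert abs(corr) < 0.02

    def test_identical_seed_bit_identical(self, table1_params):
        stim = StimulusSpec.full_field()
        sim = SimSpec(duration=0.2, discard=0.0, repeats=1, seed=0)
        a = lgn_drive(stim, table1_params, sim, np.random.default_rng(5))
        b = lgn_drive(stim, table1_params, sim, np.random.default_rng(5))
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])


class TestSimulate:
    def test_leak_only_decay_matches_closed_form(self, small_params):
        p = small_params.replace(
            w_ee_rc=0.0, w_ei_rc=0.0, w_ie_rc=0.0, w_ii_rc=0.0,
            w_el=0.0, w_il=0.0, w_ge=0.0,
        )
        sim = SimSpec(duration=0.06, discard=0.0, repeats=1, seed=0)
        traj = simulate(p, StimulusSpec(rate_in=0.0, noise_sd=0.0), sim,
                        init=(1.0, 0.0, 0.0))
        steps = np.arange(1, sim.n_steps + 1)
        euler = (1.0 - sim.dt / p.tau_e) ** steps
        exact = np.exp(-steps * sim.dt / p.tau_e)
        assert np.allclose(traj.lfp[0], euler, rtol=1e-12)
        # global Euler error of exponential decay is bounded by
        # dt * max_t |t f''| / 2 = dt * e^-1 / (2 tau) at this step size
        err = np.max(np.abs(traj.lfp[0] - exact))
        assert err < sim.dt * np.exp(-1.0) / (2 * p.tau_e) * 1.1
        # first order: halving dt roughly halves the error
        sim2 = SimSpec(dt=sim.dt / 2, duration=sim.duration, discard=0.0,
                       repeats=1, seed=0)
        traj2 = simulate(p, StimulusSpec(rate_in=0.0, noise_sd=0.0), sim2,
                         init=(1.0, 0.0, 0.0))
        exact2 = np.exp(-np.arange(1, sim2.n_steps + 1) * sim2.dt / p.tau_e)
        err2 = np.max(np.abs(traj2.lfp[0] - exact2))
        assert err2 == pytest.approx(err / 2, rel=0.2)

    def test_fb_ablation_bit_equivalent(self, small_params, full_field, quick_sim):
        with_hc = small_params.replace(w_ee_hc=0.02, w_ie_hc=1.5)
        no_fb = with_hc.replace(w_eg=0.0, w_ig=0.0)
        # G influences nothing when its feedback weights vanish; even the
        # feed-forward weight onto G may differ without changing E/I
        no_g = no_fb.replace(w_ge=0.0)
        a = simulate(no_fb, full_field, quick_sim)
        b = simulate(no_g, full_field, quick_sim)
        assert np.array_equal(a.lfp, b.lfp)
        assert np.array_equal(a.mua_e, b.mua_e)

    def test_noise_free_pipeline_deterministic(self, small_params, quick_sim):
        stim = StimulusSpec.full_field(noise_sd=0.0)
        a = simulate(small_params, stim, quick_sim)
        b = simulate(small_params, stim, quick_sim.replace(seed=999))
        assert np.array_equal(a.lfp, b.lfp)
        # all repeats identical without noise
        assert np.array_equal(a.lfp[0], a.lfp[-1])

    def test_same_seed_bit_identical(self, small_params, full_field, quick_sim):
        a = simulate(small_params, full_field, quick_sim)
        b = simulate(small_params, full_field, quick_sim)
        assert np.array_equal(a.lfp, b.lfp)
        assert np.array_equal(a.g, b.g)

    def test_repeats_differ_with_noise(self, small_params, full_field, quick_sim):
        traj = simulate(small_params, full_field, quick_sim)
        assert not np.array_equal(traj.lfp[0], traj.lfp[1])

    def test_interior_units_statistically_homogeneous(self, table1_params, full_field):
        """Full-field drive with HC on: time-averaged rectified activity of
        interior units differs only by sampling error."""
        p = table1_params.replace(w_ee_hc=0.01, w_ie_hc=0.5)
        sim = SimSpec(duration=0.8, discard=0.2, repeats=2, seed=11)
        traj = simulate(p, full_field, sim, record_full=True)
        e = traj.full_state[:, sim.n_discard :, 0, :]  # (rep, t, unit)
        means = np.maximum(e, 0.0).mean(axis=(0, 1))
        grid = means.reshape(15, 15)
        interior = grid[5:10, 5:10].ravel()
        assert interior.std() / interior.mean() < 0.05

    def test_overflow_flagged_not_nan(self, small_params, full_field):
        # runaway self-excitation must be caught by the guard
        p = small_params.replace(w_ee_rc=40.0, overflow=1e4)
        sim = SimSpec(duration=0.3, discard=0.1, repeats=2, seed=3)
        traj = simulate(p, full_field, sim)
        assert traj.unstable.all()
        assert np.isfinite(traj.lfp).all()

    def test_stability_envelope_predicted_by_reduction(self, table1_params,
                                                       full_field):
        """Within the stated HC/FB ranges the simulation stays below the
        overflow bound wherever the linear reduction is stable, and the
        guard fires where the reduction predicts exponential growth
        (excitation-dominated feedback with no inhibitory feedback)."""
        from v1gamma import reduce_fb_matrix

        sim = SimSpec(repeats=2, seed=5)
        stable_corners = [
            dict(w_ee_hc=0.03, w_ie_hc=4.5),
            dict(w_ee_hc=0.03, w_ie_hc=4.5, w_eg=0.27, w_ig=0.45),
            dict(w_eg=0.09, w_ig=0.0),
        ]
        for kw in stable_corners:
            fb_only = {k: v for k, v in kw.items() if k.startswith("w_eg")
                       or k.startswith("w_ig")}
            rs = reduce_fb_matrix(table1_params.replace(**fb_only))
            assert rs.eigenvalues.real.max() < 0
            traj = simulate(table1_params.replace(**kw), full_field, sim)
            assert not traj.any_unstable, kw
        runaway = dict(w_eg=0.27, w_ig=0.0)
        rs = reduce_fb_matrix(table1_params.replace(**runaway))
        assert rs.eigenvalues.real.max() > 0
        traj = simulate(table1_params.replace(**runaway), full_field, sim)
        assert traj.unstable.all()


class TestLfpAndMua:
    def test_lfp_is_central_unit_analysis_window(self, small_params, full_field,
                                                 quick_sim):
        traj = simulate(small_params, full_field, quick_sim, record_full=True)
        lfp = extract_lfp(traj)
        n_analysis = quick_sim.n_steps - quick_sim.n_discard
        assert lfp.shape == (quick_sim.repeats, n_analysis)
        from v1gamma import center_index

        c = center_index(small_params)
        assert np.array_equal(
            lfp, traj.full_state[:, quick_sim.n_discard :, 0, c]
        )

    def test_default_protocol_window_is_one_second(self, table1_params):
        sim = SimSpec()  # 1.3 s, discard 0.3 s
        assert sim.n_steps - sim.n_discard == 1000

    @pytest.mark.parametrize(
        "series, expected",
        [
            (np.full(10, 2.0), 2.0),
            (np.full(10, -1.0), 0.0),
            (np.tile([1.0, -1.0], 5), 0.5),
        ],
    )
    def test_mua_rectified_time_average(self, series, expected):
        sim = SimSpec(duration=0.01, discard=0.0, repeats=1)
        p = ModelParams(grid_rows=1, grid_cols=1)
        traj = Trajectory(
            times=np.arange(10) * 0.001,
            lfp=series[None, :],
            g=series[None, :],
            mua_e=np.array([np.maximum(series, 0).mean()]),
            mua_g=np.array([np.maximum(series, 0).mean()]),
            unstable=np.zeros(1, bool),
            params=p, stim=StimulusSpec(), sim=sim,
        )
        mua_e, mua_g = compute_mua(traj)
        assert mua_e == pytest.approx(expected)
        assert mua_g == pytest.approx(expected)

    def test_mua_nonnegative_from_simulation(self, small_params, full_field,
                                             quick_sim):
        traj = simulate(small_params, full_field, quick_sim)
        assert (traj.mua_e >= 0).all() and (traj.mua_g >= 0).all()
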