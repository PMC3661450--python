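"""Cortical network: firing functions, connectivity geometry, dynamics."""

from dataclasses import replace

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from v1bright import (
    ModelParams,
    build_connectivity,
    g_x,
    g_y,
    run_static,
)
from v1bright.network import CorticalNetwork, _lateral_tables


class TestFiringFunctions:
    def test_gx_piecewise(self):
        p = ModelParams()
        assert g_x(np.array(p.Tx), p) == 0.0
        assert g_x(np.array(p.Tx + 0.5), p) == 0.5
        assert g_x(np.array(p.Tx + 5.0), p) == 1.0
        assert g_x(np.array(p.Tx - 2.0), p) == 0.0

    def test_gy_threshold_and_monotonicity(self):
        p = ModelParams()
        assert g_y(np.array(p.Ty), p) == 0.0
        ys = np.linspace(-1, 4, 200)
        vals = g_y(ys, p)
        assert np.all(np.diff(vals) >= 0)

    def test_gy_knee_slope_change(self):
        p = ModelParams()
        h = 1e-4
        k = p.Ty + p.gy_knee
        lo = (g_y(np.array(k - h), p) - g_y(np.array(k - 2 * h), p)) / h
        hi = (g_y(np.array(k + 2 * h), p) - g_y(np.array(k + h), p)) / h
        assert lo == pytest.approx(p.gy_slopes[0], rel=1e-6)
        assert hi == pytest.approx(p.gy_slopes[1], rel=1e-6)


@pytest.fixture(scope="module")
def kernel():
    return build_connectivity(ModelParams(), n_scales=4)


class TestConnectivity:

    def test_collinear_pair_is_excitatory_only(self, kernel):
        R = kernel.radius
        # two horizontal units displaced horizontally by 3 grid units
        assert kernel.J[0, 0, R, R + 3] > 0.0
        assert kernel.W[0, 0, R, R + 3] == 0.0

    def test_parallel_flankers_are_inhibitory_only(self, kernel):
        R = kernel.radius
        # two horizontal units displaced vertically by 3 grid units
        assert kernel.W[0, 0, R + 3, R] > 0.0
        assert kernel.J[0, 0, R + 3, R] == 0.0

    def test_geometry_is_disjoint(self, kernel):
        assert np.all(kernel.J * kernel.W == 0.0)

    def test_reciprocity(self, kernel):
        flipped = kernel.J[:, :, ::-1, ::-1]
        np.testing.assert_allclose(kernel.J, flipped.transpose(1, 0, 2, 3),
                                   atol=1e-12)
        flipped_w = kernel.W[:, :, ::-1, ::-1]
        np.testing.assert_allclose(kernel.W, flipped_w.transpose(1, 0, 2, 3),
                                   atol=1e-12)

    def test_mirror_maps_diagonal_tables(self, kernel):
        # flipping columns swaps 45 and 135 deg orientations
        m = [0, 3, 2, 1]
        for which in ("J", "W"):
            tab = getattr(kernel, which)
            np.testing.assert_allclose(
                tab, tab[np.ix_(m, m)][..., :, ::-1], atol=1e-12
            )

    def test_scale_factor_gaussian_tail(self, kernel):
        assert kernel.Gs[0, 0] == 1.0
        assert np.all(np.diag(kernel.Gs) == 1.0)
        np.testing.assert_allclose(kernel.Gs, kernel.Gs.T)
        assert kernel.Gs[0, 3] == 0.0  # |ds| = 3 beyond the 2-octave cutoff
        assert kernel.Gs[0, 0] > kernel.Gs[0, 1] > kernel.Gs[0, 2] > 0.0

    def test_small_radius_rejected(self):
        with pytest.raises(ValueError):
            build_connectivity(replace(ModelParams(), conn_radius=1))

    def test_dilated_tables_conserve_total_weight(self):
        # dilation spreads the same continuous profile over a denser grid;
        # weight / dilation^2 keeps the summed input comparable
        p = ModelParams()
        j1, w1 = _lateral_tables(p, 1.0)
        j2, w2 = _lateral_tables(p, 2.0)
        assert j2.sum() == pytest.approx(j1.sum(), rel=0.3)
        assert w2.sum() == pytest.approx(w1.sum(), rel=0.3)


def _uniform_hypercolumn_fixed_point(p: ModelParams):
    """Context-free rest state: x* = I0 - sum_dtheta psi * g_y(Ic), y* = Ic
    (subthreshold branch, g_x = 0)."""
    psi_sum = p.psi[0] + 2 * p.psi[1] + p.psi[2]
    y_star = p.Ic
    x_star = p.I0 - psi_sum * float(g_y(np.array(y_star), p))
    return x_star, y_star


class TestDynamics:
    def test_zero_drive_settles_to_subthreshold_fixed_point(self, quiet_params):
        p = replace(quiet_params, settle_time=60.0)
        kernel = build_connectivity(p, n_scales=2)
        drive = np.zeros((2, 2, 4, 8, 8), dtype=np.float32)
        resp = run_static(drive, kernel, p)
        x_star, _ = _uniform_hypercolumn_fixed_point(p)
        assert x_star < p.Tx
        np.testing.assert_allclose(resp.alpha, 0.0, atol=1e-6)
        net = CorticalNetwork(kernel, p, (8, 8))
        state = net.initial_state(drive)
        for _ in range(600):
            net.step(state, drive)
        np.testing.assert_allclose(state.x, x_star, atol=1e-4)
        np.testing.assert_allclose(state.y, p.Ic, atol=1e-4)

    def test_isolated_unit_matches_reference_integration(self, quiet_params):
        """A single driven unit (lateral connections off) against a
        high-accuracy integration of the reduced hypercolumn ODE system."""
        p = quiet_params
        kernel = build_connectivity(p, n_scales=1)
        d0 = 2.0
        drive = np.zeros((2, 1, 4, 1, 1), dtype=np.float32)
        drive[0, 0, 2, 0, 0] = d0

        def rhs(_, u):
            # driven unit (x1,y1); 45-deg neighbors (xa,ya); orthogonal (xb,yb)
            x1, y1, xa, ya, xb, yb = u
            gx1, gxa, gxb = (float(g_x(np.array(v), p)) for v in (x1, xa, xb))
            gy1, gya, gyb = (float(g_y(np.array(v), p)) for v in (y1, ya, yb))
            pool = p.norm_strength * ((gx1 + 2 * gxa + gxb) / 4.0) ** 2
            ps = p.psi
            dx1 = -x1 - (ps[0] * gy1 + 2 * ps[1] * gya + ps[2] * gyb) \
                + p.J0 * gx1 + d0 + p.I0
            dy1 = -y1 + gx1 + p.Ic + pool
            dxa = -xa - (ps[0] * gya + ps[1] * (gy1 + gyb) + ps[2] * gya) \
                + p.J0 * gxa + p.I0
            dya = -ya + gxa + p.Ic + pool
            dxb = -xb - (ps[0] * gyb + 2 * ps[1] * gya + ps[2] * gy1) \
                + p.J0 * gxb + p.I0
            dyb = -yb + gxb + p.Ic + pool
            return [dx1, dy1, dxa, dya, dxb, dyb]

        net = CorticalNetwork(kernel, p, (1, 1), disable_lateral=True)
        state = net.initial_state(drive)
        n_steps = int(round(50.0 / p.dt))
        for _ in range(n_steps):
            net.step(state, drive)
        sol = solve_ivp(rhs, (0.0, 50.0), [d0, 0.0, 0.0, 0.0, 0.0, 0.0],
                        rtol=1e-10, atol=1e-12, dense_output=True)
        ref = sol.y[:, -1]
        assert abs(state.x[0, 0, 2, 0, 0] - ref[0]) < 1e-3
        assert abs(state.y[0, 0, 2, 0, 0] - ref[1]) < 1e-3
        assert abs(state.x[0, 0, 0, 0, 0] - ref[4]) < 1e-3

    def test_step_halving_changes_average_by_less_than_1pct(self, small_params):
        """Doubling the Euler step leaves the cycle-aligned steady-state
        average of the oscillatory SBC response within 1%."""
        from v1bright import make_sbc, decompose, rectify_normalize
        from v1bright.analysis import cycle_aligned_mean

        img = make_sbc(16, 0.25, 1.0, 0.0, 0.5)  # 16 x 32
        pyr = decompose(img, n_scales=2)
        drive = rectify_normalize(pyr)
        kernel = build_connectivity(small_params, n_scales=2)
        outs = {}
        for dt in (0.05, 0.025):
            p = replace(small_params, dt=dt, settle_time=20.0, avg_window=40.0)
            outs[dt] = cycle_aligned_mean(run_static(drive, kernel, p).trace)
        assert abs(outs[0.05] - outs[0.025]) / outs[0.025] < 0.01

    def test_bounded_activity_over_long_run(self, small_params, rng):
        p = small_params
        kernel = build_connectivity(p, n_scales=1)
        drive = (3.0 * rng.random((2, 1, 4, 16, 16))).astype(np.float32)
        net = CorticalNetwork(kernel, p, (16, 16))
        state = net.initial_state(drive)
        for i in range(5000):  # 500 tau
            net.step(state, drive)
        assert np.isfinite(state.x).all() and np.isfinite(state.y).all()
        gx = g_x(state.x, p)
        assert gx.min() >= 0.0 and gx.max() <= 1.0


@pytest.fixture(scope="module")
def equivariance_setup():
    p = replace(
        ModelParams(),
        noise_amp=0.0,
        boundary="wrap",
        settle_time=8.0,
        avg_window=6.0,
        conn_radius=4,
        max_reach_px=8,
    )
    kernel = build_connectivity(p, n_scales=2)
    rng = np.random.default_rng(7)
    drive = np.zeros((2, 2, 4, 24, 24), dtype=np.float32)
    mask = rng.random((2, 2, 4, 24, 24)) < 0.05
    drive[mask] = (1.0 + 2.0 * rng.random(mask.sum())).astype(np.float32)
    return p, kernel, drive


class TestEquivariance:
    def test_translation_equivariance_periodic(self, equivariance_setup):
        p, kernel, drive = equivariance_setup
        shift = (5, 9)
        a = run_static(drive, kernel, p).alpha
        b = run_static(np.roll(drive, shift, axis=(-2, -1)), kernel, p).alpha
        np.testing.assert_allclose(b, np.roll(a, shift, axis=(-2, -1)), atol=2e-5)

    def test_mirror_equivariance(self, equivariance_setup):
        p, kernel, drive = equivariance_setup
        m = [0, 3, 2, 1]  # horizontal mirror swaps the two diagonals
        mirrored = drive[:, :, m][..., ::-1].copy()
        a = run_static(drive, kernel, p).alpha
        b = run_static(mirrored, kernel, p).alpha
        np.testing.assert_allclose(b, a[:, :, m][..., ::-1], atol=2e-5)

    def test_polarity_swap_is_exact(self, equivariance_setup):
        p, kernel, drive = equivariance_setup
        a = run_static(drive, kernel, p).alpha
        b = run_static(drive[::-1].copy(), kernel, p).alpha
        np.testing.assert_array_equal(b, a[::-1])
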