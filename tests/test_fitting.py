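import numpy as np
import pytest

import lutloc
from lutloc import fitting
from lutloc.fitting import FitParams, Termination


def make_window(table, bg, p, dx, dy, z):
    """Noiseless window rendered from the grid template at (dx, dy, z)."""
    c = table.spec.center
    k = table.index_of(c + dx, c + dy, z)
    return bg + p * table.templates[k, :, :, 0], c


def center_candidate(window, bg):
    m = window.shape[0] // 2
    return lutloc.Candidate(0, m, m, float(window.max()), bg,
                            score=float(window[m - 1:m + 2, m - 1:m + 2].mean()))


class TestGaussNewtonStep:
    def test_zero_residual_is_fixed_point(self, default_table):
        win, c = make_window(default_table, 100.0, 2000.0, 0.2, -0.3, 50.0)
        theta = FitParams(100.0, 2000.0, c + 0.2, c - 0.3, 50.0)
        new, res = fitting.gauss_newton_step(win, default_table, theta)
        assert res == pytest.approx(0.0, abs=1e-9)
        assert (new.x, new.y, new.z) == (theta.x, theta.y, theta.z)
        assert new.bg == pytest.approx(theta.bg, abs=1e-9)
        assert new.p == pytest.approx(theta.p, abs=1e-9)

    def test_matches_pseudo_inverse_oracle(self, default_table, rng):
        """Update equals an explicit full-pinv least-squares solve."""
        spec = default_table.spec
        c = spec.center
        for _ in range(25):
            win = rng.uniform(50, 3000, (spec.window, spec.window))
            theta = FitParams(float(rng.uniform(0, 200)),
                              float(rng.uniform(500, 3000)),
                              c + round(rng.uniform(-1, 1), 1),
                              c + round(rng.uniform(-1, 1), 1),
                              25.0 * round(rng.uniform(-10, 10)))
            k = default_table.index_of(theta.x, theta.y, theta.z)
            t, tx, ty, tz = lutloc.template_at(default_table, k)
            J = np.column_stack([np.ones(t.size), t.ravel(),
                                 theta.p * tx.ravel(), theta.p * ty.ravel(),
                                 theta.p * tz.ravel()])
            assert np.abs(J.T @ J - (J.T @ J).T).max() == 0.0
            r = win.ravel() - (theta.bg + theta.p * t.ravel())
            delta = np.linalg.pinv(J) @ r
            new, _ = fitting.gauss_newton_step(win, default_table, theta)
            assert new.bg == pytest.approx(theta.bg + delta[0], rel=1e-8)
            assert new.p == pytest.approx(theta.p + delta[1], rel=1e-8)
            # positions are rounded back to the grid
            exp = fitting._snap(default_table, theta.x + delta[2],
                                theta.y + delta[3], theta.z + delta[4])
            assert (new.x, new.y, new.z) == pytest.approx(exp)


class TestFitEmitter:
    def test_noiseless_on_grid_exact_recovery(self, default_table):
        win, c = make_window(default_table, 100.0, 2000.0, 0.2, -0.3, 50.0)
        res = fitting.fit_emitter(win, default_table,
                                  center_candidate(win, 100.0))
        assert res.termination is Termination.CONVERGED
        m = default_table.spec.window // 2
        assert res.params.x - m == pytest.approx(0.2)
        assert res.params.y - m == pytest.approx(-0.3)
        assert res.params.z == pytest.approx(50.0)
        assert res.params.bg == pytest.approx(100.0, rel=1e-6)
        assert res.params.p == pytest.approx(2000.0, rel=1e-6)

    def test_noiseless_off_grid_lands_on_adjacent_step(self, default_table,
                                                       calib):
        """True x = +0.23 px (step 0.1) must fit to +0.2 or +0.3."""
        spec = default_table.spec
        c = spec.center
        ii, jj = np.meshgrid(np.arange(9.), np.arange(9.), indexing="ij")
        win = 100.0 + 2000.0 * lutloc.psf_value(c + 0.23, c, 40.0, calib,
                                                ii, jj)
        res = fitting.fit_emitter(win, default_table,
                                  center_candidate(win, 100.0))
        m = spec.window // 2
        assert min(abs(res.params.x - m - 0.2),
                   abs(res.params.x - m - 0.3)) < 1e-9
        assert abs(res.params.y - m) <= spec.dxy / 2 + 1e-9
        assert abs(res.params.z - 40.0) <= spec.dz / 2 + 1e-9

    def test_positions_stay_on_grid(self, default_table, rng):
        spec = default_table.spec
        m = spec.window // 2
        for _ in range(10):
            win, c = make_window(default_table, 100.0, 2000.0,
                                 round(rng.uniform(-0.5, 0.5), 1),
                                 round(rng.uniform(-0.5, 0.5), 1),
                                 25.0 * round(rng.uniform(-8, 8)))
            noisy = rng.poisson(win).astype(float)
            res = fitting.fit_emitter(noisy, default_table,
                                      center_candidate(noisy, 100.0))
            fx = (res.params.x - m) / spec.dxy
            fz = (res.params.z - default_table.calib.z_focus) / spec.dz
            assert fx == pytest.approx(round(fx), abs=1e-9)
            assert fz == pytest.approx(round(fz), abs=1e-9)

    def test_monte_carlo_std_within_crlb_band(self, calib, rng):
        """Poisson-replicate lateral scatter lies in [1x, 2x] the CRLB.

        Uses a laterally fine grid (0.01 px) so the discretization floor
        (step / sqrt(12)) stays well below the information limit at this
        signal level; on the default 0.1 px grid the quantization, not the
        photon noise, would dominate the comparison.
        """
        spec = lutloc.LookupTableSpec(window=9, dxy=0.01, rxy=1.0,
                                      dz=25.0, rz=200.0)
        table = lutloc.build_table(spec, calib)
        win, c = make_window(table, 100.0, 2000.0, 0.0, 0.0, 0.0)
        xs = []
        crlbs = []
        for _ in range(400):
            noisy = rng.poisson(win).astype(float)
            res = fitting.fit_emitter(noisy, table,
                                      center_candidate(noisy, 100.0))
            if res.termination in (Termination.CONVERGED,
                                   Termination.MAX_ITERATIONS):
                xs.append(res.params.x)
                if res.crlb is not None:
                    crlbs.append(res.crlb[2])
        assert len(xs) > 300
        std = np.std(xs)
        mean_crlb = np.mean(crlbs)
        assert mean_crlb <= std <= 2.0 * mean_crlb


class TestCRLB:
    def test_quadrupling_photons_halves_positional_bounds(self, default_table):
        # 4x the full photon budget (signal and background alike): the
        # positional information quadruples, so the bounds halve
        c = default_table.spec.center
        lo = fitting.crlb(FitParams(100.0, 1000.0, c, c, 0.0), default_table)
        hi = fitting.crlb(FitParams(400.0, 4000.0, c, c, 0.0), default_table)
        for i in (2, 3, 4):
            assert hi[i] == pytest.approx(lo[i] / 2, rel=0.01)

    def test_matches_numerical_fisher_oracle(self, default_table, calib):
        """Fisher information from finite differences of the Poisson model."""
        c = default_table.spec.center
        theta = FitParams(80.0, 1500.0, c + 0.3, c - 0.2, 100.0)
        got = fitting.crlb(theta, default_table)
        ii, jj = np.meshgrid(np.arange(9.), np.arange(9.), indexing="ij")

        def mu(q):
            bg, p, x, y, z = q
            return bg + p * lutloc.psf_value(x, y, z, calib, ii, jj).ravel()

        q0 = np.array([theta.bg, theta.p, theta.x, theta.y, theta.z])
        steps = np.array([1e-3, 1e-2, 1e-5, 1e-5, 1e-3])
        D = np.empty((81, 5))
        for a in range(5):
            dq = np.zeros(5)
            dq[a] = steps[a]
            D[:, a] = (mu(q0 + dq) - mu(q0 - dq)) / (2 * steps[a])
        info = D.T @ (D / mu(q0)[:, None])
        expected = np.sqrt(np.diag(np.linalg.inv(info)))
        assert np.allclose(got, expected, rtol=1e-3)

    def test_symmetric_in_focus_bounds_equal(self, default_table):
        c = default_table.spec.center
        b = fitting.crlb(FitParams(100.0, 2000.0, c, c, 0.0), default_table)
        assert b[2] == pytest.approx(b[3], rel=1e-6)

    def test_excess_noise_inflates_by_sqrt2(self, default_table):
        c = default_table.spec.center
        theta = FitParams(100.0, 2000.0, c, c, 0.0)
        a = fitting.crlb(theta, default_table)
        b = fitting.crlb(theta, default_table, excess_noise_factor=2.0)
        assert b[2] == pytest.approx(np.sqrt(2) * a[2], rel=1e-9)


class TestFitFrame:
    def test_blank_frame(self, default_table):
        assert lutloc.fit_frame(np.zeros((64, 64)), default_table) == []

    def test_three_separated_emitters_recovered(self, default_table, calib):
        frame = np.full((96, 96), 50.0)
        truth = [(24.2, 30.1, 0.0), (50.4, 70.3, 150.0), (76.1, 20.2, -250.0)]
        ii, jj = np.meshgrid(np.arange(96.), np.arange(96.), indexing="ij")
        for (x, y, z) in truth:
            frame += 2000.0 * lutloc.psf_value(x, y, z, calib, ii, jj)
        res = lutloc.fit_frame(frame, default_table,
                               lutloc.DetectionConfig(threshold=300.0))
        assert len(res) == 3
        spec = default_table.spec
        got = sorted((r.params.x, r.params.y, r.params.z) for r in res)
        for (gx, gy, gz), (tx, ty, tz) in zip(got, sorted(truth)):
            assert abs(gx - tx) <= spec.dxy / 2 + 1e-9
            assert abs(gy - ty) <= spec.dxy / 2 + 1e-9
            assert abs(gz - tz) <= spec.dz / 2 + 1e-9

    def test_deterministic(self, default_table, rng):
        frame = rng.uniform(0, 1000, (64, 64))
        a = lutloc.fit_frame(frame, default_table)
        b = lutloc.fit_frame(frame, default_table)
        assert len(a) == len(b)
        for ra, rb in zip(a, b):
            assert ra == rb


class TestContinuousReference:
    def test_noiseless_positions_match_discrete_within_half_step(
            self, default_table, calib, rng):
        spec = default_table.spec
        c = spec.center
        ii, jj = np.meshgrid(np.arange(9.), np.arange(9.), indexing="ij")
        for _ in range(10):
            dx, dy = rng.uniform(-0.45, 0.45, 2)
            z = rng.uniform(-350, 350)
            win = 100.0 + 2000.0 * lutloc.psf_value(c + dx, c + dy, z,
                                                    calib, ii, jj)
            cand = center_candidate(win, 100.0)
            disc = fitting.fit_emitter(win, default_table, cand)
            cont = fitting.fit_emitter_continuous(win, default_table, cand)
            assert abs(disc.params.x - cont.params.x) <= spec.dxy / 2 + 1e-6
            assert abs(disc.params.y - cont.params.y) <= spec.dxy / 2 + 1e-6
            assert abs(disc.params.z - cont.params.z) <= spec.dz / 2 + 1e-3
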