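import numpy as np
import pytest

from facseg import (
    DegeneratePartitionError,
    DegenerateUpdateError,
    DeltaFTerms,
    ModelParams,
    build_kernel,
    delta_f,
    lfac_energy,
    lfac_step,
    run_lfac,
    p_mp,
)
from facseg.fac import global_prototypes, membership_update
from facseg.lfac import delta_f_values
from facseg.local import KernelWindow, local_prototype_field


def delta_f_transcription(u_o, u_n, I_o, c1, c2, s1, s2, m):
    """Independent transcription of the closed-form energy difference."""
    a = u_n**m * (s1 / (s1 + u_n**m - u_o**m)) ** 2 - u_o**m
    b = (1 - u_n) ** m * (s2 / (s2 + (1 - u_n) ** m - (1 - u_o) ** m)) ** 2 - (
        1 - u_o
    ) ** m
    return a * (I_o - c1) ** 2 + b * (I_o - c2) ** 2


def local_energy_oracle(window_I, window_u, g_unit, center, m, x):
    """Centre-pixel energy contribution rebuilt from scratch with the centre
    membership set to x (kernel weights normalised to centre weight 1)."""
    r, c = center
    u = window_u.copy()
    u[r, c] = x
    w1 = u**m * g_unit
    w2 = (1 - u) ** m * g_unit
    c1 = (w1 * window_I).sum() / w1.sum()
    c2 = (w2 * window_I).sum() / w2.sum()
    I0 = window_I[r, c]
    return x**m * (I0 - c1) ** 2 + (1 - x) ** m * (I0 - c2) ** 2


class TestDeltaF:
    def test_zero_when_membership_unchanged(self, rng):
        for _ in range(20):
            u_o = rng.uniform(0, 1)
            t = DeltaFTerms(u_o, u_o, rng.uniform(0, 255), 10.0, 50.0, 5.0, 7.0)
            assert delta_f(t, 2.0) == 0.0

    def test_zero_when_residuals_vanish(self):
        t = DeltaFTerms(u_o=0.3, u_n=0.9, I_o=42.0, c1_loc=42.0, c2_loc=42.0,
                        s1=4.0, s2=4.0)
        assert delta_f(t, 2.0) == 0.0

    def test_matches_independent_transcription(self, rng):
        for _ in range(300):
            u_o, u_n = rng.uniform(0.01, 0.99, 2)
            I_o = rng.uniform(0, 255)
            c1, c2 = rng.uniform(0, 255, 2)
            s1, s2 = rng.uniform(2.0, 50.0, 2)
            m = 2.0
            got = delta_f(DeltaFTerms(u_o, u_n, I_o, c1, c2, s1, s2), m)
            want = delta_f_transcription(u_o, u_n, I_o, c1, c2, s1, s2, m)
            assert got == pytest.approx(want, rel=1e-12, abs=1e-12)

    def test_degenerate_denominator_raises(self):
        # s1 + u_n^m - u_o^m <= 0
        t = DeltaFTerms(u_o=0.99, u_n=0.0, I_o=5.0, c1_loc=1.0, c2_loc=9.0,
                        s1=0.5, s2=5.0)
        with pytest.raises(DegenerateUpdateError):
            delta_f(t, 2.0)

    def test_equals_from_scratch_local_energy_difference(self, rng):
        """The closed form is the exact energy change of the centre pixel's
        own contribution, with the prototypes re-derived for the new centre
        membership (centre kernel weight 1)."""
        m = 2.0
        R = 3
        kernel = build_kernel(1.5, R)
        g_unit = kernel.weights / kernel.center_weight
        for _ in range(200):
            W_I = rng.uniform(0, 255, (2 * R + 1, 2 * R + 1))
            W_u = rng.uniform(0.02, 0.98, (2 * R + 1, 2 * R + 1))
            u_o = W_u[R, R]
            u_n = rng.uniform(0.02, 0.98)
            w1 = W_u**m * g_unit
            w2 = (1 - W_u) ** m * g_unit
            s1, s2 = w1.sum(), w2.sum()
            c1 = (w1 * W_I).sum() / s1
            c2 = (w2 * W_I).sum() / s2
            got = delta_f(DeltaFTerms(u_o, u_n, W_I[R, R], c1, c2, s1, s2), m)
            want = local_energy_oracle(W_I, W_u, g_unit, (R, R), m, u_n) - \
                local_energy_oracle(W_I, W_u, g_unit, (R, R), m, u_o)
            assert got == pytest.approx(want, rel=1e-8, abs=1e-8)


def brute_force_lfac_energy(image, u, kernel, m):
    h, w = image.shape
    r = kernel.radius
    total = 0.0
    for x in range(h):
        for y in range(w):
            n1 = d1 = n2 = d2 = 0.0
            for i in range(max(x - r, 0), min(x + r + 1, h)):
                for j in range(max(y - r, 0), min(y + r + 1, w)):
                    g = kernel.weights[i - x + r, j - y + r]
                    n1 += u[i, j] ** m * g * image[i, j]
                    d1 += u[i, j] ** m * g
                    n2 += (1 - u[i, j]) ** m * g * image[i, j]
                    d2 += (1 - u[i, j]) ** m * g
            total += u[x, y] ** m * (image[x, y] - n1 / d1) ** 2
            total += (1 - u[x, y]) ** m * (image[x, y] - n2 / d2) ** 2
    return total


class TestLfacEnergy:
    def test_uniform_image_zero_energy_for_any_membership(self, rng):
        img = np.full((8, 8), 123.0)
        u = rng.uniform(0.05, 0.95, (8, 8))
        assert lfac_energy(img, u, build_kernel(1.5, 3), 2.0) == pytest.approx(0.0, abs=1e-16)

    def test_matches_quadruple_loop_oracle(self, rng):
        img = rng.uniform(0, 255, (8, 8))
        u = rng.uniform(0.05, 0.95, (8, 8))
        kernel = build_kernel(1.2, 2)
        got = lfac_energy(img, u, kernel, 2.0)
        want = brute_force_lfac_energy(img, u, kernel, 2.0)
        assert got == pytest.approx(want, rel=1e-8)


class TestLfacStep:
    def test_reduces_to_global_sweep_with_uniform_global_window(self, rng):
        """With a window covering the whole image and uniform weights, one
        full-domain sweep reproduces one global-prototype sweep exactly."""
        img = rng.uniform(0, 255, (20, 24))
        u0 = rng.uniform(0.01, 0.99, (20, 24))
        R = 30
        kernel = KernelWindow(sigma=np.inf, radius=R, weights=np.ones((2 * R + 1,) * 2))
        params = ModelParams(accept_tol=0.0, contiguous_flips=False, kernel_radius=R)
        u1, accepted = lfac_step(img, u0, kernel, params, np.ones_like(u0, bool))
        proto = global_prototypes(img, u0, 2.0)
        u_fac = membership_update(img, proto.c1, proto.c2, 2.0)
        np.testing.assert_allclose(u1, u_fac, atol=1e-8)

    def test_fixed_point_accepts_nothing(self):
        """A locally perfect crisp segmentation admits no improving update."""
        img = np.full((20, 30), 40.0)
        img[:, 15:] = 160.0
        u = (img > 100).astype(float)
        params = ModelParams(sigma=1.5)
        kernel = build_kernel(1.5, 5)
        u1, accepted = lfac_step(img, u, kernel, params, np.ones_like(u, bool))
        assert accepted == 0
        np.testing.assert_array_equal(u1, u)

    def test_deterministic(self, rng):
        img = rng.uniform(0, 255, (15, 15))
        u = rng.uniform(0.1, 0.9, (15, 15))
        kernel = build_kernel(1.5, 4)
        params = ModelParams()
        band = rng.random((15, 15)) < 0.5
        a = lfac_step(img, u, kernel, params, band)
        b = lfac_step(img, u, kernel, params, band)
        np.testing.assert_array_equal(a[0], b[0])
        assert a[1] == b[1]

    def test_untouched_outside_band(self, rng):
        img = rng.uniform(0, 255, (15, 15))
        u = rng.uniform(0.1, 0.9, (15, 15))
        band = np.zeros((15, 15), bool)
        band[4:8, 4:8] = True
        u1, _ = lfac_step(img, u, build_kernel(1.5, 4), ModelParams(), band)
        np.testing.assert_array_equal(u1[~band], u[~band])


class TestRunLfac:
    def test_recovers_bar_on_constant_background(self):
        """A thin bright bar (every object pixel within kernel reach of an
        edge, object clear of the frame) is recovered exactly from a
        partial seed."""
        img = np.full((40, 60), 30.0)
        img[10:31, 28:39] = 90.0
        truth = img > 50
        init = np.full(img.shape, 0.2)
        init[14:26, 29:38] = 0.8  # partial seed inside the bar
        res = run_lfac(img, init, ModelParams(sigma=3.0))
        assert p_mp(truth, res.mask) == 0.0
        assert res.converged

    def test_uniform_half_init_raises(self):
        img = np.ones((10, 10))
        with pytest.raises(DegeneratePartitionError):
            run_lfac(img, np.full((10, 10), 0.5))

    def test_deterministic(self, clean_scene):
        img, _ = clean_scene
        init = np.full(img.shape, 0.2)
        init[75:110, 60:90] = 0.8
        r1 = run_lfac(img, init)
        r2 = run_lfac(img, init)
        np.testing.assert_array_equal(r1.membership, r2.membership)
        np.testing.assert_array_equal(r1.energy_trace, r2.energy_trace)

    def test_mask_is_threshold_of_membership(self, clean_lfac):
        np.testing.assert_array_equal(clean_lfac.mask, clean_lfac.membership > 0.5)

    def test_accepted_updates_decrease_local_energy(self, rng):
        """Every accepted update strictly decreases the pixel's local energy
        contribution, re-derived from scratch by an independent oracle."""
        m = 2.0
        R = 4
        kernel = build_kernel(1.5, R)
        g_unit = kernel.weights / kernel.center_weight
        img = rng.uniform(0, 255, (20, 20))
        u = rng.uniform(0.05, 0.95, (20, 20))
        params = ModelParams(sigma=1.5, kernel_radius=R, contiguous_flips=False)
        band = np.zeros((20, 20), bool)
        band[R:-R, R:-R] = True
        u1, accepted = lfac_step(img, u, kernel, params, band)
        assert accepted > 0
        changed = np.argwhere(u1 != u)
        for r, c in changed[:50]:
            W_I = img[r - R : r + R + 1, c - R : c + R + 1]
            W_u = u[r - R : r + R + 1, c - R : c + R + 1]
            before = local_energy_oracle(W_I, W_u, g_unit, (R, R), m, u[r, c])
            after = local_energy_oracle(W_I, W_u, g_unit, (R, R), m, u1[r, c])
            assert after < before + 1e-8
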