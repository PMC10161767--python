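"""Forward diffraction model: geometry, symmetries, and the Monte-Carlo oracle."""

import dataclasses

import numpy as np
import pytest

from fiberchi import (ChiGrid, OrientationParams, group_fiber_axes,
                      rotation_from_tilts, simulate_ichi, simulate_ichi_mc)
from conftest import random_params


def explicit_rotation(alpha, beta):
    """Independent trigonometric construction of Ry(beta) @ Rx(alpha)."""
    a, b = np.deg2rad(alpha), np.deg2rad(beta)
    ca, sa, cb, sb = np.cos(a), np.sin(a), np.cos(b), np.sin(b)
    return np.array([
        [cb, sa * sb, ca * sb],
        [0.0, ca, -sa],
        [-sb, sa * cb, ca * cb],
    ])


class TestRotation:
    def test_identity(self):
        assert np.allclose(rotation_from_tilts(0, 0), np.eye(3), atol=1e-15)

    def test_proper_rotation_against_trig_matrices(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            a, b = rng.uniform(-90, 90, 2)
            r = rotation_from_tilts(a, b)
            assert np.allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.isclose(np.linalg.det(r), 1.0, atol=1e-12)
            assert np.allclose(r, explicit_rotation(a, b), atol=1e-12)

    def test_period_180_equivalent_curve(self, params):
        """(alpha+180, beta) induces the same fiber-plane physics as (alpha, beta)."""
        base = simulate_ichi(params)
        shifted = simulate_ichi(dataclasses.replace(params, alpha1=params.alpha1 + 180.0))
        assert np.abs(base.intensity - shifted.intensity).max() < 1e-9


class TestFiberAxes:
    @pytest.mark.parametrize("gamma,expect", [(0.0, (1, 0, 0)), (90.0, (0, 1, 0))])
    def test_untilted_single_axis(self, gamma, expect):
        axes, w = group_fiber_axes(0, 0, gamma, 0, n_samples=1)
        assert np.allclose(axes[0], expect, atol=1e-12)
        assert np.isclose(w.sum(), 1.0)

    def test_axes_unit_norm_and_weights(self):
        axes, w = group_fiber_axes(33, -12, 50, 80, n_samples=301)
        assert np.allclose(np.linalg.norm(axes, axis=1), 1.0, atol=1e-12)
        assert np.isclose(w.sum(), 1.0, atol=1e-12)

    def test_zero_spread_repeats_single_direction(self):
        axes, _ = group_fiber_axes(0, 0, 25, 0, n_samples=7)
        assert np.allclose(axes, axes[0], atol=1e-15)

    def test_fan_mean_direction_by_symmetry(self):
        axes, w = group_fiber_axes(0, 0, 30, 40, n_samples=1001)
        mean = (w[:, None] * axes).sum(axis=0)
        mean /= np.linalg.norm(mean)
        expect = np.array([np.cos(np.deg2rad(30)), np.sin(np.deg2rad(30)), 0.0])
        assert np.abs(mean - expect).max() < 1e-6

    def test_invalid_n_samples(self):
        with pytest.raises(ValueError):
            group_fiber_axes(0, 0, 0, 10, n_samples=0)


class TestSimulate:
    def test_identical_groups_match_single_group(self, params):
        twin = OrientationParams(params.alpha1, params.beta1, params.gamma1,
                                 params.dgamma1, params.alpha1, params.beta1,
                                 params.gamma1, params.dgamma1, 1.0)
        # a "single group" realized by zeroing the other side via lam_ratio
        merged = simulate_ichi(twin)
        solo = simulate_ichi(dataclasses.replace(twin, lam_ratio=1e12))
        assert np.abs(merged.intensity - solo.intensity).max() < 1e-9

    def test_group_swap_symmetry(self, params):
        a = simulate_ichi(params)
        b = simulate_ichi(params.swapped())
        assert np.abs(a.intensity - b.intensity).max() < 1e-12

    def test_deterministic(self, params):
        a = simulate_ichi(params)
        b = simulate_ichi(params)
        assert np.array_equal(a.intensity, b.intensity)

    def test_linearity_before_normalization(self, params):
        """Combined unnormalized curve = lam * C1 + C2 exactly."""
        from fiberchi.forward import DiffractionGeometry, _group_curve
        grid, geom = ChiGrid(), DiffractionGeometry()
        c1 = _group_curve(params.alpha1, params.beta1, params.gamma1,
                          params.dgamma1, grid, 5.0, 181, "uniform", geom)
        c2 = _group_curve(params.alpha2, params.beta2, params.gamma2,
                          params.dgamma2, grid, 5.0, 181, "uniform", geom)
        combined = params.lam_ratio * c1 + c2
        curve = simulate_ichi(params)
        resid = combined / combined.max() - curve.intensity
        assert np.abs(resid).max() < 1e-12

    def test_period_180_all_angles(self):
        rng = np.random.default_rng(7)
        rows = random_params(rng, 5)
        for row in rows:
            p = OrientationParams.from_array(row)
            base = simulate_ichi(p)
            for fieldname in ("alpha1", "beta1", "gamma1", "alpha2", "beta2", "gamma2"):
                q = dataclasses.replace(p, **{fieldname: getattr(p, fieldname) + 180.0})
                assert np.abs(simulate_ichi(q).intensity - base.intensity).max() < 1e-9

    def test_validation_errors(self, params):
        with pytest.raises(ValueError):
            simulate_ichi(params, n_quad=4)
        with pytest.raises(ValueError):
            simulate_ichi(params, smear_width=0.0)
        with pytest.raises(ValueError):
            simulate_ichi(dataclasses.replace(params, lam_ratio=-1.0))


class TestMonteCarloOracle:
    def test_seeded_determinism(self, params):
        a = simulate_ichi_mc(params, n_draws=2000, seed=5)
        b = simulate_ichi_mc(params, n_draws=2000, seed=5)
        assert np.array_equal(a.intensity, b.intensity)

    def test_quadrature_matches_mc(self):
        """Quadrature curve within Monte-Carlo error per bin, for random
        parameter sets (empirical SE from replicate seeds).

        Shapes are compared under unit-area normalization: normalizing each
        replicate by its own noisy maximum would bias peak bins, whereas the
        area aggregates all deposits and its noise is negligible. The
        quadrature runs at elevated order (the fan-to-azimuth map has fold
        points where the default 181 nodes leave percent-level discretization
        error), and the per-bin bound is 5 SE - the expected maximum of
        25 x 360 independent fluctuations is ~4.3 SE, while genuine model
        errors show up at 7-12 SE.
        """
        rng = np.random.default_rng(42)
        rows = random_params(rng, 25)
        n_reps, n_draws = 8, 40_000
        for row in rows:
            p = OrientationParams.from_array(row)
            quad = simulate_ichi(p, n_quad=721).intensity
            quad = quad / quad.sum()
            reps = np.stack([simulate_ichi_mc(p, n_draws=n_draws, seed=s).intensity
                             for s in range(n_reps)])
            reps /= reps.sum(axis=1, keepdims=True)
            mean = reps.mean(axis=0)
            se = reps.std(axis=0, ddof=1) / np.sqrt(n_reps) + 2e-5
            assert np.all(np.abs(mean - quad) < 5.0 * se), \
                f"MC mismatch for params {row}"

    def test_mc_error_shrinks_with_draws(self, params):
        """RMS deviation from the quadrature curve shrinks ~1/sqrt(2) when
        n_draws doubles (averaged over replicate seeds)."""
        quad = simulate_ichi(params).intensity

        def rms(n_draws):
            devs = [np.sqrt(np.mean((simulate_ichi_mc(
                params, n_draws=n_draws, seed=s).intensity - quad) ** 2))
                for s in range(20)]
            return np.mean(devs)

        r1, r2 = rms(8000), rms(16000)
        assert 0.55 < r2 / r1 < 0.90  # ~0.707 expected

    def test_zero_spread_single_group_support(self):
        """With dgamma=0 and one dominant group all deposits come from one pole
        circle: MC nonzero bins are a subset of the quadrature support."""
        p = OrientationParams(15, 0, 30, 0, 15, 0, 30, 0, 1.0)
        quad = simulate_ichi(p, smear_width=2.0).intensity
        mc = simulate_ichi_mc(p, smear_width=2.0, n_draws=5000, seed=0).intensity
        support_quad = quad > 1e-10
        # widen by one bin to absorb histogram-edge effects
        widened = support_quad | np.roll(support_quad, 1) | np.roll(support_quad, -1)
        assert np.all(widened[mc > 0])

    def test_min_draws_validated(self, params):
        with pytest.raises(ValueError):
            simulate_ichi_mc(params, n_draws=10)


def test_degenerate_geometry_flagged():
    """Fibers along the beam axis intersect the Ewald ring nowhere: the curve
    is all-zero and flagged."""
    p = OrientationParams(90, 0, 90, 0, 90, 0, 90, 0, 1.0)  # axes ~ +/-z
    with pytest.warns(RuntimeWarning, match="degenerate"):
        c = simulate_ichi(p)
    assert c.degenerate
    assert np.all(c.intensity == 0)
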