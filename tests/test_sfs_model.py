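"""Unit tests for the expected SFS and the Poisson likelihood models."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.special import comb

from sispec.sfs import CLASSES, ClassSFS
from sispec.sfs_model import (
    GbgcFit,
    expected_sfs,
    fit_model,
    likelihood_ratio_test,
    model_loglik,
    sfs_cell_means,
)
from sispec.simulate import SimulationConfig, simulate_class_sfs


def quad_expected_sfs(gamma, theta, n, j):
    """Independent quadrature oracle for one SFS entry."""

    def f(x):
        if gamma == 0:
            soj = 1.0 / x
        else:
            soj = -np.expm1(-gamma * (1 - x)) / (-np.expm1(-gamma) * x * (1 - x))
        return theta * comb(n, j) * soj * x**j * (1 - x) ** (n - j)

    return quad(f, 0, 1, limit=200)[0]


class TestExpectedSfs:
    def test_neutral_is_theta_over_j(self):
        n = 21
        np.testing.assert_allclose(
            expected_sfs(0.0, 2.5, n), 2.5 / np.arange(1, n), rtol=0, atol=0
        )

    @pytest.mark.parametrize("gamma", [-5.0, -2.0, 0.5, 2.0, 10.0])
    @pytest.mark.parametrize("n", [5, 21, 69])
    def test_matches_quadrature_oracle(self, gamma, n):
        got = expected_sfs(gamma, 1.3, n)
        for j in (1, n // 2, n - 1):
            assert got[j - 1] == pytest.approx(
                quad_expected_sfs(gamma, 1.3, n, j), rel=1e-8
            )

    def test_continuity_at_zero(self):
        # the small-gamma expansion joins the quadrature path smoothly and
        # the gamma -> 0 limit approaches the neutral form
        n = 21
        lo = expected_sfs(0.99e-6, 1.0, n)  # expansion branch
        hi = expected_sfs(1.01e-6, 1.0, n)  # quadrature branch
        assert np.max(np.abs(lo - hi)) < 1e-9
        assert np.max(np.abs(expected_sfs(1e-7, 1.0, n) - expected_sfs(0.0, 1.0, n))) < 1e-8

    def test_reflection_identity(self):
        # E[xi_j; -g] + E[xi_{n-j}; +g] = theta * n / (j (n - j)),
        # the sojourn-density symmetry of the semidominant diffusion
        n, g, theta = 21, 2.7, 1.9
        neg = expected_sfs(-g, theta, n)
        pos = expected_sfs(g, theta, n)
        j = np.arange(1, n)
        np.testing.assert_allclose(
            neg + pos[::-1], theta * n / (j * (n - j)), rtol=1e-10
        )

    def test_gamma_out_of_range(self):
        with pytest.raises(ValueError):
            expected_sfs(60.0, 1.0, 10)
        with pytest.raises(ValueError):
            expected_sfs(np.nan, 1.0, 10)


class TestLoglik:
    def _toy_sfs(self):
        n = 3
        xi = {"S>W": np.array([2.0, 1.0]), "W>S": np.array([3.0, 0.0]),
              "neutral": np.array([1.0, 1.0])}
        return ClassSFS(n=n, xi=xi, L_W=50.0, L_S=30.0)

    def test_hand_computed_poisson_loglik(self):
        # gamma = 0, r = 1: mean[c] = (theta_c, theta_c / 2)
        sfs = self._toy_sfs()
        fit = GbgcFit(
            model="M0", n=3, gamma=0.0, theta_ws=2.0, theta_sw=1.5,
            theta_neu=1.0, distortion=np.array([1.0, 1.0]), epsilon=0.0,
            loglik=0.0,
        )
        expected = 0.0
        means = {"S>W": (1.5, 0.75), "W>S": (2.0, 1.0), "neutral": (1.0, 0.5)}
        for c in CLASSES:
            for o, m in zip(sfs.xi[c], means[c]):
                expected += o * math.log(m) - m - math.lgamma(o + 1)
        assert model_loglik(sfs, fit) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance_r_vs_theta(self):
        # doubling every r_j while halving every theta leaves means unchanged
        # (why r_1 is pinned to 1)
        sfs = self._toy_sfs()
        base = GbgcFit(model="M1", n=3, gamma=0.8, theta_ws=2.0, theta_sw=1.5,
                       theta_neu=1.0, distortion=np.array([1.0, 1.3]),
                       epsilon=0.0, loglik=0.0)
        m1 = sfs_cell_means(0.8, 2.0, 1.5, 1.0, 3, base.distortion)
        m2 = sfs_cell_means(0.8, 1.0, 0.75, 0.5, 3, 2 * base.distortion)
        for c in CLASSES:
            np.testing.assert_allclose(m1[c], m2[c])

    def test_epsilon_zero_matches_unstarred(self):
        sfs = self._toy_sfs()
        kw = dict(n=3, gamma=0.5, theta_ws=2.0, theta_sw=1.5, theta_neu=1.0,
                  distortion=np.array([1.0, 1.1]), loglik=0.0)
        f1 = GbgcFit(model="M1", epsilon=0.0, **kw)
        f1s = GbgcFit(model="M1*", epsilon=0.0, **kw)
        assert model_loglik(sfs, f1) == model_loglik(sfs, f1s)

    def test_epsilon_mixes_reflected_opposite_class(self):
        m0 = sfs_cell_means(1.0, 2.0, 1.5, 1.0, 5, epsilon=0.0)
        m = sfs_cell_means(1.0, 2.0, 1.5, 1.0, 5, epsilon=0.1)
        np.testing.assert_allclose(
            m["S>W"], 0.9 * m0["S>W"] + 0.1 * m0["W>S"][::-1]
        )
        np.testing.assert_allclose(
            m["neutral"], 0.9 * m0["neutral"] + 0.1 * m0["neutral"][::-1]
        )


class TestFitting:
    def _simulate(self, gamma, kappa, seed, **kw):
        cfg = SimulationConfig(
            gamma=gamma, kappa=kappa, n=21, seed=seed,
            theta_ws=3200, theta_sw=3000, theta_neu=2100, **kw
        )
        return simulate_class_sfs(cfg)

    def test_recovers_planted_parameters(self):
        sfs = self._simulate(2.0, 3.0, seed=5)
        fit = fit_model(sfs, "M1", n_restarts=2, seed=0)
        assert fit.gamma == pytest.approx(2.0, abs=0.3)
        assert fit.kappa == pytest.approx(3.0, rel=0.05)

    def test_m1_loglik_dominates_m0(self):
        sfs = self._simulate(1.0, 3.0, seed=6)
        f0 = fit_model(sfs, "M0", n_restarts=2, seed=0)
        f1 = fit_model(sfs, "M1", n_restarts=2, seed=0)
        assert f1.loglik >= f0.loglik - 1e-6

    def test_distortion_robustness(self):
        # an arbitrary positive distortion shared across classes must not
        # bias the gamma estimate — the rationale for the nuisance terms
        rng = np.random.default_rng(3)
        r = np.exp(rng.normal(0.0, 0.5, size=20))
        r[0] = 1.0
        sfs = self._simulate(1.5, 3.0, seed=7, distortion=r)
        fit = fit_model(sfs, "M1", n_restarts=2, seed=1)
        assert fit.gamma == pytest.approx(1.5, abs=0.35)

    def test_degenerate_sfs_rejected(self):
        sfs = self._simulate(0.0, 3.0, seed=8)
        sfs.xi["neutral"][:] = 0.0
        with pytest.raises(ValueError):
            fit_model(sfs, "M1", n_restarts=1, seed=0)


class TestLrt:
    def test_identical_fits_give_zero(self):
        fit = GbgcFit(model="M0", n=5, gamma=0.0, theta_ws=1, theta_sw=1,
                      theta_neu=1, distortion=np.ones(4), epsilon=0.0,
                      loglik=-10.0)
        alt = GbgcFit(model="M1", n=5, gamma=0.0, theta_ws=1, theta_sw=1,
                      theta_neu=1, distortion=np.ones(4), epsilon=0.0,
                      loglik=-10.0)
        stat, df, p = likelihood_ratio_test(fit, alt)
        assert stat == 0.0 and df == 1 and p == 1.0

    def test_non_nested_pair_rejected(self):
        kw = dict(n=5, gamma=0.0, theta_ws=1, theta_sw=1, theta_neu=1,
                  distortion=np.ones(4), epsilon=0.0, loglik=-10.0)
        with pytest.raises(ValueError):
            likelihood_ratio_test(GbgcFit(model="M1", **kw),
                                  GbgcFit(model="M0*", **kw))

    def test_df_counts(self):
        kw = dict(n=5, gamma=0.0, theta_ws=1, theta_sw=1, theta_neu=1,
                  distortion=np.ones(4), epsilon=0.0, loglik=-10.0)
        _, df, _ = likelihood_ratio_test(GbgcFit(model="M0", **kw),
                                         GbgcFit(model="M1", **kw))
        assert df == 1
        _, df, _ = likelihood_ratio_test(GbgcFit(model="M1", **kw),
                                         GbgcFit(model="M1*", **kw))
        assert df == 1
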