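"""Tests of the synthetic-data generators against analytic expectations."""

import numpy as np
import pytest

from sispec.sfs import CLASSES
from sispec.sfs_model import expected_sfs
from sispec.simulate import (
    BASES,
    SimulationConfig,
    concat_datasets,
    simulate_class_sfs,
    simulate_triplet_alignment,
    wright_fisher_oracle,
)


class TestClassSfs:
    def test_bit_identical_under_fixed_seed(self):
        cfg = SimulationConfig(gamma=1.0, kappa=3.0, n=21, seed=4,
                               theta_ws=500, theta_sw=450, theta_neu=300)
        a, b = simulate_class_sfs(cfg), simulate_class_sfs(cfg)
        for c in CLASSES:
            np.testing.assert_array_equal(a.xi[c], b.xi[c])

    def test_neutral_one_over_j_law(self):
        theta = 50_000.0
        cfg = SimulationConfig(gamma=0.0, kappa=1.0, n=21, seed=1,
                               theta_ws=theta, theta_sw=theta, theta_neu=theta)
        sfs = simulate_class_sfs(cfg)
        j = sfs.j
        for c in CLASSES:
            # Poisson relative error ~ 1/sqrt(theta/j) <= 1/sqrt(2500) = 2%
            np.testing.assert_allclose(sfs.xi[c] * j / theta, 1.0, atol=0.1)

    def test_uniform_distortion_scales_neutral_shape(self):
        theta = 50_000.0
        r = np.full(20, 1.7)
        cfg = SimulationConfig(gamma=0.0, kappa=1.0, n=21, seed=2,
                               theta_ws=theta, theta_sw=theta, theta_neu=theta,
                               distortion=r)
        sfs = simulate_class_sfs(cfg)
        np.testing.assert_allclose(sfs.xi["neutral"] * sfs.j / theta, 1.7, atol=0.15)

    def test_site_totals_consistent_with_kappa(self):
        cfg = SimulationConfig(gamma=0.3, kappa=2.8, n=21, seed=3,
                               theta_ws=3200, theta_sw=3000, theta_neu=2100)
        L_W, L_S = cfg.site_totals()
        assert L_W + L_S == pytest.approx(cfg.n_sites)
        kappa = (cfg.theta_sw / L_S) / (cfg.theta_ws / L_W)
        assert kappa == pytest.approx(2.8, rel=1e-12)

    def test_daf_gap_matches_diffusion_prediction(self):
        # with a GC-favoring force, mean DAF(W>S) exceeds mean DAF(S>W) by
        # the gap predicted from the expected-SFS integrals
        theta = 30_000.0
        cfg = SimulationConfig(gamma=2.0, kappa=3.0, n=21, seed=9,
                               theta_ws=theta, theta_sw=theta, theta_neu=theta)
        sfs = simulate_class_sfs(cfg)
        j = sfs.j

        def daf(x):
            return np.sum(j * x) / (21 * np.sum(x))

        pred_ws = daf(expected_sfs(2.0, theta, 21))
        pred_sw = daf(expected_sfs(-2.0, theta, 21))
        got_gap = daf(sfs.xi["W>S"]) - daf(sfs.xi["S>W"])
        assert got_gap == pytest.approx(pred_ws - pred_sw, abs=0.01)
        assert got_gap > 0

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            SimulationConfig(kappa=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(polarization_error=0.6)
        with pytest.raises(ValueError):
            SimulationConfig(n=21, distortion=np.zeros(20))


class TestWrightFisherOracle:
    def test_neutral_matches_theta_over_j(self):
        n = 11
        per = wright_fisher_oracle(0.0, n, pop_size=550, reps=30_000, seed=3,
                                   theta=1.0, per_rep=True)
        m = per["neutral"]
        est, se = m.mean(0), m.std(0, ddof=1) / np.sqrt(m.shape[0])
        exp = 1.0 / np.arange(1, n)
        assert np.all(np.abs(est - exp) <= np.maximum(4 * se, 0.02 * exp))

    def test_selected_matches_expected_sfs(self):
        # the forward simulation is the independent oracle of the analytic
        # expectation; agreement within Monte-Carlo error (4 SE) with a 2%
        # allowance for the O(1/pop_size) discreteness of the WF model
        n, gamma = 21, 2.0
        per = wright_fisher_oracle(gamma, n, pop_size=50 * n, reps=40_000,
                                   seed=5, theta=1.0, per_rep=True)
        for cls, g in (("W>S", gamma), ("S>W", -gamma)):
            m = per[cls]
            est, se = m.mean(0), m.std(0, ddof=1) / np.sqrt(m.shape[0])
            exp = expected_sfs(g, 1.0, n)
            assert np.all(np.abs(est - exp) <= np.maximum(4 * se, 0.02 * exp)), cls

    def test_sign_swap_reflection(self):
        # the +gamma and -gamma spectra of one oracle call satisfy the
        # sojourn-density reflection identity
        n, gamma, theta = 11, 2.0, 1.0
        per = wright_fisher_oracle(gamma, n, pop_size=550, reps=30_000, seed=7,
                                   theta=theta, per_rep=True)
        j = np.arange(1, n)
        tot = per["S>W"].mean(0) + per["W>S"].mean(0)[::-1]
        se = np.sqrt(
            per["S>W"].var(0) / per["S>W"].shape[0]
            + per["W>S"].var(0)[::-1] / per["W>S"].shape[0]
        )
        ident = theta * n / (j * (n - j))
        assert np.all(np.abs(tot - ident) <= np.maximum(4 * se, 0.02 * ident))

    def test_few_reps_warns(self):
        with pytest.warns(UserWarning):
            wright_fisher_oracle(0.0, 5, pop_size=250, reps=200, seed=1)


class TestTripletAlignment:
    def test_zero_branch_lengths(self):
        cfg = SimulationConfig(n_introns=40, seed=3,
                               theta_ws=5, theta_sw=5, theta_neu=5,
                               branch_lengths={b: 0.0 for b in
                                               ("in1", "in2", "anc", "out")})
        ds = simulate_triplet_alignment(cfg)
        assert ds.truth["n_total"].sum() == 0
        np.testing.assert_array_equal(ds.refs["in1"], ds.refs["out"])
        np.testing.assert_array_equal(ds.refs["in1"], ds.refs["in2"])

    def test_stationary_equilibrium_gc(self):
        # kappa = 3, gamma = 0: equilibrium GC = 1 / (1 + kappa) = 0.25
        n_int = 2500
        cfg = SimulationConfig(kappa=3.0, gamma=0.0, n_introns=n_int, seed=4,
                               gc_distribution=np.full(n_int, 0.25),
                               theta_ws=1e-9, theta_sw=1e-9, theta_neu=1e-9)
        ds = simulate_triplet_alignment(cfg)
        for sp in ("in1", "in2", "out"):
            gc = np.isin(ds.refs[sp], (1, 2)).mean()
            assert gc == pytest.approx(0.25, abs=0.01)

    def test_truth_label_counts_conserve_totals(self, triplet_dataset):
        t = triplet_dataset.truth
        np.testing.assert_array_equal(
            t["n_SW"] + t["n_WS"] + t["n_neu"], t["n_total"]
        )

    def test_polymorphism_replaces_never_stacks(self, triplet_dataset):
        # overlay sites were chosen where no substitution occurred on the
        # focal branch, so the recorded ancestral allele equals the focal
        # reference allele at every polymorphic site
        ds = triplet_dataset
        L = ds.config.intron_length
        for _, row in ds.poly.head(500).iterrows():
            ref = BASES[ds.refs["in1"][row["intron"], row["offset"]]]
            assert ref == row["ancestral"]

    def test_planted_sfs_matches_poly_table(self, triplet_dataset):
        ds = triplet_dataset
        assert ds.sfs.total_segregating() == len(ds.poly)
        assert ds.sfs.L_S + ds.sfs.L_W == ds.config.n_sites

    def test_determinism(self):
        cfg = SimulationConfig(gamma=0.5, kappa=2.0, n=5, n_introns=30, seed=12,
                               theta_ws=20, theta_sw=20, theta_neu=10)
        a = simulate_triplet_alignment(cfg)
        b = simulate_triplet_alignment(cfg)
        np.testing.assert_array_equal(a.haplotypes, b.haplotypes)
        assert a.truth.equals(b.truth)
        assert a.poly.equals(b.poly)


class TestConcat:
    def test_concat_offsets_and_totals(self):
        kw = dict(kappa=2.0, n=5, n_introns=20, theta_ws=10, theta_sw=10,
                  theta_neu=5)
        a = simulate_triplet_alignment(SimulationConfig(seed=1, **kw))
        b = simulate_triplet_alignment(SimulationConfig(seed=2, **kw))
        m = concat_datasets([a, b])
        assert m.config.n_introns == 40
        assert m.haplotypes.shape[1] == 40
        assert len(m.truth) == len(a.truth) + len(b.truth)
        assert m.sfs.total_segregating() == (
            a.sfs.total_segregating() + b.sfs.total_segregating()
        )
        if len(b.poly):
            assert m.poly["site"].max() >= 20 * 23
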