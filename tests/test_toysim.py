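"""Synthetic generators: analytic potentials, Brownian dynamics, discrete
chains and planted network fixtures."""

import numpy as np
import pytest
from scipy import stats

from memmpath import toysim
from conftest import grid_minimax_oracle


ALL_POTENTIALS = ["double_well_1d", "tilted_double_well_1d",
                  "double_well_2d", "triple_well_2d", "mueller_brown_like"]


class TestPotentials:
    def test_double_well_closed_form(self):
        pot = toysim.make_potential("double_well_1d", h=2.5, a=1.5)
        assert pot.energy(np.array([0.0])) == pytest.approx(2.5)
        assert pot.energy(np.array([1.5])) == pytest.approx(0.0)
        assert pot.energy(np.array([-1.5])) == pytest.approx(0.0)

    @pytest.mark.parametrize("name", ALL_POTENTIALS)
    def test_gradient_zero_at_minima(self, name):
        pot = toysim.make_potential(name)
        for m in pot.minima:
            g = pot.gradient(np.asarray(m, dtype=float))
            # declared minima are stationary (tabulated ones to ~1e-3)
            tol = 1e-8 if name.endswith("1d") or name == "double_well_2d" \
                else 0.05
            assert np.max(np.abs(g)) < tol

    @pytest.mark.parametrize("name", ALL_POTENTIALS)
    def test_gradient_matches_finite_difference(self, name):
        pot = toysim.make_potential(name)
        rng = np.random.default_rng(0)
        pts = rng.uniform(-1.5, 1.5, size=(20, pot.dimensionality))
        eps = 1e-6
        for x in pts:
            g = pot.gradient(x)
            for d in range(pot.dimensionality):
                e = np.zeros_like(x)
                e[d] = eps
                fd = (pot.energy(x + e) - pot.energy(x - e)) / (2 * eps)
                assert g[d] == pytest.approx(float(fd), rel=1e-5, abs=1e-6)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError, match="unknown potential"):
            toysim.make_potential("quadruple_well")

    def test_mueller_brown_saddle_matches_grid_oracle(self):
        pot = toysim.make_potential("mueller_brown_like", scale=0.05)
        bounds = ((-1.7, 1.2), (-0.4, 2.2))
        p, e = toysim.grid_minimax_saddle(pot, bounds, 601,
                                          a=pot.minima[1], b=pot.minima[2])
        level = grid_minimax_oracle(pot, bounds, 401,
                                    pot.minima[1], pot.minima[2])
        assert e == pytest.approx(level, abs=0.02)
        # refined saddle is a stationary point
        assert np.linalg.norm(pot.gradient(p)) < 1e-4


class TestLangevin:
    def test_free_diffusion_variance(self):
        flat = toysim.PotentialModel(
            "flat", 1, {}, lambda x: np.zeros(np.shape(x)[:-1]),
            lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        )
        n, D, dt = 5000, 0.7, 0.01
        ts = toysim.simulate_langevin(flat, toysim.NULL_BIAS, n, dt, 1.0, D,
                                      [0.0], seed=1)
        x = ts.trajectories[0].frames[:, 0]
        disp_var = x[-1] ** 2  # single path; use increments instead
        inc = np.diff(x)
        est = np.var(inc) / (2 * D * dt)
        se = np.sqrt(2.0 / len(inc))
        assert abs(est - 1.0) < 3 * se

    def test_harmonic_equipartition(self):
        k = 2.0
        pot = toysim.PotentialModel(
            "harm", 1, {"k": k},
            lambda x: 0.5 * k * np.asarray(x)[..., 0] ** 2,
            lambda x: k * np.asarray(x, dtype=float),
        )
        ts = toysim.simulate_langevin(pot, toysim.NULL_BIAS, 1_000_000, 0.01,
                                      1.0, 1.0, [0.0], seed=2, save_stride=10)
        x = ts.trajectories[0].frames[:, 0]
        g = 1 + 2 * 10  # rough decorrelation in saved frames (tau ~ 1/k/dt)
        n_eff = len(x) / g
        se = np.sqrt(2.0 / n_eff)
        assert abs(np.var(x) * k - 1.0) < 3 * se

    def test_double_well_basin_ratio_matches_quadrature(self):
        from conftest import quadrature_basin_delta_f

        pot = toysim.make_potential("tilted_double_well_1d", h=3.0, a=1.0,
                                    tilt=0.5)
        ts = toysim.simulate_langevin_batch(
            pot, [toysim.NULL_BIAS] * 8,
            np.array([[-1.0]] * 4 + [[1.0]] * 4), 150_000, 0.005, 1.0, 1.0,
            seed=3, save_stride=10, ensembles=[0] * 8,
        )
        x = np.concatenate([t.frames[:, 0] for t in ts.trajectories])
        split = 0.043  # barrier top of the tilted well (argmax U)
        est = -np.log(np.mean(x > split) / np.mean(x <= split))
        true = quadrature_basin_delta_f(pot, split)
        # hops are rare events; allow a generous stochastic margin
        assert est == pytest.approx(true, abs=0.35)

    def test_seed_determinism(self, double_well_pot):
        a = toysim.simulate_langevin(double_well_pot, toysim.NULL_BIAS, 500,
                                     0.005, 1.0, 1.0, [-1.0], seed=9)
        b = toysim.simulate_langevin(double_well_pot, toysim.NULL_BIAS, 500,
                                     0.005, 1.0, 1.0, [-1.0], seed=9)
        np.testing.assert_array_equal(a.trajectories[0].frames,
                                      b.trajectories[0].frames)

    def test_divergence_reports_step(self, double_well_pot):
        with np.errstate(over="ignore"), \
                pytest.raises(toysim.LangevinDivergedError), \
                pytest.warns(UserWarning, match="dt looks large"):
            toysim.simulate_langevin(double_well_pot, toysim.NULL_BIAS,
                                     2000, 50.0, 1.0, 1.0, [2.5], seed=0)


class TestUmbrella:
    def test_paper_style_window_layout(self):
        # 12 windows at unit spacing with the study's force constant; in kT
        # units that spacing is wide, so the overlap warning must fire
        flat = toysim.PotentialModel(
            "flat", 1, {}, lambda x: np.zeros(np.shape(x)[:-1]),
            lambda x: np.zeros_like(np.asarray(x, dtype=float)),
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("error")  # unit spacing at k=15 overlaps
            ts = toysim.generate_umbrella_ensembles(
                flat, np.arange(12, dtype=float), 15.0, 100,
                0.002, 1.0, seed=0,
            )
        assert ts.n_ensembles == 12
        assert all(b.kind == "harmonic" and b.force_constant == 15.0
                   for b in ts.biases)
        np.testing.assert_allclose([b.center for b in ts.biases],
                                   np.arange(12.0))
        # spacing beyond 4 sqrt(kT/k) must trigger the overlap warning
        with pytest.warns(UserWarning, match="overlap"):
            toysim.generate_umbrella_ensembles(
                flat, [0.0, 2.0], 15.0, 100, 0.002, 1.0, seed=0,
            )

    def test_zero_bias_window_matches_unbiased(self, double_well_pot):
        direct = toysim.simulate_langevin(double_well_pot, toysim.NULL_BIAS,
                                          300, 0.005, 1.0, 1.0, [0.5], seed=4)
        nobias = toysim.BiasSpec("harmonic", center=0.5, force_constant=1e-12)
        windowed = toysim.simulate_langevin(double_well_pot, nobias, 300,
                                            0.005, 1.0, 1.0, [0.5], seed=4)
        np.testing.assert_allclose(direct.trajectories[0].frames,
                                   windowed.trajectories[0].frames,
                                   atol=1e-9)

    def test_windows_cover_barrier(self, double_well_pot):
        ts = toysim.generate_umbrella_ensembles(
            double_well_pot, np.linspace(-1.3, 1.3, 8), 15.0, 20_000,
            0.005, 1.0, seed=5, save_stride=10,
        )
        x = np.concatenate([t.frames[:, 0] for t in ts.trajectories])
        counts, _ = np.histogram(x, bins=30, range=(-1.2, 1.2))
        assert np.all(counts > 0)

    def test_invalid_inputs(self, double_well_pot):
        with pytest.raises(ValueError, match="empty"):
            toysim.generate_umbrella_ensembles(double_well_pot, [], 15.0,
                                               10, 0.005, 1.0, seed=0)
        with pytest.raises(ValueError, match="positive"):
            toysim.generate_umbrella_ensembles(double_well_pot, [0.0], -1.0,
                                               10, 0.005, 1.0, seed=0)


class TestMarkovChain:
    def test_identity_matrix_gives_constant_sequences(self):
        dts = toysim.generate_markov_chain(np.eye(3), 50, 4, seed=0)
        for seq in dts.dtrajs:
            assert len(np.unique(seq)) == 1

    def test_two_state_frequencies_within_binomial_error(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        dts = toysim.generate_markov_chain(T, 100_000, 1, seed=1)
        seq = dts.dtrajs[0]
        for i in range(2):
            mask = seq[:-1] == i
            n = mask.sum()
            phat = np.mean(seq[1:][mask] != i)
            p = T[i, 1 - i]
            se = np.sqrt(p * (1 - p) / n)
            assert abs(phat - p) < 3 * se

    def test_block_occupancy_matches_stationary_eigenvector(self):
        from conftest import three_block_transition_matrix

        T = three_block_transition_matrix()
        vals, vecs = np.linalg.eig(T.T)
        pi = np.real(vecs[:, np.argmin(np.abs(vals - 1))])
        pi /= pi.sum()
        dts = toysim.generate_markov_chain(T, 200_000, 1, seed=2)
        seq = dts.dtrajs[0]
        occ = np.array([np.mean(seq // 3 == b) for b in range(3)])
        ref = np.array([pi[3 * b:3 * b + 3].sum() for b in range(3)])
        # block dwell times ~ 1/0.02 steps; effective sample size shrinks
        n_eff = len(seq) / 100
        se = np.sqrt(ref * (1 - ref) / n_eff)
        assert np.all(np.abs(occ - ref) < 3 * se + 1e-3)

    def test_non_stochastic_rejected(self):
        with pytest.raises(ValueError, match="stochastic"):
            toysim.generate_markov_chain(np.array([[0.5, 0.4], [0.2, 0.8]]),
                                         10, 1, seed=0)

    def test_seed_determinism(self):
        T = np.array([[0.9, 0.1], [0.2, 0.8]])
        a = toysim.generate_markov_chain(T, 100, 3, seed=5)
        b = toysim.generate_markov_chain(T, 100, 3, seed=5)
        for s1, s2 in zip(a.dtrajs, b.dtrajs):
            np.testing.assert_array_equal(s1, s2)


class TestNetworkFixture:
    def test_single_community_no_noise_fully_correlated(self):
        fx = toysim.generate_network_fixture(
            6, np.zeros(6, dtype=int), [0, 1, 2, 3, 4, 5], noise=0.0,
            n_frames=200, seed=0,
        )
        c = toysim.verify_network_fixture(fx)["correlation"]
        np.testing.assert_allclose(c, 1.0, atol=1e-9)

    def test_cross_community_correlation_small(self):
        comm = np.array([0] * 10 + [1] * 10)
        fx = toysim.generate_network_fixture(
            20, comm, [0, 1, 2], noise=0.1, n_frames=5000, seed=1,
        )
        c = toysim.verify_network_fixture(fx)["correlation"]
        cross = [abs(c[i, j]) for i in range(3, 10) for j in range(10, 20)]
        assert np.max(cross) < 0.2  # Fisher-z bound at 5000 frames ~ 0.05

    def test_backbone_contacts_persist(self, planted_network):
        pers = toysim.verify_network_fixture(
            planted_network
        )["contact_persistence"]
        assert min(pers.values()) >= 0.9

    def test_same_community_correlation_strong(self, planted_network):
        fx = planted_network
        c = toysim.verify_network_fixture(fx)["correlation"]
        bb = fx.critical_nodes
        vals = [abs(c[i, j]) for i in bb for j in bb if i < j]
        assert np.mean(vals) >= 0.5


class TestBoltzmannConsistency:
    """Long-run histograms match exp(-(U+bias)/kT) (chi-square, fixed seed)."""

    @staticmethod
    def _chi2_pvalue(pot, bias, x, lo, hi, nbins=12):
        from scipy.integrate import quad

        def w(v):
            u = float(pot.energy(np.array([[v]]))[0])
            u += float(bias.energy(np.array([v])))
            return np.exp(-u)

        edges = np.linspace(lo, hi, nbins + 1)
        probs = np.array([quad(w, edges[i], edges[i + 1])[0]
                          for i in range(nbins)])
        probs /= probs.sum()
        x = x[(x >= lo) & (x < hi)]
        counts, _ = np.histogram(x, bins=edges)
        keep = probs * len(x) >= 5
        c, p = counts[keep], probs[keep]
        stat = np.sum((c - p / p.sum() * c.sum()) ** 2 /
                      (p / p.sum() * c.sum()))
        return 1.0 - stats.chi2.cdf(stat, df=keep.sum() - 1)

    def test_biased_window_histogram(self):
        pot = toysim.make_potential("double_well_1d", h=2.0)
        bias = toysim.BiasSpec("harmonic", center=0.5, force_constant=10.0)
        ts = toysim.simulate_langevin(pot, bias, 200_000, 0.005, 1.0, 1.0,
                                      [0.5], seed=21, save_stride=100)
        x = ts.trajectories[0].frames[200:, 0]
        assert self._chi2_pvalue(pot, bias, x, -0.6, 1.4) > 0.01
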