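"""Multi-ensemble Markov model estimation: bias tables, reversible MSM,
TRAM, implied timescales, free energies and surfaces."""

import numpy as np
import pytest
from scipy.optimize import minimize

from memmpath import memm, microstates, toysim
from memmpath.toysim import BiasSpec, DiscreteTrajectorySet, Trajectory, TrajectorySet


def _reversible_mle_oracle(C):
    """Reversible MLE via generic constrained optimization over symmetric
    flows (log-parameterized), independent of the fixed-point iteration."""
    C = np.asarray(C, dtype=float)
    n = C.shape[0]
    iu = np.triu_indices(n)

    def unpack(theta):
        X = np.zeros((n, n))
        X[iu] = np.exp(theta)
        X = X + X.T - np.diag(np.diag(X))
        return X

    def negll(theta):
        X = unpack(theta)
        T = X / X.sum(axis=1, keepdims=True)
        with np.errstate(divide="ignore"):
            ll = np.where(C > 0, C * np.log(np.maximum(T, 1e-300)), 0.0)
        return -ll.sum()

    theta0 = np.log((C + C.T + 1e-3)[iu])
    res = minimize(negll, theta0, method="L-BFGS-B",
                   options={"maxiter": 5000, "ftol": 1e-15, "gtol": 1e-12})
    X = unpack(res.x)
    return X / X.sum(axis=1, keepdims=True)


class TestBiasEnergies:
    def test_frame_at_center_zero(self):
        ts = TrajectorySet(
            [Trajectory(np.array([[0.5], [0.5]]), ensemble=0)],
            [BiasSpec("harmonic", center=0.5, force_constant=3.0)],
        )
        # the table convention puts the unbiased ensemble first
        tab = memm.evaluate_bias_energies(
            ts, biases=[toysim.NULL_BIAS, ts.biases[0]]
        )
        np.testing.assert_allclose(tab.tables[0][:, 1], 0.0)

    def test_closed_form_value(self):
        ts = TrajectorySet(
            [Trajectory(np.array([[1.0], [1.0]]), ensemble=0)],
            [BiasSpec("harmonic", center=0.0, force_constant=2.0)],
        )
        tab = memm.evaluate_bias_energies(
            ts, biases=[toysim.NULL_BIAS, ts.biases[0]]
        )
        np.testing.assert_allclose(tab.tables[0][:, 1], 1.0)

    def test_full_table_matches_bruteforce(self):
        rng = np.random.default_rng(0)
        biases = [toysim.NULL_BIAS] + [
            BiasSpec("harmonic", center=c, force_constant=k)
            for c, k in [(0.3, 4.0), (-0.8, 7.5)]
        ]
        trajs = [Trajectory(rng.normal(size=(20, 1)), ensemble=e)
                 for e in range(3)]
        ts = TrajectorySet(trajs, biases)
        tab = memm.evaluate_bias_energies(ts)
        for t, tr in enumerate(trajs):
            for f, x in enumerate(tr.frames[:, 0]):
                for k, b in enumerate(biases):
                    ref = 0.0 if b.kind == "none" else \
                        0.5 * b.force_constant * (x - b.center) ** 2
                    assert tab.tables[t][f, k] == pytest.approx(ref, abs=1e-12)

    def test_biased_ensemble_zero_requirement(self):
        with pytest.raises(ValueError, match="unbiased"):
            memm.BiasEnergyTable([np.ones((4, 2))])


class TestReversibleMSM:
    def test_symmetric_counts_forced_swap(self):
        T, pi, _ = memm.estimate_reversible_msm(np.array([[0, 5], [5, 0]]))
        np.testing.assert_allclose(T, [[0, 1], [1, 0]], atol=1e-12)
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_matches_constrained_optimizer(self):
        C = np.array([[90, 10], [20, 80]])
        T, pi, _ = memm.estimate_reversible_msm(C)
        T_ref = _reversible_mle_oracle(C)
        np.testing.assert_allclose(T, T_ref, atol=1e-6)

    def test_matches_optimizer_three_states(self):
        C = np.array([[50, 6, 2], [9, 70, 5], [1, 8, 40]])
        T, pi, _ = memm.estimate_reversible_msm(C)
        T_ref = _reversible_mle_oracle(C)
        np.testing.assert_allclose(T, T_ref, atol=1e-5)

    def test_detailed_balance_on_random_counts(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            n = rng.integers(2, 7)
            C = rng.integers(1, 60, size=(n, n))
            T, pi, _ = memm.estimate_reversible_msm(C)
            flux = pi[:, None] * T
            assert np.max(np.abs(flux - flux.T)) < 1e-10
            assert np.max(np.abs(T.sum(axis=1) - 1.0)) < 1e-10

    def test_empty_counts_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            memm.estimate_reversible_msm(np.zeros((3, 3)))


class TestTRAM:
    def _single_ensemble(self, seed=0, n_steps=4000):
        T = np.array([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.05, 0.15, 0.8]])
        dts = toysim.generate_markov_chain(T, n_steps, 3, seed=seed)
        cnt = microstates.count_transitions(dts, 1)
        bias = memm.BiasEnergyTable([np.zeros((len(d), 1))
                                     for d in dts.dtrajs])
        return dts, cnt, bias

    def test_reduces_to_reversible_msm(self):
        dts, cnt, bias = self._single_ensemble()
        T_msm, pi_msm, _ = memm.estimate_reversible_msm(cnt.counts[0])
        model = memm.estimate_tram(cnt, dts, bias, tol=1e-10)
        sub, T_tram = model.unbiased_transition_matrix()
        assert model.converged
        np.testing.assert_allclose(T_tram, T_msm, atol=1e-6)
        f_ref = -np.log(pi_msm)
        np.testing.assert_allclose(model.f - model.f.min(),
                                   f_ref - f_ref.min(), atol=1e-6)

    def test_duplicated_ensembles_leave_f_unchanged(self):
        dts, cnt, bias = self._single_ensemble(seed=3)
        model1 = memm.estimate_tram(cnt, dts, bias, tol=1e-10)
        dts2 = DiscreteTrajectorySet(
            list(dts.dtrajs) + [d.copy() for d in dts.dtrajs],
            [0] * 3 + [1] * 3, 3,
        )
        cnt2 = microstates.count_transitions(dts2, 1)
        bias2 = memm.BiasEnergyTable([np.zeros((len(d), 2))
                                      for d in dts2.dtrajs])
        model2 = memm.estimate_tram(cnt2, dts2, bias2, tol=1e-10)
        d1 = model1.f - model1.f.min()
        d2 = model2.f - model2.f.min()
        np.testing.assert_allclose(d1, d2, atol=1e-6)

    def test_bias_gauge_invariance(self, double_well_tram):
        """Shifting one ensemble's bias energies by a constant must not
        change unbiased free-energy differences."""
        pot, disc, model = double_well_tram
        # rebuild with a shifted copy of the last biased ensemble
        # (cheap re-run at reduced size)
        from conftest import run_double_well_tram

        pot2, disc2, base = run_double_well_tram(seed=29, n_steps=8000, k=12)
        # shift: rebuild bias table with +5 kT on ensemble 3 and re-estimate
        kT, stride = 1.0, 10
        unb = toysim.simulate_langevin_batch(
            pot2, [toysim.NULL_BIAS] * 2, np.tile(pot2.minima[0], (2, 1)),
            8000, 0.005, kT, 1.0, seed=29, save_stride=stride,
            ensembles=[0, 0],
        )
        umb = toysim.generate_umbrella_ensembles(
            pot2, np.linspace(-1.3, 1.3, 8), 15.0, 8000, 0.005, kT,
            seed=29 + 1000, diffusion=1.0, save_stride=stride,
        )
        ts = unb.extend(umb)
        feats = [tr.frames for tr in ts.trajectories]
        disc3 = microstates.kmeans_cluster(feats, 12, seed=29)
        dts = DiscreteTrajectorySet(
            disc3.dtrajs, [tr.ensemble for tr in ts.trajectories], 12
        )
        cnt = microstates.count_transitions(dts, 10)
        tab = memm.evaluate_bias_energies(ts, kT=kT)
        m_plain = memm.estimate_tram(cnt, dts, tab, tol=1e-9)
        shifted = [t.copy() for t in tab.tables]
        for t in shifted:
            t[:, 3] += 5.0
        m_shift = memm.estimate_tram(cnt, dts,
                                     memm.BiasEnergyTable(shifted), tol=1e-9)
        np.testing.assert_allclose(
            m_plain.f - m_plain.f.min(), m_shift.f - m_shift.f.min(),
            atol=1e-6,
        )

    def test_invariants_of_transition_matrices(self, double_well_tram):
        pot, disc, model = double_well_tram
        assert model.converged
        for sub, T in model.transition_matrices:
            if len(sub) == 0:
                continue
            assert np.max(np.abs(T.sum(axis=1) - 1.0)) < 1e-10
            vals, vecs = np.linalg.eig(T.T)
            p = np.real(vecs[:, np.argmin(np.abs(vals - 1.0))])
            p = np.abs(p) / np.abs(p).sum()
            flux = p[:, None] * T
            assert np.max(np.abs(flux - flux.T)) < 1e-8
        pi = model.stationary_distribution
        assert pi.sum() == pytest.approx(1.0, abs=1e-10)

    def test_free_energy_recovery_single_seed(self, double_well_tram):
        from conftest import quadrature_basin_delta_f

        pot, disc, model = double_well_tram
        split = 0.043
        pi = model.stationary_distribution
        cx = disc.centers[model.active_set, 0]
        est = -np.log(pi[cx > split].sum() / pi[cx <= split].sum())
        ref = quadrature_basin_delta_f(pot, split)
        assert est == pytest.approx(ref, abs=0.2)

    def test_no_connected_set_rejected(self):
        dts = DiscreteTrajectorySet([[0, 0], [1, 1]], [0, 1], 2)
        cnt = microstates.count_transitions(dts, 1)
        bias = memm.BiasEnergyTable([np.zeros((2, 2)), np.zeros((2, 2))])
        model = memm.estimate_tram(cnt, dts, bias)
        # only one (state, ensemble) island survives
        assert len(model.active_set) == 1


class TestImpliedTimescales:
    def test_two_state_closed_form_flat_in_lag(self):
        p, q = 0.1, 0.2
        T = np.array([[1 - p, p], [q, 1 - q]])
        dts = toysim.generate_markov_chain(T, 200_000, 1, seed=4)
        its = memm.implied_timescales(dts, lags=[1, 2, 5, 10], n_its=1)
        ref = -1.0 / np.log(1 - p - q)
        for lag, vals in its.items():
            assert vals[0] == pytest.approx(ref, rel=0.1)

    def test_three_block_matches_generator_spectrum(self):
        from conftest import three_block_transition_matrix

        T = three_block_transition_matrix()
        vals = np.sort(np.linalg.eigvals(T).real)[::-1]
        ref = -1.0 / np.log(vals[1:3])
        dts = toysim.generate_markov_chain(T, 500_000, 2, seed=5)
        its = memm.implied_timescales(dts, lags=[1], n_its=2)
        np.testing.assert_allclose(its[1], ref, rtol=0.1)

    def test_white_noise_timescales_vanish(self):
        rng = np.random.default_rng(6)
        dts = DiscreteTrajectorySet([rng.integers(3, size=20_000)], [0], 3)
        its = memm.implied_timescales(dts, lags=[1], n_its=2)
        vals = its[1]
        assert np.all(np.isnan(vals) | (vals < 1.0))


class TestFreeEnergies:
    def test_reference_all_states_min_zero(self, double_well_tram):
        _, _, model = double_well_tram
        _, dg = memm.microstate_free_energies(model)
        assert dg.min() == pytest.approx(0.0, abs=1e-12)

    def test_two_state_closed_form(self):
        model = memm.MEMM(
            active_set=np.array([0, 1]),
            f=-np.log(np.array([0.8, 0.2])),
            f_k=np.zeros((1, 2)), transition_matrices=[], lag=1,
            converged=True, residual=0.0, n_iter=1,
        )
        _, dg = memm.microstate_free_energies(model, reference=[0])
        assert dg[1] == pytest.approx(np.log(4.0))

    def test_empty_reference_rejected(self, double_well_tram):
        _, _, model = double_well_tram
        with pytest.raises(ValueError, match="reference"):
            memm.microstate_free_energies(model, reference=[10**6])

    def test_barrier_microstate_vs_quadrature(self, double_well_tram):
        from conftest import quadrature_cell_free_energies

        pot, disc, model = double_well_tram
        f_oracle = quadrature_cell_free_energies(pot, disc.centers[:, 0])
        fo = f_oracle[model.active_set]
        dg_o = fo - np.nanmin(fo)
        dg_e = model.f - model.f.min()
        cx = disc.centers[model.active_set, 0]
        ibar = np.argmin(np.abs(cx - 0.043))
        assert dg_e[ibar] == pytest.approx(dg_o[ibar], abs=0.3)


class TestFES:
    def test_uniform_weights_flat_surface(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1, size=(200_000, 2))
        w = np.full(len(pts), 1.0 / len(pts))
        fes = memm.free_energy_surface(pts, w, bins=5)
        spread = np.nanmax(fes.delta_g) - np.nanmin(fes.delta_g)
        assert spread < 0.05      # binning noise only

    def test_harmonic_profile_curvature(self):
        # biased sampling from a k=4 harmonic well reweighted to unbiased
        k_true, kT = 4.0, 1.0
        rng = np.random.default_rng(8)
        bias_k, center = 6.0, 0.3
        tot = k_true + bias_k
        mean = bias_k * center / tot
        x = rng.normal(mean, np.sqrt(kT / tot), size=400_000)
        logw = 0.5 * bias_k * (x - center) ** 2 / kT
        w = np.exp(logw - logw.max())
        w /= w.sum()
        fes = memm.free_energy_surface(x[:, None], w, bins=(25, 1), kT=kT,
                                       extent=[(-1.2, 1.2), (-1, 1)])
        xc = 0.5 * (fes.x_edges[:-1] + fes.x_edges[1:])
        prof = fes.delta_g[:, 0]
        ok = ~np.isnan(prof)
        coef = np.polyfit(xc[ok], prof[ok], 2)
        assert coef[0] * 2 == pytest.approx(k_true, rel=0.1)

    def test_masked_bins_not_exported(self):
        pts = np.array([[0.1, 0.1], [0.9, 0.9]])
        w = np.array([0.5, 0.5])
        fes = memm.free_energy_surface(pts, w, bins=4,
                                       extent=[(0, 1), (0, 1)])
        table = fes.to_table()
        assert len(table) == 2
        assert np.all(np.isfinite(table[:, 2]))

    def test_all_outside_grid_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            memm.free_energy_surface(np.ones((5, 2)), np.ones(5) / 5,
                                     bins=3, extent=[(10, 11), (10, 11)])
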