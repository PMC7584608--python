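"""Shared fixtures and independent oracle helpers for the suite."""

import numpy as np
import pytest

from memmpath import toysim


def three_block_transition_matrix(n_per_block=3, intra=0.98):
    """Metastable chain: probability ``intra`` stays inside the block."""
    n = 3 * n_per_block
    T = np.zeros((n, n))
    for i in range(n):
        b = i // n_per_block
        peers = [j for j in range(n) if j // n_per_block == b]
        others = [j for j in range(n) if j // n_per_block != b]
        for j in peers:
            T[i, j] = intra / len(peers)
        for j in others:
            T[i, j] = (1 - intra) / len(others)
    return T


def random_reversible_chain(n, rng):
    """Reversible transition matrix from a random symmetric flow matrix."""
    X = rng.uniform(0.1, 1.0, size=(n, n))
    X = X + X.T
    T = X / X.sum(axis=1, keepdims=True)
    pi = X.sum(axis=1) / X.sum()
    return T, pi


def ar1_series(phi, n, rng):
    e = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = e[0]
    for i in range(1, n):
        x[i] = phi * x[i - 1] + e[i]
    return x


def quadrature_cell_free_energies(potential, centers, kT=1.0, lo=-6.0, hi=6.0):
    """-ln of Boltzmann weight per 1-D Voronoi cell of sorted centers."""
    from scipy.integrate import quad

    order = np.argsort(centers)
    cs = centers[order]
    edges = np.concatenate([[lo], (cs[:-1] + cs[1:]) / 2.0, [hi]])
    z = np.array([
        quad(lambda x: np.exp(-float(potential.energy(np.array([[x]]))[0]) / kT),
             edges[i], edges[i + 1])[0]
        for i in range(len(cs))
    ])
    f = np.full(len(cs), np.nan)
    f[order] = -np.log(z / z.sum())
    return f


def quadrature_basin_delta_f(potential, split, kT=1.0, lo=-6.0, hi=6.0):
    """Free-energy difference of the basins left/right of ``split``."""
    from scipy.integrate import quad

    w = lambda x: np.exp(-float(potential.energy(np.array([[x]]))[0]) / kT)
    za = quad(w, lo, split)[0]
    zb = quad(w, split, hi)[0]
    return -kT * np.log(zb / za)


def grid_minimax_oracle(potential, bounds, n_grid, a, b):
    """Independent saddle-level oracle: bisection on the energy threshold
    with connectivity by image labeling (no union-find, unlike the
    package's own search)."""
    from scipy import ndimage

    (x0, x1), (y0, y1) = bounds
    xs = np.linspace(x0, x1, n_grid)
    ys = np.linspace(y0, y1, n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    E = potential.energy(np.stack([X.ravel(), Y.ravel()], axis=1))
    E = E.reshape(n_grid, n_grid)
    ia = (np.abs(xs - a[0]).argmin(), np.abs(ys - a[1]).argmin())
    ib = (np.abs(xs - b[0]).argmin(), np.abs(ys - b[1]).argmin())
    levels = np.unique(E.ravel())
    lo_i, hi_i = 0, len(levels) - 1
    while hi_i - lo_i > 1:
        mid = (lo_i + hi_i) // 2
        lab, _ = ndimage.label(E <= levels[mid])
        if lab[ia] > 0 and lab[ia] == lab[ib]:
            hi_i = mid
        else:
            lo_i = mid
    return levels[hi_i]


@pytest.fixture(scope="session")
def double_well_pot():
    return toysim.make_potential("tilted_double_well_1d", h=3.0, a=1.0,
                                 tilt=0.5)


def run_double_well_tram(seed, n_steps=100_000, k=30, lag=10):
    """Full TRAM pipeline on the tilted double well: 8 umbrella windows +
    2 unbiased trajectories, k-means microstates in the coordinate."""
    from memmpath import memm, microstates

    pot = toysim.make_potential("tilted_double_well_1d", h=3.0, a=1.0,
                                tilt=0.5)
    kT, dt, D, stride = 1.0, 0.005, 1.0, 10
    unb = toysim.simulate_langevin_batch(
        pot, [toysim.NULL_BIAS] * 2, np.tile(pot.minima[0], (2, 1)),
        n_steps, dt, kT, D, seed=seed, save_stride=stride, ensembles=[0, 0],
    )
    umb = toysim.generate_umbrella_ensembles(
        pot, np.linspace(-1.3, 1.3, 8), 15.0, n_steps, dt, kT,
        seed=seed + 1000, diffusion=D, save_stride=stride,
    )
    ts = unb.extend(umb)
    feats = [tr.frames for tr in ts.trajectories]
    disc = microstates.kmeans_cluster(feats, k, seed=seed)
    dts = toysim.DiscreteTrajectorySet(
        disc.dtrajs, [tr.ensemble for tr in ts.trajectories], k
    )
    cnt = microstates.count_transitions(dts, lag)
    bias = memm.evaluate_bias_energies(ts, kT=kT)
    model = memm.estimate_tram(cnt, dts, bias, tol=1e-8, max_iter=100_000)
    return pot, disc, model


@pytest.fixture(scope="session")
def double_well_tram():
    """One moderate-size TRAM run shared by the unit tests."""
    return run_double_well_tram(seed=11, n_steps=60_000)


@pytest.fixture(scope="session")
def planted_network():
    n_nodes, n_bb = 60, 10
    comm = np.zeros(n_nodes, dtype=int)
    rest = np.arange(n_bb, n_nodes)
    comm[rest] = 1 + (rest - n_bb) % 2
    return toysim.generate_network_fixture(
        n_nodes, comm, list(range(n_bb)), noise=0.5, n_frames=5000, seed=7
    )
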