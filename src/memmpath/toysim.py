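"""Synthetic dynamics generators.

Everything downstream of this module (featurization, TICA, microstate
clustering, TRAM, PCCA+, kinetics, network scoring, band optimization) is
exercised on data produced here: analytic multi-well potentials, overdamped
Langevin trajectories with optional harmonic umbrella biases, discrete Markov
chains with planted metastable structure, and coordinate trajectories of
pseudo-residue "nodes" with planted correlated communities, contacts and
conservation scores.

Units are internal throughout: energies in kT (kT = 1), times in integration
steps, lengths dimensionless.  Physical units (kcal/mol, ns, Angstrom) only
ever appear as metadata attached by the caller.
"""

from __future__ import annotations

import dataclasses
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "PotentialModel",
    "BiasSpec",
    "Trajectory",
    "TrajectorySet",
    "DiscreteTrajectorySet",
    "NetworkFixture",
    "make_potential",
    "simulate_langevin",
    "generate_umbrella_ensembles",
    "generate_markov_chain",
    "generate_network_fixture",
    "verify_network_fixture",
    "grid_minimax_saddle",
    "LangevinDivergedError",
]


# ---------------------------------------------------------------------------
# Potentials
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PotentialModel:
    """Analytic potential energy model U(x) with gradient, energies in kT.

    ``energy`` and ``gradient`` accept a single configuration of shape (d,)
    or a batch of shape (n, d) and broadcast accordingly.
    """

    name: str
    dimensionality: int
    params: dict
    energy: Callable[[np.ndarray], np.ndarray]
    gradient: Callable[[np.ndarray], np.ndarray]
    minima: tuple = ()

    def __call__(self, x):
        return self.energy(np.asarray(x, dtype=float))


def _double_well_1d(h: float, a: float) -> PotentialModel:
    # U(x) = h ((x/a)^2 - 1)^2 + tilt * x ; minima near +-a, barrier ~h at 0
    def u(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        x0 = x[..., 0]
        return h * ((x0 / a) ** 2 - 1.0) ** 2

    def g(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        x0 = x[..., 0]
        out = np.zeros_like(x)
        out[..., 0] = 4.0 * h * x0 * ((x0 / a) ** 2 - 1.0) / a**2
        return out

    return PotentialModel(
        "double_well_1d", 1, {"h": h, "a": a}, u, g,
        minima=((-a,), (a,)),
    )


def _tilted_double_well_1d(h: float, a: float, tilt: float) -> PotentialModel:
    base = _double_well_1d(h, a)

    def u(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        return base.energy(x) + tilt * x[..., 0]

    def g(x):
        x = np.atleast_1d(np.asarray(x, dtype=float))
        out = base.gradient(x).copy()
        out[..., 0] += tilt
        return out

    # minima shift slightly under the tilt; refine by Newton on the gradient
    mins = []
    for x0 in (-a, a):
        xk = float(x0)
        for _ in range(60):
            gg = 4.0 * h * xk * ((xk / a) ** 2 - 1.0) / a**2 + tilt
            hh = 4.0 * h * (3.0 * xk**2 / a**2 - 1.0) / a**2
            xk -= gg / hh
        mins.append((xk,))
    return PotentialModel(
        "tilted_double_well_1d", 1, {"h": h, "a": a, "tilt": tilt}, u, g,
        minima=tuple(mins),
    )


def _double_well_2d(h: float, a: float, ky: float) -> PotentialModel:
    # quartic double well along x, harmonic confinement along y;
    # saddle at the origin with energy h
    def u(x):
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        return h * ((xx / a) ** 2 - 1.0) ** 2 + 0.5 * ky * yy**2

    def g(x):
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        return np.stack([
            4.0 * h * xx * ((xx / a) ** 2 - 1.0) / a**2,
            ky * yy,
        ], axis=-1)

    return PotentialModel(
        "double_well_2d", 2, {"h": h, "a": a, "ky": ky}, u, g,
        minima=((-a, 0.0), (a, 0.0)),
    )


def _triple_well_2d() -> PotentialModel:
    # classic 2-D triple well: two deep wells at (+-1, 0), shallow well near
    # (0, 5/3), saddles a few kT above the deep minima.
    def u(x):
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        return (
            +3.0 * np.exp(-(xx**2) - (yy - 1.0 / 3.0) ** 2)
            - 3.0 * np.exp(-(xx**2) - (yy - 5.0 / 3.0) ** 2)
            - 5.0 * np.exp(-((xx - 1.0) ** 2) - yy**2)
            - 5.0 * np.exp(-((xx + 1.0) ** 2) - yy**2)
            + 0.2 * xx**4
            + 0.2 * (yy - 1.0 / 3.0) ** 4
        )

    def g(x):
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        e1 = np.exp(-(xx**2) - (yy - 1.0 / 3.0) ** 2)
        e2 = np.exp(-(xx**2) - (yy - 5.0 / 3.0) ** 2)
        e3 = np.exp(-((xx - 1.0) ** 2) - yy**2)
        e4 = np.exp(-((xx + 1.0) ** 2) - yy**2)
        gx = (
            3.0 * e1 * (-2 * xx)
            - 3.0 * e2 * (-2 * xx)
            - 5.0 * e3 * (-2 * (xx - 1.0))
            - 5.0 * e4 * (-2 * (xx + 1.0))
            + 0.8 * xx**3
        )
        gy = (
            3.0 * e1 * (-2 * (yy - 1.0 / 3.0))
            - 3.0 * e2 * (-2 * (yy - 5.0 / 3.0))
            - 5.0 * e3 * (-2 * yy)
            - 5.0 * e4 * (-2 * yy)
            + 0.8 * (yy - 1.0 / 3.0) ** 3
        )
        return np.stack([gx, gy], axis=-1)

    return PotentialModel(
        "triple_well_2d", 2, {}, u, g,
        minima=((-1.0, 0.0), (1.0, 0.0), (0.0, 1.534)),
    )


_MB_A = (-200.0, -100.0, -170.0, 15.0)
_MB_a = (-1.0, -1.0, -6.5, 0.7)
_MB_b = (0.0, 0.0, 11.0, 0.6)
_MB_c = (-10.0, -10.0, -6.5, 0.7)
_MB_x0 = (1.0, 0.0, -0.5, -1.0)
_MB_y0 = (0.0, 0.5, 1.5, 1.0)


def _mueller_brown_like(scale: float) -> PotentialModel:
    """Sum of four anisotropic Gaussians with two saddle points.

    ``scale`` maps the conventional parameterization onto a kT-sized energy
    range (default 0.05 puts the lower barrier at a few kT).
    """

    def terms(x):
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        out = []
        for A, a, b, c, p, q in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            dx, dy = xx - p, yy - q
            out.append(A * np.exp(a * dx**2 + b * dx * dy + c * dy**2))
        return out

    def u(x):
        return scale * sum(terms(x))

    def g(x):
        x = np.asarray(x, dtype=float)
        xx, yy = x[..., 0], x[..., 1]
        gx = np.zeros_like(xx)
        gy = np.zeros_like(yy)
        for A, a, b, c, p, q in zip(_MB_A, _MB_a, _MB_b, _MB_c, _MB_x0, _MB_y0):
            dx, dy = xx - p, yy - q
            e = A * np.exp(a * dx**2 + b * dx * dy + c * dy**2)
            gx += e * (2 * a * dx + b * dy)
            gy += e * (b * dx + 2 * c * dy)
        return scale * np.stack([gx, gy], axis=-1)

    return PotentialModel(
        "mueller_brown_like", 2, {"scale": scale}, u, g,
        minima=((-0.558, 1.442), (-0.050, 0.467), (0.623, 0.028)),
    )


_FAMILIES = {
    "double_well_1d": lambda **p: _double_well_1d(
        h=p.get("h", 3.0), a=p.get("a", 1.0)
    ),
    "tilted_double_well_1d": lambda **p: _tilted_double_well_1d(
        h=p.get("h", 3.0), a=p.get("a", 1.0), tilt=p.get("tilt", 0.5)
    ),
    "double_well_2d": lambda **p: _double_well_2d(
        h=p.get("h", 3.0), a=p.get("a", 1.0), ky=p.get("ky", 4.0)
    ),
    "triple_well_2d": lambda **p: _triple_well_2d(),
    "mueller_brown_like": lambda **p: _mueller_brown_like(
        scale=p.get("scale", 0.05)
    ),
}


def make_potential(name: str, **params) -> PotentialModel:
    """Construct a named analytic potential (energies in kT).

    Families: ``double_well_1d`` (h barrier height, a minimum position),
    ``tilted_double_well_1d`` (adds a linear term making the wells
    inequivalent), ``triple_well_2d``, ``mueller_brown_like`` (scale).
    """
    if name not in _FAMILIES:
        raise ValueError(
            f"unknown potential {name!r}; known: {sorted(_FAMILIES)}"
        )
    pot = _FAMILIES[name](**params)
    if pot.dimensionality > 1:
        # polish tabulated minima so they are stationary to high precision
        from scipy.optimize import minimize

        refined = []
        for m in pot.minima:
            res = minimize(lambda z: float(pot.energy(z)),
                           np.asarray(m, dtype=float),
                           jac=lambda z: pot.gradient(z), method="BFGS",
                           options={"gtol": 1e-12})
            refined.append(tuple(res.x))
        pot = dataclasses.replace(pot, minima=tuple(refined))
    for m in pot.minima:
        e = float(pot.energy(np.asarray(m, dtype=float)))
        if not np.isfinite(e):
            raise ValueError(f"non-finite energy at declared minimum {m}")
    return pot


# ---------------------------------------------------------------------------
# Bias specifications
# ---------------------------------------------------------------------------

def _first_coordinate(x: np.ndarray) -> np.ndarray:
    return np.asarray(x)[..., 0]


def _first_coordinate_grad(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    g[..., 0] = 1.0
    return g


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic (or null) restraint on a scalar reaction coordinate.

    ``coordinate_map`` maps a configuration to the scalar coordinate;
    ``coordinate_grad`` is its gradient, required for sampling under bias.
    The bias energy is ``force_constant/2 * (rc - center)^2`` in kT.
    """

    kind: str = "none"  # {"none", "harmonic"}
    center: float = 0.0
    force_constant: float = 0.0
    coordinate_map: Callable[[np.ndarray], np.ndarray] = _first_coordinate
    coordinate_grad: Callable[[np.ndarray], np.ndarray] = _first_coordinate_grad

    def __post_init__(self):
        if self.kind not in ("none", "harmonic"):
            raise ValueError(f"bias kind {self.kind!r} not in {{none, harmonic}}")
        if self.force_constant < 0:
            raise ValueError("force_constant must be >= 0")

    def energy(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros(np.asarray(x).shape[:-1])
        rc = self.coordinate_map(x)
        return 0.5 * self.force_constant * (rc - self.center) ** 2

    def gradient(self, x: np.ndarray) -> np.ndarray:
        if self.kind == "none":
            return np.zeros_like(np.asarray(x, dtype=float))
        rc = self.coordinate_map(x)
        drc = self.coordinate_grad(x)
        return (self.force_constant * (rc - self.center))[..., None] * drc


NULL_BIAS = BiasSpec()


# ---------------------------------------------------------------------------
# Trajectory containers
# ---------------------------------------------------------------------------

@dataclass
class Trajectory:
    frames: np.ndarray          # (T, d) coordinates or features
    ensemble: int = 0
    dt: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim == 1:
            self.frames = self.frames[:, None]
        if len(self.frames) < 2:
            raise ValueError("trajectory needs >= 2 frames")

    def __len__(self):
        return len(self.frames)


@dataclass
class TrajectorySet:
    """Trajectories grouped by thermodynamic ensemble.

    ``biases[k]`` is the BiasSpec shared by every trajectory with
    ``ensemble == k``; ensemble indices must be contiguous from 0.
    """

    trajectories: list
    biases: list

    def __post_init__(self):
        ens = sorted({t.ensemble for t in self.trajectories})
        if ens != list(range(len(self.biases))):
            raise ValueError(
                f"ensemble indices {ens} not contiguous over {len(self.biases)} biases"
            )

    @property
    def n_ensembles(self) -> int:
        return len(self.biases)

    def by_ensemble(self, k: int) -> list:
        return [t for t in self.trajectories if t.ensemble == k]

    def extend(self, other: "TrajectorySet") -> "TrajectorySet":
        """Concatenate, re-indexing the other set's ensembles after ours."""
        off = self.n_ensembles
        moved = [
            dataclasses.replace(t, ensemble=t.ensemble + off)
            for t in other.trajectories
        ]
        return TrajectorySet(
            self.trajectories + moved, list(self.biases) + list(other.biases)
        )


@dataclass
class DiscreteTrajectorySet:
    """Integer state sequences with a per-sequence ensemble index."""

    dtrajs: list                # list of int arrays
    ensembles: list             # ensemble index per sequence
    n_states: int

    def __post_init__(self):
        self.dtrajs = [np.asarray(d, dtype=np.int64) for d in self.dtrajs]
        if len(self.dtrajs) != len(self.ensembles):
            raise ValueError("one ensemble index per sequence required")
        for d in self.dtrajs:
            if len(d) < 2:
                raise ValueError("sequences must have length >= 2")
            if d.min() < 0 or d.max() >= self.n_states:
                raise ValueError("state index outside [0, n_states)")


class LangevinDivergedError(RuntimeError):
    def __init__(self, step: int):
        super().__init__(f"non-finite coordinate at step {step}")
        self.step = step


# ---------------------------------------------------------------------------
# Brownian (overdamped Langevin) dynamics
# ---------------------------------------------------------------------------

def _traj_rng(seed: int, index: int) -> np.random.Generator:
    # independent substream per (seed, trajectory index): adding trajectories
    # never reshuffles existing ones
    return np.random.default_rng(np.random.SeedSequence(seed).spawn(index + 1)[index])


def _integrate_batch(potential, biases, x0, n_steps, dt, kT, diffusion, rngs,
                     save_stride=1):
    """Euler–Maruyama on U + bias for a batch of walkers, one rng each.

    x <- x - D grad(U+b) dt / kT + sqrt(2 D dt) xi.  Returns saved frames of
    shape (n_saved, n_walkers, d) including the initial configuration.
    """
    x = np.array(x0, dtype=float)          # (n, d)
    n, d = x.shape
    amp = np.sqrt(2.0 * diffusion * dt)
    scale = diffusion * dt / kT
    n_saved = n_steps // save_stride + 1
    out = np.empty((n_saved, n, d))
    out[0] = x
    # pre-draw noise per walker from its own stream, in chunks to bound memory
    chunk = 20000
    step = 0
    save_i = 1
    while step < n_steps:
        m = min(chunk, n_steps - step)
        noise = np.empty((m, n, d))
        for w, rng in enumerate(rngs):
            noise[:, w, :] = rng.standard_normal((m, d))
        for s in range(m):
            grad = potential.gradient(x)
            for w, b in enumerate(biases):
                if b.kind != "none":
                    grad[w] += b.gradient(x[w])
            x = x - scale * grad + amp * noise[s]
            step += 1
            if not np.all(np.isfinite(x)):
                raise LangevinDivergedError(step)
            if step % save_stride == 0:
                out[save_i] = x
                save_i += 1
    return out[:save_i]


def simulate_langevin(potential: PotentialModel, bias: BiasSpec, n_steps: int,
                      dt: float, kT: float, diffusion: float,
                      x0: Sequence[float], seed: int,
                      save_stride: int = 1) -> TrajectorySet:
    """Single overdamped Langevin trajectory under U + bias.

    The long-run histogram converges to exp(-(U+bias)/kT).  ``save_stride``
    thins the saved frames (the update itself always uses ``dt``).
    """
    x0 = np.atleast_1d(np.asarray(x0, dtype=float))
    g0 = potential.gradient(x0) + bias.gradient(x0)
    if np.max(np.abs(g0)) * dt * diffusion / kT >= 0.5 * max(1.0, np.linalg.norm(x0)):
        warnings.warn("dt looks large for the initial gradient; risk of divergence")
    rng = _traj_rng(seed, 0)
    frames = _integrate_batch(
        potential, [bias], x0[None, :], n_steps, dt, kT, diffusion, [rng],
        save_stride=save_stride,
    )[:, 0, :]
    traj = Trajectory(frames, ensemble=0, dt=dt * save_stride, seed=seed)
    return TrajectorySet([traj], [bias])


def simulate_langevin_batch(potential, biases, x0s, n_steps, dt, kT, diffusion,
                            seed, save_stride=1, ensembles=None):
    """Many walkers integrated in lockstep, one rng substream per walker.

    Statistically identical to calling :func:`simulate_langevin` per walker
    with the matching substream, but vectorized over walkers.
    """
    x0s = np.asarray(x0s, dtype=float)
    if x0s.ndim == 1:
        x0s = x0s[:, None]
    n = len(x0s)
    rngs = [_traj_rng(seed, i) for i in range(n)]
    frames = _integrate_batch(potential, biases, x0s, n_steps, dt, kT,
                              diffusion, rngs, save_stride=save_stride)
    if ensembles is None:
        ensembles = list(range(n))
        bias_list = list(biases)
    else:
        bias_list = []
        for k in range(max(ensembles) + 1):
            bias_list.append(biases[ensembles.index(k)])
    trajs = [
        Trajectory(frames[:, i, :], ensemble=ensembles[i],
                   dt=dt * save_stride, seed=seed)
        for i in range(n)
    ]
    return TrajectorySet(trajs, bias_list)


def generate_umbrella_ensembles(potential: PotentialModel,
                                centers: Sequence[float],
                                force_constant: float,
                                steps_per_window: int, dt: float, kT: float,
                                seed: int, diffusion: float = 1.0,
                                save_stride: int = 1) -> TrajectorySet:
    """One harmonic umbrella window per center, seeded at its own center.

    Neighboring windows should overlap: spacing below ~4 sqrt(kT/k) keeps the
    pooled biased histograms gap-free across a barrier.
    """
    centers = np.asarray(centers, dtype=float)
    if centers.size == 0:
        raise ValueError("empty centers")
    if force_constant <= 0:
        raise ValueError("force constant must be positive")
    if np.any(np.diff(centers) <= 0):
        raise ValueError("centers must be strictly increasing")
    sigma = np.sqrt(kT / force_constant)
    if centers.size > 1 and np.max(np.diff(centers)) > 4.0 * sigma:
        warnings.warn("umbrella windows may not overlap (spacing > 4 sigma)")
    biases = [
        BiasSpec("harmonic", center=float(c), force_constant=force_constant)
        for c in centers
    ]
    d = potential.dimensionality
    x0s = np.zeros((len(centers), d))
    x0s[:, 0] = centers
    return simulate_langevin_batch(
        potential, biases, x0s, steps_per_window, dt, kT, diffusion, seed,
        save_stride=save_stride, ensembles=list(range(len(centers))),
    )


# ---------------------------------------------------------------------------
# Discrete Markov chains
# ---------------------------------------------------------------------------

def generate_markov_chain(T: np.ndarray, n_steps: int, n_trajs: int,
                          seed: int, ensemble: int = 0,
                          start_states=None) -> DiscreteTrajectorySet:
    """Sample state sequences from a row-stochastic transition matrix."""
    T = np.asarray(T, dtype=float)
    if T.ndim != 2 or T.shape[0] != T.shape[1]:
        raise ValueError("T must be square")
    if np.any(T < 0) or np.max(np.abs(T.sum(axis=1) - 1.0)) > 1e-12:
        raise ValueError("T is not row-stochastic")
    n = T.shape[0]
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    dtrajs = []
    for i in range(n_trajs):
        rng = _traj_rng(seed, i)
        if start_states is None:
            s = int(rng.integers(n))
        else:
            s = int(start_states[i % len(start_states)])
        u = rng.random(n_steps)
        seq = np.empty(n_steps + 1, dtype=np.int64)
        seq[0] = s
        for t in range(n_steps):
            s = int(np.searchsorted(cum[s], u[t], side="right"))
            seq[t + 1] = s
        dtrajs.append(seq)
    return DiscreteTrajectorySet(dtrajs, [ensemble] * n_trajs, n)


# ---------------------------------------------------------------------------
# Network fixtures with planted structure
# ---------------------------------------------------------------------------

@dataclass
class NetworkFixture:
    """Pseudo-residue coordinate trajectory with planted ground truth.

    Nodes in the same community share a latent displacement (high pairwise
    correlation); backbone nodes form a contact chain from source to sink and
    additionally share a backbone latent, making the chain the dominant
    communication route.  Conservation is planted at 1.0 on critical nodes.
    """

    frames: np.ndarray                  # (T, n_nodes, 3)
    communities: np.ndarray             # (n_nodes,) community label
    contacts: list                      # planted (i, j) contact pairs
    conservation: dict                  # node -> score in [0, 1]
    source: int
    sink: int
    critical_nodes: list                # planted high-traffic nodes
    contact_cutoff: float
    persistence: float                  # declared min persistence of contacts


def generate_network_fixture(n_nodes: int, communities, backbone_path,
                             noise: float, n_frames: int, seed: int,
                             contact_cutoff: float = 5.0,
                             latent_amp: float = 1.0) -> NetworkFixture:
    """Plant communities, a contact backbone, and conservation scores.

    ``communities`` is a node->label array (or list of member lists);
    ``backbone_path`` an ordered node chain from source to sink.  Same-
    community displacement correlation is latent^2/(latent^2+noise^2) by
    construction, >= 0.5 whenever noise <= latent_amp.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    if isinstance(communities, (list, tuple)) and communities and \
            isinstance(communities[0], (list, tuple)):
        lab = np.empty(n_nodes, dtype=int)
        for c, members in enumerate(communities):
            lab[list(members)] = c
        communities = lab
    communities = np.asarray(communities, dtype=int)
    if communities.shape != (n_nodes,):
        raise ValueError("communities must label every node")
    backbone = list(backbone_path)
    if len(backbone) < 2:
        raise ValueError("backbone must connect source to sink")

    # base geometry: communities on a coarse grid, far apart; backbone nodes
    # re-placed on a chain with spacing safely inside the cutoff
    n_comm = communities.max() + 1
    comm_centers = rng.normal(size=(n_comm, 3))
    comm_centers *= (6.0 * contact_cutoff) / np.maximum(
        np.linalg.norm(comm_centers, axis=1, keepdims=True), 1e-9
    )
    comm_centers *= np.arange(1, n_comm + 1)[:, None]
    base = comm_centers[communities] + rng.normal(scale=0.3 * contact_cutoff,
                                                  size=(n_nodes, 3))
    spacing = 0.6 * contact_cutoff
    direction = np.array([1.0, 0.0, 0.0])
    origin = base[backbone[0]].copy()
    for idx, node in enumerate(backbone):
        base[node] = origin + idx * spacing * direction

    # displacements: community latent + backbone latent + node noise
    comm_lat = rng.normal(scale=latent_amp, size=(n_frames, n_comm, 3))
    bb_lat = rng.normal(scale=latent_amp, size=(n_frames, 3))
    disp = comm_lat[:, communities, :]
    in_bb = np.zeros(n_nodes, dtype=bool)
    in_bb[backbone] = True
    disp[:, in_bb, :] = bb_lat[:, None, :]
    disp += rng.normal(scale=noise, size=(n_frames, n_nodes, 3))
    # keep displacements small relative to the contact margin
    max_amp = np.sqrt(latent_amp**2 + noise**2)
    if max_amp > 0:
        disp *= min(1.0, 0.05 * contact_cutoff / max_amp)
    frames = base[None, :, :] + disp

    contacts = [(backbone[i], backbone[i + 1]) for i in range(len(backbone) - 1)]
    # planted contacts must actually persist under the cutoff
    for i, j in contacts:
        dij = np.linalg.norm(frames[:, i] - frames[:, j], axis=1)
        if np.mean(dij < contact_cutoff) < 0.9:
            raise RuntimeError("backbone chain not connected under the cutoff")

    conservation = {int(n): float(rng.uniform(0.0, 0.4)) for n in range(n_nodes)}
    critical = [int(n) for n in backbone[1:-1]]
    for n in backbone:
        conservation[int(n)] = 1.0
    return NetworkFixture(
        frames=frames, communities=communities, contacts=contacts,
        conservation=conservation, source=int(backbone[0]),
        sink=int(backbone[-1]), critical_nodes=critical,
        contact_cutoff=contact_cutoff, persistence=0.9,
    )


def verify_network_fixture(fx: NetworkFixture) -> dict:
    """Recompute the fixture's planted invariants from its coordinates."""
    d = fx.frames - fx.frames.mean(axis=0, keepdims=True)
    dots = np.einsum("tif,tjf->ij", d, d) / len(fx.frames)
    norm = np.sqrt(np.outer(np.diag(dots), np.diag(dots)))
    corr = dots / norm
    pers = {}
    for i, j in fx.contacts:
        dij = np.linalg.norm(fx.frames[:, i] - fx.frames[:, j], axis=1)
        pers[(i, j)] = float(np.mean(dij < fx.contact_cutoff))
    return {"correlation": corr, "contact_persistence": pers}


# ---------------------------------------------------------------------------
# Grid minimax saddle search (oracle-grade, independent of band optimization)
# ---------------------------------------------------------------------------

def grid_minimax_saddle(potential: PotentialModel, bounds, n_grid: int,
                        a=None, b=None, refine: bool = True):
    """Lowest saddle between two minima by threshold union-find on a grid.

    Cells are merged in order of increasing energy; the energy at which the
    components holding the two minima join is the minimax (saddle) level.
    The saddle location is then refined by minimizing |grad U|^2 locally.
    Returns (saddle_point, saddle_energy).
    """
    (x0, x1), (y0, y1) = bounds
    xs = np.linspace(x0, x1, n_grid)
    ys = np.linspace(y0, y1, n_grid)
    X, Y = np.meshgrid(xs, ys, indexing="ij")
    pts = np.stack([X.ravel(), Y.ravel()], axis=1)
    E = potential.energy(pts).reshape(n_grid, n_grid)

    if a is None or b is None:
        a, b = potential.minima[0], potential.minima[-1]
    ia = (np.abs(xs - a[0]).argmin(), np.abs(ys - a[1]).argmin())
    ib = (np.abs(xs - b[0]).argmin(), np.abs(ys - b[1]).argmin())

    order = np.argsort(E.ravel(), kind="stable")
    parent = np.full(n_grid * n_grid, -1, dtype=np.int64)  # -1: not yet active

    def find(i):
        root = i
        while parent[root] != root:
            root = parent[root]
        while parent[i] != root:
            parent[i], i = root, parent[i]
        return root

    la = ia[0] * n_grid + ia[1]
    lb = ib[0] * n_grid + ib[1]
    nbr = ((1, 0), (-1, 0), (0, 1), (0, -1))
    saddle_cell = None
    for flat in order:
        parent[flat] = flat
        i, j = divmod(int(flat), n_grid)
        for di, dj in nbr:
            ni, nj = i + di, j + dj
            if 0 <= ni < n_grid and 0 <= nj < n_grid:
                nflat = ni * n_grid + nj
                if parent[nflat] >= 0:
                    parent[find(flat)] = find(nflat)
        if parent[la] >= 0 and parent[lb] >= 0 and find(la) == find(lb):
            saddle_cell = (i, j)
            break
    if saddle_cell is None:
        raise RuntimeError("minima never connected on the grid")
    p = np.array([xs[saddle_cell[0]], ys[saddle_cell[1]]])
    if refine:
        from scipy.optimize import minimize

        res = minimize(
            lambda z: float(np.sum(potential.gradient(z) ** 2)), p,
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 4000},
        )
        if np.linalg.norm(res.x - p) < 3.0 * max(xs[1] - xs[0], ys[1] - ys[0]):
            p = res.x
    return p, float(potential.energy(p))
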