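"""Chain-of-replicas minimum-energy-path optimization (partial NEB).

A band of replicas connects two fixed endpoint configurations.  Interior
replicas feel the physical force with its component parallel to the path
projected out (improved-tangent convention) plus a spring force along the
tangent that keeps replicas spread; the "partial" variant applies those
band modifications only to a configurable subset of coordinates, all other
coordinates relax under the plain physical force.  Optimization follows a
simulated-annealing schedule: finite-temperature stages use overdamped
Langevin dynamics on the band forces, zero-temperature stages a damped
steepest descent with a step-size cap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Band",
    "AnnealingSchedule",
    "initialize_band",
    "neb_forces",
    "optimize_band",
    "band_convergence",
    "default_schedule",
]


@dataclass
class Band:
    """Ordered chain of replicas between two endpoint configurations."""

    replicas: np.ndarray            # (n, D)
    active: np.ndarray              # boolean coordinate mask, band forces only here
    fix_endpoints: bool = True
    energies: np.ndarray | None = None
    history: list = field(default_factory=list)   # max inter-iteration RMSD per cycle

    def __post_init__(self):
        self.replicas = np.asarray(self.replicas, dtype=float)
        self.active = np.asarray(self.active, dtype=bool)
        if self.replicas.ndim != 2 or len(self.replicas) < 3:
            raise ValueError("band needs >= 3 replicas of shape (n, D)")
        if self.active.shape != (self.replicas.shape[1],):
            raise ValueError("active mask must cover the coordinates")
        if not self.active.any():
            raise ValueError("active coordinate subset must be non-empty")

    @property
    def n_replicas(self):
        return len(self.replicas)


@dataclass
class AnnealingSchedule:
    """Stages of (duration in steps, temperature in kT, spring constant)."""

    stages: list

    def __post_init__(self):
        for dur, temp, k in self.stages:
            if dur <= 0:
                raise ValueError("stage durations must be positive")
            if temp < 0:
                raise ValueError("temperatures must be >= 0")


def default_schedule(steps: int = 300, k_hot: float = 20.0,
                     k_hold: float = 10.0, temperature: float = 0.02,
                     cool_steps: int | None = None):
    """Three-stage annealing cycle: heat at spring k_hot, hold at k_hold,
    cool (0 K minimization) at k_hot.  The cool stage is stretched relative
    to the hot stages so each cycle ends fully relaxed at toy scale."""
    return AnnealingSchedule([
        (steps, temperature, k_hot),
        (2 * steps, temperature, k_hold),
        (5 * steps if cool_steps is None else cool_steps, 0.0, k_hot),
    ])


def initialize_band(start, end, n_replicas: int, mode: str = "linear",
                    trajectory=None, active=None) -> Band:
    """Linear interpolation between endpoints, or evenly spaced trajectory
    frames (indices floor(i*T/n) with the last replica corrected to the
    final frame)."""
    start = np.atleast_1d(np.asarray(start, dtype=float))
    end = np.atleast_1d(np.asarray(end, dtype=float))
    if start.shape != end.shape:
        raise ValueError("start and end must share a dimensionality")
    if n_replicas < 3:
        raise ValueError("need at least 3 replicas")
    if mode == "linear":
        t = np.linspace(0.0, 1.0, n_replicas)[:, None]
        reps = (1 - t) * start[None, :] + t * end[None, :]
    elif mode == "from_trajectory":
        frames = np.asarray(trajectory, dtype=float)
        if len(frames) < n_replicas:
            raise ValueError("trajectory shorter than the band")
        idx = (np.arange(n_replicas) * len(frames)) // n_replicas
        idx[-1] = len(frames) - 1
        reps = frames[idx].copy()
        reps[0], reps[-1] = start, end
    else:
        raise ValueError("mode must be 'linear' or 'from_trajectory'")
    if active is None:
        active = np.ones(start.shape[0], dtype=bool)
    return Band(replicas=reps, active=active)


def _tangents(reps, energies):
    """Improved (energy-weighted) tangent per interior replica, normalized."""
    n, D = reps.shape
    tau = np.zeros((n, D))
    for i in range(1, n - 1):
        dplus = reps[i + 1] - reps[i]
        dminus = reps[i] - reps[i - 1]
        e0, e1, e2 = energies[i - 1], energies[i], energies[i + 1]
        if e2 > e1 > e0:
            t = dplus
        elif e2 < e1 < e0:
            t = dminus
        else:
            dmax = max(abs(e2 - e1), abs(e0 - e1))
            dmin = min(abs(e2 - e1), abs(e0 - e1))
            if e2 > e0:
                t = dplus * dmax + dminus * dmin
            else:
                t = dplus * dmin + dminus * dmax
        norm = np.linalg.norm(t)
        tau[i] = t / norm if norm > 0 else 0.0
    return tau


def neb_forces(band: Band, potential, k_spring: float):
    """Per-replica NEB force vectors (zero on fixed endpoints).

    On the active coordinate subset of each interior replica: true force
    with the tangent-parallel component removed, plus the spring force
    k_spring (|R_{i+1}-R_i| - |R_i-R_{i-1}|) along the tangent.  Inactive
    coordinates feel the plain physical force.
    """
    reps = band.replicas
    n, D = reps.shape
    energies = np.asarray(potential.energy(reps), dtype=float)
    grad = np.asarray(potential.gradient(reps), dtype=float)
    true_force = -grad
    tau = _tangents(reps, energies)
    act = band.active
    forces = true_force.copy()
    for i in range(1, n - 1):
        t = tau[i].copy()
        t[~act] = 0.0
        nt = np.linalg.norm(t)
        if nt > 0:
            t = t / nt
        fa = true_force[i][act]
        ta = t[act]
        perp = fa - (fa @ ta) * ta
        spring = k_spring * (
            np.linalg.norm((reps[i + 1] - reps[i])[act])
            - np.linalg.norm((reps[i] - reps[i - 1])[act])
        )
        forces[i][act] = perp + spring * ta
    if band.fix_endpoints:
        forces[0] = 0.0
        forces[-1] = 0.0
    band.energies = energies
    return forces


def _max_perp_force(band, potential, k_spring):
    reps = band.replicas
    energies = np.asarray(potential.energy(reps), dtype=float)
    grad = np.asarray(potential.gradient(reps), dtype=float)
    tau = _tangents(reps, energies)
    best = 0.0
    for i in range(1, len(reps) - 1):
        f = -grad[i][band.active]
        t = tau[i][band.active]
        nt = np.linalg.norm(t)
        if nt > 0:
            t /= nt
        perp = f - (f @ t) * t
        best = max(best, float(np.linalg.norm(perp)))
    return best


def optimize_band(band: Band, potential, schedule: AnnealingSchedule,
                  dt: float = 1e-3, friction: float = 1.0, seed: int = 0,
                  n_cycles: int = 3, max_step: float = 0.05) -> Band:
    """Annealing-cycle optimization of the band on NEB forces.

    Each cycle runs the schedule's stages in order; finite-temperature
    stages evolve x <- x + F dt/friction + sqrt(2 T dt/friction) xi, the
    0 K stages are steepest descent with per-step displacement capped at
    ``max_step``.  The band records, per cycle, the maximum per-replica
    RMSD relative to the previous cycle and the maximum perpendicular force
    after the final (0 K) stage.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    for cycle in range(n_cycles):
        prev = band.replicas.copy()
        for duration, temp, k_spring in schedule.stages:
            amp = np.sqrt(2.0 * temp * dt / friction)
            for _ in range(duration):
                F = neb_forces(band, potential, k_spring)
                step = F * (dt / friction)
                if temp > 0:
                    noise = amp * rng.standard_normal(band.replicas.shape)
                    if band.fix_endpoints:
                        noise[0] = 0.0
                        noise[-1] = 0.0
                    step = step + noise
                norms = np.linalg.norm(step, axis=1)
                too_big = norms > max_step
                if too_big.any():
                    step[too_big] *= (max_step / norms[too_big])[:, None]
                band.replicas = band.replicas + step
                if not np.all(np.isfinite(band.replicas)):
                    raise RuntimeError(f"replica diverged in cycle {cycle}")
        _, per_replica, max_rmsd = band_convergence_arrays(prev, band)
        band.history.append({
            "cycle": cycle,
            "max_rmsd": max_rmsd,
            "max_perp_force": _max_perp_force(
                band, potential, schedule.stages[-1][2]
            ),
        })
    band.energies = np.asarray(potential.energy(band.replicas), dtype=float)
    return band


def band_convergence_arrays(previous, current, point_dim: int | None = None):
    """(per-replica RMSD over active coords, list, max) between two bands.

    Active coordinates are grouped into points of ``point_dim`` components
    for the RMSD; by default a replica whose active coordinates number at
    most 3 is a single point (so in 2-D the RMSD is the Euclidean
    displacement), otherwise triples are assumed.
    """
    prev = previous.replicas if isinstance(previous, Band) else np.asarray(previous)
    cur = current.replicas if isinstance(current, Band) else np.asarray(current)
    act = current.active if isinstance(current, Band) else \
        np.ones(cur.shape[1], dtype=bool)
    if prev.shape != cur.shape:
        raise ValueError("bands must have identical shape")
    diff = (cur - prev)[:, act]
    n_act = diff.shape[1]
    if point_dim is None:
        point_dim = n_act if n_act <= 3 or n_act % 3 else 3
    n_points = max(1, n_act // point_dim)
    rmsd = np.sqrt(np.sum(diff**2, axis=1) / n_points)
    return rmsd, rmsd.tolist(), float(rmsd.max())


def band_convergence(previous, current, threshold: float = 0.3,
                     point_dim: int | None = None):
    """Max per-replica RMSD between band iterates and a convergence flag."""
    rmsd, per_replica, max_rmsd = band_convergence_arrays(
        previous, current, point_dim
    )
    return {
        "max_rmsd": max_rmsd,
        "per_replica": per_replica,
        "converged": max_rmsd < threshold,
    }
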