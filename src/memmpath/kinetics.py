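"""Transition-path kinetics and bootstrap uncertainty.

Committor probabilities and mean first passage times (MFPTs) are obtained
from linear solves on the unbiased transition matrix; macrostate-to-
macrostate MFPTs (the kinetic model) weight the source states by the
stationary distribution restricted to the source macrostate.  Error bars
combine a simple bootstrap (whole unbiased trajectories drawn with
replacement) with a stationary bootstrap (geometric-length blocks with
wrap-around) over the biased trajectories, re-estimating the full model for
every bootstrap sample.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linear_sum_assignment

from .macro import MacrostateModel, pcca
from .memm import BiasEnergyTable, estimate_reversible_msm, estimate_tram
from .microstates import count_transitions
from .toysim import DiscreteTrajectorySet

__all__ = [
    "KineticModel",
    "BootstrapSpec",
    "committor",
    "mfpt",
    "timescale_table",
    "statistical_inefficiency",
    "mean_statistical_inefficiency",
    "bootstrap_kinetics",
]


# ---------------------------------------------------------------------------
# Committors and MFPTs
# ---------------------------------------------------------------------------

def _as_sets(n, A, B):
    A = np.asarray(sorted(set(np.atleast_1d(A).tolist())), dtype=int)
    B = np.asarray(sorted(set(np.atleast_1d(B).tolist())), dtype=int)
    if len(A) == 0 or len(B) == 0:
        raise ValueError("source and sink sets must be non-empty")
    if np.intersect1d(A, B).size:
        raise ValueError("source and sink sets must be disjoint")
    return A, B


def committor(T, A, B) -> np.ndarray:
    """Forward committor q+: probability of hitting B before A.

    q = 0 on A, q = 1 on B, and q = T q on all intermediate states (solved
    as a dense linear system).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    A, B = _as_sets(n, A, B)
    q = np.zeros(n)
    q[B] = 1.0
    C = np.setdiff1d(np.arange(n), np.concatenate([A, B]))
    if C.size:
        M = np.eye(C.size) - T[np.ix_(C, C)]
        rhs = T[np.ix_(C, B)].sum(axis=1)
        q[C] = np.linalg.solve(M, rhs)
    return q


def mfpt(T, B, lag_time: float = 1.0) -> np.ndarray:
    """Expected first-passage time into B from every state.

    Solves m = lag_time + T m with m = 0 on B.  States that cannot reach B
    come out infinite (flagged as np.inf).
    """
    T = np.asarray(T, dtype=float)
    n = T.shape[0]
    B = np.asarray(sorted(set(np.atleast_1d(B).tolist())), dtype=int)
    if B.size == 0:
        raise ValueError("target set must be non-empty")
    m = np.zeros(n)
    C = np.setdiff1d(np.arange(n), B)
    if C.size:
        M = np.eye(C.size) - T[np.ix_(C, C)]
        try:
            m[C] = np.linalg.solve(M, np.full(C.size, lag_time))
        except np.linalg.LinAlgError:
            m[C] = np.inf
        if np.any(m[C] < 0):
            m[C][m[C] < 0] = np.inf
    return m


@dataclass
class KineticModel:
    """Macrostate-to-macrostate MFPT table in physical time units."""

    pairs: list                 # [(source, target), ...]
    mfpts: np.ndarray
    lo: np.ndarray | None = None
    hi: np.ndarray | None = None
    units: str = "steps"
    macrostates: MacrostateModel | None = None

    def to_records(self):
        rec = []
        for p, (a, b) in enumerate(self.pairs):
            rec.append({
                "source": a, "target": b, "mfpt": float(self.mfpts[p]),
                "lo": float(self.lo[p]) if self.lo is not None else np.nan,
                "hi": float(self.hi[p]) if self.hi is not None else np.nan,
                "units": self.units,
            })
        return rec


def macrostate_mfpts(T, pi, labels, m, lag_time=1.0):
    """All ordered macrostate pair MFPTs, pi-weighted over source states."""
    pairs, vals = [], []
    for a in range(m):
        src = np.where(labels == a)[0]
        if src.size == 0:
            continue
        w = pi[src] / pi[src].sum()
        for b in range(m):
            if a == b:
                pairs.append((a, b))
                vals.append(0.0)
                continue
            tgt = np.where(labels == b)[0]
            if tgt.size == 0:
                continue
            mv = mfpt(T, tgt, lag_time)
            pairs.append((a, b))
            vals.append(float(w @ mv[src]))
    return pairs, np.array(vals)


def timescale_table(memm, macrostates: MacrostateModel,
                    lag_time: float = 1.0, units: str = "steps") -> KineticModel:
    """Kinetic model: MFPTs between all ordered macrostate pairs.

    Uses the unbiased transition matrix of the MEMM; microstates outside its
    subset are ignored (flagged by their absence).  ``lag_time`` converts
    lags to physical time.
    """
    sub, T = memm.unbiased_transition_matrix()
    pi_full = memm.stationary_distribution
    pi = pi_full[sub] / pi_full[sub].sum()
    labels = macrostates.labels[sub] if len(macrostates.labels) > len(sub) \
        else macrostates.labels
    pairs, vals = macrostate_mfpts(T, pi, labels, macrostates.m, lag_time)
    return KineticModel(pairs=pairs, mfpts=vals, units=units,
                        macrostates=macrostates)


# ---------------------------------------------------------------------------
# Statistical inefficiency
# ---------------------------------------------------------------------------

def statistical_inefficiency(series) -> float:
    """g = 1 + 2 * sum of autocorrelations (initial-positive-sequence).

    The autocorrelation sum is truncated at the first non-positive value;
    the result is clipped to >= 1.  A constant series is fully correlated:
    g is defined as the series length (with a warning flag by convention).
    """
    x = np.asarray(series, dtype=float)
    n = len(x)
    if n < 10:
        raise ValueError("series too short (need >= 10 points)")
    x = x - x.mean()
    var = np.dot(x, x) / n
    if var == 0:
        return float(n)
    # FFT autocorrelation
    nfft = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(x, nfft)
    acf = np.fft.irfft(f * np.conjugate(f), nfft)[:n].real
    acf /= acf[0]
    s = 0.0
    for t in range(1, n):
        if acf[t] <= 0.0:
            break
        s += acf[t] * (1.0 - t / n)
    return max(1.0, 1.0 + 2.0 * s)


def mean_statistical_inefficiency(dtrajs: DiscreteTrajectorySet,
                                  ensembles=None) -> float:
    """Mean statistical inefficiency over (selected) discrete trajectories."""
    gs = []
    for seq, ens in zip(dtrajs.dtrajs, dtrajs.ensembles):
        if ensembles is not None and ens not in ensembles:
            continue
        if len(seq) >= 10:
            gs.append(statistical_inefficiency(seq.astype(float)))
    if not gs:
        raise ValueError("no trajectories selected")
    return float(np.mean(gs))


# ---------------------------------------------------------------------------
# Bootstrap
# ---------------------------------------------------------------------------

@dataclass
class BootstrapSpec:
    n_samples: int
    min_block_length: float = 1.0
    percentiles: tuple = (5.0, 95.0)
    seed: int = 0

    def __post_init__(self):
        if self.n_samples < 2:
            raise ValueError("n_samples must be >= 2")
        if self.min_block_length < 1:
            raise ValueError("min_block_length must be >= 1")


def _stationary_bootstrap_indices(length, mean_block, rng):
    """Index sequence of ``length`` by geometric blocks with wrap-around."""
    p = 1.0 / mean_block
    out = np.empty(length, dtype=np.int64)
    pos = 0
    while pos < length:
        start = int(rng.integers(length))
        block = int(rng.geometric(p))
        block = min(block, length - pos)
        idx = (start + np.arange(block)) % length
        out[pos:pos + block] = idx
        pos += block
    return out


@dataclass
class EstimatorConfig:
    """What to re-estimate per bootstrap sample.

    ``n_macrostates=None`` treats each microstate as its own macrostate
    (no PCCA+ step), which is the natural choice for small planted chains.
    """

    lag: int = 1
    lag_time: float = 1.0
    n_macrostates: int | None = None
    mfpt_pairs: list | None = None      # macrostate pairs to report
    n_states: int | None = None


def _estimate_once(dtrajs, bias_tables, cfg, reference=None):
    dts = DiscreteTrajectorySet(
        dtrajs.dtrajs, dtrajs.ensembles,
        cfg.n_states or dtrajs.n_states,
    )
    cnt = count_transitions(dts, cfg.lag)
    if cnt.n_ensembles == 1 and bias_tables is None:
        T, pi, active = estimate_reversible_msm(cnt.counts[0])
    else:
        memm = estimate_tram(cnt, dts, BiasEnergyTable(bias_tables),
                             tol=1e-8, max_iter=50_000)
        sub, T = memm.unbiased_transition_matrix()
        pi_full = memm.stationary_distribution
        pi = pi_full[sub] / pi_full[sub].sum()
        active = memm.active_set[sub]

    if cfg.n_macrostates is None:
        # each microstate is its own macrostate, labeled by its original id
        lab_T = active
        m = dts.n_states
        model = None
    else:
        model = pcca(T, pi, cfg.n_macrostates)
        if reference is not None:
            model = _align_macrostates(model, reference, active)
        lab_T = model.labels
        m = cfg.n_macrostates
    pairs, vals = macrostate_mfpts(T, pi, lab_T, m, cfg.lag_time)
    out = {}
    for (a, b), v in zip(pairs, vals):
        if a == b:
            continue
        if cfg.mfpt_pairs is None or (a, b) in cfg.mfpt_pairs:
            out[(a, b)] = v
    ref_labels = None
    if model is not None:
        ref_labels = {int(s): int(l) for s, l in zip(active, model.labels)}
    return out, ref_labels


def _align_macrostates(model, ref_labels_by_state, active):
    """Permute macrostates to best overlap the reference (Hungarian).

    ``ref_labels_by_state`` maps original microstate ids to the reference
    (point-estimate) macrostate labels; ``active`` gives the original id of
    each row of the model's membership matrix.
    """
    m = model.m
    overlap = np.zeros((m, m))
    for row, orig in enumerate(active):
        l = ref_labels_by_state.get(int(orig), -1)
        if l >= 0:
            overlap[:, l] += model.memberships[row]
    row_ind, col_ind = linear_sum_assignment(-overlap)
    perm = np.empty(m, dtype=int)
    perm[col_ind] = row_ind       # new column l <- old column assigned to l
    chi = model.memberships[:, perm]
    labels = np.argmax(chi, axis=1)
    pops = model.populations[perm]
    return MacrostateModel(memberships=chi, labels=labels,
                           populations=pops, m=m)


def bootstrap_kinetics(dtrajs: DiscreteTrajectorySet, bias_tables,
                       unbiased_ids, biased_ids, cfg: EstimatorConfig,
                       spec: BootstrapSpec):
    """Percentile intervals for MFPTs by mixed simple/stationary bootstrap.

    Each bootstrap sample redraws whole trajectories with replacement from
    ``unbiased_ids`` and rebuilds each biased trajectory from stationary-
    bootstrap blocks (geometric lengths with mean ``spec.min_block_length``,
    wrap-around) of the biased data; one full estimation (TRAM when several
    ensembles are present, reversible MSM otherwise, then optional PCCA+
    aligned to the point estimate by membership overlap, then MFPTs) is run
    per sample.  Failed samples are dropped and counted.
    """
    rng = np.random.default_rng(np.random.SeedSequence(spec.seed))
    point, ref_labels = _estimate_once(dtrajs, bias_tables, cfg)
    keys = sorted(point)
    samples = {k: [] for k in keys}
    n_failed = 0
    unbiased_ids = list(unbiased_ids)
    biased_ids = list(biased_ids)
    for _ in range(spec.n_samples):
        pick = [unbiased_ids[i] for i in
                rng.integers(len(unbiased_ids), size=len(unbiased_ids))]
        new_dtrajs = [dtrajs.dtrajs[i] for i in pick]
        new_ens = [dtrajs.ensembles[i] for i in pick]
        new_bias = [bias_tables[i] for i in pick] if bias_tables else None
        for i in biased_ids:
            seq = dtrajs.dtrajs[i]
            idx = _stationary_bootstrap_indices(
                len(seq), spec.min_block_length, rng
            )
            new_dtrajs.append(seq[idx])
            new_ens.append(dtrajs.ensembles[i])
            if bias_tables:
                new_bias.append(bias_tables[i][idx])
        try:
            est, _ = _estimate_once(
                DiscreteTrajectorySet(new_dtrajs, new_ens, dtrajs.n_states),
                new_bias, cfg, reference=ref_labels,
            )
            for k in keys:
                if k not in est or not np.isfinite(est[k]):
                    raise ValueError("missing quantity in sample")
            for k in keys:
                samples[k].append(est[k])
        except (ValueError, np.linalg.LinAlgError):
            n_failed += 1
    lo_p, hi_p = spec.percentiles
    result = {}
    for k in keys:
        arr = np.asarray(samples[k])
        result[k] = {
            "point": point[k],
            "mean": float(arr.mean()) if arr.size else np.nan,
            "lo": float(np.percentile(arr, lo_p)) if arr.size else np.nan,
            "hi": float(np.percentile(arr, hi_p)) if arr.size else np.nan,
            "samples": arr,
        }
    return {"quantities": result, "n_failed": n_failed,
            "n_samples": spec.n_samples}
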