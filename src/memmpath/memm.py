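"""Multi-ensemble Markov model estimation.

The central estimator is TRAM (transition-based reweighting analysis
method): given microstate transition counts from several thermodynamic
ensembles (one unbiased, the rest harmonically biased umbrella windows) and
the reduced bias energy of every frame in every ensemble, it solves a
coupled maximum-likelihood problem whose fixed point yields

* a reversible transition matrix per ensemble (detailed balance with respect
  to that ensemble's own stationary distribution), and
* unbiased microstate free energies f_i (in kT, up to an additive constant),
  consistently reweighted across ensembles.

The self-consistent iteration updates Lagrange multipliers v_i^k, local free
energies f_i^k, and per-sample unbiased weights mu(x):

    v_i^k   <- sum_j (c_ij^k + c_ji^k) v_i^k e^{-f_j^k}
               / (v_i^k e^{-f_j^k} + v_j^k e^{-f_i^k})
    R_i^k    = sum_j (c_ij^k + c_ji^k) v_j^k e^{-f_i^k}
               / (v_i^k e^{-f_j^k} + v_j^k e^{-f_i^k}) + N_i^k - sum_j c_ji^k
    mu(x)    = 1 / sum_k R_{i(x)}^k exp(f_{i(x)}^k - b^k(x))
    e^{-f_i^k} <- sum_{x in i} e^{-b^k(x)} mu(x)

all evaluated in log space.  With a single unbiased ensemble the fixed point
coincides with the reversible MSM maximum-likelihood estimate, which this
module also provides directly (and which serves as an internal special-case
check).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.special import logsumexp

from .microstates import CountTensor
from .toysim import DiscreteTrajectorySet, TrajectorySet

__all__ = [
    "BiasEnergyTable",
    "MEMM",
    "FESGrid",
    "evaluate_bias_energies",
    "estimate_tram",
    "estimate_reversible_msm",
    "implied_timescales",
    "microstate_free_energies",
    "free_energy_surface",
    "KT_TO_KCAL_PER_MOL",
]

#: kcal/mol per kT at 298.15 K, used for display only
KT_TO_KCAL_PER_MOL = 0.5924847


# ---------------------------------------------------------------------------
# Bias energies
# ---------------------------------------------------------------------------

@dataclass
class BiasEnergyTable:
    """Per-frame reduced bias energies b^k(x_t) in kT.

    ``tables[t]`` has shape (n_frames_t, K): the bias energy of every frame
    of trajectory t evaluated in every ensemble k.  Ensemble 0 is the
    unbiased ensemble and its column is identically zero.
    """

    tables: list

    def __post_init__(self):
        self.tables = [np.asarray(t, dtype=float) for t in self.tables]
        for t in self.tables:
            if not np.all(np.isfinite(t)):
                raise ValueError("non-finite bias energy")
            if t.ndim != 2:
                raise ValueError("each table must be (frames, n_ensembles)")
            if np.any(t[:, 0] != 0.0):
                raise ValueError("ensemble 0 must be unbiased (zero bias)")

    @property
    def n_ensembles(self):
        return self.tables[0].shape[1]


def evaluate_bias_energies(trajectories: TrajectorySet,
                           biases=None, kT: float = 1.0) -> BiasEnergyTable:
    """Evaluate every ensemble's bias on every frame of every trajectory."""
    biases = list(biases) if biases is not None else list(trajectories.biases)
    for b in biases:
        if b.kind == "harmonic" and b.coordinate_map is None:
            raise ValueError("harmonic bias without a coordinate_map")
    tables = []
    for tr in trajectories.trajectories:
        cols = [b.energy(tr.frames) / kT for b in biases]
        tables.append(np.stack(cols, axis=1))
    return BiasEnergyTable(tables)


# ---------------------------------------------------------------------------
# Reversible MSM (maximum likelihood, fixed-point iteration)
# ---------------------------------------------------------------------------

def _largest_strong_component(C):
    n = C.shape[0]
    ncomp, labels = connected_components(coo_matrix(C > 0), directed=True,
                                         connection="strong")
    # pick the component with the most counts
    best, best_w = 0, -1.0
    for c in range(ncomp):
        idx = np.where(labels == c)[0]
        w = C[np.ix_(idx, idx)].sum()
        if w > best_w:
            best, best_w = c, w
    return np.where(labels == best)[0]


def estimate_reversible_msm(counts, tol: float = 1e-12,
                            max_iter: int = 100_000):
    """Maximum-likelihood reversible transition matrix from counts.

    Fixed-point iteration on the symmetric flow variables
    x_ij <- (c_ij + c_ji) / (c_i / x_i + c_j / x_j); the result satisfies
    detailed balance to machine precision by construction (T = X / rowsum,
    X symmetric).  Returns (T, pi, active_indices) over the largest strongly
    connected component of the count matrix.
    """
    C = np.asarray(getattr(counts, "counts", counts), dtype=float)
    if C.ndim == 3:
        if C.shape[0] != 1:
            raise ValueError("single-ensemble counts required")
        C = C[0]
    if C.sum() == 0:
        raise ValueError("empty counts")
    active = _largest_strong_component(C)
    C = C[np.ix_(active, active)]
    n = C.shape[0]
    CS = C + C.T
    c_row = C.sum(axis=1)
    X = CS / CS.sum()
    for _ in range(max_iter):
        x_row = X.sum(axis=1)
        denom = c_row / x_row
        Xn = CS / (denom[:, None] + denom[None, :])
        Xn /= Xn.sum()
        delta = np.max(np.abs(Xn - X))
        X = Xn
        if delta < tol:
            break
    x_row = X.sum(axis=1)
    T = X / x_row[:, None]
    pi = x_row / x_row.sum()
    return T, pi, active


# ---------------------------------------------------------------------------
# TRAM
# ---------------------------------------------------------------------------

@dataclass
class MEMM:
    """Converged multi-ensemble Markov model.

    ``f`` are unbiased microstate free energies (kT, gauge: sum of unbiased
    stationary weights = 1) over ``active_set`` (indices into the original
    microstates).  ``f_k`` are per-ensemble local free energies.
    ``transition_matrices[k]`` is a pair (subset, T) where ``subset`` indexes
    into ``active_set`` and T is reversible w.r.t. its own stationary vector.
    ``log_mu`` holds per-trajectory log unbiased frame weights (normalized
    over all frames; -inf for frames outside the active set).
    """

    active_set: np.ndarray
    f: np.ndarray
    f_k: np.ndarray
    transition_matrices: list
    lag: int
    converged: bool
    residual: float
    n_iter: int
    log_mu: list = field(default_factory=list)

    @property
    def stationary_distribution(self):
        w = np.exp(-self.f)
        return w / w.sum()

    def unbiased_transition_matrix(self):
        """(subset, T) of the unbiased ensemble (ensemble 0)."""
        return self.transition_matrices[0]

    def frame_weights(self):
        """Normalized unbiased weight per frame, aligned with input dtrajs."""
        return [np.exp(lm) for lm in self.log_mu]


def _segment_logsumexp(a, offsets):
    """logsumexp over row segments of a 2-D array (segments along axis 0)."""
    m = np.maximum.reduceat(a, offsets, axis=0)
    m[np.isneginf(m)] = 0.0
    s = np.add.reduceat(np.exp(a - np.repeat(m, np.diff(np.append(offsets, len(a))), axis=0)), offsets, axis=0)
    with np.errstate(divide="ignore"):
        return np.log(s) + m


def estimate_tram(counts: CountTensor, dtrajs: DiscreteTrajectorySet,
                  bias: BiasEnergyTable, tol: float = 1e-8,
                  max_iter: int = 100_000) -> MEMM:
    """Self-consistent TRAM estimation over biased + unbiased ensembles.

    Restricts to the largest set of (microstate, ensemble) pairs connected
    through reversible transition counts within ensembles and sample sharing
    of states across ensembles, then iterates the TRAM equations until the
    maximum change of all f_i^k and log-Lagrange multipliers drops below
    ``tol``.  A non-converged run returns the best iterate with
    ``converged=False`` and a warning.
    """
    C = np.asarray(counts.counts, dtype=float)
    K, n, _ = C.shape
    if bias.n_ensembles != K:
        raise ValueError("bias table ensembles != count ensembles")

    # --- flatten samples -------------------------------------------------
    states = np.concatenate([d for d in dtrajs.dtrajs])
    gen_ens = np.concatenate([
        np.full(len(d), e, dtype=np.int64)
        for d, e in zip(dtrajs.dtrajs, dtrajs.ensembles)
    ])
    B_all = np.concatenate(bias.tables, axis=0)
    if len(B_all) != len(states):
        raise ValueError("bias table not aligned with discrete trajectories")
    N_samples = np.asarray(counts.state_counts, dtype=float)  # (K, n)

    # --- connectivity on (state, ensemble) pairs -------------------------
    CS = C + np.transpose(C, (0, 2, 1))
    node = lambda k, i: k * n + i
    rows, cols = [], []
    for k in range(K):
        ii, jj = np.nonzero(np.triu(CS[k], 1))
        rows += list(node(k, ii))
        cols += list(node(k, jj))
    for i in range(n):
        ks = np.where(N_samples[:, i] > 0)[0]
        for a, b in zip(ks[:-1], ks[1:]):
            rows.append(node(a, i))
            cols.append(node(b, i))
    adj = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(K * n, K * n))
    ncomp, labels = connected_components(adj, directed=False)
    weights = np.zeros(ncomp)
    for k in range(K):
        for i in range(n):
            weights[labels[node(k, i)]] += N_samples[k, i]
    comp = np.argmax(weights)
    pair_active = (labels.reshape(K, n) == comp) & (
        (N_samples > 0) | (CS.sum(axis=2) > 0)
    )
    active = np.where(pair_active.any(axis=0))[0]
    if active.size == 0:
        raise ValueError("no connected set of microstates")
    na = active.size
    remap = -np.ones(n, dtype=np.int64)
    remap[active] = np.arange(na)

    # restrict counts/samples to active pairs
    pa = pair_active[:, active]                      # (K, na)
    Ca = C[np.ix_(range(K), active, active)]
    for k in range(K):
        Ca[k][~pa[k], :] = 0.0
        Ca[k][:, ~pa[k]] = 0.0
    CSa = Ca + np.transpose(Ca, (0, 2, 1))
    Ns = N_samples[:, active] * pa                   # (K, na)
    c_in = Ca.sum(axis=1)                            # (K, na) incoming pairs

    # keep a sample only if its (state, generating ensemble) pair is active
    sample_ok = remap[states] >= 0
    sample_ok &= pair_active[gen_ens, states]
    s_act = remap[states[sample_ok]]
    B_act = B_all[sample_ok]
    order = np.argsort(s_act, kind="stable")
    s_sorted = s_act[order]
    B_sorted = B_act[order]
    seg_states, seg_offsets = np.unique(s_sorted, return_index=True)
    # seg_states should be arange(na) whenever every active state has samples
    has_samples = np.zeros(na, dtype=bool)
    has_samples[seg_states] = True

    with np.errstate(divide="ignore"):
        logCS = np.log(CSa)                          # -inf where no counts
        log_extra = np.log(np.maximum(Ns - c_in, 0.0))
    has_counts = CSa.sum(axis=2) > 0                 # (K, na)
    W = np.exp(-B_sorted)                            # (N, K), constant

    f = np.zeros((K, na))
    log_v = np.zeros((K, na))
    residual = np.inf
    it = 0
    log_R = np.full((K, na), -np.inf)
    # Convergence is measured on the local free energies f_i^k, on
    # log R_i^k (the effective per-state sample counts), and on the
    # per-ensemble transition matrices themselves: at boundary solutions
    # individual Lagrange multipliers drift toward zero forever while every
    # quantity that enters the model converges geometrically.
    T_prev = None
    for it in range(1, max_iter + 1):
        # pairwise log denominators: log(v_i e^{-f_j} + v_j e^{-f_i})
        lvi = log_v[:, :, None] - f[:, None, :]      # [k,i,j]: log v_i - f_j
        lvj = log_v[:, None, :] - f[:, :, None]      # [k,i,j]: log v_j - f_i
        log_den = np.logaddexp(lvi, lvj)

        # v update
        log_v_new = logsumexp(logCS + lvi - log_den, axis=2)
        log_v_new[~has_counts] = 0.0

        # R
        log_R_prev = log_R
        log_R = np.logaddexp(logsumexp(logCS + lvj - log_den, axis=2),
                             log_extra)
        log_R[~pa] = -np.inf

        # sample weights mu(x)^-1 = sum_k R e^{f - b}; linear space with a
        # single scalar scale (biases >= 0, so W <= 1 and the scale of
        # R e^{f} is controlled by its maximum element)
        log_rf = log_R + f                           # (K, na)
        M = log_rf[np.isfinite(log_rf)].max()
        Amat = np.exp(log_rf - M)
        denom = np.einsum("nk,nk->n", Amat[:, s_sorted].T, W)

        # f update: e^{-f_i^k} = sum_{x in i} e^{-b^k(x)} mu(x)
        S = W / denom[:, None]                       # (N, K), scaled by e^{M}
        sums = np.add.reduceat(S, seg_offsets, axis=0)
        with np.errstate(divide="ignore"):
            f_new = f.copy()
            f_new[:, seg_states] = (-np.log(sums) + M).T

        both = np.isfinite(log_R) & np.isfinite(log_R_prev)
        r_res = float(np.max(np.abs(log_R[both] - log_R_prev[both]))) \
            if both.any() else np.inf
        # row-normalized symmetric flows give the current transition
        # matrices (rows without counts are left as zero)
        with np.errstate(invalid="ignore"):
            X = np.exp(logCS - f[:, :, None] - f[:, None, :] - log_den)
        X[~np.isfinite(X)] = 0.0
        rs = X.sum(axis=2)
        T_cur = X / np.where(rs > 0, rs, 1.0)[:, :, None]
        t_res = np.inf if T_prev is None else \
            float(np.max(np.abs(T_cur - T_prev)))
        T_prev = T_cur
        residual = max(float(np.max(np.abs(f_new - f))), r_res, t_res)
        f = f_new
        log_v = log_v_new
        if residual < tol:
            break
    converged = residual < tol
    if not converged:
        warnings.warn(
            f"TRAM did not converge in {it} iterations (residual {residual:.2e})"
        )

    # final per-sample weights and unbiased free energies
    log_rf = log_R + f
    D = logsumexp(log_rf[:, s_sorted].T - B_sorted, axis=1)
    norm = logsumexp(-D)
    log_mu_sorted = -D - norm
    f_unb = np.full(na, np.inf)
    f_unb[seg_states] = -_segment_logsumexp(log_mu_sorted[:, None],
                                            seg_offsets)[:, 0]
    # express all local free energies in the same gauge (sum_x mu(x) = 1)
    f = f + norm

    # transition matrices per ensemble from symmetric flows (recompute the
    # pair denominators with the final f, log_v)
    lvi = log_v[:, :, None] - f[:, None, :]
    lvj = log_v[:, None, :] - f[:, :, None]
    log_den = np.logaddexp(lvi, lvj)
    tmats = []
    for k in range(K):
        sub = np.where(has_counts[k])[0]
        if sub.size == 0:
            tmats.append((sub, np.zeros((0, 0))))
            continue
        lX = (logCS[k][np.ix_(sub, sub)]
              - f[k][sub][:, None] - f[k][sub][None, :]
              - log_den[k][np.ix_(sub, sub)])
        X = np.exp(lX - lX[np.isfinite(lX)].max())
        rs = X.sum(axis=1)
        T = X / rs[:, None]
        tmats.append((sub, T))

    # scatter per-sample log weights back to per-trajectory arrays
    log_mu_act = np.empty(len(s_act))
    log_mu_act[order] = log_mu_sorted
    log_mu_all = np.full(len(states), -np.inf)
    log_mu_all[sample_ok] = log_mu_act
    log_mu = []
    pos = 0
    for d in dtrajs.dtrajs:
        log_mu.append(log_mu_all[pos:pos + len(d)])
        pos += len(d)

    return MEMM(active_set=active, f=f_unb, f_k=f,
                transition_matrices=tmats, lag=counts.lag,
                converged=converged, residual=residual, n_iter=it,
                log_mu=log_mu)


# ---------------------------------------------------------------------------
# Implied timescales, free energies, surfaces
# ---------------------------------------------------------------------------

def implied_timescales(dtrajs: DiscreteTrajectorySet, lags, n_its: int = 2):
    """t_i(tau) = -tau / ln lambda_i(tau) from reversible MSMs per lag.

    Returns a dict lag -> array of the ``n_its`` slowest timescales
    (NaN where the eigenvalue is non-positive, i.e. undefined).
    """
    from .microstates import count_transitions

    out = {}
    for lag in lags:
        cnt = count_transitions(dtrajs, lag)
        C = cnt.counts.sum(axis=0)
        T, pi, _ = estimate_reversible_msm(C)
        # reversible: symmetrize in the pi metric for a stable real spectrum
        sq = np.sqrt(pi)
        S = sq[:, None] * T / sq[None, :]
        vals = np.linalg.eigvalsh((S + S.T) / 2.0)[::-1]
        its = []
        for lam in vals[1:n_its + 1]:
            its.append(-lag / np.log(lam) if 0 < lam < 1 else np.nan)
        out[lag] = np.array(its)
    return out


def microstate_free_energies(memm: MEMM, reference=None):
    """Delta G_i = f_i - min(f over reference states), in kT.

    ``reference`` holds original microstate indices (subset of the active
    set); default: all active states.  Returns (active_set, dG).
    """
    if reference is None:
        ref_mask = np.ones(len(memm.active_set), dtype=bool)
    else:
        reference = np.asarray(reference)
        ref_mask = np.isin(memm.active_set, reference)
        if not ref_mask.any():
            raise ValueError("empty reference after intersection with active set")
    dg = memm.f - memm.f[ref_mask].min()
    return memm.active_set, dg


@dataclass
class FESGrid:
    """Free-energy surface on a 2-D grid over independent components."""

    x_edges: np.ndarray
    y_edges: np.ndarray
    delta_g: np.ndarray         # (nx, ny), NaN on masked (empty) bins
    kT: float = 1.0

    @property
    def mask(self):
        return np.isnan(self.delta_g)

    def to_table(self):
        """Long-format (x_center, y_center, delta_g) rows, masked bins dropped."""
        xc = 0.5 * (self.x_edges[:-1] + self.x_edges[1:])
        yc = 0.5 * (self.y_edges[:-1] + self.y_edges[1:])
        rows = []
        for i, x in enumerate(xc):
            for j, y in enumerate(yc):
                if not np.isnan(self.delta_g[i, j]):
                    rows.append((x, y, self.delta_g[i, j]))
        return np.array(rows)


def free_energy_surface(ics, weights, bins=40, kT: float = 1.0,
                        reference_region=None, extent=None) -> FESGrid:
    """Delta G(bin) = -kT ln sum of frame weights in the bin.

    ``ics`` is (N, 2) (or (N, 1) / (N,) for a 1-D profile stored as a single
    row of bins), ``weights`` the normalized unbiased frame weights from the
    MEMM.  The minimum over ``reference_region`` bins (a boolean mask on the
    grid; default all populated bins) is shifted to zero; empty bins are NaN.
    """
    ics = np.asarray(ics, dtype=float)
    if ics.ndim == 1:
        ics = ics[:, None]
    if ics.shape[1] == 1:
        ics = np.column_stack([ics[:, 0], np.zeros(len(ics))])
    w = np.asarray(weights, dtype=float)
    if extent is None:
        extent = [
            (ics[:, 0].min(), ics[:, 0].max()),
            (ics[:, 1].min(), ics[:, 1].max()),
        ]
    hist, xe, ye = np.histogram2d(
        ics[:, 0], ics[:, 1], bins=bins, range=extent, weights=w
    )
    if hist.sum() == 0:
        raise ValueError("all frames fall outside the grid")
    with np.errstate(divide="ignore"):
        dg = -kT * np.log(hist)
    dg[hist == 0] = np.nan
    ref = ~np.isnan(dg) if reference_region is None else (
        reference_region & ~np.isnan(dg)
    )
    dg -= np.nanmin(dg[ref])
    return FESGrid(x_edges=xe, y_edges=ye, delta_g=dg, kT=kT)
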