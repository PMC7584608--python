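"""Macrostate agglomeration by PCCA+.

Kinetically similar microstates are merged into m metastable macrostates by
the Perron cluster cluster analysis (PCCA+) simplex transformation: the m
dominant right eigenvectors of a reversible transition matrix span an
invariant subspace in which metastable aggregates appear as the vertices of
an (m-1)-simplex.  The inner-simplex vertex search gives an initial linear
transformation A; A is then refined by maximizing the crispness objective
trace(diag(1/A[0, :]) A^T A) subject to the feasibility constraints
(memberships nonnegative, rows summing to one).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize

__all__ = ["MacrostateModel", "pcca", "crisp_assign"]


@dataclass
class MacrostateModel:
    memberships: np.ndarray     # (n_micro, m), rows sum to 1
    labels: np.ndarray          # crisp macrostate per microstate
    populations: np.ndarray     # stationary weight per macrostate (crisp)
    m: int

    def members(self, j):
        return np.where(self.labels == j)[0]


def crisp_assign(memberships) -> np.ndarray:
    """Argmax membership per microstate; ties resolve to the lowest index."""
    memberships = np.asarray(memberships, dtype=float)
    return np.argmax(memberships, axis=1).astype(np.int64)


def _dominant_right_eigenvectors(T, pi, m):
    # reversible T: symmetrize in the pi metric, eigenvectors are real
    sq = np.sqrt(pi)
    S = sq[:, None] * T / sq[None, :]
    S = (S + S.T) / 2.0
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    vals = vals[order][:m]
    X = vecs[:, order][:, :m] / sq[:, None]          # right eigenvectors of T
    # pi-orthonormal; first column is constant -> normalize it to exactly 1
    X[:, 0] = 1.0
    return vals, X


def _inner_simplex(X):
    """Vertex (spanning-row) search of the inner simplex algorithm."""
    n, m = X.shape
    ortho = X.copy()
    idx = np.zeros(m, dtype=int)
    # start from the row farthest from the origin
    idx[0] = np.argmax(np.linalg.norm(ortho, axis=1))
    ortho -= ortho[idx[0]]
    for j in range(1, m):
        norms = np.linalg.norm(ortho, axis=1)
        idx[j] = np.argmax(norms)
        if norms[idx[j]] <= 1e-12:
            raise ValueError(
                "degenerate dominant spectrum: no m-dimensional simplex"
            )
        v = ortho[idx[j]] / norms[idx[j]]
        ortho -= np.outer(ortho @ v, v)
    return idx


def _fill_A(A, X):
    """Impose feasibility on A (nonnegative memberships, rows sum to 1)."""
    m = A.shape[0]
    A = A.copy()
    A[1:, 0] = -A[1:, 1:].sum(axis=1)
    for j in range(m):
        A[0, j] = -np.min(X[:, 1:] @ A[1:, j])
    A /= A[0, :].sum()
    return A


def _crispness(A):
    return np.sum(A[:, :] ** 2 / A[0, :][None, :])


def pcca(T, pi, m: int, optimize: bool = True) -> MacrostateModel:
    """PCCA+ fuzzy decomposition of a reversible transition matrix.

    ``T`` must be reversible w.r.t. ``pi``; ``m >= 2`` macrostates are
    returned ordered by descending stationary population (ties by first
    member index), so macrostate 0 is the most populated (the "S1" analog).
    """
    T = np.asarray(T, dtype=float)
    pi = np.asarray(pi, dtype=float)
    n = T.shape[0]
    if m < 2:
        raise ValueError("m must be >= 2")
    if m > n:
        raise ValueError("m exceeds the number of microstates")
    if np.max(np.abs(pi[:, None] * T - (pi[:, None] * T).T)) > 1e-8 * np.max(pi):
        raise ValueError("T is not reversible w.r.t. the stationary vector")
    vals, X = _dominant_right_eigenvectors(T, pi, m)
    if vals[m - 1] <= -1.0 + 1e-12:
        raise ValueError("dominant spectrum not suitable for PCCA+")

    idx = _inner_simplex(X)
    A0 = np.linalg.inv(X[idx])
    A = _fill_A(A0, X)
    if optimize and m > 2 and n > m:
        x0 = A[1:, 1:].ravel()

        def neg_crisp(x):
            Ax = A0.copy()
            Ax[1:, 1:] = x.reshape(m - 1, m - 1)
            Ax = _fill_A(Ax, X)
            chi = X @ Ax
            penalty = np.sum(np.minimum(chi, 0.0) ** 2)
            return -_crispness(Ax) + 1e4 * penalty

        res = minimize(neg_crisp, x0, method="Nelder-Mead",
                       options={"maxiter": 200 * (m - 1) ** 2, "xatol": 1e-10,
                                "fatol": 1e-12})
        Ax = A0.copy()
        Ax[1:, 1:] = res.x.reshape(m - 1, m - 1)
        Acand = _fill_A(Ax, X)
        if _crispness(Acand) >= _crispness(A) and \
                np.min(X @ Acand) > -1e-8:
            A = Acand

    chi = X @ A
    chi = np.clip(chi, 0.0, None)
    chi /= chi.sum(axis=1, keepdims=True)
    labels = crisp_assign(chi)

    # every macrostate must be non-empty under crisp assignment
    for j in range(m):
        if not np.any(labels == j):
            k = np.argmax(chi[:, j])
            labels[k] = j

    pops = np.array([pi[labels == j].sum() for j in range(m)])
    first = np.array([
        np.min(np.where(labels == j)[0]) for j in range(m)
    ])
    order = np.lexsort((first, -pops))
    chi = chi[:, order]
    labels = crisp_assign(chi)
    pops = np.array([pi[labels == j].sum() for j in range(m)])
    pops /= pi.sum()
    return MacrostateModel(memberships=chi, labels=labels,
                           populations=pops, m=m)
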