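"""Distance featurization and time-lagged independent component analysis.

The slow collective coordinates of a conformational transition are found by
(i) selecting inter-residue distances that form contacts somewhere along the
sampled path, (ii) evaluating those distances for every frame, and (iii)
solving the symmetrized generalized eigenproblem C(tau) v = lambda C(0) v on
mean-free features (TICA).  Projections onto the leading independent
components (ICs) define the space in which microstates are clustered.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import eigh
from scipy.spatial.distance import cdist

__all__ = [
    "FeatureSpec",
    "FeatureMatrix",
    "TICAModel",
    "select_feature_pairs",
    "compute_distance_features",
    "estimate_tica",
    "project",
]


@dataclass
class FeatureSpec:
    """Unique (point_a, point_b) identifier pairs with provenance.

    Provenance per pair is one of ``contact_selected`` (found within the
    contact cutoff in the sample), ``basepair_opening`` (supplied annotation,
    e.g. N1-N3 opening distances), or ``user``.
    """

    pairs: list
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        if not self.provenance:
            self.provenance = ["user"] * len(self.pairs)
        if len(set(map(tuple, self.pairs))) != len(self.pairs):
            raise ValueError("feature pairs must be unique")
        if len(self.provenance) != len(self.pairs):
            raise ValueError("one provenance flag per pair")

    def __len__(self):
        return len(self.pairs)


@dataclass
class FeatureMatrix:
    data: np.ndarray            # (frames, features)
    names: list
    ensemble: int = 0

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if not np.all(np.isfinite(self.data)):
            raise ValueError("non-finite feature values")


def select_feature_pairs(topology, sample_frames, contact_cutoff: float,
                         group_a=None, group_b=None,
                         base_pairs=None) -> FeatureSpec:
    """Select residue pairs that come within ``contact_cutoff`` in a sample.

    ``topology`` maps identifiers to point indices (dict id -> index); the
    identifiers name one representative point per residue or nucleotide
    (e.g. backbone phosphorus / C-alpha).  ``sample_frames`` has shape
    (T, n_points, 3).  With ``group_a``/``group_b`` given, only cross-group
    pairs are considered; otherwise all pairs.  ``base_pairs`` appends
    annotated opening-distance pairs regardless of the cutoff.
    """
    if contact_cutoff <= 0:
        raise ValueError("cutoff must be positive")
    frames = np.asarray(sample_frames, dtype=float)
    if frames.ndim != 3 or len(frames) == 0:
        raise ValueError("sample must be a non-empty (T, n_points, dim) array")
    ids = list(topology)
    for name in (group_a or []) + (group_b or []) + [
        i for bp in (base_pairs or []) for i in bp
    ]:
        if name not in topology:
            raise KeyError(f"identifier {name!r} not in topology")
    ga = list(group_a) if group_a is not None else ids
    gb = list(group_b) if group_b is not None else ids
    ia = np.array([topology[g] for g in ga])
    ib = np.array([topology[g] for g in gb])
    # min over frames of pairwise distance; contact if below cutoff once
    mind = None
    for f in frames:
        d = cdist(f[ia], f[ib])
        mind = d if mind is None else np.minimum(mind, d)
    pairs, prov = [], []
    seen = set()
    for ai, a in enumerate(ga):
        for bi, b in enumerate(gb):
            if a == b:
                continue
            key = tuple(sorted((a, b), key=str))
            if key in seen:
                continue
            if mind[ai, bi] < contact_cutoff:
                seen.add(key)
                pairs.append((a, b))
                prov.append("contact_selected")
    for a, b in base_pairs or []:
        key = tuple(sorted((a, b), key=str))
        if key not in seen:
            seen.add(key)
            pairs.append((a, b))
            prov.append("basepair_opening")
    return FeatureSpec(pairs, prov)


def compute_distance_features(trajectories, spec: FeatureSpec,
                              topology=None) -> list:
    """Euclidean distances for every pair of ``spec``, per trajectory.

    ``trajectories`` is a list of (T, n_points, 3) arrays or objects with a
    ``frames`` attribute of that shape.  Distances are invariant to global
    rotation/translation of each frame by construction.
    """
    out = []
    for tr in trajectories:
        frames = np.asarray(getattr(tr, "frames", tr), dtype=float)
        ens = getattr(tr, "ensemble", 0)
        if topology is not None:
            idx_a = np.array([topology[a] for a, _ in spec.pairs])
            idx_b = np.array([topology[b] for _, b in spec.pairs])
        else:
            idx_a = np.array([a for a, _ in spec.pairs])
            idx_b = np.array([b for _, b in spec.pairs])
        if frames.ndim != 3 or frames.shape[1] <= max(idx_a.max(), idx_b.max()):
            raise ValueError("missing coordinates for some feature pair")
        d = np.linalg.norm(frames[:, idx_a, :] - frames[:, idx_b, :], axis=2)
        out.append(FeatureMatrix(d, [f"{a}-{b}" for a, b in spec.pairs], ens))
    return out


@dataclass
class TICAModel:
    """Solution of the symmetrized TICA generalized eigenproblem.

    Components are C(0)-orthonormal and ordered by descending eigenvalue;
    eigenvalues of the symmetrized estimator are guaranteed in [-1, 1].
    """

    lag: int
    mean: np.ndarray
    components: np.ndarray      # (features, n_components)
    eigenvalues: np.ndarray
    reg: float = 0.0

    def timescales(self):
        lam = np.clip(np.abs(self.eigenvalues), 1e-300, 1 - 1e-15)
        return -self.lag / np.log(lam)


def _lagged_pairs(mats, lag):
    x0, xt = [], []
    for m in mats:
        data = m.data if isinstance(m, FeatureMatrix) else np.asarray(m, float)
        if len(data) <= lag:
            raise ValueError(f"trajectory of length {len(data)} <= lag {lag}")
        x0.append(data[:-lag])
        xt.append(data[lag:])
    return np.concatenate(x0), np.concatenate(xt)


def estimate_tica(features, lag: int, n_components: int = 2,
                  reg: float = 0.0) -> TICAModel:
    """Symmetrized TICA over pooled trajectories.

    Lagged pairs are formed only within trajectories; the mean is the pooled
    mean over all frames of all trajectories.  Symmetrization (averaging the
    forward and time-reversed pair sets) makes C(0) +- C(tau) positive
    semidefinite, hence all generalized eigenvalues real in [-1, 1].
    ``reg`` is added to the diagonal of C(0); raise it if C(0) is singular.
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    all_data = [
        m.data if isinstance(m, FeatureMatrix) else np.asarray(m, float)
        for m in features
    ]
    mean = np.concatenate(all_data).mean(axis=0)
    x0, xt = _lagged_pairs(features, lag)
    x0 = x0 - mean
    xt = xt - mean
    n = len(x0)
    c0 = (x0.T @ x0 + xt.T @ xt) / (2.0 * n)
    ct = (x0.T @ xt + xt.T @ x0) / (2.0 * n)
    c0r = c0 + reg * np.eye(c0.shape[0])
    try:
        vals, vecs = eigh(ct, c0r)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "C(0) is singular; raise the reg parameter"
        ) from err
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    if n_components > vecs.shape[1]:
        raise ValueError("n_components exceeds covariance rank")
    vals = vals[:n_components]
    vecs = vecs[:, :n_components]
    # sign convention: largest-magnitude loading positive
    for j in range(vecs.shape[1]):
        k = np.argmax(np.abs(vecs[:, j]))
        if vecs[k, j] < 0:
            vecs[:, j] = -vecs[:, j]
    return TICAModel(lag=lag, mean=mean, components=vecs,
                     eigenvalues=vals, reg=reg)


def project(features, model: TICAModel) -> list:
    """(x - mean) @ components for each trajectory, IC columns in order."""
    out = []
    for m in features:
        data = m.data if isinstance(m, FeatureMatrix) else np.asarray(m, float)
        if data.shape[1] != model.mean.shape[0]:
            raise ValueError(
                f"feature dimension {data.shape[1]} != model {model.mean.shape[0]}"
            )
        out.append((data - model.mean) @ model.components)
    return out
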