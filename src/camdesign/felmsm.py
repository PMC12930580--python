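"""Markov-state-model free-energy landscapes from swarm transition data.

The short unbiased swarms collected over the converged tail of a string
run are pairs (start, end) at a fixed lag. After optional tICA projection
and k-means discretization, a maximum-likelihood Markov state model over
the microstates yields the equilibrium distribution π, which reweights the
biased swarm sampling; two-dimensional free-energy surfaces along chosen
collective variables follow as F = -kT ln(Σ weights) per bin, shifted so
the occupied minimum is zero.

The reversible transition-matrix estimator is the standard iterative
detailed-balance (self-consistent) maximum-likelihood scheme on the
largest strongly connected state set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse.csgraph
from sklearn.cluster import KMeans

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class SwarmTransitionData:
    """Transition pairs (start, end) in CV space at a fixed lag."""

    starts: np.ndarray           # (n_pairs, d)
    ends: np.ndarray             # (n_pairs, d)
    iteration_tags: np.ndarray   # (n_pairs,) nondecreasing
    lag: int

    def __post_init__(self):
        self.starts = np.atleast_2d(np.asarray(self.starts, dtype=float))
        self.ends = np.atleast_2d(np.asarray(self.ends, dtype=float))
        self.iteration_tags = np.asarray(self.iteration_tags)
        if self.starts.shape != self.ends.shape:
            raise ValueError("start and end arrays must have equal shape")
        if np.any(np.diff(self.iteration_tags) < 0):
            raise ValueError("iteration tags must be nondecreasing")

    @property
    def n_pairs(self) -> int:
        return self.starts.shape[0]

    def all_points(self) -> np.ndarray:
        return np.concatenate([self.starts, self.ends])


@dataclass
class ProjectionModel:
    """tICA projection: components sorted by descending autocorrelation."""

    lag: int
    mean: np.ndarray
    components: np.ndarray       # (d, n_components), unit C0-norm columns
    eigenvalues: np.ndarray      # descending

    def transform(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        return (x - self.mean) @ self.components


@dataclass
class Discretization:
    """k-means microstates with a deterministic assignment function."""

    centers: np.ndarray
    seed: int
    feature_labels: list | None = None

    @property
    def k(self) -> int:
        return self.centers.shape[0]

    def assign(self, points: np.ndarray) -> np.ndarray:
        points = np.atleast_2d(np.asarray(points, dtype=float))
        d2 = ((points[:, None, :] - self.centers[None, :, :]) ** 2).sum(-1)
        return d2.argmin(axis=1)


@dataclass
class TransitionModel:
    """Microstate transition matrix with stationary distribution.

    ``state_labels`` maps model state index -> original microstate index
    (estimation is restricted to the largest connected set);
    ``discarded_states`` lists the microstates dropped.
    """

    counts: np.ndarray
    transition_matrix: np.ndarray
    stationary_distribution: np.ndarray
    reversible: bool
    state_labels: np.ndarray
    discarded_states: np.ndarray = field(
        default_factory=lambda: np.array([], dtype=int))

    @property
    def n_states(self) -> int:
        return self.transition_matrix.shape[0]

    def model_state(self, microstates: np.ndarray) -> np.ndarray:
        """Model state per microstate assignment; -1 for discarded states."""
        lookup = -np.ones(int(max(self.state_labels.max(initial=0),
                                  np.max(microstates, initial=0))) + 1,
                          dtype=int)
        lookup[self.state_labels] = np.arange(self.n_states)
        return lookup[np.asarray(microstates, dtype=int)]


@dataclass
class FESurface:
    """2-D free-energy grid over two CVs, in units of kT_proj.

    Empty bins are masked (NaN in ``free_energy``, True in ``mask``); the
    minimum over occupied bins is exactly zero.
    """

    cv_labels: tuple
    x_edges: np.ndarray
    y_edges: np.ndarray
    free_energy: np.ndarray
    mask: np.ndarray
    kT: float
    metadata: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def select_converged(history: list, last_n: int) -> SwarmTransitionData:
    """Swarm pairs from the final ``last_n`` string iterations.

    Flattens over images and swarms; the lag is the swarm length in engine
    steps, inferred from the records' swarm arrays.
    """
    if last_n <= 0:
        raise ValueError(f"last_n must be > 0, got {last_n}")
    if last_n > len(history):
        raise ValueError(
            f"last_n ({last_n}) exceeds history length ({len(history)})"
        )
    tail = history[len(history) - last_n:]
    starts, ends, tags = [], [], []
    for rec in tail:
        n_img, n_swarms, d = rec.swarm_starts.shape
        starts.append(rec.swarm_starts.reshape(-1, d))
        ends.append(rec.swarm_ends.reshape(-1, d))
        tags.append(np.full(n_img * n_swarms, rec.iteration))
    return SwarmTransitionData(starts=np.concatenate(starts),
                               ends=np.concatenate(ends),
                               iteration_tags=np.concatenate(tags),
                               lag=1)


def _tica_from_pairs(x0: np.ndarray, xt: np.ndarray, lag: int,
                     n_components: int, regularization: float
                     ) -> ProjectionModel:
    mean = np.concatenate([x0, xt]).mean(axis=0)
    a = x0 - mean
    b = xt - mean
    n = a.shape[0]
    c0 = 0.5 * (a.T @ a + b.T @ b) / n
    ct = 0.5 * (a.T @ b + b.T @ a) / n
    c0reg = c0 + regularization * np.eye(c0.shape[0])
    try:
        w, v = scipy.linalg.eigh(ct, c0reg)
    except scipy.linalg.LinAlgError as exc:
        raise ValueError(
            "singular instantaneous covariance; pass a small "
            "regularization (e.g. 1e-8) to fit_tica"
        ) from exc
    order = np.argsort(w)[::-1][:n_components]
    return ProjectionModel(lag=lag, mean=mean, components=v[:, order],
                           eigenvalues=w[order])


def fit_tica(data, lag: int, n_components: int = 2,
             regularization: float = 0.0) -> ProjectionModel:
    """Time-lagged independent component analysis.

    ``data`` is either a single (n, d) trajectory, a list of trajectories
    (pairs are formed at ``lag`` within each), or a
    :class:`SwarmTransitionData` whose pairs are used directly. Solves the
    symmetrized time-lagged generalized eigenproblem on mean-free data.
    """
    if lag < 1:
        raise ValueError(f"lag must be >= 1, got {lag}")
    if isinstance(data, SwarmTransitionData):
        x0, xt = data.starts, data.ends
    else:
        trajs = [np.atleast_2d(np.asarray(t, dtype=float))
                 for t in (data if isinstance(data, (list, tuple)) else [data])]
        x0 = np.concatenate([t[:-lag] for t in trajs if t.shape[0] > lag])
        xt = np.concatenate([t[lag:] for t in trajs if t.shape[0] > lag])
    if x0.shape[0] <= x0.shape[1]:
        raise ValueError("need more lagged samples than dimensions")
    return _tica_from_pairs(x0, xt, lag, n_components, regularization)


def discretize(points: np.ndarray, k: int, seed: int = 0,
               feature_labels: list | None = None) -> Discretization:
    """Seeded k-means microstate discretization."""
    if k <= 0:
        raise ValueError(f"k must be > 0, got {k}")
    points = np.atleast_2d(np.asarray(points, dtype=float))
    n_distinct = np.unique(points, axis=0).shape[0]
    if k > n_distinct:
        raise ValueError(
            f"k ({k}) exceeds the number of distinct points ({n_distinct})"
        )
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(points)
    return Discretization(centers=km.cluster_centers_.copy(), seed=seed,
                          feature_labels=feature_labels)


def _largest_connected_set(counts: np.ndarray):
    adj = (counts > 0).astype(int)
    n_comp, labels = scipy.sparse.csgraph.connected_components(
        adj, directed=True, connection="strong")
    sizes = [(counts[np.ix_(labels == c, labels == c)].sum(),
              (labels == c).sum(), -c) for c in range(n_comp)]
    best = -max(sizes)[2]
    keep = np.nonzero(labels == best)[0]
    drop = np.nonzero(labels != best)[0]
    return keep, drop


def _reversible_mle(counts: np.ndarray, tol: float = 1e-13,
                    max_iter: int = 100000) -> np.ndarray:
    """Self-consistent detailed-balance maximum-likelihood estimator."""
    c = counts.astype(float)
    csym = c + c.T
    ci = c.sum(axis=1)
    x = csym.copy()
    for _ in range(max_iter):
        xi = x.sum(axis=1)
        denom = (ci / xi)[:, None] + (ci / xi)[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            xnew = np.where(csym > 0, csym / denom, 0.0)
        xi_new = xnew.sum(axis=1)
        if np.max(np.abs(xi_new / xi_new.sum() - xi / xi.sum())) < tol:
            x = xnew
            break
        x = xnew
    t = x / x.sum(axis=1)[:, None]
    return t


def _stationary_from_t(t: np.ndarray) -> np.ndarray:
    w, v = scipy.linalg.eig(t.T)
    i = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, i])
    pi = np.abs(pi)
    return pi / pi.sum()


def estimate_msm(data: SwarmTransitionData, disc: Discretization,
                 reversible: bool = True) -> TransitionModel:
    """Maximum-likelihood MSM from discretized transition pairs.

    Counts are (state(start) -> state(end)) at the swarm lag, restricted to
    the largest strongly connected microstate set. Reversible estimation
    (default) enforces detailed balance; the non-reversible fallback simply
    row-normalizes the counts. π is the stationary distribution of the
    resulting transition matrix.
    """
    if data.n_pairs < 1:
        raise ValueError("need at least one transition pair")
    si = disc.assign(data.starts)
    sj = disc.assign(data.ends)
    k = disc.k
    counts = np.zeros((k, k))
    np.add.at(counts, (si, sj), 1.0)
    keep, drop = _largest_connected_set(counts)
    if counts[np.ix_(keep, keep)].sum() == 0:
        raise ValueError("no connected transitions among the microstates")
    if drop.size:
        logger.info("MSM restricted to largest connected set: kept %d of %d "
                    "microstates (discarded %s)", keep.size, k, drop.tolist())
    sub = counts[np.ix_(keep, keep)]
    if reversible:
        t = _reversible_mle(sub)
        pi = _stationary_from_t(t)
    else:
        t = sub / sub.sum(axis=1)[:, None]
        pi = _stationary_from_t(t)
    # kill residual float drift in row sums
    t = t / t.sum(axis=1)[:, None]
    return TransitionModel(counts=sub, transition_matrix=t,
                           stationary_distribution=pi,
                           reversible=reversible, state_labels=keep,
                           discarded_states=drop)


def msm_sample_weights(model_states: np.ndarray, model: TransitionModel
                       ) -> np.ndarray:
    """Per-sample equilibrium weights π_i / n_i given model-state labels.

    Samples in discarded states (label -1) receive weight NaN.
    """
    states = np.asarray(model_states, dtype=int)
    weights = np.full(states.shape, np.nan)
    valid = states >= 0
    n_i = np.bincount(states[valid], minlength=model.n_states).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        per_state = np.where(n_i > 0,
                             model.stationary_distribution / n_i, 0.0)
    weights[valid] = per_state[states[valid]]
    return weights


def weighted_fel(samples: pd.DataFrame, model: TransitionModel,
                 disc: Discretization, cv_pair: tuple, bins: int = 40,
                 kT_proj: float = 1.0, bin_range=None,
                 on_unassigned: str = "raise") -> FESurface:
    """MSM-reweighted 2-D free-energy surface along two CV columns.

    Each sample in model state i carries weight π_i / n_i; per bin,
    F = -kT_proj · ln(Σ weights), shifted so the occupied minimum is 0, and
    empty bins are masked. ``samples`` must contain both the ``cv_pair``
    columns and the feature columns the discretization was fit on. Samples
    falling in discarded microstates raise by default
    (``on_unassigned="drop"`` removes them instead).
    """
    for label in cv_pair:
        if label not in samples.columns:
            raise KeyError(f"CV label {label!r} not among sample columns "
                           f"{list(samples.columns)}")
    if disc.feature_labels is not None:
        features = samples[list(disc.feature_labels)].to_numpy()
    else:
        features = samples[list(cv_pair)].to_numpy()
    states = model.model_state(disc.assign(features))
    if np.any(states < 0):
        if on_unassigned == "raise":
            raise ValueError(
                f"{int((states < 0).sum())} samples fall in microstates "
                "discarded from the connected set; pass "
                "on_unassigned='drop' to exclude them"
            )
        keepmask = states >= 0
        samples = samples.loc[keepmask]
        states = states[keepmask]
    weights = msm_sample_weights(states, model)

    x = samples[cv_pair[0]].to_numpy()
    y = samples[cv_pair[1]].to_numpy()
    if bin_range is None:
        pad = 0.05
        xr = (x.min(), x.max())
        yr = (y.min(), y.max())
        dx = pad * max(xr[1] - xr[0], 1e-12)
        dy = pad * max(yr[1] - yr[0], 1e-12)
        bin_range = ((xr[0] - dx, xr[1] + dx), (yr[0] - dy, yr[1] + dy))
    hist, xe, ye = np.histogram2d(x, y, bins=bins, range=bin_range,
                                  weights=weights)
    mask = hist <= 0.0
    f = np.full_like(hist, np.nan)
    with np.errstate(divide="ignore"):
        f[~mask] = -kT_proj * np.log(hist[~mask])
    f[~mask] -= np.nanmin(f[~mask])
    return FESurface(cv_labels=tuple(cv_pair), x_edges=xe, y_edges=ye,
                     free_energy=f, mask=mask, kT=kT_proj,
                     metadata={"bins": bins, "n_samples": int(len(x)),
                               "reversible": model.reversible})
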