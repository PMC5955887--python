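"""Microstate discretization and reversible Markov state model estimation.

Trajectories embedded in the 4D order-parameter space are discretized with
k-means (fitted only on frames with ``d < L/2``; farther frames are assigned a
reserved *unbound* microstate), transitions are counted with a sliding window
at a fixed lag, and a reversible transition matrix is estimated by maximum
likelihood with the standard self-consistent iteration.  Validation utilities
(implied timescales, trajectory bootstrap, Chapman–Kolmogorov test) follow the
conventions used throughout the MSM literature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.linalg import eig, eigh
from sklearn.cluster import KMeans

from .geometry import invert_embedding

__all__ = [
    "Discretization",
    "MSM",
    "kmeans_discretize",
    "assign",
    "count_transitions",
    "largest_connected_set",
    "mle_reversible",
    "transition_matrix_mle_reversible",
    "stationary_distribution",
    "eigenvalues_reversible",
    "implied_timescales",
    "bootstrap_models",
    "ck_test",
]


@dataclass
class Discretization:
    """k-means centers in the embedded 4D space plus the reserved unbound state.

    Microstates ``0 .. n_centers-1`` are k-means cells; index ``n_centers`` is
    the unbound microstate holding every frame with ``d >= L/2``.
    """

    centers: np.ndarray
    L: float
    unbound_index: int = field(init=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, float)
        d, _, _ = invert_embedding(self.centers)
        if np.any(d >= self.L / 2):
            raise ValueError("all centers must have d < L/2")
        self.unbound_index = len(self.centers)

    @property
    def n_states(self) -> int:
        return len(self.centers) + 1

    def center_cvs(self) -> np.ndarray:
        """(n_centers, 3) array of (d, alpha1, alpha2) for the k-means centers."""
        d, a1, a2 = invert_embedding(self.centers)
        return np.column_stack([d, a1, a2])


def assign(disc: Discretization, X: np.ndarray) -> np.ndarray:
    """Map embedded frames (n, 4) to microstate indices."""
    X = np.asarray(X, float)
    d = np.hypot(X[:, 0], X[:, 1])  # embedding norm identity: |(x0,x1)| = d
    out = np.empty(len(X), dtype=np.int64)
    far = d >= disc.L / 2
    out[far] = disc.unbound_index
    if (~far).any():
        diff = X[~far, None, :] - disc.centers[None, :, :]
        out[~far] = np.argmin(np.einsum("ijk,ijk->ij", diff, diff), axis=1)
    return out


def kmeans_discretize(
    trajs: Sequence[np.ndarray],
    n_centers: int,
    L: float,
    seed: int = 0,
    fit_stride: int = 1,
) -> tuple[Discretization, list[np.ndarray]]:
    """Fit k-means on bound frames and assign all frames to microstates.

    ``trajs`` are embedded (n, 4) arrays.  k-means (k-means++ seeding, fixed
    seed) is fitted only on frames with ``d < L/2``; frames at ``d >= L/2``
    go to the reserved unbound microstate.  ``fit_stride`` subsamples the
    frames used for fitting the centers (assignment always uses all frames).
    """
    if n_centers < 2:
        raise ValueError("n_centers must be >= 2")
    X = np.vstack([np.asarray(t, float)[::fit_stride] for t in trajs])
    d = np.hypot(X[:, 0], X[:, 1])
    bound = X[d < L / 2]
    if len(bound) == 0:
        raise ValueError("no frames with d < L/2: nothing to cluster")
    if len(np.unique(bound, axis=0)) < n_centers:
        raise ValueError("fewer distinct bound frames than requested centers")
    km = KMeans(n_clusters=n_centers, init="k-means++", n_init=1,
                max_iter=500, random_state=seed)
    km.fit(bound)
    disc = Discretization(centers=km.cluster_centers_, L=L)
    dtrajs = [assign(disc, np.asarray(t, float)) for t in trajs]
    return disc, dtrajs


def count_transitions(
    dtrajs: Sequence[np.ndarray],
    lag: int,
    n_states: int | None = None,
) -> np.ndarray:
    """Sliding-window transition counts at integer lag (in frames).

    Trajectories are never concatenated; a trajectory shorter than ``lag + 1``
    contributes nothing (with a warning).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1 frame")
    dtrajs = [np.asarray(t, dtype=np.int64) for t in dtrajs]
    if n_states is None:
        n_states = int(max(t.max() for t in dtrajs if len(t))) + 1
    C = np.zeros((n_states, n_states), dtype=np.int64)
    for t in dtrajs:
        if len(t) <= lag:
            warnings.warn("trajectory shorter than lag contributes no counts")
            continue
        np.add.at(C, (t[:-lag], t[lag:]), 1)
    return C


def largest_connected_set(C: np.ndarray, directed: bool = True) -> np.ndarray:
    """States of the largest (strongly) connected component of the count graph."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    n, labels = connected_components(
        csr_matrix(C > 0), directed=directed, connection="strong" if directed else "weak"
    )
    sizes = np.bincount(labels)
    return np.flatnonzero(labels == np.argmax(sizes))


def transition_matrix_mle_reversible(
    C: np.ndarray, tol: float = 1e-12, max_iter: int = 500_000
) -> np.ndarray:
    """Reversible maximum-likelihood transition matrix from counts.

    Standard self-consistent iteration on the Boltzmann-weighted edge
    variables

        x_ij ∝ (c_ij + c_ji) / (c_i/x_i + c_j/x_j)

    iterated until the transition-matrix entries change by less than ``tol``.
    The count graph must be connected.
    """
    C = np.asarray(C, float)
    if C.sum() == 0:
        raise ValueError("empty count matrix")
    Csym = C + C.T
    crow = C.sum(axis=1)
    if np.any((crow == 0) & (C.sum(axis=0) == 0)):
        raise ValueError("count matrix contains fully unvisited states")
    X = Csym / Csym.sum()
    T_prev = None
    for it in range(max_iter):
        x = X.sum(axis=1)
        q = crow / x
        denom = q[:, None] + q[None, :]
        with np.errstate(divide="ignore", invalid="ignore"):
            X = np.where(Csym > 0, Csym / denom, 0.0)
        X /= X.sum()
        if it % 5 == 0:
            x = X.sum(axis=1)
            T = X / x[:, None]
            if T_prev is not None and np.abs(T - T_prev).max() <= tol:
                break
            T_prev = T
    x = X.sum(axis=1)
    T = X / x[:, None]
    T /= T.sum(axis=1, keepdims=True)
    return T


def stationary_distribution(T: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (leading left eigenvector)."""
    w, v = eig(T.T)
    k = np.argmin(np.abs(w - 1.0))
    pi = np.real(v[:, k])
    pi = np.abs(pi)
    return pi / pi.sum()


@dataclass
class MSM:
    """Reversible Markov state model at a fixed lag.

    ``active_set`` maps the model's state indices back to the original
    microstate labels (states outside the largest connected set are dropped
    and reported there).
    """

    T: np.ndarray
    pi: np.ndarray
    lag: int
    active_set: np.ndarray

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def eigenvalues(self, k: int | None = None) -> np.ndarray:
        return eigenvalues_reversible(self.T, self.pi, k)

    def timescales(self, k: int | None = None) -> np.ndarray:
        """Implied timescales −lag/ln λ_i for the non-unit eigenvalues (in frames)."""
        ev = self.eigenvalues(k)[1:]
        with np.errstate(divide="ignore"):
            lt = np.log(np.clip(np.abs(ev), 0.0, None))
            out = np.where(lt == 0, np.inf, -self.lag / np.where(lt == 0, 1.0, lt))
        return out


def eigenvalues_reversible(
    T: np.ndarray, pi: np.ndarray | None = None, k: int | None = None
) -> np.ndarray:
    """Real eigenvalue spectrum of a reversible T via the symmetrized matrix.

    Sorted by decreasing modulus, ties broken by real part (all eigenvalues of
    a reversible chain are real).
    """
    if pi is None:
        pi = stationary_distribution(T)
    s = np.sqrt(pi)
    S = (s[:, None] / s[None, :]) * T
    Ssym = 0.5 * (S + S.T)
    asym = np.abs(S - S.T).max()
    if asym > 1e-6:
        raise ValueError(f"transition matrix is not reversible (asymmetry {asym:.2e})")
    w = eigh(Ssym, eigvals_only=True)[::-1]
    order = np.lexsort((-w, -np.abs(w)))
    w = w[order]
    return w if k is None else w[:k]


def mle_reversible(C: np.ndarray, lag: int = 1) -> MSM:
    """Reversible MLE restricted to the largest connected set of the counts."""
    C = np.asarray(C)
    lcc = largest_connected_set(C)
    if len(lcc) < C.shape[0]:
        warnings.warn(
            f"restricting to largest connected set: {len(lcc)}/{C.shape[0]} states kept"
        )
    Cr = C[np.ix_(lcc, lcc)]
    T = transition_matrix_mle_reversible(Cr)
    pi = stationary_distribution(T)
    return MSM(T=T, pi=pi, lag=lag, active_set=lcc)


def implied_timescales(
    dtrajs: Sequence[np.ndarray],
    lags: Sequence[int],
    n_timescales: int = 5,
    rtol_converged: float = 0.25,
) -> "pd.DataFrame":
    """Implied-timescale table over several lags, with a convergence flag.

    Returns a DataFrame with one row per lag; column ``t{i}`` is the i-th
    implied timescale (in frames).  A timescale is flagged non-converged when
    successive lags differ by more than ``rtol_converged`` relative.  Infinite
    timescales (eigenvalue 1 beyond the Perron root, e.g. for an identity
    matrix) are returned as ``inf`` and flagged.
    """
    import pandas as pd

    if len(lags) < 2:
        raise ValueError("need at least two lags")
    rows = []
    for lag in lags:
        C = count_transitions(dtrajs, lag)
        m = mle_reversible(C, lag=lag)
        ts = m.timescales(min(n_timescales + 1, m.n_states))
        row = {"lag": lag}
        for i, t in enumerate(ts[:n_timescales], start=2):
            row[f"t{i}"] = t
        rows.append(row)
    df = pd.DataFrame(rows).set_index("lag")
    conv = {}
    for col in df.columns:
        v = df[col].to_numpy()
        ok = np.all(np.isfinite(v))
        if ok:
            rel = np.abs(np.diff(v)) / np.maximum(np.abs(v[:-1]), 1e-300)
            ok = bool(np.all(rel <= rtol_converged))
        conv[col] = ok
    df.attrs["converged"] = conv
    return df


def bootstrap_models(
    dtrajs: Sequence[np.ndarray],
    estimator: Callable[[Sequence[np.ndarray]], object],
    n_boot: int = 10,
    seed: int = 0,
) -> list:
    """Resample whole trajectories with replacement and re-estimate.

    Returns the list of estimator outputs (models or derived scalars); use
    :func:`percentile_interval` to summarize.
    """
    if len(dtrajs) < 2:
        raise ValueError("bootstrap needs at least two trajectories")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_boot):
        idx = rng.integers(0, len(dtrajs), len(dtrajs))
        out.append(estimator([dtrajs[i] for i in idx]))
    return out


def percentile_interval(samples: Sequence[float]) -> tuple[float, float, float]:
    """Mean and 5%/95% percentiles of a bootstrap sample."""
    a = np.asarray(samples, float)
    return float(a.mean()), float(np.percentile(a, 5)), float(np.percentile(a, 95))


def ck_test(
    model: MSM,
    dtrajs: Sequence[np.ndarray],
    sets: Sequence[Sequence[int]],
    k_steps: int = 5,
) -> dict:
    """Chapman–Kolmogorov test on groups of states.

    Compares the occupation probability of each set after ``k`` lag steps as
    predicted by ``T(τ)^k`` with the estimate from a model re-estimated at lag
    ``kτ``, starting from the stationary distribution restricted to the set.
    Returns ``{"predicted": (n_sets, k), "estimated": ..., "deviation": ...}``.
    """
    sets = [np.asarray(s, dtype=np.int64) for s in sets]
    n_sets = len(sets)
    pred = np.zeros((n_sets, k_steps))
    est = np.zeros((n_sets, k_steps))
    # map original labels to model indices
    index_of = {s: i for i, s in enumerate(model.active_set)}
    for k in range(1, k_steps + 1):
        Tk = np.linalg.matrix_power(model.T, k)
        try:
            mk = mle_reversible(count_transitions(dtrajs, model.lag * k), lag=model.lag * k)
        except ValueError:
            warnings.warn(f"insufficient data at lag {model.lag * k}; truncating CK test")
            pred = pred[:, : k - 1]
            est = est[:, : k - 1]
            break
        idx_k = {s: i for i, s in enumerate(mk.active_set)}
        for a, S in enumerate(sets):
            rows = [index_of[s] for s in S if s in index_of]
            w = model.pi[rows]
            w = w / w.sum()
            pred[a, k - 1] = float(w @ Tk[np.ix_(rows, rows)].sum(axis=1))
            rows_k = [idx_k[s] for s in S if s in idx_k]
            wk = mk.pi[rows_k]
            wk = wk / wk.sum()
            est[a, k - 1] = float(wk @ mk.T[np.ix_(rows_k, rows_k)].sum(axis=1))
    return {"predicted": pred, "estimated": est, "deviation": np.abs(pred - est)}
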