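"""Multi-ensemble estimation: TRAM (transition-based reweighting analysis).

Combines transition counts and per-frame bias energies from an unbiased
ensemble and umbrella-restrained ensembles into a single statistically-optimal
estimate of the unbiased stationary distribution and reversible transition
matrix at a fixed lag.

The self-consistent equations solved here are the standard TRAM fixed point:
with ``c_ij^k`` the transition counts of ensemble ``k``, ``f_i^k`` the reduced
free energy of microstate ``i`` under ensemble ``k``'s bias and ``ν_i^k`` the
row-normalization (Lagrange) multipliers,

    ν_i^k  ←  Σ_j (c_ij^k + c_ji^k) · ν_i^k e^{-f_j^k}
                 / (ν_i^k e^{-f_j^k} + ν_j^k e^{-f_i^k})

    R_i^k  =  Σ_j (c_ij^k + c_ji^k) · ν_j^k e^{-f_i^k}
                 / (ν_i^k e^{-f_j^k} + ν_j^k e^{-f_i^k})
              + N_i^k − Σ_j c_ji^k

    e^{-f_i^k}  ←  Σ_{x ∈ i} e^{-b^k(x)} / Σ_l R_i^l e^{f_i^l − b^l(x)}

where the last sum runs over the pooled samples of all ensembles that fall in
microstate ``i`` and ``b^l(x)`` is the bias energy ensemble ``l`` would assign
to configuration ``x`` (zero for the unbiased ensemble).  At convergence the
ensemble-k transition matrix is

    p_ij^k = (c_ij^k + c_ji^k) e^{-f_j^k} / (ν_i^k e^{-f_j^k} + ν_j^k e^{-f_i^k}),

which is reversible with respect to ``e^{-f^k}``.  With a single unbiased
ensemble this reduces to the reversible maximum-likelihood MSM estimator.

All accumulation is done in log space.  Samples with identical
(microstate, bias-energy vector) are aggregated with multiplicities, which
makes discrete (state-wise constant bias) problems cheap without changing the
estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .msm import count_transitions, mle_reversible, stationary_distribution
from .synthetic import BiasSpec, CVTrajectory

__all__ = [
    "GAS_CONSTANT_KJ_PER_MOL_K",
    "kT_kJ_per_mol",
    "EnsembleData",
    "TRAMModel",
    "evaluate_bias_energies",
    "resample_unbound",
    "tram_estimate",
    "tram_bootstrap",
]

GAS_CONSTANT_KJ_PER_MOL_K = 0.0083145
"""Molar gas constant R in kJ/(mol·K)."""


def kT_kJ_per_mol(temperature_K: float) -> float:
    """Thermal energy kT in kJ/mol at the given temperature (310 K → 2.577)."""
    return GAS_CONSTANT_KJ_PER_MOL_K * temperature_K


def evaluate_bias_energies(
    cv_traj: CVTrajectory,
    specs: Sequence[BiasSpec | None],
    kT: float = 1.0,
) -> np.ndarray:
    """Reduced bias energies U_b/kT of every frame under every ensemble's bias.

    ``specs`` lists one bias per ensemble (``None`` for the unbiased ensemble,
    giving a zero column).  ``kT`` converts the restraint energies to reduced
    units; pass :func:`kT_kJ_per_mol`(310) when the restraint constants are in
    kJ/mol units.
    """
    d = np.asarray(cv_traj.d, float)
    if not (np.all(np.isfinite(d)) and np.all(np.isfinite(cv_traj.alpha1))
            and np.all(np.isfinite(cv_traj.alpha2))):
        raise ValueError("trajectory contains non-finite CVs")
    out = np.zeros((len(d), len(specs)))
    for k, spec in enumerate(specs):
        if spec is None:
            continue
        out[:, k] = spec.energy(cv_traj.d, cv_traj.alpha1, cv_traj.alpha2) / kT
    return out


@dataclass
class EnsembleData:
    """One thermodynamic ensemble's discretized data.

    ``bias_matrices[t][f, l]`` is the reduced bias energy that ensemble ``l``
    would assign to frame ``f`` of trajectory ``t`` (column order = order of
    the ensembles passed to :func:`tram_estimate`).  The unbiased ensemble has
    ``bias=None`` and a zero own-column.
    """

    bias: BiasSpec | None
    dtrajs: list[np.ndarray]
    bias_matrices: list[np.ndarray]

    def __post_init__(self) -> None:
        self.dtrajs = [np.asarray(t, dtype=np.int64) for t in self.dtrajs]
        self.bias_matrices = [np.asarray(b, float) for b in self.bias_matrices]
        if len(self.dtrajs) != len(self.bias_matrices):
            raise ValueError("need one bias matrix per trajectory")
        for t, b in zip(self.dtrajs, self.bias_matrices):
            if len(t) != len(b):
                raise ValueError("bias matrix rows must match trajectory frames")
            if not np.all(np.isfinite(b)):
                raise ValueError("bias energies must be finite")


@dataclass
class TRAMModel:
    """Converged TRAM estimate.

    ``f[k, i]`` are per-ensemble per-microstate reduced free energies
    (gauge: the unbiased ensemble's state weights sum to 1), ``pi`` and ``T``
    the unbiased stationary distribution and reversible transition matrix at
    the estimation lag, ``history`` the max|Δf| per iteration.
    """

    f: np.ndarray
    pi: np.ndarray
    T: np.ndarray
    lag: int
    history: np.ndarray
    unbiased_index: int

    @property
    def n_states(self) -> int:
        return len(self.pi)

    def free_energies(self) -> np.ndarray:
        """Unbiased reduced free energies −ln π_i."""
        return -np.log(self.pi)


def resample_unbound(
    dtrajs: Sequence[np.ndarray],
    unbound_states: Sequence[int],
    counts: np.ndarray,
    centers: np.ndarray | None = None,
    n_new: int = 1,
    seed: int = 0,
) -> tuple[np.ndarray, list[np.ndarray]]:
    """Merge unbound-component microstates that never leave the component.

    A microstate of the (preliminary PCCA+) unbound component qualifies when
    the lag count matrix shows no transitions between it and any state outside
    the component, in either direction.  Qualifying states are merged into
    ``n_new`` replacement states (by k-means on their ``centers`` when given,
    otherwise into a single state); all other microstates keep their identity.

    Returns ``(mapping, new_dtrajs)`` with ``mapping[old] = new`` covering all
    original states with a contiguous new labelling; the total frame count is
    conserved.
    """
    counts = np.asarray(counts)
    n = counts.shape[0]
    unbound = np.zeros(n, bool)
    unbound[np.asarray(list(unbound_states), int)] = True
    out_mask = ~unbound
    qualifies = unbound.copy()
    qualifies[unbound] = (counts[np.ix_(unbound, out_mask)].sum(axis=1) == 0) & (
        counts[np.ix_(out_mask, unbound)].sum(axis=0) == 0
    )
    keep = np.flatnonzero(~qualifies)
    merged = np.flatnonzero(qualifies)
    mapping = np.empty(n, dtype=np.int64)
    mapping[keep] = np.arange(len(keep))
    if len(merged) == 0:
        return np.arange(n, dtype=np.int64), [t.copy() for t in dtrajs]
    n_new = min(n_new, len(merged))
    if centers is not None and n_new > 1:
        km = KMeans(n_clusters=n_new, n_init=1, random_state=seed)
        sub = km.fit_predict(np.asarray(centers, float)[merged])
    else:
        sub = np.zeros(len(merged), dtype=int)
        n_new = 1
    mapping[merged] = len(keep) + sub
    return mapping, [mapping[np.asarray(t, dtype=np.int64)] for t in dtrajs]


# ----------------------------------------------------------------------------
# TRAM core
# ----------------------------------------------------------------------------

def _aggregate_samples(
    data: Sequence[EnsembleData], n_states: int, n_ens: int
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Pool all frames by microstate, collapsing duplicate bias rows.

    Returns per-state ``(B_i, logw_i)``: unique (m_i, K) bias rows and the log
    multiplicity of each.
    """
    rows: list[list[np.ndarray]] = [[] for _ in range(n_states)]
    for ens in data:
        for t, b in zip(ens.dtrajs, ens.bias_matrices):
            for i in range(n_states):
                m = t == i
                if m.any():
                    rows[i].append(b[m])
    B, logw = [], []
    for i in range(n_states):
        if rows[i]:
            allb = np.vstack(rows[i])
            uniq, cnt = np.unique(allb, axis=0, return_counts=True)
            B.append(uniq)
            logw.append(np.log(cnt.astype(float)))
        else:
            B.append(np.zeros((0, n_ens)))
            logw.append(np.zeros(0))
    return B, logw


def tram_estimate(
    data: Sequence[EnsembleData],
    lag: int,
    tol: float = 1e-9,
    max_iter: int = 100_000,
    n_states: int | None = None,
) -> TRAMModel:
    """Self-consistent TRAM solution over all ensembles.

    ``lag`` is in recorded frames.  Iteration stops when the maximal change of
    any finite ``f_i^k`` drops below ``tol`` (in kT); non-convergence raises,
    with the history attached to the exception.
    """
    data = list(data)
    for e in data:
        for b in e.bias_matrices:
            if b.shape[1] != len(data):
                raise ValueError("bias matrices must have one column per ensemble")
    data = _merge_identical_ensembles(data)
    n_ens = len(data)
    unbiased = [k for k, e in enumerate(data) if e.bias is None]
    if len(unbiased) != 1:
        raise ValueError("exactly one unbiased ensemble (bias=None) is required")
    k0 = unbiased[0]

    if n_states is None:
        n_states = 1 + max(int(t.max()) for e in data for t in e.dtrajs)

    # per-ensemble count matrices and state visit counts
    C = np.zeros((n_ens, n_states, n_states))
    N = np.zeros((n_ens, n_states))
    for k, e in enumerate(data):
        C[k] = count_transitions(e.dtrajs, lag, n_states=n_states)
        for t in e.dtrajs:
            N[k] += np.bincount(t, minlength=n_states)

    visited = N.sum(axis=0) > 0
    if not visited.all():
        raise ValueError(
            f"microstates never visited in any ensemble: {np.flatnonzero(~visited).tolist()}"
        )
    _check_connectivity(C)

    B, logw = _aggregate_samples(data, n_states, n_ens)

    Csym = C + C.transpose(0, 2, 1)
    with np.errstate(divide="ignore"):
        logCsym = np.log(Csym)
    logNminusCin = np.full((n_ens, n_states), -np.inf)
    nc = N - C.sum(axis=1)  # N_i^k - Σ_j c_ji^k  (>= 0 with sliding counts)
    pos = nc > 0
    logNminusCin[pos] = np.log(nc[pos])

    f = np.zeros((n_ens, n_states))
    with np.errstate(divide="ignore"):
        lv = np.log(np.maximum(C.sum(axis=2), 0.0))  # log ν init: row counts

    history = []
    for it in range(max_iter):
        # --- ν update ----------------------------------------------------
        # log denominator_ij^k = logaddexp(lv_i - f_j, lv_j - f_i)
        a = lv[:, :, None] - f[:, None, :]
        den = np.logaddexp(a, a.transpose(0, 2, 1))
        with np.errstate(invalid="ignore"):
            terms = logCsym + a - den
        terms[np.isnan(terms)] = -np.inf
        lv = logsumexp(terms, axis=2)

        # --- R ----------------------------------------------------------
        a = lv[:, :, None] - f[:, None, :]
        den = np.logaddexp(a, a.transpose(0, 2, 1))
        with np.errstate(invalid="ignore"):
            terms = logCsym + (lv[:, None, :] - f[:, :, None]) - den
        terms[np.isnan(terms)] = -np.inf
        logR = np.logaddexp(logsumexp(terms, axis=2), logNminusCin)

        # --- f update ----------------------------------------------------
        f_new = np.empty_like(f)
        for i in range(n_states):
            Bi = B[i]
            if len(Bi) == 0:
                f_new[:, i] = np.inf
                continue
            # log μ̂ weight of each pooled sample (up to gauge)
            log_denom = logsumexp(
                logR[:, i][None, :] + f[:, i][None, :] - Bi, axis=1
            )
            f_new[:, i] = -logsumexp(
                logw[i][None, :] - Bi.T - log_denom[None, :], axis=1
            )
        # gauge: normalize unbiased state weights to sum to 1
        shift = -logsumexp(-f_new[k0])
        f_new -= shift
        finite = np.isfinite(f_new) & np.isfinite(f)
        delta = float(np.max(np.abs(f_new[finite] - f[finite]))) if finite.any() else np.inf
        f = f_new
        history.append(delta)
        if delta < tol:
            break
    else:
        err = RuntimeError(
            f"TRAM did not converge in {max_iter} iterations (last Δf = {history[-1]:.3e})"
        )
        err.history = np.asarray(history)  # type: ignore[attr-defined]
        raise err

    pi = np.exp(-f[k0])
    pi = pi / pi.sum()
    T = _transition_matrix(Csym[k0], lv[k0], f[k0])
    return TRAMModel(
        f=f, pi=pi, T=T, lag=lag, history=np.asarray(history), unbiased_index=k0
    )


def _transition_matrix(Csym_k: np.ndarray, lv_k: np.ndarray, f_k: np.ndarray) -> np.ndarray:
    """Ensemble transition matrix from converged multipliers (linear space)."""
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        a = lv_k[:, None] - f_k[None, :]
        den = np.logaddexp(a, a.T)
        logP = np.where(Csym_k > 0, np.log(Csym_k) - f_k[None, :] - den, -np.inf)
    P = np.exp(logP)
    # states with no counts in this ensemble: absorbing placeholder rows
    empty = Csym_k.sum(axis=1) == 0
    if empty.any():
        warnings.warn(
            f"{int(empty.sum())} states have no counts in the output ensemble; "
            "their rows are set to identity"
        )
        P[empty] = 0.0
        P[empty, empty] = 1.0
    # at the fixed point rows sum to 1 up to solver tolerance
    P /= P.sum(axis=1, keepdims=True)
    return P


def _merge_identical_ensembles(data: list[EnsembleData]) -> list[EnsembleData]:
    """Pool ensembles whose bias energies agree on every frame of the dataset.

    TRAM keeps one transition matrix per thermodynamic state; two ensembles
    with identical bias columns are the *same* thermodynamic state, and
    pooling their counts is required for data-pooling consistency (a zero-bias
    duplicate of the unbiased ensemble must not change the estimate).
    """
    n = len(data)
    same = np.ones((n, n), bool)
    for e in data:
        for b in e.bias_matrices:
            for i in range(n):
                same[i] &= np.all(np.isclose(b, b[:, [i]], atol=1e-12), axis=0)
    groups: list[list[int]] = []
    seen: set[int] = set()
    for i in range(n):
        if i in seen:
            continue
        g = [j for j in range(n) if same[i, j] and same[j, i]]
        seen |= set(g)
        groups.append(g)
    if len(groups) == n:
        return data
    keep = [g[0] for g in groups]
    out = []
    for g in groups:
        bias = None if any(data[j].bias is None for j in g) else data[g[0]].bias
        dtrajs = [t for j in g for t in data[j].dtrajs]
        mats = [b[:, keep] for j in g for b in data[j].bias_matrices]
        out.append(EnsembleData(bias=bias, dtrajs=dtrajs, bias_matrices=mats))
    return out


def _check_connectivity(C: np.ndarray) -> None:
    """All visited states must form one connected component across ensembles."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import connected_components

    A = (C.sum(axis=0) + C.sum(axis=0).T) > 0
    np.fill_diagonal(A, True)
    n, labels = connected_components(csr_matrix(A), directed=False)
    if n > 1:
        frags = [np.flatnonzero(labels == i).tolist() for i in range(n)]
        raise ValueError(f"state space disconnected across all ensembles: {frags}")


def tram_bootstrap(
    data: Sequence[EnsembleData],
    lag: int,
    n_boot: int = 10,
    seed: int = 0,
    tol: float = 1e-9,
    max_iter: int = 100_000,
) -> list[TRAMModel]:
    """Bootstrap TRAM by resampling the unbiased trajectories only.

    Biased ensembles are reused unchanged in every replicate; the unbiased
    ensemble's trajectories (with their bias matrices) are drawn with
    replacement.  Deterministic under a fixed seed.
    """
    data = list(data)
    k0 = [k for k, e in enumerate(data) if e.bias is None]
    if len(k0) != 1:
        raise ValueError("exactly one unbiased ensemble is required")
    k0 = k0[0]
    rng = np.random.default_rng(seed)
    models = []
    n_states = 1 + max(int(t.max()) for e in data for t in e.dtrajs)
    for _ in range(n_boot):
        idx = rng.integers(0, len(data[k0].dtrajs), len(data[k0].dtrajs))
        resampled = EnsembleData(
            bias=None,
            dtrajs=[data[k0].dtrajs[i] for i in idx],
            bias_matrices=[data[k0].bias_matrices[i] for i in idx],
        )
        boot = list(data)
        boot[k0] = resampled
        models.append(
            tram_estimate(boot, lag=lag, tol=tol, max_iter=max_iter, n_states=n_states)
        )
    return models
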