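"""End-to-end analysis driver: CV trajectories → kinetic components and rates.

Chains the pipeline stages with sensible defaults: protomer-swap duplication,
4D embedding, k-means microstates with a reserved far-field state, sliding
count matrix, reversible MLE (or TRAM when umbrella ensembles are supplied),
unbound-cluster detection, kinetically disconnected components, macrostate
assembly and component-level coarse-graining with entry/exit rates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import cluster as _cluster
from .cluster import (
    CGModel,
    ComponentDecomposition,
    Macrostate,
    assemble_macrostates,
    coarse_grain,
    disconnected_components,
    select_unbound,
)
from .geometry import embed_trajectory, swap_augment
from .msm import MSM, Discretization, count_transitions, kmeans_discretize, mle_reversible
from .rxndiff import ComponentRates, component_rates, estimate_r0
from .synthetic import CVTrajectory

__all__ = ["PipelineResult", "analyze_unbiased", "component_partition", "state_cv_table"]


@dataclass
class PipelineResult:
    """Everything the downstream analyses need, in one place.

    ``state_cvs`` rows are (d, α1, α2) per active microstate; the reserved
    far-field state carries its empirical mean distance and NaN angles.
    """

    discretization: Discretization
    dtrajs: list[np.ndarray]
    msm: MSM
    counts: np.ndarray
    state_cvs: np.ndarray
    n_clusters: int
    unbound_cluster: int
    clustering: "_cluster.PCCAClustering"
    decomposition: ComponentDecomposition
    macrostates: list[Macrostate]
    cg: CGModel
    rates: ComponentRates
    component_labels: list[str]
    lag: int
    dt: float

    def unbound_microstates(self) -> np.ndarray:
        return np.flatnonzero(self.clustering.labels == self.unbound_cluster)

    def r0(self) -> float:
        """Encounter distance from the unbound cluster (nm)."""
        return estimate_r0(
            self.msm.pi, self.state_cvs[:, 0], self.unbound_microstates()
        )

    def component_weight(self, label: str) -> float:
        k = self.decomposition.labels.index(label)
        return float(self.msm.pi[self.decomposition.microstates_of_component(k)].sum())


def state_cv_table(
    disc: Discretization, dtrajs: Sequence[np.ndarray], trajs: Sequence[CVTrajectory]
) -> np.ndarray:
    """Per-microstate (d, α1, α2): k-means centers plus the far-field state.

    The reserved state's distance is the empirical mean of its frames (NaN
    angles, it has no preferred orientation); falls back to L/2 if unvisited.
    """
    cvs = disc.center_cvs()
    d_far = []
    for dt_, tr in zip(dtrajs, trajs):
        m = np.asarray(dt_) == disc.unbound_index
        if m.any():
            d_far.append(np.asarray(tr.d)[m])
    dbar = float(np.concatenate(d_far).mean()) if d_far else disc.L / 2
    return np.vstack([cvs, [dbar, np.nan, np.nan]])


def component_partition(
    decomposition: ComponentDecomposition, n_states: int
) -> tuple[list[list[int]], list[str]]:
    """Partition microstates into [unbound+other, component_1, ...].

    The encounter/unbound group aggregates the unbound cluster, any "other"
    components and any microstate not assigned to a main component.
    """
    labels = []
    parts: list[list[int]] = []
    assigned = np.zeros(n_states, bool)
    for k, lbl in enumerate(decomposition.labels):
        mem = decomposition.microstates_of_component(k)
        if lbl == "other":
            continue
        parts.append(mem.tolist())
        labels.append(lbl)
        assigned[mem] = True
    rest = np.flatnonzero(~assigned).tolist()
    return [rest] + parts, labels


def analyze_unbiased(
    trajs: Sequence[CVTrajectory],
    box_side: float,
    n_centers: int = 120,
    lag: int = 4,
    rate_lag: int | None = None,
    seed: int = 0,
    fit_stride: int = 8,
    n_min_clusters: int = 2,
    d_threshold: float = 4.2,
    time_scale: float = 1.0,
) -> PipelineResult:
    """Run the unbiased pipeline from CV trajectories to component rates.

    Lags are in recorded frames.  ``lag`` is the *detection* lag: short, so
    that passages between components within one lag window are essentially
    impossible and the count-matrix support cleanly separates them.  Rates are
    read off a second model at ``rate_lag`` (default ``8 * lag``), long enough
    for the implied timescales to converge; the partition found at the
    detection lag is reused there.  ``time_scale`` is the coarse-grained-time
    factor applied to the final rates (1 for synthetic worlds, 4 for MARTINI
    data).  Trajectories are swap-duplicated before discretization, so all
    downstream statistics are exactly protomer-exchange symmetric.
    """
    if rate_lag is None:
        rate_lag = 8 * lag
    aug: list[CVTrajectory] = []
    for tr in trajs:
        a, b = swap_augment(tr)
        aug += [a, b]
    X = [embed_trajectory(t) for t in aug]
    disc, dtrajs = kmeans_discretize(X, n_centers, L=box_side, seed=seed,
                                     fit_stride=fit_stride)
    C = count_transitions(dtrajs, lag)
    msm = mle_reversible(C, lag=lag)
    full_cvs = state_cv_table(disc, dtrajs, aug)
    state_cvs = full_cvs[msm.active_set]
    n_clusters, unbound, clustering = select_unbound(
        msm.T, msm.pi, state_cvs, d_threshold=d_threshold, n_min=n_min_clusters
    )
    C_active = C[np.ix_(msm.active_set, msm.active_set)]
    decomposition = disconnected_components(
        C_active, clustering, unbound, msm.pi, state_cvs
    )
    macrostates = assemble_macrostates(decomposition, state_cvs, msm.pi)
    parts, labels = component_partition(decomposition, msm.n_states)
    dt = trajs[0].dt
    # kinetics at the longer, converged lag with the detection-lag partition
    C_rate = count_transitions(dtrajs, rate_lag)
    msm_rate = mle_reversible(C_rate, lag=rate_lag)
    orig_parts = [msm.active_set[p] for p in parts]
    pos = {s: i for i, s in enumerate(msm_rate.active_set)}
    rate_parts = [[pos[s] for s in p if s in pos] for p in orig_parts]
    rate_parts = [p for p in rate_parts if p]
    if len(rate_parts) != len(parts):
        raise RuntimeError("a component vanished from the rate-lag connected set")
    cg = coarse_grain(msm_rate.T, msm_rate.pi, rate_parts, lag=rate_lag, neg_tol=1e-3)
    rates = component_rates(
        cg.T_cg, lag_us=rate_lag * dt, labels=labels, time_scale=time_scale,
        method="matrix_log",
    )
    return PipelineResult(
        discretization=disc,
        dtrajs=dtrajs,
        msm=msm,
        counts=C,
        state_cvs=state_cvs,
        n_clusters=n_clusters,
        unbound_cluster=unbound,
        clustering=clustering,
        decomposition=decomposition,
        macrostates=macrostates,
        cg=cg,
        rates=rates,
        component_labels=labels,
        lag=lag,
        dt=dt,
    )
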