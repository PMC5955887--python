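"""Reaction-diffusion extrapolation of dimerization kinetics to arbitrary
2D receptor concentrations.

The kinetics are modelled as the two-step scheme

    A + B  ⇌(k+1·c, k−1)  A·B  ⇌(k_enter, k_exit)  AB_I   per component I,

where A·B is the *encounter complex* (identified with the unbound cluster of
the Markov model) and AB_I the bound states of kinetic component I.  The
diffusive association step uses the 2D dilute-limit rate

    k+1 = 4πD / ln(λ/r0),      λ = (πc)^{−1/2}  (mean free path),

with ``r0`` the encounter distance (stationary-weighted mean separation in the
unbound cluster).  The capture probability follows the
Northrup–Allison–McCammon construction

    γ = f_ass(r1) / (1 − f_esc(r1) · p_ass(r1)),
    p_ass = 1 − ln(λ/r1) / ln(λ/r0),

and the overall association rate is ``k_on = γ·k+1`` (partitioned per
component as γ_I ∝ k_enter,I).  Entry/exit rates come from the reduced
(component-level) transfer matrix; a conventional ×4 coarse-grained-time
factor is applied exactly once, when those rates are extracted.

Units: lengths nm, concentrations μm⁻², diffusion μm²/s, rates μs⁻¹.
Numerically 1 nm²/μs = 1 μm²/s, so a diffusion constant estimated from
nm/μs trajectories can be passed straight through.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.linalg import logm
from scipy.stats import linregress

from .synthetic import CVTrajectory

__all__ = [
    "RDParams",
    "ComponentRates",
    "RDResult",
    "convert_rate",
    "estimate_diffusion",
    "estimate_r0",
    "estimate_passage_fractions",
    "k_plus1",
    "capture_probability",
    "component_rates",
    "concentration_scan",
    "lifetimes",
]

_RATE_POW = {"per_s": 0, "per_ms": 3, "per_us": 6}


def convert_rate(value: float, from_unit: str, to_unit: str) -> float:
    """Convert first-order rates between s⁻¹/ms⁻¹/μs⁻¹ (exact powers of ten)."""
    return value * 10.0 ** (_RATE_POW[from_unit] - _RATE_POW[to_unit])


def estimate_diffusion(
    trajs: Sequence[CVTrajectory],
    d_window: tuple[float, float] = (8.0, 11.0),
    max_lag: int = 10,
) -> tuple[float, float]:
    """Relative 2D diffusion constant from the distance-variance growth.

    Fits ``Var[d(t+Δ) − d(t)]`` against lag Δ over frame pairs whose starting
    distance lies in ``d_window`` (nm; far from contact and from the box
    diagonal, where the radial coordinate diffuses like a 1D projection with
    variance ``2·D_rel·Δ``).  Returns ``(D_rel, stderr)`` in nm²/μs
    (numerically equal to μm²/s).
    """
    lags = np.arange(1, max_lag + 1)
    var = np.full(len(lags), np.nan)
    for li, lag in enumerate(lags):
        deltas = []
        for tr in trajs:
            d = np.asarray(tr.d)
            if len(d) <= lag:
                continue
            m = (d[:-lag] >= d_window[0]) & (d[:-lag] <= d_window[1])
            if m.any():
                deltas.append((d[lag:] - d[:-lag])[m])
        if deltas:
            var[li] = np.var(np.concatenate(deltas))
    ok = np.isfinite(var)
    if ok.sum() < 2:
        raise ValueError("too few frames in the distance window to fit diffusion")
    dt = trajs[0].dt
    fit = linregress(lags[ok] * dt, var[ok])
    D = fit.slope / 2.0
    return float(D), float(fit.stderr / 2.0 if fit.stderr is not None else np.nan)


def estimate_r0(
    pi: np.ndarray, d_centers: np.ndarray, unbound_states: Sequence[int]
) -> float:
    """Encounter distance: π-weighted mean separation over the unbound cluster."""
    idx = np.asarray(list(unbound_states), int)
    if len(idx) == 0:
        raise ValueError("empty unbound cluster")
    w = np.asarray(pi, float)[idx]
    return float(np.sum(w * np.asarray(d_centers, float)[idx]) / w.sum())


def estimate_passage_fractions(
    trajs: Sequence[CVTrajectory],
    r0: float,
    r1: float,
    is_associated,
) -> tuple[float, float]:
    """Measure f_ass and f_esc from unbiased trajectories.

    Each excursion starting when ``d`` crosses ``r0`` is followed until it
    either enters an associated state (``is_associated(d, a1, a2)`` true)
    — counted toward ``f_ass`` — or reaches the escape distance ``r1``
    — counted toward ``f_esc``.  Unresolved excursions at trajectory end are
    discarded.
    """
    if not r1 > r0 > 0:
        raise ValueError("need r1 > r0 > 0")
    n_ass = n_esc = 0
    for tr in trajs:
        d = np.asarray(tr.d)
        assoc = np.asarray(is_associated(tr.d, tr.alpha1, tr.alpha2), bool)
        active = False
        for k in range(1, len(d)):
            if not active:
                if (d[k - 1] - r0) * (d[k] - r0) <= 0 and not assoc[k]:
                    active = True
            else:
                if assoc[k]:
                    n_ass += 1
                    active = False
                elif d[k] >= r1:
                    n_esc += 1
                    active = False
    total = n_ass + n_esc
    if total == 0:
        raise ValueError("no resolved excursions from r0")
    return n_ass / total, n_esc / total


def k_plus1(c: float, D: float, r0: float) -> float:
    """2D diffusive association rate 4πD/ln(λ/r0) in μm²/μs.

    ``c`` in μm⁻², ``D`` in μm²/s, ``r0`` in nm.  Multiplying by ``c`` gives a
    first-order rate in μs⁻¹.  Raises when the mean free path λ = (πc)^(−1/2)
    does not exceed r0 (the dilute formula breaks down).
    """
    lam_um = (np.pi * c) ** -0.5
    r0_um = r0 * 1e-3
    if lam_um <= r0_um:
        raise ValueError(
            f"mean free path {lam_um * 1e3:.2f} nm <= r0 = {r0:.2f} nm: "
            "concentration too high for the dilute 2D rate"
        )
    return 4 * np.pi * D / np.log(lam_um / r0_um) * 1e-6  # μm²/s → μm²/μs


def capture_probability(
    f_ass: float, f_esc: float, lam: float, r0: float, r1: float
) -> float:
    """Northrup–Allison–McCammon capture probability γ.

    ``lam`` (mean free path), ``r0`` and ``r1`` all in nm with λ > r1 > r0.
    ``p_ass = 1 − ln(λ/r1)/ln(λ/r0)`` is the probability that an excursion
    reaching r1 returns to r0 rather than escaping to λ.
    """
    if not (lam > r1 > r0 > 0):
        raise ValueError("need lam > r1 > r0 > 0")
    if not (0 <= f_ass <= 1 and 0 <= f_esc <= 1):
        raise ValueError("fractions must lie in [0, 1]")
    p_ass = 1.0 - np.log(lam / r1) / np.log(lam / r0)
    denom = 1.0 - f_esc * p_ass
    if denom <= 0:
        raise ValueError("inconsistent fractions: denominator of γ is non-positive")
    gamma = f_ass / denom
    return float(min(gamma, 1.0))


@dataclass
class ComponentRates:
    """Entry/exit rates per kinetic component from the reduced transfer matrix.

    Rates are in μs⁻¹ of effective (already time-scaled) time; ``labels``
    orders the components.  ``k_enter[i]`` is encounter→component ``i``,
    ``k_exit[i]`` the reverse.
    """

    labels: list[str]
    k_enter: np.ndarray
    k_exit: np.ndarray
    lag_us: float
    time_scale: float

    @property
    def k_enter_total(self) -> float:
        return float(self.k_enter.sum())


def component_rates(
    T_cg: np.ndarray,
    lag_us: float,
    labels: Sequence[str],
    time_scale: float = 4.0,
    encounter_index: int = 0,
    method: str = "prob_over_lag",
) -> ComponentRates:
    """Extract per-component entry/exit rates from the reduced transfer matrix.

    ``T_cg`` is the component-level matrix with the encounter (unbound) state
    at ``encounter_index`` and one state per component, at lag ``lag_us``
    (simulation μs).  The default converts transition probabilities to rates
    as ``p/lag`` (valid for small p); ``method="matrix_log"`` uses the exact
    generator ``log(T)/lag`` and falls back to ``p/lag`` with a warning if the
    generator has negative off-diagonal entries.  The coarse-grained time
    factor (default ×4) divides the rates — it is applied here, exactly once.
    """
    T_cg = np.asarray(T_cg, float)
    m = T_cg.shape[0]
    comp_idx = [i for i in range(m) if i != encounter_index]
    if len(labels) != len(comp_idx):
        raise ValueError("need one label per non-encounter state")
    if method == "matrix_log":
        K = logm(T_cg).real / lag_us
        off = K - np.diag(np.diag(K))
        if off.min() < -1e-10:
            warnings.warn(
                "matrix logarithm yields negative rates; falling back to p/lag"
            )
            K = T_cg / lag_us
    elif method == "prob_over_lag":
        K = T_cg / lag_us
    else:
        raise ValueError(f"unknown method {method!r}")
    k_enter = np.array([K[encounter_index, i] for i in comp_idx]) / time_scale
    k_exit = np.array([K[i, encounter_index] for i in comp_idx]) / time_scale
    if np.any(k_enter < 0) or np.any(k_exit < 0):
        raise ValueError("negative rates extracted from the reduced matrix")
    return ComponentRates(
        labels=list(labels), k_enter=k_enter, k_exit=k_exit,
        lag_us=lag_us, time_scale=time_scale,
    )


@dataclass
class RDParams:
    """Parameters of the reaction-diffusion concentration scan.

    ``D`` μm²/s (default 0.1, a physiologically relevant membrane-protein
    value), ``r0``/``r1`` nm (escape distance default 7 nm), ``f_ass``/``f_esc``
    passage fractions at r1, ``c_grid`` 2D concentrations in μm⁻².
    """

    D: float = 0.1
    r0: float = 6.2
    r1: float = 7.0
    f_ass: float = 0.5
    f_esc: float = 0.5
    c_grid: np.ndarray = field(default_factory=lambda: np.logspace(-1, 5, 61))

    def __post_init__(self) -> None:
        self.c_grid = np.asarray(self.c_grid, float)
        if not (self.r1 > self.r0 > 0):
            raise ValueError("need r1 > r0 > 0")
        if self.D <= 0:
            raise ValueError("D must be positive")
        if not (0 <= self.f_ass <= 1 and 0 <= self.f_esc <= 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class RDResult:
    """Tidy per-(concentration, component) table plus totals."""

    table: pd.DataFrame
    labels: list[str]

    def total_bound_fraction(self) -> pd.Series:
        return self.table.groupby("c")["fraction"].sum()


def concentration_scan(rates: ComponentRates, params: RDParams) -> RDResult:
    """Scan concentrations: k_on per component and equilibrium dimer fractions.

    For each concentration ``c``: the diffusive rate ``k+1(c)``, the capture
    probability γ from the NAM formula, the dissociation rate of the encounter
    complex ``k−1 = (1−γ)/γ · Σ k_enter`` (from the definition of γ), the
    per-component ``k_on,I = γ_I k+1`` with ``γ_I ∝ k_enter,I``, and the
    steady state of the full linear scheme
    unbound ⇌ encounter ⇌ component I.  Grid points with λ ≤ r1 are flagged
    invalid.  ``k_on`` is second-order (μm²/μs); ``k_on_first_order = k_on·c``
    (μs⁻¹).
    """
    rows = []
    ke_sum = rates.k_enter_total
    for c in params.c_grid:
        lam_nm = (np.pi * c) ** -0.5 * 1e3
        if lam_nm <= params.r1:
            for lab in rates.labels:
                rows.append({"c": c, "component": lab, "valid": False,
                             "k_plus1": np.nan, "gamma": np.nan, "k_on": np.nan,
                             "k_on_first_order": np.nan, "k_on_eff": np.nan,
                             "k_off": np.nan, "fraction": np.nan})
            continue
        kp1 = k_plus1(c, params.D, params.r0)
        gamma = capture_probability(params.f_ass, params.f_esc, lam_nm,
                                    params.r0, params.r1)
        if gamma > 0 and ke_sum > 0:
            k_minus1 = (1.0 - gamma) / gamma * ke_sum
        else:
            k_minus1 = np.inf
        # steady state of the reversible linear network via detailed balance
        w_unbound = 1.0
        w_enc = (kp1 * c / k_minus1) if np.isfinite(k_minus1) and k_minus1 > 0 else 0.0
        w_comp = np.zeros(len(rates.labels))
        for i in range(len(rates.labels)):
            w_comp[i] = (
                w_enc * rates.k_enter[i] / rates.k_exit[i]
                if rates.k_exit[i] > 0
                else 0.0
            )
        z = w_unbound + w_enc + w_comp.sum()
        denom = k_minus1 + ke_sum
        for i, lab in enumerate(rates.labels):
            gamma_i = rates.k_enter[i] / denom if np.isfinite(denom) else 0.0
            k_diff = gamma_i * kp1 * c  # first-order diffusive supply, μs⁻¹
            if k_diff > 0 and rates.k_enter[i] > 0:
                # series composition: diffusion-limited at low c, saturating at
                # the reaction-limited entry rate at high c
                k_eff = 1.0 / (1.0 / k_diff + 1.0 / rates.k_enter[i])
            else:
                k_eff = 0.0
            rows.append({
                "c": c,
                "component": lab,
                "valid": True,
                "k_plus1": kp1,
                "gamma": gamma,
                "k_on": gamma_i * kp1,
                "k_on_first_order": k_diff,
                "k_on_eff": k_eff,
                "k_off": rates.k_exit[i],
                "fraction": w_comp[i] / z,
            })
    return RDResult(table=pd.DataFrame(rows), labels=list(rates.labels))


def lifetimes(rates: ComponentRates) -> pd.DataFrame:
    """Per-component dimer lifetimes T_off = 1/k_exit (μs, time scale included).

    The ×time_scale factor is already inside ``k_exit``; it is not applied
    again here.  Components with zero exit rate get an infinite lifetime.
    """
    T_off = np.where(rates.k_exit > 0, 1.0 / np.where(rates.k_exit > 0, rates.k_exit, 1.0), np.inf)
    if np.any(rates.k_exit == 0):
        warnings.warn("some components have zero exit rate: infinite lifetime")
    return pd.DataFrame({
        "component": rates.labels,
        "k_off_per_us": rates.k_exit,
        "T_off_us": T_off,
    })
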