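"""Synthetic ground-truth systems for the dimerization-kinetics pipeline.

Two kinds of truth are generated:

* **Continuous worlds** (:class:`SyntheticWorld`): two orientable point
  protomers diffusing in a periodic membrane plane, with orientation-dependent
  bound basins expressed directly on the collective variables
  ``(d, alpha1, alpha2)`` — the inter-protomer centre-of-mass distance and the
  two unsigned orientation angles.  Dynamics are overdamped Langevin
  (Euler–Maruyama) on the underlying positions/orientations, so the
  non-Euclidean CV space is never integrated directly.  Umbrella-restrained
  counterparts carry their harmonic bias energy per frame.

* **Discrete truths** (:class:`DiscreteTruth`): reversible row-stochastic
  transition matrices with a planted metastable block structure and known
  per-ensemble bias energies, the unit-test substrate for the MSM, TRAM and
  PCCA+ estimators.

Reduced units are used throughout: lengths in nm, times in μs, energies in
units of kT (``temperature_kT = 1``).  Physical-unit conversions live in
:mod:`dimerkin.rxndiff` and :func:`dimerkin.tram.evaluate_bias_energies`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numba import njit

__all__ = [
    "Well",
    "SyntheticWorld",
    "StericWall",
    "BiasSpec",
    "CVTrajectory",
    "DiscreteTruth",
    "simulate_unbiased",
    "simulate_umbrella",
    "generate_discrete_truth",
    "sample_chain",
    "equilibrium_grid",
    "region_probability",
    "ideal_pair_distance_pdf",
]


@dataclass(frozen=True)
class Well:
    """Gaussian attractive basin on the (d, alpha1, alpha2) landscape.

    ``depth`` is in kT; ``width_d`` (nm) and ``width_alpha`` (rad) are the
    Gaussian standard deviations along the distance and angle axes.
    """

    alpha1_center: float
    alpha2_center: float
    d_center: float
    depth: float
    width_d: float
    width_alpha: float

    def __post_init__(self) -> None:
        if self.depth < 0:
            raise ValueError("well depth must be >= 0 (depth is the basin depth in kT)")
        if self.width_d <= 0 or self.width_alpha <= 0:
            raise ValueError("well widths must be positive")
        if not (0 <= self.alpha1_center <= np.pi and 0 <= self.alpha2_center <= np.pi):
            raise ValueError("angle centers must lie in [0, pi]")


@dataclass(frozen=True)
class StericWall:
    """Orientation-dependent excluded-volume wall.

    Two receptors can only approach closely when their orientations are
    complementary; elsewhere their shapes clash.  The wall is a half-harmonic
    repulsion ``U = ½ k_wall (d − d_wall(α1, α2))²`` for ``d < d_wall``, where
    the contact distance relaxes from ``d_far`` down to ``d_close`` inside a
    Gaussian opening (width ``width_alpha``) around each well's orientation.
    This is what makes bound basins kinetically disconnected: interconverting
    orientations while in contact is sterically forbidden, so the passage goes
    through large separations (the unbound state).
    """

    k_wall: float = 50.0
    d_far: float = 4.6
    d_close: float = 2.5
    width_alpha: float = 0.6

    def __post_init__(self) -> None:
        if not (self.d_far > self.d_close > 0):
            raise ValueError("need d_far > d_close > 0")
        if self.k_wall < 0 or self.width_alpha <= 0:
            raise ValueError("k_wall must be >= 0 and width_alpha positive")


@dataclass(frozen=True)
class SyntheticWorld:
    """Stated world for the two-protomer synthetic membrane system.

    Parameters
    ----------
    box_side:
        Side of the periodic square membrane patch (nm).  Default 15 nm,
        matching a typical coarse-grained two-receptor box.
    diffusion_translation:
        Translational diffusion constant per protomer (nm²/μs).  Default 5,
        i.e. a relative diffusion of 10 nm²/μs = 10 μm²/s, the order of
        magnitude observed for lipid-embedded receptors in coarse-grained
        membranes.
    diffusion_rotation:
        Rotational diffusion constant (rad²/μs).
    wells:
        Bound basins; an empty tuple gives free diffusion.
    wall:
        Optional orientation-dependent excluded-volume wall (its openings
        follow the wells' orientations).  ``None`` means point protomers.
    temperature_kT:
        Energy unit; 1 in reduced units.
    seed:
        Base seed; trajectory ``i`` uses ``seed + i``.
    """

    box_side: float = 15.0
    diffusion_translation: float = 5.0
    diffusion_rotation: float = 5.0
    wells: tuple[Well, ...] = ()
    wall: StericWall | None = None
    temperature_kT: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "wells", tuple(self.wells))
        if self.box_side <= 0:
            raise ValueError("box_side must be positive")
        if self.diffusion_translation <= 0 or self.diffusion_rotation <= 0:
            raise ValueError("diffusion constants must be positive")
        if self.wells:
            dmax = max(w.d_center for w in self.wells)
            if self.box_side <= 2 * dmax:
                raise ValueError("box_side must exceed 2 * max(d_center)")

    # --- potential -------------------------------------------------------
    def _well_arrays(self) -> tuple[np.ndarray, ...]:
        nw = len(self.wells)
        a10 = np.array([w.alpha1_center for w in self.wells], float)
        a20 = np.array([w.alpha2_center for w in self.wells], float)
        d0 = np.array([w.d_center for w in self.wells], float)
        dep = np.array([w.depth for w in self.wells], float)
        wd = np.array([w.width_d for w in self.wells], float)
        wa = np.array([w.width_alpha for w in self.wells], float)
        if nw == 0:
            return (np.zeros(0),) * 6
        return a10, a20, d0, dep, wd, wa

    def potential(self, d, alpha1, alpha2):
        """Potential U(d, α1, α2) in kT: wells plus steric wall (broadcasting)."""
        d = np.asarray(d, float)
        alpha1 = np.asarray(alpha1, float)
        alpha2 = np.asarray(alpha2, float)
        u = np.zeros(np.broadcast(d, alpha1, alpha2).shape)
        for w in self.wells:
            u -= w.depth * np.exp(
                -((d - w.d_center) ** 2) / (2 * w.width_d**2)
                - ((alpha1 - w.alpha1_center) ** 2 + (alpha2 - w.alpha2_center) ** 2)
                / (2 * w.width_alpha**2)
            )
        if self.wall is not None:
            g = np.zeros_like(u)
            for w in self.wells:
                g += np.exp(
                    -((alpha1 - w.alpha1_center) ** 2 + (alpha2 - w.alpha2_center) ** 2)
                    / (2 * self.wall.width_alpha**2)
                )
            g = np.clip(g, 0.0, 1.0)
            dw = self.wall.d_far - (self.wall.d_far - self.wall.d_close) * g
            u += 0.5 * self.wall.k_wall * np.clip(dw - d, 0.0, None) ** 2
        return u


@dataclass(frozen=True)
class BiasSpec:
    """Harmonic umbrella restraint on the order parameter.

    ``center`` is ``(d0, alpha1_0, alpha2_0)``; the bias energy of a frame is
    ``0.5*k_d*(d-d0)**2 + 0.5*k_alpha*((a1-a10)**2 + (a2-a20)**2)``.
    Constants are in energy units per nm² / per rad² (kT-reduced for the
    synthetic world).
    """

    center: tuple[float, float, float]
    k_d: float
    k_alpha: float

    def __post_init__(self) -> None:
        if self.k_d < 0 or self.k_alpha < 0:
            raise ValueError("restraint constants must be >= 0")
        d0, a10, a20 = self.center
        if d0 < 0 or not (0 <= a10 <= np.pi and 0 <= a20 <= np.pi):
            raise ValueError("bias center must have d >= 0 and angles in [0, pi]")

    def energy(self, d, alpha1, alpha2):
        d0, a10, a20 = self.center
        d = np.asarray(d, float)
        return 0.5 * self.k_d * (d - d0) ** 2 + 0.5 * self.k_alpha * (
            (np.asarray(alpha1, float) - a10) ** 2 + (np.asarray(alpha2, float) - a20) ** 2
        )


@dataclass
class CVTrajectory:
    """Per-frame order parameter of a protomer pair, tagged by ensemble.

    ``bias`` is ``None`` for the unbiased ensemble; ``bias_energy`` then holds
    zeros.  ``dt`` is the spacing between *recorded* frames (μs).
    """

    t: np.ndarray
    d: np.ndarray
    alpha1: np.ndarray
    alpha2: np.ndarray
    dt: float
    bias: BiasSpec | None = None
    bias_energy: np.ndarray | None = None

    def __post_init__(self) -> None:
        n = len(self.d)
        if not (len(self.t) == len(self.alpha1) == len(self.alpha2) == n):
            raise ValueError("CV arrays must have equal length")
        if self.bias is not None and self.bias_energy is None:
            self.bias_energy = np.asarray(
                self.bias.energy(self.d, self.alpha1, self.alpha2), float
            )
        if self.bias is None and self.bias_energy is None:
            self.bias_energy = np.zeros(n)

    def __len__(self) -> int:
        return len(self.d)

    def cv_array(self) -> np.ndarray:
        """(n, 3) array of (d, alpha1, alpha2)."""
        return np.column_stack([self.d, self.alpha1, self.alpha2])

    def to_table(self) -> "np.ndarray":
        """Columnar (time, d, alpha1, alpha2, bias_energy) array for export."""
        return np.column_stack([self.t, self.d, self.alpha1, self.alpha2, self.bias_energy])


# ----------------------------------------------------------------------------
# Brownian-dynamics integrator
# ----------------------------------------------------------------------------

@njit(cache=True)
def _bd_run(state, n_steps, stride, dt, Dt, Dr, L,
            a10, a20, d0, dep, wd, wa,
            wall_k, wall_far, wall_close, wall_sig,
            kd, kal, bd0, ba1, ba2, noise, out):  # pragma: no cover - jitted
    """Euler–Maruyama loop; ``state`` = (x1, y1, th1, x2, y2, th2) mutated in place.

    ``noise`` is (n_steps, 6) standard normals drawn outside (determinism is
    owned by the caller's Generator).  ``out`` is (n_records, 3) for
    (d, alpha1, alpha2) recorded every ``stride`` steps (after the step).
    """
    x1, y1, th1, x2, y2, th2 = state
    sx = np.sqrt(2.0 * Dt * dt)
    sr = np.sqrt(2.0 * Dr * dt)
    nw = d0.shape[0]
    rec = 0
    for step in range(n_steps):
        rx = x2 - x1
        ry = y2 - y1
        rx -= L * np.round(rx / L)
        ry -= L * np.round(ry / L)
        dist = np.sqrt(rx * rx + ry * ry)
        if dist < 1e-9:
            dist = 1e-9
        rhx = rx / dist
        rhy = ry / dist
        u1x = np.cos(th1)
        u1y = np.sin(th1)
        u2x = np.cos(th2)
        u2y = np.sin(th2)
        c1 = u1x * rhx + u1y * rhy
        c2 = -(u2x * rhx + u2y * rhy)
        if c1 > 1.0:
            c1 = 1.0
        elif c1 < -1.0:
            c1 = -1.0
        if c2 > 1.0:
            c2 = 1.0
        elif c2 < -1.0:
            c2 = -1.0
        a1 = np.arccos(c1)
        a2 = np.arccos(c2)

        # dU/d(d, a1, a2): Gaussian wells + harmonic bias
        dUdd = 0.0
        dUda1 = 0.0
        dUda2 = 0.0
        for w in range(nw):
            e = dep[w] * np.exp(
                -((dist - d0[w]) ** 2) / (2.0 * wd[w] * wd[w])
                - ((a1 - a10[w]) ** 2 + (a2 - a20[w]) ** 2) / (2.0 * wa[w] * wa[w])
            )
            dUdd += e * (dist - d0[w]) / (wd[w] * wd[w])
            dUda1 += e * (a1 - a10[w]) / (wa[w] * wa[w])
            dUda2 += e * (a2 - a20[w]) / (wa[w] * wa[w])
        if wall_k > 0.0:
            # orientation-gated excluded volume: contact distance shrinks
            # from wall_far to wall_close inside the wells' angular openings
            g = 0.0
            dg1 = 0.0
            dg2 = 0.0
            for w in range(nw):
                ew = np.exp(
                    -((a1 - a10[w]) ** 2 + (a2 - a20[w]) ** 2)
                    / (2.0 * wall_sig * wall_sig)
                )
                g += ew
                dg1 += ew * (-(a1 - a10[w]) / (wall_sig * wall_sig))
                dg2 += ew * (-(a2 - a20[w]) / (wall_sig * wall_sig))
            if g > 1.0:
                g = 1.0
                dg1 = 0.0
                dg2 = 0.0
            dwall = wall_far - (wall_far - wall_close) * g
            if dist < dwall:
                gap = dist - dwall
                dUdd += wall_k * gap
                coef = wall_k * gap * (wall_far - wall_close)
                dUda1 += coef * dg1
                dUda2 += coef * dg2
        dUdd += kd * (dist - bd0)
        dUda1 += kal * (a1 - ba1)
        dUda2 += kal * (a2 - ba2)

        # chain rule to forces on (x1, y1, th1, x2, y2, th2)
        fx1 = dUdd * rhx
        fy1 = dUdd * rhy
        fx2 = -dUdd * rhx
        fy2 = -dUdd * rhy
        fth1 = 0.0
        fth2 = 0.0
        s1 = np.sqrt(1.0 - c1 * c1)
        if s1 > 1e-8:
            ga1x = (u1x - c1 * rhx) / (dist * s1)  # d a1 / d x1 (via dr/dx1 = -1)
            ga1y = (u1y - c1 * rhy) / (dist * s1)
            fx1 -= dUda1 * ga1x
            fy1 -= dUda1 * ga1y
            fx2 += dUda1 * ga1x
            fy2 += dUda1 * ga1y
            dc1dth1 = -u1y * rhx + u1x * rhy
            fth1 = dUda1 * dc1dth1 / s1
        s2 = np.sqrt(1.0 - c2 * c2)
        if s2 > 1e-8:
            ga2x = (u2x + c2 * rhx) / (dist * s2)  # d a2 / d x2
            ga2y = (u2y + c2 * rhy) / (dist * s2)
            fx1 += dUda2 * ga2x
            fy1 += dUda2 * ga2y
            fx2 -= dUda2 * ga2x
            fy2 -= dUda2 * ga2y
            dc2dth2 = u2y * rhx - u2x * rhy
            fth2 = dUda2 * dc2dth2 / s2

        x1 += Dt * fx1 * dt + sx * noise[step, 0]
        y1 += Dt * fy1 * dt + sx * noise[step, 1]
        th1 += Dr * fth1 * dt + sr * noise[step, 2]
        x2 += Dt * fx2 * dt + sx * noise[step, 3]
        y2 += Dt * fy2 * dt + sx * noise[step, 4]
        th2 += Dr * fth2 * dt + sr * noise[step, 5]
        x1 -= L * np.floor(x1 / L)
        y1 -= L * np.floor(y1 / L)
        x2 -= L * np.floor(x2 / L)
        y2 -= L * np.floor(y2 / L)

        if (step + 1) % stride == 0:
            rx = x2 - x1
            ry = y2 - y1
            rx -= L * np.round(rx / L)
            ry -= L * np.round(ry / L)
            dist = np.sqrt(rx * rx + ry * ry)
            if dist < 1e-9:
                dist = 1e-9
            rhx = rx / dist
            rhy = ry / dist
            c1 = np.cos(th1) * rhx + np.sin(th1) * rhy
            c2 = -(np.cos(th2) * rhx + np.sin(th2) * rhy)
            c1 = min(1.0, max(-1.0, c1))
            c2 = min(1.0, max(-1.0, c2))
            out[rec, 0] = dist
            out[rec, 1] = np.arccos(c1)
            out[rec, 2] = np.arccos(c2)
            rec += 1
    state[0] = x1
    state[1] = y1
    state[2] = th1
    state[3] = x2
    state[4] = y2
    state[5] = th2


def _run_single(
    world: SyntheticWorld,
    bias: BiasSpec | None,
    n_steps: int,
    dt: float,
    stride: int,
    rng: np.random.Generator,
    start: np.ndarray | None,
) -> CVTrajectory:
    if dt <= 0:
        raise ValueError("dt must be positive")
    widths = [w.width_d for w in world.wells] + [w.width_alpha for w in world.wells]
    step_len = np.sqrt(2 * world.diffusion_translation * dt)
    if widths and step_len > 0.5 * min(widths):
        raise ValueError(
            f"dt too large: per-step displacement {step_len:.3g} nm is not small "
            f"compared to the narrowest well width {min(widths):.3g}"
        )
    if world.wall is not None and world.diffusion_translation * world.wall.k_wall * dt > 0.5:
        raise ValueError("dt too large for stable integration against the steric wall")
    a10, a20, d0, dep, wd, wa = world._well_arrays()
    if not (np.all(np.isfinite(dep)) and np.all(wd > 0) and np.all(wa > 0)):
        raise ValueError("degenerate well parameters produce non-finite forces")
    L = world.box_side
    if start is None:
        state = np.empty(6)
        state[0], state[1] = rng.uniform(0, L, 2)
        state[3], state[4] = rng.uniform(0, L, 2)
        state[2], state[5] = rng.uniform(0, 2 * np.pi, 2)
    else:
        state = np.asarray(start, float).copy()
    if bias is None:
        kd = kal = 0.0
        bd0 = ba1 = ba2 = 0.0
    else:
        bd0, ba1, ba2 = bias.center
        if bd0 >= L / np.sqrt(2.0):
            raise ValueError("bias center distance lies outside the periodic box")
        kd, kal = bias.k_d, bias.k_alpha
    n_rec = n_steps // stride
    out = np.empty((n_rec, 3))
    # chunk the noise to bound memory for long runs
    chunk = 200_000
    done = 0
    rec_off = 0
    while done < n_steps:
        m = min(chunk, n_steps - done)
        # align chunks on stride boundaries so the record index stays simple
        m -= m % stride
        if m == 0:
            m = n_steps - done
        noise = rng.standard_normal((m, 6))
        n_rec_chunk = m // stride
        if world.wall is None:
            wk, wfar, wclose, wsig = 0.0, 0.0, 0.0, 1.0
        else:
            wk = world.wall.k_wall
            wfar = world.wall.d_far
            wclose = world.wall.d_close
            wsig = world.wall.width_alpha
        _bd_run(
            state, m, stride, dt,
            world.diffusion_translation, world.diffusion_rotation, L,
            a10, a20, d0, dep, wd, wa,
            wk, wfar, wclose, wsig,
            kd, kal, bd0, ba1, ba2,
            noise, out[rec_off : rec_off + n_rec_chunk],
        )
        rec_off += n_rec_chunk
        done += m
    t = (np.arange(1, n_rec + 1)) * (stride * dt)
    traj = CVTrajectory(
        t=t, d=out[:, 0], alpha1=out[:, 1], alpha2=out[:, 2], dt=stride * dt, bias=bias
    )
    return traj


def simulate_unbiased(
    world: SyntheticWorld,
    n_traj: int,
    n_steps: int,
    dt: float,
    stride: int = 1,
    start: np.ndarray | None = None,
) -> list[CVTrajectory]:
    """Run ``n_traj`` independent overdamped-Langevin trajectories.

    Trajectory ``i`` uses seed ``world.seed + i``, so runs are reproducible
    and individually re-generable.  ``stride`` subsamples the recorded frames
    (the recorded frame spacing is ``stride * dt``).
    """
    if n_traj < 1 or n_steps < 1:
        raise ValueError("n_traj and n_steps must be >= 1")
    out = []
    for i in range(n_traj):
        rng = np.random.default_rng(world.seed + i)
        out.append(_run_single(world, None, n_steps, dt, stride, rng, start))
    return out


def simulate_umbrella(
    world: SyntheticWorld,
    bias: BiasSpec,
    n_steps: int,
    dt: float,
    stride: int = 1,
    seed_offset: int = 0,
) -> CVTrajectory:
    """Run one umbrella-restrained trajectory started at the bias center.

    The initial configuration realizes the bias center exactly: protomers
    placed ``d0`` apart along x in the box center with orientations rotated to
    the target angles.  Frames carry their bias energy ``U_b`` recomputed from
    the recorded CVs.
    """
    rng = np.random.default_rng(world.seed + 100_000 + seed_offset)
    d0c, a10c, a20c = bias.center
    L = world.box_side
    start = np.array([
        (L - d0c) / 2.0, L / 2.0, a10c,           # protomer 1: angle vs +x
        (L + d0c) / 2.0, L / 2.0, np.pi - a20c,   # protomer 2: angle vs -x
    ])
    return _run_single(world, bias, n_steps, dt, stride, rng, start)


# ----------------------------------------------------------------------------
# Equilibrium oracle (numerical Boltzmann integration)
# ----------------------------------------------------------------------------

def ideal_pair_distance_pdf(d: np.ndarray, L: float) -> np.ndarray:
    """Pair-distance density for two uniform points on an L×L torus.

    The displacement is uniform on the square [-L/2, L/2)²; for d ≤ L/2 the
    density is 2πd/L², and for L/2 < d ≤ L/√2 the circle of radius d is
    clipped by the square.
    """
    d = np.asarray(d, float)
    p = np.zeros_like(d)
    inside = d <= L / 2
    p[inside] = 2 * np.pi * d[inside] / L**2
    corner = (d > L / 2) & (d <= L / np.sqrt(2))
    dc = d[corner]
    p[corner] = 2 * dc * (np.pi - 4 * np.arccos(L / (2 * dc))) / L**2
    return p


def equilibrium_grid(
    world: SyntheticWorld,
    bias: BiasSpec | None = None,
    n_d: int = 200,
    n_alpha: int = 60,
    d_max: float | None = None,
):
    """Normalized Boltzmann probability on a (d, α1, α2) grid.

    The configuration-space measure reduces to ``p ∝ d · exp(-U/kT)`` on
    ``0 < d ≤ L/2``, ``α ∈ [0, π]`` (the angle multiplicities are
    d-independent constants).  For ``d > L/2`` the exact torus pair-distance
    Jacobian is used, so the free-diffusion marginal matches the ideal-gas
    pair-distance law out to the box diagonal.

    Returns ``(d_centers, alpha_centers, P)`` with ``P[i, j, k]`` the
    probability of the cell at ``(d_i, α1_j, α2_k)`` summing to 1.
    """
    L = world.box_side
    if d_max is None:
        d_max = L / np.sqrt(2.0)
    d_edges = np.linspace(0, d_max, n_d + 1)
    a_edges = np.linspace(0, np.pi, n_alpha + 1)
    dc = 0.5 * (d_edges[1:] + d_edges[:-1])
    ac = 0.5 * (a_edges[1:] + a_edges[:-1])
    dd = np.diff(d_edges)
    da = np.diff(a_edges)
    U = world.potential(dc[:, None, None], ac[None, :, None], ac[None, None, :])
    if bias is not None:
        U = U + bias.energy(dc[:, None, None], ac[None, :, None], ac[None, None, :])
    jac = ideal_pair_distance_pdf(dc, L)
    P = jac[:, None, None] * np.exp(-U / world.temperature_kT)
    P *= dd[:, None, None] * da[None, :, None] * da[None, None, :]
    P /= P.sum()
    return dc, ac, P


def region_probability(
    world: SyntheticWorld,
    region: Callable[[np.ndarray, np.ndarray, np.ndarray], np.ndarray],
    bias: BiasSpec | None = None,
    n_d: int = 300,
    n_alpha: int = 80,
) -> float:
    """Equilibrium probability of ``region(d, a1, a2) -> bool`` by grid integration."""
    dc, ac, P = equilibrium_grid(world, bias=bias, n_d=n_d, n_alpha=n_alpha)
    D, A1, A2 = np.meshgrid(dc, ac, ac, indexing="ij")
    mask = region(D, A1, A2)
    return float(P[mask].sum())


# ----------------------------------------------------------------------------
# Discrete Markov-chain truths
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteTruth:
    """Reversible chain with planted metastable blocks and known bias energies.

    ``T_true`` is row-stochastic and in detailed balance with ``pi_true``;
    ``bias_energies[k, i]`` is the reduced bias of state ``i`` in ensemble
    ``k`` (row 0 is the unbiased ensemble, identically zero).
    ``blocks[i]`` is the planted metastable block label of state ``i``.
    """

    n_states: int
    T_true: np.ndarray
    pi_true: np.ndarray
    bias_energies: np.ndarray
    blocks: np.ndarray

    @property
    def n_ensembles(self) -> int:
        return self.bias_energies.shape[0]

    def biased_transition_matrix(self, ensemble: int) -> np.ndarray:
        """Metropolis-reweighted chain, reversible w.r.t. ``pi_i exp(-b_i)``."""
        b = self.bias_energies[ensemble]
        T = self.T_true * np.minimum(1.0, np.exp(b[:, None] - b[None, :]))
        np.fill_diagonal(T, 0.0)
        np.fill_diagonal(T, 1.0 - T.sum(axis=1))
        return T

    def biased_pi(self, ensemble: int) -> np.ndarray:
        w = self.pi_true * np.exp(-self.bias_energies[ensemble])
        return w / w.sum()


def generate_discrete_truth(
    n_states: int,
    n_ensembles: int,
    seed: int,
    n_blocks: int = 3,
    coupling: float = 0.01,
    bias_scale: float = 2.0,
) -> DiscreteTruth:
    """Random reversible chain with ``n_blocks`` planted metastable blocks.

    Built from a symmetric weight matrix (intra-block weights O(1),
    inter-block weights ``coupling`` times smaller between adjacent states of
    neighbouring blocks), which guarantees detailed balance with
    ``pi ∝ row sums``.  Ensemble 0 is unbiased; other ensembles get i.i.d.
    uniform bias energies in ``[0, bias_scale]`` kT.
    """
    if n_states < 2:
        raise ValueError("need at least 2 states")
    n_blocks = min(n_blocks, n_states)
    rng = np.random.default_rng(seed)
    blocks = np.sort(rng.integers(0, n_blocks, n_states))
    # ensure every block non-empty
    blocks[:n_blocks] = np.arange(n_blocks)
    blocks = np.sort(blocks)
    W = rng.uniform(0.5, 1.0, (n_states, n_states))
    W = 0.5 * (W + W.T)
    same = blocks[:, None] == blocks[None, :]
    W[~same] *= coupling
    T = W / W.sum(axis=1, keepdims=True)
    pi = W.sum(axis=1) / W.sum()
    bias = np.zeros((n_ensembles, n_states))
    if n_ensembles > 1:
        bias[1:] = rng.uniform(0.0, bias_scale, (n_ensembles - 1, n_states))
    return DiscreteTruth(n_states=n_states, T_true=T, pi_true=pi,
                         bias_energies=bias, blocks=blocks)


def sample_chain(
    truth: DiscreteTruth,
    ensemble: int,
    n_steps: int,
    seed: int,
    start: int | None = None,
) -> np.ndarray:
    """Sample a discrete trajectory of length ``n_steps`` from one ensemble.

    Biased ensembles use the Metropolis-reweighted chain consistent with
    ``bias_energies``.  ``n_steps = 1`` returns the start state only.
    """
    if ensemble >= truth.n_ensembles:
        raise ValueError("ensemble index out of range")
    rng = np.random.default_rng(seed)
    T = truth.biased_transition_matrix(ensemble) if ensemble else truth.T_true
    cdf = np.cumsum(T, axis=1)
    cdf[:, -1] = 1.0
    if start is None:
        start = int(rng.integers(truth.n_states))
    traj = np.empty(n_steps, dtype=np.int64)
    traj[0] = start
    u = rng.random(n_steps)
    s = start
    for k in range(1, n_steps):
        s = int(np.searchsorted(cdf[s], u[k]))
        traj[k] = s
    return traj
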