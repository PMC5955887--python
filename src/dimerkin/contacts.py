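"""Inter-protomer contact statistics, dimeric microstates and interface naming.

A *contact* is a residue pair (one residue from each protomer) whose backbone
beads approach within a cutoff (default 0.8 nm, minimal image).  A bound pair
is a *dimer* in a frame when it has at least ``n_dimer`` (default 10)
contacts; a microstate is *dimeric* when the probability of observing a dimer
among its unbiased frames is at least ``p_dimer`` (default 0.9).

Contact maps per macrostate are stationary-weighted sums over the dimeric
microstates; interfaces are named from the expected per-frame contact counts
of each receptor region: more than three contacts lists the region in the
interface name, fewer than three puts it in parentheses (exactly three is
treated as parenthetical).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .geometry import BeadFrame, RegionMap

__all__ = [
    "ContactStats",
    "InterfaceLabel",
    "frame_contacts",
    "microstate_stats",
    "macrostate_contact_map",
    "residue_contact_summary",
    "region_contact_counts",
    "name_interface",
]


def frame_contacts(frame: BeadFrame, cutoff: float = 0.8) -> set[tuple[int, int]]:
    """Residue pairs (protomer-1 residue, protomer-2 residue) in contact.

    A pair is in contact when any backbone bead of the first residue is within
    ``cutoff`` (minimal image) of any backbone bead of the second; each pair
    counts once per frame.
    """
    bb1 = (frame.protomer == 1) & frame.is_backbone
    bb2 = (frame.protomer == 2) & frame.is_backbone
    if not bb1.any() or not bb2.any():
        raise ValueError("missing backbone beads on one protomer")
    p1, r1 = frame.positions[bb1], frame.residue[bb1]
    p2, r2 = frame.positions[bb2], frame.residue[bb2]
    diff = p1[:, None, :] - p2[None, :, :]
    diff -= frame.box * np.round(diff / frame.box)
    close = (diff**2).sum(axis=2) < cutoff**2
    ii, jj = np.nonzero(close)
    return {(int(r1[i]), int(r2[j])) for i, j in zip(ii, jj)}


@dataclass
class ContactStats:
    """Per-microstate contact statistics from unbiased frames.

    ``p_tot[k][n]`` is the probability of at least ``n`` contacts in
    microstate ``k`` (index 0..max_n); ``pair_probs[k]`` maps a residue pair
    to its contact probability; ``n_frames[k]`` counts contributing frames.
    Microstates without frames have undefined stats and are flagged.
    """

    n_states: int
    max_n: int
    p_tot: np.ndarray
    pair_probs: list[dict]
    n_frames: np.ndarray
    n_dimer: int = 10
    p_dimer: float = 0.9

    @property
    def dimeric(self) -> np.ndarray:
        """Dimeric flag per microstate: p_tot(n_dimer) >= p_dimer."""
        with np.errstate(invalid="ignore"):
            flag = self.p_tot[:, self.n_dimer] >= self.p_dimer
        flag[self.n_frames == 0] = False
        return flag

    @property
    def undefined(self) -> np.ndarray:
        return self.n_frames == 0


def microstate_stats(
    dtraj: np.ndarray,
    frames: Sequence[BeadFrame],
    cutoff: float = 0.8,
    n_dimer: int = 10,
    p_dimer: float = 0.9,
    n_states: int | None = None,
) -> ContactStats:
    """Accumulate contact statistics per microstate over aligned frames.

    ``dtraj[k]`` is the microstate of ``frames[k]``; only unbiased frames
    should be passed (the stationary weighting happens later).
    """
    dtraj = np.asarray(dtraj, dtype=np.int64)
    if len(dtraj) != len(frames):
        raise ValueError("dtraj and frames must be aligned")
    if n_states is None:
        n_states = int(dtraj.max()) + 1
    max_n = max(n_dimer + 5, 1)
    tot_counts: list[list[int]] = [[] for _ in range(n_states)]
    pair_counts: list[dict] = [dict() for _ in range(n_states)]
    for s, fr in zip(dtraj, frames):
        contacts = frame_contacts(fr, cutoff)
        tot_counts[s].append(len(contacts))
        pc = pair_counts[s]
        for p in contacts:
            pc[p] = pc.get(p, 0) + 1
    n_frames = np.array([len(c) for c in tot_counts])
    max_obs = max([max(c) for c in tot_counts if c] or [0])
    max_n = max(max_n, max_obs)
    p_tot = np.full((n_states, max_n + 1), np.nan)
    pair_probs: list[dict] = []
    for k in range(n_states):
        m = n_frames[k]
        if m:
            cnt = np.asarray(tot_counts[k])
            p_tot[k] = [(cnt >= n).mean() for n in range(max_n + 1)]
            pair_probs.append({p: c / m for p, c in pair_counts[k].items()})
        else:
            pair_probs.append({})
    return ContactStats(
        n_states=n_states, max_n=max_n, p_tot=p_tot, pair_probs=pair_probs,
        n_frames=n_frames, n_dimer=n_dimer, p_dimer=p_dimer,
    )


def macrostate_contact_map(
    stats: ContactStats,
    pi: np.ndarray,
    macrostate: Sequence[int],
    normalized: bool = True,
) -> dict[tuple[int, int], float]:
    """Stationary-weighted contact map over the dimeric microstates of a macrostate.

    The raw map is ``Σ'_k π_k p_k(i,j)`` with the primed sum over dimeric
    microstates; ``normalized=True`` divides by ``Σ' π_k`` so maps of
    macrostates with different weights are comparable (the normalized map is
    the one used for interface naming).  A macrostate without dimeric
    microstates yields an empty map.
    """
    pi = np.asarray(pi, float)
    dimeric = stats.dimeric
    members = [k for k in macrostate if dimeric[k]]
    out: dict[tuple[int, int], float] = {}
    for k in members:
        for p, v in stats.pair_probs[k].items():
            out[p] = out.get(p, 0.0) + pi[k] * v
    if normalized and members:
        z = pi[members].sum()
        if z > 0:
            out = {p: v / z for p, v in out.items()}
    return out


def residue_contact_summary(
    stats: ContactStats,
    pi: np.ndarray,
    region_map: RegionMap | None = None,
    residue_threshold: float = 0.2,
    pair_threshold: float = 0.1,
) -> dict[str, pd.DataFrame]:
    """π-weighted per-residue contact numbers and per-pair probabilities.

    The average contact number of a residue pools its occurrences on both
    (identical) protomers; ranked tables are filtered at the stated thresholds.
    Returns ``{"residues": ..., "pairs": ...}`` DataFrames, region-annotated
    when a :class:`RegionMap` is given.
    """
    pi = np.asarray(pi, float)
    defined = stats.n_frames > 0
    z = pi[defined].sum()
    w = np.where(defined, pi, 0.0) / (z if z > 0 else 1.0)
    res_avg: dict[int, float] = {}
    pair_prob: dict[tuple[int, int], float] = {}
    for k in range(stats.n_states):
        if w[k] == 0:
            continue
        for (i, j), v in stats.pair_probs[k].items():
            pair_prob[(i, j)] = pair_prob.get((i, j), 0.0) + w[k] * v
            # each protomer side contributes; protomers are identical, so
            # average the two sides
            res_avg[i] = res_avg.get(i, 0.0) + 0.5 * w[k] * v
            res_avg[j] = res_avg.get(j, 0.0) + 0.5 * w[k] * v
    res_rows = [
        {
            "residue": r,
            "avg_contacts": v,
            "region": region_map.region_of(r) if region_map else None,
        }
        for r, v in res_avg.items()
        if v > residue_threshold
    ]
    pair_rows = [
        {
            "residue_i": i,
            "residue_j": j,
            "probability": v,
            "region_i": region_map.region_of(i) if region_map else None,
            "region_j": region_map.region_of(j) if region_map else None,
        }
        for (i, j), v in pair_prob.items()
        if v > pair_threshold
    ]
    residues = pd.DataFrame(
        res_rows, columns=["residue", "avg_contacts", "region"]
    ).sort_values("avg_contacts", ascending=False, ignore_index=True)
    pairs = pd.DataFrame(
        pair_rows,
        columns=["residue_i", "residue_j", "probability", "region_i", "region_j"],
    ).sort_values("probability", ascending=False, ignore_index=True)
    return {"residues": residues, "pairs": pairs}


def region_contact_counts(
    contact_map: dict[tuple[int, int], float], region_map: RegionMap
) -> tuple[dict[str, float], dict[str, float]]:
    """Expected per-frame contact counts per region, for each protomer side.

    The value of a region is the sum of contact probabilities of its residues,
    i.e. the expected number of contacts the region forms in a frame.
    """
    side1: dict[str, float] = {}
    side2: dict[str, float] = {}
    for (i, j), v in contact_map.items():
        side1[region_map.region_of(i)] = side1.get(region_map.region_of(i), 0.0) + v
        side2[region_map.region_of(j)] = side2.get(region_map.region_of(j), 0.0) + v
    return side1, side2


@dataclass(frozen=True)
class InterfaceLabel:
    """Rendered interface name, e.g. ``TM1,2,(H8)/TM1,2,(H8)``."""

    primary_1: tuple[str, ...]
    parenthetical_1: tuple[str, ...]
    primary_2: tuple[str, ...]
    parenthetical_2: tuple[str, ...]
    text: str

    def __str__(self) -> str:
        return self.text


def _render_side(primary: list[str], paren: list[str], order: dict[str, int]) -> str:
    items = sorted(primary, key=lambda r: order[r]) + [
        f"({r})" for r in sorted(paren, key=lambda r: order[r])
    ]
    # collapse TM runs: TM1, TM2 -> TM1,2 (parenthetical kept as-is)
    out: list[str] = []
    for it in items:
        if out and it.startswith("TM") and out[-1].startswith("TM"):
            out.append(it[2:])
        else:
            out.append(it)
    return ",".join(out) if out else "-"


def name_interface(
    side1: dict[str, float],
    side2: dict[str, float],
    region_map: RegionMap,
    primary_threshold: float = 3.0,
) -> InterfaceLabel:
    """Interface name from region-level expected contact counts.

    Regions with more than ``primary_threshold`` contacts are primary; regions
    with three or fewer (but more than zero) are parenthetical.  Regions are
    listed in sequence order; for asymmetric interfaces the two sides are
    ordered canonically (lexicographically).
    """
    order = {name: rng[0] for name, rng in region_map.ranges.items()}

    def split(side):
        prim = [r for r, v in side.items() if v > primary_threshold]
        paren = [r for r, v in side.items() if 0 < v <= primary_threshold]
        return prim, paren

    p1, q1 = split(side1)
    p2, q2 = split(side2)
    s1 = _render_side(p1, q1, order)
    s2 = _render_side(p2, q2, order)
    if s2 < s1:
        p1, q1, p2, q2 = p2, q2, p1, q1
        s1, s2 = s2, s1
    return InterfaceLabel(
        primary_1=tuple(sorted(p1, key=lambda r: order[r])),
        parenthetical_1=tuple(sorted(q1, key=lambda r: order[r])),
        primary_2=tuple(sorted(p2, key=lambda r: order[r])),
        parenthetical_2=tuple(sorted(q2, key=lambda r: order[r])),
        text=f"{s1}/{s2}",
    )
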