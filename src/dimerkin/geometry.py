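"""Order parameter (d, α1, α2), 4D embedding, swap augmentation, bead decoration.

The order parameter of a protomer pair is

* ``d`` — the minimal-image distance between the protomers' centres of mass;
* ``alpha1`` — the unsigned 3-point angle at protomer 1's COM between the
  vector to its TM1 (transmembrane helix 1) COM and the vector to protomer 2's
  COM;
* ``alpha2`` — the same with the protomers swapped.

Angles are in ``[0, π]``.  To handle the angular periodicity uniformly in a
Euclidean clustering space, frames are embedded as
``(d sin α1, d cos α1, d sin α2, d cos α2)``.

COMs are computed from backbone beads only, unweighted, and the 3-point angles
are computed in full 3D by default (a membrane-plane projection is available
via ``project_xy=True``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .synthetic import CVTrajectory

__all__ = [
    "BeadFrame",
    "RegionMap",
    "ProtomerTemplate",
    "compute_cvs",
    "embed",
    "invert_embedding",
    "embed_trajectory",
    "swap_augment",
    "decorate_beads",
    "synthetic_protomer_template",
]


@dataclass(frozen=True)
class RegionMap:
    """Residue-index → structural-region mapping (TM1..TM7, H8, loops, termini).

    ``ranges`` maps a region name to an inclusive ``(first, last)`` residue
    range; ranges must not overlap and must jointly cover the declared residue
    span.  Optional Ballesteros–Weinstein labels may be attached per residue.
    """

    ranges: dict[str, tuple[int, int]]
    bw_labels: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        seen: set[int] = set()
        for name, (a, b) in self.ranges.items():
            if b < a:
                raise ValueError(f"region {name} has inverted range")
            ids = set(range(a, b + 1))
            if ids & seen:
                raise ValueError(f"region {name} overlaps a previous region")
            seen |= ids
        object.__setattr__(self, "_lookup", {})
        for name, (a, b) in self.ranges.items():
            for r in range(a, b + 1):
                self._lookup[r] = name  # type: ignore[attr-defined]

    def region_of(self, residue: int) -> str:
        try:
            return self._lookup[residue]  # type: ignore[attr-defined]
        except KeyError:
            raise KeyError(f"residue {residue} is not covered by the region map")

    @property
    def residues(self) -> list[int]:
        return sorted(self._lookup)  # type: ignore[attr-defined]


@dataclass
class BeadFrame:
    """Labelled coarse-grained bead coordinates for a protomer pair.

    ``positions`` is (n_beads, 3) in nm; ``protomer`` ∈ {1, 2}; ``residue`` is
    the residue index; ``is_backbone`` flags backbone beads; ``box`` is the
    orthorhombic periodic cell (3,) in nm.
    """

    positions: np.ndarray
    protomer: np.ndarray
    residue: np.ndarray
    is_backbone: np.ndarray
    box: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, float)
        self.protomer = np.asarray(self.protomer, int)
        self.residue = np.asarray(self.residue, int)
        self.is_backbone = np.asarray(self.is_backbone, bool)
        self.box = np.asarray(self.box, float)
        if set(np.unique(self.protomer)) != {1, 2}:
            raise ValueError("both protomers must be present")
        for p in (1, 2):
            m = (self.protomer == p) & self.is_backbone
            if not m.any():
                raise ValueError(f"protomer {p} has no backbone beads")


def _minimal_image(vec: np.ndarray, box: np.ndarray) -> np.ndarray:
    return vec - box * np.round(vec / box)


def _unwrap_com(pos: np.ndarray, box: np.ndarray) -> np.ndarray:
    """COM of a bead cloud that may be split across periodic boundaries.

    Beads are unwrapped relative to the first bead before averaging; valid as
    long as the cloud diameter is below half the box (true for one protomer).
    """
    ref = pos[0]
    return ref + _minimal_image(pos - ref, box).mean(axis=0)


def compute_cvs(
    frame: BeadFrame,
    tm1_residues,
    project_xy: bool = False,
) -> tuple[float, float, float]:
    """Compute (d, alpha1, alpha2) from a bead frame.

    ``tm1_residues`` is the set of residue indices forming TM1 (shared by both
    protomers).  With ``project_xy=True`` the angle vectors are projected onto
    the membrane plane before the 3-point angle is taken.
    """
    tm1_residues = set(int(r) for r in tm1_residues)
    if not tm1_residues:
        raise ValueError("tm1_residues must be non-empty")
    box = frame.box
    coms = {}
    tm1_coms = {}
    for p in (1, 2):
        bb = (frame.protomer == p) & frame.is_backbone
        coms[p] = _unwrap_com(frame.positions[bb], box)
        tm1 = bb & np.isin(frame.residue, list(tm1_residues))
        if not tm1.any():
            raise ValueError(f"protomer {p} has no TM1 backbone beads")
        # unwrap TM1 beads relative to the protomer COM reference
        ref = frame.positions[bb][0]
        tm1_pos = ref + _minimal_image(frame.positions[tm1] - ref, box)
        tm1_coms[p] = tm1_pos.mean(axis=0)

    r12 = _minimal_image(coms[2] - coms[1], box)
    d = float(np.linalg.norm(r12))

    def angle_at(p: int, to_other: np.ndarray) -> float:
        v_tm1 = tm1_coms[p] - coms[p]
        v_oth = to_other
        if project_xy:
            v_tm1 = v_tm1.copy()
            v_oth = v_oth.copy()
            v_tm1[2] = 0.0
            v_oth[2] = 0.0
        n1 = np.linalg.norm(v_tm1)
        n2 = np.linalg.norm(v_oth)
        if n1 < 1e-12 or n2 < 1e-12:
            raise ValueError("degenerate geometry: TM1 COM coincides with protomer COM")
        c = float(np.dot(v_tm1, v_oth) / (n1 * n2))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    a1 = angle_at(1, r12)
    a2 = angle_at(2, -r12)
    return d, a1, a2


def embed(d, alpha1, alpha2) -> np.ndarray:
    """Map (d, α1, α2) to (d sin α1, d cos α1, d sin α2, d cos α2).

    Broadcasts over arrays; the result's last axis has length 4.  The norms of
    the first and second coordinate pairs both equal d.
    """
    d = np.asarray(d, float)
    a1 = np.asarray(alpha1, float)
    a2 = np.asarray(alpha2, float)
    return np.stack(
        [d * np.sin(a1), d * np.cos(a1), d * np.sin(a2), d * np.cos(a2)], axis=-1
    )


def invert_embedding(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (d, α1, α2) from the 4D embedding (exact for d > 0)."""
    x = np.asarray(x, float)
    d1 = np.hypot(x[..., 0], x[..., 1])
    d2 = np.hypot(x[..., 2], x[..., 3])
    d = 0.5 * (d1 + d2)
    with np.errstate(invalid="ignore"):
        a1 = np.where(d1 > 0, np.arctan2(x[..., 0], x[..., 1]), 0.0)
        a2 = np.where(d2 > 0, np.arctan2(x[..., 2], x[..., 3]), 0.0)
    return d, a1, a2


def embed_trajectory(traj: CVTrajectory) -> np.ndarray:
    """(n_frames, 4) embedded order parameter of a CV trajectory."""
    return embed(traj.d, traj.alpha1, traj.alpha2)


def swap_augment(traj: CVTrajectory) -> tuple[CVTrajectory, CVTrajectory]:
    """Duplicate a trajectory with α1 and α2 exchanged (protomer swap).

    Returns ``(original, swapped)``.  Downstream statistics built from the
    pair are exactly symmetric under protomer exchange.
    """
    swapped = CVTrajectory(
        t=traj.t.copy(),
        d=traj.d.copy(),
        alpha1=traj.alpha2.copy(),
        alpha2=traj.alpha1.copy(),
        dt=traj.dt,
        bias=traj.bias,
        bias_energy=None if traj.bias is not None else None,
    )
    if traj.bias is not None:
        # recompute: a swapped frame's bias energy differs unless the bias is symmetric
        swapped.bias_energy = np.asarray(
            traj.bias.energy(swapped.d, swapped.alpha1, swapped.alpha2), float
        )
    return traj, swapped


# ----------------------------------------------------------------------------
# Synthetic bead decoration
# ----------------------------------------------------------------------------

@dataclass(frozen=True)
class ProtomerTemplate:
    """Per-residue backbone bead layout in a protomer-fixed frame.

    ``positions[i]`` is the bead of ``residues[i]`` (nm), with the protomer
    COM at the origin and the TM1 COM direction along the body +x axis.
    """

    residues: np.ndarray
    positions: np.ndarray
    region_map: RegionMap
    tm1_residues: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "residues", np.asarray(self.residues, int))
        object.__setattr__(self, "positions", np.asarray(self.positions, float))
        for r in self.residues:
            self.region_map.region_of(int(r))  # raises if inconsistent
        com = self.positions.mean(axis=0)
        if np.linalg.norm(com) > 1e-9:
            raise ValueError("template COM must be at the origin")
        tm1 = np.isin(self.residues, list(self.tm1_residues))
        if not tm1.any():
            raise ValueError("template has no TM1 residues")
        tm1_com = self.positions[tm1].mean(axis=0)
        if np.hypot(tm1_com[1], tm1_com[2]) > 1e-9 or tm1_com[0] <= 0:
            raise ValueError("template TM1 COM must lie on the body +x axis")


def synthetic_protomer_template(radius: float = 1.2, n_per_region: int = 3) -> ProtomerTemplate:
    """Minimal synthetic receptor: 8 regions (TM1–TM7, H8) on a ring.

    Residues are numbered from 65 upward in blocks of ``n_per_region`` per
    region; beads sit on a circle of ``radius`` nm in the body xy-plane with
    TM1 centred on the +x axis.  This is a synthetic stand-in that lets the
    contact analysis run on worlds generated at the CV level; it does not
    reproduce any real receptor architecture.
    """
    regions = ["TM1", "TM2", "TM3", "TM4", "TM5", "TM6", "TM7", "H8"]
    n_reg = len(regions)
    residues = []
    positions = []
    ranges = {}
    next_res = 65
    for k, name in enumerate(regions):
        theta0 = 2 * np.pi * k / n_reg
        first = next_res
        for m in range(n_per_region):
            # spread beads of a region over a small arc around its direction
            theta = theta0 + (m - (n_per_region - 1) / 2) * (0.25 * 2 * np.pi / n_reg)
            residues.append(next_res)
            positions.append([radius * np.cos(theta), radius * np.sin(theta), 0.0])
            next_res += 1
        ranges[name] = (first, next_res - 1)
    residues = np.asarray(residues)
    positions = np.asarray(positions)
    positions -= positions.mean(axis=0)
    rmap = RegionMap(ranges=ranges)
    tm1 = frozenset(range(ranges["TM1"][0], ranges["TM1"][1] + 1))
    # rotate so that the TM1 COM lies exactly on +x (centering shifts it slightly)
    tm1_com = positions[np.isin(residues, list(tm1))].mean(axis=0)
    phi = np.arctan2(tm1_com[1], tm1_com[0])
    c, s = np.cos(-phi), np.sin(-phi)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    positions = positions @ R.T
    return ProtomerTemplate(
        residues=residues, positions=positions, region_map=rmap, tm1_residues=tm1
    )


def _rot_z(angle: float) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def decorate_beads(
    cv_traj: CVTrajectory,
    template: ProtomerTemplate,
    box_side: float,
    z0: float = 0.0,
) -> list[BeadFrame]:
    """Rigid-body bead placement of both protomers for every frame.

    Protomer 1 is placed left of the box centre, protomer 2 right, separated
    by the frame's ``d`` along x; each protomer is rotated about z so that its
    TM1 direction realizes the frame's α.  Feeding a decorated frame back to
    :func:`compute_cvs` recovers the input CVs.
    """
    L = box_side
    n = len(template.residues)
    frames = []
    box = np.array([L, L, L])
    for k in range(len(cv_traj)):
        d = cv_traj.d[k]
        a1 = cv_traj.alpha1[k]
        a2 = cv_traj.alpha2[k]
        c1 = np.array([(L - d) / 2.0, L / 2.0, z0])
        c2 = np.array([(L + d) / 2.0, L / 2.0, z0])
        p1 = c1 + template.positions @ _rot_z(a1).T
        p2 = c2 + template.positions @ _rot_z(np.pi - a2).T
        frames.append(
            BeadFrame(
                positions=np.vstack([p1, p2]) % box,
                protomer=np.concatenate([np.ones(n, int), np.full(n, 2)]),
                residue=np.concatenate([template.residues, template.residues]),
                is_backbone=np.ones(2 * n, bool),
                box=box,
            )
        )
    return frames
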