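"""Potential energies and forces between subcellular elements.

Each epithelial cell is represented by an ordered ring of membrane nodes
enclosing a cloud of internal (cytoplasm) nodes.  Five interaction families
couple the nodes:

``II``
    Morse potential between internal nodes of the same cell (cytoplasmic
    pressure).
``MI``
    Morse potential between internal and membrane nodes of the same cell
    (pressure of the cytoplasm on the membrane; keeps the cytoplasm inside).
``MMD``
    Morse potential between membrane nodes of *different* cells (volume
    exclusion of neighboring cells).
``MMS``
    Linear + torsional springs along a cell's own membrane ring (cortical
    stiffness).
``Adh``
    Linear spring between at most one membrane-node partner on a neighboring
    cell (cell-cell adhesion through adherens junctions).

The Morse potential is ``E(r) = U exp(-r/xi) - W exp(-r/gamma)``: a
short-range repulsive and a longer-range attractive exponential.  All
interactions are cut off sharply beyond a family-specific distance ``L``.

Every family carries an interphase and a mitotic parameter value; a cell in
the mitotic phase interpolates linearly between them as its cycle progress
``CP`` runs from the mitosis-entry point ``CP_mit`` to 1
(:func:`phase_interpolate`).

Units throughout the package: micrometres (um), nanonewtons (nN), seconds,
radians.  Energies are nN.um; pressures nN/um^2 (= kPa).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Generic, TypeVar

import numpy as np

__all__ = [
    "MorseParams",
    "CortexParams",
    "AdhesionParams",
    "PhasePair",
    "PhaseParams",
    "default_phase_params",
    "morse_energy",
    "morse_force",
    "morse_radial_force",
    "point_segment_distance",
    "morse_segment_energy",
    "morse_segment_force",
    "cortex_energy",
    "cortex_forces",
    "adhesion_energy",
    "adhesion_force",
    "adhesion_pairs",
    "pair_membranes",
    "phase_interpolate",
    "PARAM_NAMES",
    "param_vector",
    "params_from_vector",
]

# Fraction of xi below which the Morse force magnitude is frozen (coincident
# nodes can occur transiently after random internal-node insertion).
MORSE_CAP_FRACTION = 0.01

T = TypeVar("T")


@dataclass(frozen=True)
class MorseParams:
    """Morse potential parameters for one interaction family.

    Parameters
    ----------
    U, W : float
        Repulsive / attractive energy amplitudes (nN.um).  ``W = 0`` gives a
        purely repulsive single exponential.
    xi, gamma : float
        Repulsive / attractive decay lengths (um).
    L : float
        Hard interaction cutoff (um): energy and force are identically zero
        for separations beyond ``L``.
    repulsive_only : bool
        Keep only the repulsive branch: the pair force is cut (and the
        energy shifted to stay continuous) at the zero-force separation.
        Used for the cross-cell volume-exclusion family, whose role is
        purely to keep membranes of different cells from overlapping —
        cross-cell cohesion is the adhesion springs' job.
    """

    U: float
    W: float
    xi: float
    gamma: float
    L: float
    repulsive_only: bool = False

    def __post_init__(self) -> None:
        if self.U < 0 or self.W < 0:
            raise ValueError("Morse amplitudes U, W must be non-negative")
        if self.xi <= 0 or self.gamma <= 0:
            raise ValueError("Morse length scales xi, gamma must be positive")
        if self.L <= 0:
            raise ValueError("Morse cutoff L must be positive")

    def zero_force_separation(self) -> float:
        """Separation where repulsion and attraction balance (inf if the
        force never turns attractive)."""
        if self.W <= 0 or self.xi >= self.gamma:
            return math.inf
        # U/xi e^{-r/xi} = W/gamma e^{-r/gamma}
        return math.log((self.U * self.gamma) / (self.W * self.xi)) / (1.0 / self.xi - 1.0 / self.gamma)


@dataclass(frozen=True)
class CortexParams:
    """Membrane/cortex stiffness: linear springs along the ring segments
    (constant ``k_stiff``, rest length ``L_stiff``) plus a torsional spring at
    every ring vertex (constant ``k_tor``, rest angle = the regular-polygon
    interior angle)."""

    k_stiff: float  # nN/um
    L_stiff: float  # um
    k_tor: float  # nN.um/rad

    def __post_init__(self) -> None:
        if min(self.k_stiff, self.L_stiff, self.k_tor) <= 0:
            raise ValueError("cortex parameters must be strictly positive")


@dataclass(frozen=True)
class AdhesionParams:
    """Cell-cell adhesion spring: engages between mutually-nearest membrane
    nodes of different cells closer than ``L_max``; pulls with
    ``k_adh * (d - L_min)`` for ``L_min <= d <= L_max`` and exerts no force
    below ``L_min`` (volume exclusion there is the MMD family's job)."""

    k_adh: float  # nN/um
    L_min: float  # um
    L_max: float  # um

    def __post_init__(self) -> None:
        if self.k_adh < 0:
            raise ValueError("k_adh must be non-negative")
        if not (0 < self.L_min < self.L_max):
            raise ValueError("need 0 < L_min < L_max")


@dataclass(frozen=True)
class PhasePair(Generic[T]):
    """An (interphase value, mitotic value) pair of one parameter set."""

    inter: T
    mit: T


@dataclass(frozen=True)
class PhaseParams:
    """The complete per-cell parameter table: one interphase/mitotic pair for
    each interaction family."""

    ii: PhasePair[MorseParams]
    mi: PhasePair[MorseParams]
    mmd: PhasePair[MorseParams]
    cortex: PhasePair[CortexParams]
    adhesion: PhasePair[AdhesionParams]


def default_phase_params() -> PhaseParams:
    """Calibrated parameter set for the wing-disc epithelium.

    The MI family has no attractive term (``W = 0``); ``gamma`` is set to 1
    as an inert placeholder.  MMD and the adhesion engagement window are
    phase-constant.
    """
    return PhaseParams(
        ii=PhasePair(
            inter=MorseParams(U=0.49, W=0.15, xi=0.31, gamma=1.25, L=1.56),
            mit=MorseParams(U=21.75, W=6.71, xi=0.58, gamma=1.34, L=3.12),
        ),
        mi=PhasePair(
            inter=MorseParams(U=0.78, W=0.0, xi=0.13, gamma=1.0, L=1.56),
            mit=MorseParams(U=4.36, W=0.0, xi=0.27, gamma=1.0, L=3.12),
        ),
        mmd=PhasePair(
            inter=MorseParams(U=3.9, W=3.9, xi=0.13, gamma=1.6, L=0.78, repulsive_only=True),
            mit=MorseParams(U=3.9, W=3.9, xi=0.13, gamma=1.6, L=0.78, repulsive_only=True),
        ),
        cortex=PhasePair(
            inter=CortexParams(k_stiff=200.0, L_stiff=0.060, k_tor=6.0),
            mit=CortexParams(k_stiff=450.0, L_stiff=0.13, k_tor=7.0),
        ),
        adhesion=PhasePair(
            inter=AdhesionParams(k_adh=20.0, L_min=0.062, L_max=0.40),
            mit=AdhesionParams(k_adh=8.0, L_min=0.062, L_max=0.40),
        ),
    )


# ---------------------------------------------------------------------------
# Morse potential
# ---------------------------------------------------------------------------


def morse_energy(r, p: MorseParams):
    """Morse pair energy at separation ``r`` (scalar or array), zero beyond
    the cutoff ``p.L``.

    ``E(r) = U exp(-r/xi) - W exp(-r/gamma)`` for ``r <= L``.  For a
    ``repulsive_only`` family the potential is cut and shifted at its
    zero-force separation (zero energy and force beyond it, continuous at
    the cut).
    """
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    e = p.U * np.exp(-r / p.xi) - p.W * np.exp(-r / p.gamma)
    if p.repulsive_only:
        r0 = min(p.zero_force_separation(), p.L)
        e0 = p.U * math.exp(-r0 / p.xi) - p.W * math.exp(-r0 / p.gamma)
        e = np.where(r <= r0, e - e0, 0.0)
    else:
        e = np.where(r <= p.L, e, 0.0)
    return float(e) if e.ndim == 0 else e


def morse_radial_force(r, p: MorseParams):
    """Radial Morse force ``f(r) = -dE/dr`` (positive = repulsive), zero
    beyond the cutoff (for ``repulsive_only`` families: beyond the
    zero-force separation).  Below ``0.01 xi`` the magnitude is frozen at
    its value at ``0.01 xi`` to keep near-coincident nodes finite."""
    r = np.asarray(r, dtype=float)
    if np.any(r < 0):
        raise ValueError("separation r must be non-negative")
    rc = np.maximum(r, MORSE_CAP_FRACTION * p.xi)
    f = (p.U / p.xi) * np.exp(-rc / p.xi) - (p.W / p.gamma) * np.exp(-rc / p.gamma)
    cut = min(p.zero_force_separation(), p.L) if p.repulsive_only else p.L
    f = np.where(r <= cut, f, 0.0)
    return float(f) if f.ndim == 0 else f


def morse_force(x_i, x_j, p: MorseParams) -> np.ndarray:
    """Force on node *i* at ``x_i`` exerted by node *j* at ``x_j``.

    Equal to ``-grad_i E(|x_i - x_j|)``; antisymmetric under i <-> j.  For
    coincident nodes the direction is undefined and the capped magnitude is
    applied along +x (a deterministic fallback; the integrator separates the
    pair within a step or two).
    """
    x_i = np.asarray(x_i, dtype=float)
    x_j = np.asarray(x_j, dtype=float)
    d = x_i - x_j
    r = float(np.hypot(*d))
    f = morse_radial_force(r, p)
    if r < 1e-12:
        return np.array([f, 0.0])
    return f * d / r


def point_segment_distance(p, a, b):
    """Distance from point ``p`` to segment ``ab``.

    Returns ``(d, t, closest)`` where ``t`` in [0, 1] parameterizes the
    closest point ``closest = a + t (b - a)``.
    """
    p = np.asarray(p, dtype=float)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    e = b - a
    ee = float(e @ e)
    t = float(np.clip((p - a) @ e / ee, 0.0, 1.0)) if ee > 0 else 0.0
    c = a + t * e
    return float(np.hypot(*(p - c))), t, c


def morse_segment_energy(p, a, b, prm: MorseParams) -> float:
    """Morse energy between a node and a membrane *segment*, evaluated at
    the point-to-segment distance.

    The membrane ring stands for a continuous cortex; evaluating the pair
    potential against the segment rather than its end nodes keeps the wall
    impenetrable regardless of how coarsely it is discretized (a node-node
    wall becomes porous once the node spacing exceeds the repulsion range).
    """
    d, _, _ = point_segment_distance(p, a, b)
    return float(morse_energy(d, prm))


def morse_segment_force(p, a, b, prm: MorseParams):
    """Forces of a node-segment Morse interaction: ``(f_p, f_a, f_b)``.

    ``f_p`` acts on the node along the line to the closest segment point;
    the reaction is split between the segment endpoints by the lever rule
    ``(1-t, t)``.  For an interior closest point this is the exact negative
    gradient of :func:`morse_segment_energy` (envelope theorem: the
    derivative of the clamped projection drops out), and the three forces
    sum to zero with zero net torque.
    """
    d, t, c = point_segment_distance(p, a, b)
    f = morse_radial_force(d, prm)
    if f == 0.0:
        z = np.zeros(2)
        return z, z.copy(), z.copy()
    n = (np.asarray(p, dtype=float) - c)
    n = n / d if d > 1e-12 else np.array([1.0, 0.0])
    f_p = f * n
    return f_p, -(1.0 - t) * f_p, -t * f_p


# ---------------------------------------------------------------------------
# Cortex (membrane) springs
# ---------------------------------------------------------------------------


def _ring_orientation(ring: np.ndarray) -> float:
    """+1 for counter-clockwise node order, -1 for clockwise (shoelace sign)."""
    x, y = ring[:, 0], ring[:, 1]
    s = np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)
    return 1.0 if s >= 0 else -1.0


def _turning_angles(ring: np.ndarray) -> np.ndarray:
    """Signed exterior (turning) angle at every vertex of a closed polyline."""
    e1 = ring - np.roll(ring, 1, axis=0)  # segment entering vertex j
    e2 = np.roll(ring, -1, axis=0) - ring  # segment leaving vertex j
    cross = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    dot = np.einsum("ij,ij->i", e1, e2)
    return np.arctan2(cross, dot)


def cortex_energy(ring: np.ndarray, p: CortexParams) -> float:
    """Total MMS energy of a closed membrane ring: ``1/2 k_stiff (l - L)^2``
    per segment plus ``1/2 k_tor (psi - psi0)^2`` per vertex, where ``psi`` is
    the signed turning angle and ``psi0 = +-2 pi / n`` matches the ring
    orientation (equivalently, harmonic in the deviation of the interior
    angle from the regular-polygon angle ``pi (n-2)/n``)."""
    ring = np.asarray(ring, dtype=float)
    n = len(ring)
    if n < 3:
        raise ValueError("ring needs >= 3 nodes")
    seg = np.roll(ring, -1, axis=0) - ring
    ell = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(ell < 1e-12):
        raise ValueError("degenerate (zero-length) ring segment")
    e_lin = 0.5 * p.k_stiff * np.sum((ell - p.L_stiff) ** 2)
    psi0 = _ring_orientation(ring) * 2.0 * math.pi / n
    psi = _turning_angles(ring)
    e_tor = 0.5 * p.k_tor * np.sum((psi - psi0) ** 2)
    return float(e_lin + e_tor)


def cortex_forces(ring: np.ndarray, p: CortexParams) -> np.ndarray:
    """Per-node forces of the cortical springs on a closed ring (analytic
    negative gradient of :func:`cortex_energy`).  Internal forces: they sum
    to zero and carry zero net torque."""
    ring = np.asarray(ring, dtype=float)
    n = len(ring)
    if n < 3:
        raise ValueError("ring needs >= 3 nodes")
    forces = np.zeros_like(ring)

    # Linear springs along consecutive segments.
    seg = np.roll(ring, -1, axis=0) - ring
    ell = np.hypot(seg[:, 0], seg[:, 1])
    if np.any(ell < 1e-12):
        raise ValueError("degenerate (zero-length) ring segment")
    t = seg / ell[:, None]
    f = p.k_stiff * (ell - p.L_stiff)  # tension, + = stretched
    forces += f[:, None] * t  # node j pulled toward j+1
    forces -= np.roll(f[:, None] * t, 1, axis=0)  # node j+1 pulled toward j

    # Torsional springs at vertices: E_j = 1/2 k (psi_j - psi0)^2 with
    # psi_j = atan2(e1 x e2, e1 . e2), e1 = x_j - x_{j-1}, e2 = x_{j+1} - x_j.
    psi0 = _ring_orientation(ring) * 2.0 * math.pi / n
    e1 = ring - np.roll(ring, 1, axis=0)
    e2 = np.roll(ring, -1, axis=0) - ring
    c = e1[:, 0] * e2[:, 1] - e1[:, 1] * e2[:, 0]
    d = np.einsum("ij,ij->i", e1, e2)
    psi = np.arctan2(c, d)
    denom = c * c + d * d
    # d psi / d e1 and / d e2 (2-vectors per vertex)
    dpsi_de1 = (d[:, None] * np.stack([e2[:, 1], -e2[:, 0]], axis=1) - c[:, None] * e2) / denom[:, None]
    dpsi_de2 = (d[:, None] * np.stack([-e1[:, 1], e1[:, 0]], axis=1) - c[:, None] * e1) / denom[:, None]
    k = p.k_tor * (psi - psi0)
    g1 = k[:, None] * dpsi_de1  # dE_j/de1
    g2 = k[:, None] * dpsi_de2
    # e1_j depends on x_j (+) and x_{j-1} (-); e2_j on x_{j+1} (+) and x_j (-)
    forces -= g1 - g2  # dE_j / dx_j
    forces += np.roll(g1, -1, axis=0)  # dE_{j+1}/dx_j  (through e1_{j+1})
    forces -= np.roll(g2, 1, axis=0)  # dE_{j-1}/dx_j (through e2_{j-1})
    return forces


# ---------------------------------------------------------------------------
# Adhesion
# ---------------------------------------------------------------------------


def adhesion_energy(d, p: AdhesionParams):
    """Adhesion spring energy ``1/2 k (d - L_min)^2`` on ``[L_min, L_max]``,
    zero outside (detached beyond ``L_max``; MMD takes over below ``L_min``)."""
    d = np.asarray(d, dtype=float)
    e = 0.5 * p.k_adh * (d - p.L_min) ** 2
    e = np.where((d >= p.L_min) & (d <= p.L_max), e, 0.0)
    return float(e) if e.ndim == 0 else e


def adhesion_force(d, p: AdhesionParams):
    """Scalar adhesion force along the pair axis: ``k_adh (d - L_min)``
    (positive = attractive) for ``L_min <= d <= L_max``, zero otherwise."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("pair distance must be non-negative")
    f = p.k_adh * (d - p.L_min)
    f = np.where((d >= p.L_min) & (d <= p.L_max), f, 0.0)
    return float(f) if f.ndim == 0 else f


def pair_membranes(pos: np.ndarray, cell_of: np.ndarray, L_max: float) -> np.ndarray:
    """Pair membrane nodes of different cells for adhesion.

    Each node's candidate partner is its nearest membrane node belonging to a
    different cell within ``L_max``.  Candidates are then accepted greedily in
    order of increasing distance (ties: lower node index first), each node
    joining at most one bond — mutual-nearest conflicts therefore resolve by
    keeping the shorter bond.

    Parameters
    ----------
    pos : (n, 2) array
        Membrane-node positions.
    cell_of : (n,) int array
        Owning cell of each node.
    L_max : float
        Engagement cutoff.

    Returns
    -------
    partner : (n,) int array
        Index of the bonded partner, or -1 for unpaired nodes.  Symmetric:
        ``partner[partner[i]] == i`` wherever ``partner[i] >= 0``.
    """
    pos = np.asarray(pos, dtype=float)
    cell_of = np.asarray(cell_of)
    n = len(pos)
    partner = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return partner
    from scipy.spatial import cKDTree

    tree = cKDTree(pos)
    neighbor_lists = tree.query_ball_point(pos, L_max)
    cand_i, cand_j, cand_d = [], [], []
    for i in range(n):
        best_j, best_d = -1, np.inf
        for j in neighbor_lists[i]:
            if cell_of[j] == cell_of[i]:
                continue
            d = float(np.hypot(pos[i, 0] - pos[j, 0], pos[i, 1] - pos[j, 1]))
            if d < best_d - 1e-15 or (abs(d - best_d) <= 1e-15 and j < best_j):
                best_j, best_d = j, d
        if best_j >= 0:
            cand_i.append(i)
            cand_j.append(best_j)
            cand_d.append(best_d)
    order = sorted(range(len(cand_i)), key=lambda k: (cand_d[k], cand_i[k], cand_j[k]))
    for k in order:
        i, j = cand_i[k], cand_j[k]
        if partner[i] < 0 and partner[j] < 0:
            partner[i] = j
            partner[j] = i
    return partner


def adhesion_pairs(tissue, p: AdhesionParams) -> set[tuple[int, int]]:
    """Current adhesion bonds of a tissue as a set of ``(i, j)`` global
    membrane-node index pairs with ``i < j`` (see :func:`pair_membranes` for
    the pairing policy)."""
    mem = tissue.membrane_mask()
    idx = np.flatnonzero(mem)
    partner = pair_membranes(tissue.pos[idx], tissue.node_cell[idx], p.L_max)
    out = set()
    for a, b in enumerate(partner):
        if b >= 0:
            i, j = int(idx[a]), int(idx[b])
            if i < j:
                out.add((i, j))
    return out


# ---------------------------------------------------------------------------
# Interphase -> mitotic parameter ramp
# ---------------------------------------------------------------------------


def phase_interpolate(v_inter, v_mit, CP: float, CP_mit: float):
    """Linear ramp of a parameter during the mitotic phase.

    Returns ``v_inter (1-CP)/(1-CP_mit) + v_mit (CP-CP_mit)/(1-CP_mit)`` so
    the value moves from the interphase value at ``CP = CP_mit`` to the
    mitotic value at ``CP = 1``.
    """
    if not (0.0 <= CP_mit < 1.0):
        raise ValueError("CP_mit must lie in [0, 1)")
    if CP < CP_mit - 1e-12 or CP > 1.0 + 1e-12:
        raise ValueError("CP must lie in [CP_mit, 1]")
    w = (CP - CP_mit) / (1.0 - CP_mit)
    return v_inter * (1.0 - w) + v_mit * w


# Flat layout used by the integrator kernels: one vector of the per-cell
# mechanical parameters, linearly interpolated entrywise during mitosis.
PARAM_NAMES = (
    "ii_U", "ii_W", "ii_xi", "ii_gamma", "ii_L",
    "mi_U", "mi_W", "mi_xi", "mi_gamma", "mi_L",
    "mmd_U", "mmd_W", "mmd_xi", "mmd_gamma", "mmd_L",
    "k_stiff", "L_stiff", "k_tor",
    "k_adh", "adh_L_min", "adh_L_max",
)


# Pair forces below this magnitude (nN) are not evaluated by the integrator
# kernels: the effective cutoff exported to them is shortened to the largest
# separation where |f| still reaches the floor.  Typical nodal forces are
# 1-10 nN, so the truncation error per pair is three orders below signal.
EVAL_FORCE_FLOOR = 1e-2


def _morse_tuple(m: MorseParams):
    # the kernels apply a plain distance cutoff, so a repulsive-only family
    # exports its zero-force separation as the effective cutoff, and every
    # family truncates its tail where the force drops below the floor
    L_eff = min(m.L, m.zero_force_separation()) if m.repulsive_only else m.L
    r = np.linspace(0.0, L_eff, 2049)
    above = np.flatnonzero(np.abs(morse_radial_force(r, m)) >= EVAL_FORCE_FLOOR)
    if len(above) and above[-1] < len(r) - 1:
        L_eff = float(r[above[-1] + 1])
    return (m.U, m.W, m.xi, m.gamma, L_eff)


def param_vector(pp: PhaseParams, phase: str = "inter") -> np.ndarray:
    """Flatten one phase column of a :class:`PhaseParams` into the kernel
    parameter layout (:data:`PARAM_NAMES`)."""
    pick = (lambda pair: pair.inter) if phase == "inter" else (lambda pair: pair.mit)
    vec = (
        _morse_tuple(pick(pp.ii))
        + _morse_tuple(pick(pp.mi))
        + _morse_tuple(pick(pp.mmd))
        + (pick(pp.cortex).k_stiff, pick(pp.cortex).L_stiff, pick(pp.cortex).k_tor)
        + (pick(pp.adhesion).k_adh, pick(pp.adhesion).L_min, pick(pp.adhesion).L_max)
    )
    return np.array(vec, dtype=float)


def params_from_vector(v: np.ndarray) -> dict:
    """Inverse of :func:`param_vector` as a name -> value mapping."""
    return dict(zip(PARAM_NAMES, np.asarray(v, dtype=float)))


def scale_for_resolution(pp: PhaseParams, s: float) -> PhaseParams:
    """Rescale per-node parameters for a node-count resolution factor ``s``.

    With ``ceil(100 s)`` membrane nodes per new cell the segment rest length
    grows as ``L_stiff / s`` (perimeter preserved); spring constants that act
    per node pair are scaled by ``s`` so that line densities of tension,
    bending stiffness and adhesive strength are preserved (``k_stiff``,
    ``k_tor``, ``k_adh``).  Morse families are per-node volumetric agents and
    are left unscaled; the equilibrium cell area then scales roughly with the
    internal-node count.
    """
    if not (0 < s <= 1):
        raise ValueError("resolution must lie in (0, 1]")
    if s == 1.0:
        return pp

    def _cortex(c: CortexParams) -> CortexParams:
        # k_stiff * s preserves the cortical tension per strain; k_tor is
        # kept unscaled so the energy barrier against a sharp single-joint
        # fold does not drop with the node count (coarse rings buckle at
        # crowded vertices otherwise).
        return CortexParams(k_stiff=c.k_stiff * s, L_stiff=c.L_stiff / s, k_tor=c.k_tor)

    def _adh(a: AdhesionParams, L_stiff_inter: float) -> AdhesionParams:
        # Engagement reach is extended by half the coarsened segment length
        # so that every junction node keeps a partner in range regardless of
        # s.  The per-bond constant is NOT scaled down: with one bond per
        # node, junctions at coarse resolution carry few bonds, and weaker
        # bonds fail to zip membranes into contact (packing opens up and the
        # contact graph thins out).
        reach = a.L_max + 0.5 * (L_stiff_inter / s - L_stiff_inter)
        return AdhesionParams(k_adh=a.k_adh, L_min=a.L_min, L_max=reach)

    return replace(
        pp,
        cortex=PhasePair(inter=_cortex(pp.cortex.inter), mit=_cortex(pp.cortex.mit)),
        adhesion=PhasePair(
            inter=_adh(pp.adhesion.inter, pp.cortex.inter.L_stiff),
            mit=_adh(pp.adhesion.mit, pp.cortex.inter.L_stiff),
        ),
    )
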