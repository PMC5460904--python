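"""Cell growth, cycle progress, mitosis entry and division.

A cell's position in its cycle is the dimensionless cycle progress
``CP`` in [0, 1].  CP accrues at the growth rate
``g_i(t) = g0_i exp(-k_g t)`` where ``g0_i`` is drawn uniformly in
``[g0_min, g0_max]`` once at the cell's birth (between-cell stochastic
variation) and ``k_g`` makes tissue growth slow down over developmental
time.  As CP rises the cell gains internal nodes (cytoplasmic mass), enters
the mitotic phase close to CP = 1, rounds up under the mitotic parameter
ramp, and finally divides perpendicular to its long axis (Hertwig's rule).

Timing convention: growth rates are per simulation second.  One simulation
second of the growth clock corresponds to one biological minute, so the
default mitosis duration of 30 biological minutes is ``T_mit = 30`` s and
developmental hours map to 60 s each (see docs/methods.md).

Mitosis entry is event-driven: each cell enters mitosis when its CP first
exceeds ``1 - g_i(t) T_mit``, which makes the realized M-phase duration
approximately ``T_mit`` despite heterogeneous growth rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "GrowthConfig",
    "CellState",
    "DivisionAborted",
    "growth_rate",
    "advance_cycle",
    "insert_internal_node",
    "insert_membrane_node",
    "enter_mitosis",
    "divide_cell",
    "long_axis",
]

# Lateral offset (um) of newly created cleavage-plane membrane nodes, pushing
# the two daughter membranes apart so the cross-cell repulsion stays gentle
# (kept small against the cell diameter: each daughter sheds an offset-wide
# strip of area at the cut).
CLEAVAGE_OFFSET = 0.025


@dataclass(frozen=True)
class GrowthConfig:
    """Growth-law constants.

    g0_min, g0_max : progress/s, bounds of the per-cell base growth rate.
    k_g : 1/s, decay constant of the tissue growth rate.
    T_mit : s, target duration of the mitotic phase (30 biological minutes).
    """

    g0_min: float = 2.0e-3
    g0_max: float = 4.0e-3
    k_g: float = 4.0e-4
    T_mit: float = 30.0

    def __post_init__(self) -> None:
        if not (0 < self.g0_min <= self.g0_max):
            raise ValueError("need 0 < g0_min <= g0_max")
        if self.k_g < 0 or self.T_mit <= 0:
            raise ValueError("k_g must be >= 0 and T_mit > 0")


class DivisionAborted(RuntimeError):
    """Division could not produce two valid daughters; retry next step."""


class CellState:
    """Lightweight view of one cell inside a :class:`~episem.tissue.TissueState`.

    Attribute reads and writes go straight to the tissue's arrays, so the
    proxy is always current.  ``ring`` returns the ordered membrane
    positions, ``internal`` the internal-node positions.
    """

    __slots__ = ("tissue", "slot")

    def __init__(self, tissue, slot: int):
        self.tissue = tissue
        self.slot = int(slot)

    # -- node access -----------------------------------------------------
    @property
    def ring(self) -> np.ndarray:
        ts = self.tissue
        s = ts.cell_start[self.slot]
        return ts.pos[s: s + ts.cell_nm[self.slot]]

    @property
    def internal(self) -> np.ndarray:
        ts = self.tissue
        s = ts.cell_start[self.slot] + ts.cell_nm[self.slot]
        return ts.pos[s: s + ts.cell_ni[self.slot]]

    @property
    def n_membrane(self) -> int:
        return int(self.tissue.cell_nm[self.slot])

    @property
    def n_internal(self) -> int:
        return int(self.tissue.cell_ni[self.slot])

    # -- scalar state ------------------------------------------------------
    @property
    def id(self) -> int:
        return int(self.tissue.cell_id[self.slot])

    def _get(self, name):
        return getattr(self.tissue, name)[self.slot]

    def _set(self, name, value):
        getattr(self.tissue, name)[self.slot] = value

    @property
    def CP(self) -> float:
        return float(self._get("cell_cp"))

    @CP.setter
    def CP(self, v: float) -> None:
        self._set("cell_cp", v)

    @property
    def g0(self) -> float:
        return float(self._get("cell_g0"))

    @property
    def phase(self) -> str:
        return "mitotic" if self.tissue.cell_phase[self.slot] else "interphase"

    @property
    def CP_mit(self) -> float:
        return float(self._get("cell_cp_mit"))

    @property
    def birth_time(self) -> float:
        return float(self._get("cell_birth"))

    @property
    def division_axis(self) -> np.ndarray | None:
        a = self.tissue.cell_axis[self.slot]
        return None if np.isnan(a[0]) else a.copy()

    @property
    def rng(self) -> np.random.Generator:
        return self.tissue.cell_rng[self.slot]

    # -- geometry helpers --------------------------------------------------
    def centroid(self) -> np.ndarray:
        return self.ring.mean(axis=0)

    def radius(self) -> float:
        """Mean centroid-to-membrane distance R_c."""
        c = self.centroid()
        d = self.ring - c
        return float(np.mean(np.hypot(d[:, 0], d[:, 1])))


# ---------------------------------------------------------------------------
# Growth and cycle progress
# ---------------------------------------------------------------------------


def growth_rate(cell: CellState, t: float, cfg: GrowthConfig) -> float:
    """Current growth rate ``g_i(t) = g0_i exp(-k_g t)`` (progress/s)."""
    if t < 0:
        raise ValueError("t must be non-negative")
    return cell.g0 * math.exp(-cfg.k_g * t)


def _internal_target(cp: float, n0: int, nmax: int) -> int:
    """Internal-node count prescribed at cycle progress ``cp``: one insertion
    per ``1/(nmax-n0)`` increase in CP, from ``n0`` at CP=0 to ``nmax`` at
    CP=1."""
    return min(nmax, n0 + int(math.floor(cp * (nmax - n0) + 1e-12)))


def advance_cycle(cell: CellState, dt: float, t: float, cfg: GrowthConfig,
                  rng: np.random.Generator | None = None) -> list[str]:
    """Advance one cell's cycle by ``dt`` and fire due events.

    Returns the events that became due, in order:

    - ``"insert_internal"`` (possibly repeated) whenever CP crosses an
      internal-node insertion threshold — the node is inserted immediately;
    - ``"mitosis_entry"`` when CP first exceeds the dynamic entry point
      ``1 - g_i(t) T_mit`` — the cell switches to the mitotic phase;
    - ``"division_due"`` when CP reaches 1 (the tissue loop performs the
      actual division so it can handle retries).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    rng = cell.rng if rng is None else rng
    g = growth_rate(cell, t, cfg)
    cell.CP = min(1.0, cell.CP + g * dt)
    events: list[str] = []
    ts = cell.tissue
    while (cell.n_internal < _internal_target(cell.CP, ts.n_internal_start, ts.n_internal_max)
           and cell.n_internal < ts.n_internal_max):
        insert_internal_node(cell, rng)
        events.append("insert_internal")
    if cell.phase == "interphase":
        cp_entry = 1.0 - g * cfg.T_mit
        if cell.CP >= cp_entry:
            enter_mitosis(cell, t, cfg, cp_mit=min(cp_entry, cell.CP))
            events.append("mitosis_entry")
    if cell.CP >= 1.0:
        events.append("division_due")
    return events


def insert_internal_node(cell: CellState, rng: np.random.Generator | None = None) -> None:
    """Add one internal node, uniformly placed in the disk of radius
    ``0.2 R_c`` about the cell centroid (R_c = mean centroid-to-membrane
    distance)."""
    ts = cell.tissue
    if cell.n_internal >= ts.n_internal_max:
        import warnings

        warnings.warn("internal node count already at maximum; insertion skipped")
        return
    rng = cell.rng if rng is None else rng
    c = cell.centroid()
    r = 0.2 * cell.radius() * math.sqrt(rng.random())
    th = 2.0 * math.pi * rng.random()
    p = c + r * np.array([math.cos(th), math.sin(th)])
    ts.insert_internal(cell.slot, p)


def insert_membrane_node(cell: CellState, rest_length: float | None = None) -> int:
    """Split every over-stretched ring segment at its midpoint.

    A segment is split when it exceeds twice the cortical rest length of the
    cell's current phase.  Returns the number of nodes added (0 if the ring
    is already at the maximum size).
    """
    ts = cell.tissue
    if rest_length is None:
        rest_length = ts.current_rest_length(cell.slot)
    added = 0
    while cell.n_membrane < ts.n_membrane_max:
        ring = cell.ring
        seg = np.roll(ring, -1, axis=0) - ring
        ell = np.hypot(seg[:, 0], seg[:, 1])
        over = np.flatnonzero(ell > 2.0 * rest_length)
        if len(over) == 0:
            break
        a = int(over[np.argmax(ell[over])])
        mid = 0.5 * (ring[a] + ring[(a + 1) % len(ring)])
        ts.insert_membrane(cell.slot, a + 1, mid)
        added += 1
    return added


# ---------------------------------------------------------------------------
# Mitosis
# ---------------------------------------------------------------------------


def long_axis(points: np.ndarray) -> np.ndarray:
    """Unit principal axis of a point set (largest-eigenvalue direction of
    the centered second-moment matrix).  Ties and the sign ambiguity resolve
    to the representative with the largest x component (then largest y)."""
    pts = np.asarray(points, dtype=float)
    d = pts - pts.mean(axis=0)
    m = d.T @ d / len(d)
    evals, evecs = np.linalg.eigh(m)
    if abs(evals[1] - evals[0]) <= 1e-12 * max(abs(evals[1]), 1e-30):
        v = np.array([1.0, 0.0])
    else:
        v = evecs[:, int(np.argmax(evals))]
    if v[0] < 0 or (v[0] == 0 and v[1] < 0):
        v = -v
    return v / np.hypot(*v)


def enter_mitosis(cell: CellState, t: float, cfg: GrowthConfig,
                  cp_mit: float | None = None) -> None:
    """Switch a cell to the mitotic phase.

    The division axis (the cell's long axis, from the membrane ring's second
    moments) is computed and frozen now — before mitotic rounding erases the
    elongation — and the interphase-to-mitotic parameter ramp starts from
    ``CP_mit`` (defaults to the current CP).
    """
    if cell.phase == "mitotic":
        raise ValueError(f"cell {cell.id} is already mitotic")
    ts = cell.tissue
    slot = cell.slot
    ts.cell_axis[slot] = long_axis(cell.ring)
    ts.cell_cp_mit[slot] = cell.CP if cp_mit is None else cp_mit
    ts.cell_phase[slot] = 1


def divide_cell(cell: CellState, rng: np.random.Generator | None = None):
    """Split a mitotic cell through its centroid, perpendicular to the
    stored division axis.

    Membrane nodes go to the daughter on their side of the cleavage line;
    the two cut arcs are each closed by fresh membrane nodes laid along the
    cleavage line (spacing = the cortical rest length, offset slightly into
    each daughter).  Internal nodes are assigned by side (exactly-on-line
    goes to daughter A).  Both daughters restart at CP = 0 in interphase
    with freshly drawn base growth rates.

    Returns ``(daughter_a, daughter_b)`` proxies.  Raises
    :class:`DivisionAborted` when a clean two-arc cut is not possible.
    """
    ts = cell.tissue
    if cell.phase != "mitotic":
        raise ValueError("only mitotic cells divide")
    axis = cell.division_axis
    if axis is None:
        raise ValueError("division axis not set")
    rng = cell.rng if rng is None else rng

    ring = cell.ring.copy()
    internal = cell.internal.copy()
    c = ring.mean(axis=0)
    side = (ring - c) @ axis  # signed distance along the long axis

    pos_mask = side > 0
    if pos_mask.all() or (~pos_mask).all():
        raise DivisionAborted("cleavage line misses the membrane ring")
    # rotate so the ring starts at the first node of the positive arc
    first = int(np.flatnonzero(pos_mask & ~np.roll(pos_mask, 1))[0])
    order = (np.arange(len(ring)) + first) % len(ring)
    ring = ring[order]
    side = side[order]
    pos_mask = side > 0
    changes = int(np.sum(pos_mask != np.roll(pos_mask, 1)))
    if changes != 2:
        raise DivisionAborted("ring crosses the cleavage line more than twice")
    n_a = int(np.sum(pos_mask))  # positive arc is now ring[:n_a]

    def _crossing(p, q):
        sp = (p - c) @ axis
        sq = (q - c) @ axis
        w = sp / (sp - sq)
        return p + w * (q - p)

    x_end = _crossing(ring[n_a - 1], ring[n_a % len(ring)])  # leaving + arc
    x_start = _crossing(ring[-1], ring[0])  # re-entering + arc

    ell = ts.interphase_rest_length()
    delta = min(CLEAVAGE_OFFSET, 2.0 * ell)

    def _cleave_line(p_from, p_to, sign):
        """Nodes along the cleavage line from p_from to p_to, offset into
        the daughter's side."""
        length = float(np.hypot(*(p_to - p_from)))
        m = max(1, int(round(length / ell)))
        tvals = np.arange(0, m + 1) / m
        pts = p_from[None, :] + tvals[:, None] * (p_to - p_from)[None, :]
        return pts + sign * delta * axis

    def _dedupe(r, min_seg):
        # collapse near-coincident consecutive nodes (a cleavage crossing can
        # land right on an arc node; tiny segments blow up the vertex springs)
        keep = [0]
        for a in range(1, len(r)):
            if np.hypot(*(r[a] - r[keep[-1]])) >= min_seg:
                keep.append(a)
        while len(keep) > 3 and np.hypot(*(r[keep[-1]] - r[keep[0]])) < min_seg:
            keep.pop()
        return r[keep]

    ring_a = _dedupe(np.vstack([ring[:n_a], _cleave_line(x_end, x_start, +1.0)]), 0.4 * ell)
    ring_b = _dedupe(np.vstack([ring[n_a:], _cleave_line(x_start, x_end, -1.0)]), 0.4 * ell)

    iside = (internal - c) @ axis
    int_a = internal[iside >= 0]
    int_b = internal[iside < 0]
    if min(len(ring_a), len(ring_b)) < 3 or min(len(int_a), len(int_b)) < 1:
        raise DivisionAborted("a daughter would be degenerate")

    def _contain(nodes, r):
        # the cleavage membranes are offset into each daughter, so nodes
        # right at the cut can land outside the new ring; pull them halfway
        # toward the ring centroid until they are strictly inside
        from shapely.geometry import Point, Polygon

        poly = Polygon(r).buffer(0)
        centroid = r.mean(axis=0)
        out = nodes.copy()
        for k in range(len(out)):
            guard = 0
            while not poly.contains(Point(out[k])) and guard < 12:
                out[k] = 0.5 * (out[k] + centroid)
                guard += 1
        return out

    int_a = _contain(int_a, ring_a)
    int_b = _contain(int_b, ring_b)

    ss_a, ss_b = ts.cell_seed[cell.slot].spawn(2)
    return ts.replace_with_daughters(cell.slot, ring_a, int_a, ss_a, ring_b, int_b, ss_b)
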