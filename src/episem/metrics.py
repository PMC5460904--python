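"""Per-cell geometry, mitotic-rounding readouts and tissue-topology laws.

Cell geometry comes straight from the ordered membrane ring: area by the
shoelace formula, perimeter as polyline length, roundness as the
isoperimetric index ``4 pi A / P^2`` (1 for a circle).  Intracellular
pressure is a 2D virial estimate over the cytoplasmic Morse pairs,
``P = (1/2A) sum r_ij . f_ij``.

Tissue topology is read off the adhesion bonds: two cells are neighbors
when they share at least ``min_bonds`` bonds, a cell's polygon class is its
neighbor count, and three classical laws are checked on the interior of a
packed sheet: Euler (mean class 6), Lewis (normalized area grows with
class) and Aboav-Weaire (mean neighbor class falls with class).  Cells near
the tissue's convex-hull margin are excluded — the laws hold for packed
interiors only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .dynamics import ADH_LMAX

__all__ = [
    "CellGeometry",
    "TopologyStats",
    "MRReadout",
    "cell_geometry",
    "polygon_area",
    "bond_counts",
    "neighbor_graph",
    "interior_cells",
    "topology_stats",
    "cell_pressure",
    "mr_readouts",
    "detect_t1",
    "default_min_bonds",
]


@dataclass(frozen=True)
class CellGeometry:
    area: float  # um^2
    perimeter: float  # um
    roundness: float  # 4 pi A / P^2, in (0, 1]
    centroid: np.ndarray  # (2,)


def polygon_area(ring: np.ndarray) -> float:
    """Unsigned shoelace area of a closed polygon."""
    x, y = ring[:, 0], ring[:, 1]
    return 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)))


def cell_geometry(cell, validate: bool = True) -> CellGeometry:
    """Geometry of one cell's membrane ring.

    With ``validate=True`` a self-intersecting ring raises ``ValueError``
    (checked through shapely's polygon validity predicate).
    """
    ring = np.asarray(cell.ring if hasattr(cell, "ring") else cell, dtype=float)
    if len(ring) < 3:
        raise ValueError("ring needs >= 3 nodes")
    if validate:
        from shapely.geometry import Polygon

        if not Polygon(ring).is_valid:
            raise ValueError("membrane ring is self-intersecting")
    area = polygon_area(ring)
    seg = np.roll(ring, -1, axis=0) - ring
    perim = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    roundness = 4.0 * math.pi * area / perim**2 if perim > 0 else 0.0
    return CellGeometry(area=area, perimeter=perim, roundness=roundness,
                        centroid=ring.mean(axis=0))


# ---------------------------------------------------------------------------
# Neighbor graph and topology laws
# ---------------------------------------------------------------------------


def default_min_bonds(resolution: float) -> int:
    """Neighborship threshold: 3 shared adhesion bonds at full resolution,
    scaled with the linear membrane-node density (bonds per junction are
    proportional to it; validated against a Voronoi-contact oracle)."""
    return max(1, round(3 * resolution))


def _current_partner(tissue) -> np.ndarray:
    partner = getattr(tissue, "adh_partner", None)
    if partner is None or len(partner) != tissue.n_nodes:
        P = tissue.resolve_params()
        L_max = float(np.max(P[:, ADH_LMAX]))
        mem_idx = tissue.membrane_indices()
        partner = np.full(tissue.n_nodes, -1, dtype=np.int64)
        local = dyn.pair_membranes_fast(tissue.pos[mem_idx],
                                        tissue.node_cell[mem_idx], L_max)
        ok = local >= 0
        partner[mem_idx[ok]] = mem_idx[local[ok]]
        tissue.adh_partner = partner
    return partner


def bond_counts(tissue) -> dict[tuple[int, int], int]:
    """Number of adhesion bonds between each pair of cells (keyed by sorted
    cell-slot pairs)."""
    partner = _current_partner(tissue)
    counts: dict[tuple[int, int], int] = {}
    for i in np.flatnonzero(partner >= 0):
        j = partner[i]
        if j < i:
            continue
        a, b = int(tissue.node_cell[i]), int(tissue.node_cell[j])
        key = (a, b) if a < b else (b, a)
        counts[key] = counts.get(key, 0) + 1
    return counts


def neighbor_graph(tissue, min_bonds: int | None = None) -> list[set[int]]:
    """Per-cell (slot-indexed) neighbor sets: cells sharing at least
    ``min_bonds`` adhesion bonds."""
    if min_bonds is None:
        min_bonds = default_min_bonds(tissue.resolution)
    nbrs: list[set[int]] = [set() for _ in range(tissue.n_cells)]
    for (a, b), n in bond_counts(tissue).items():
        if n >= min_bonds:
            nbrs[a].add(b)
            nbrs[b].add(a)
    return nbrs


def interior_cells(tissue, margin: float | None = None) -> np.ndarray:
    """Boolean mask of cells well inside the sheet: a cell is excluded when
    any of its membrane nodes lies within one cell radius (default: its own
    mean radius) of the tissue's convex hull boundary."""
    from scipy.spatial import ConvexHull

    mem = tissue.membrane_indices()
    pts = tissue.pos[mem]
    mask = np.ones(tissue.n_cells, dtype=bool)
    if len(pts) < 3 or tissue.n_cells < 3:
        return np.zeros(tissue.n_cells, dtype=bool)
    hull = ConvexHull(pts)
    # hull edges as (point a, unit normal) half-planes; distance of x to the
    # boundary = min over edges of the distance to the edge segment; for
    # points inside a convex hull the distance to the boundary equals the
    # min distance to the supporting lines
    eq = hull.equations  # (n_facets, 3): a x + b y + c = 0, outward normal
    d_all = np.abs(pts @ eq[:, :2].T + eq[:, 2])  # (n_pts, n_facets)
    d_min = d_all.min(axis=1)
    for slot in range(tissue.n_cells):
        s, nm = tissue.cell_start[slot], tissue.cell_nm[slot]
        sel = (mem >= s) & (mem < s + nm)
        ring = tissue.pos[s: s + nm]
        rc = float(np.mean(np.hypot(*(ring - ring.mean(axis=0)).T)))
        limit = rc if margin is None else margin
        if d_min[sel].min() < limit:
            mask[slot] = False
    return mask


@dataclass
class TopologyStats:
    """Polygon-class statistics over the interior of a tissue."""

    classes: np.ndarray  # per-cell neighbor count (all cells; -1 = excluded)
    interior: np.ndarray  # interior mask
    histogram: dict[int, int]  # class -> count over interior cells
    mean_all: float
    mean_interphase: float
    mean_mitotic: float
    lewis: pd.DataFrame  # class, mean normalized area, count
    aboav: pd.DataFrame  # class, mean neighbor class, count
    n_interior: int
    stable: bool  # False when too few interior cells for stable statistics


def topology_stats(tissue, min_bonds: int | None = None, min_interior: int = 20) -> TopologyStats:
    """Histogram, per-phase means and the Lewis / Aboav-Weaire tables over
    interior cells.  ``stable`` is False (with a warning) below
    ``min_interior`` interior cells."""
    import warnings

    nbrs = neighbor_graph(tissue, min_bonds)
    interior = interior_cells(tissue)
    classes = np.array([len(nbrs[i]) for i in range(tissue.n_cells)])
    sel = interior
    n_interior = int(np.sum(sel))
    stable = n_interior >= min_interior
    if not stable:
        warnings.warn(f"only {n_interior} interior cells; topology statistics unstable")
    cls_int = classes[sel]
    hist: dict[int, int] = {int(c): int(n) for c, n in
                            zip(*np.unique(cls_int, return_counts=True))} if n_interior else {}
    mit = tissue.cell_phase == 1
    mean_all = float(np.mean(cls_int)) if n_interior else float("nan")
    mean_inter = float(np.mean(classes[sel & ~mit])) if np.any(sel & ~mit) else float("nan")
    mean_mit = float(np.mean(classes[sel & mit])) if np.any(sel & mit) else float("nan")

    areas = np.array([polygon_area(tissue.cell(i).ring) for i in range(tissue.n_cells)])
    abar = float(np.mean(areas[sel])) if n_interior else float("nan")
    lewis_rows, aboav_rows = [], []
    for c in sorted(hist):
        in_class = sel & (classes == c)
        lewis_rows.append({"polygon_class": c,
                           "mean_normalized_area": float(np.mean(areas[in_class]) / abar),
                           "count": int(np.sum(in_class))})
        nb_classes = [classes[j] for i in np.flatnonzero(in_class) for j in nbrs[i]]
        aboav_rows.append({"polygon_class": c,
                           "mean_neighbor_class": float(np.mean(nb_classes)) if nb_classes else float("nan"),
                           "count": int(np.sum(in_class))})
    return TopologyStats(
        classes=np.where(interior, classes, -1), interior=interior, histogram=hist,
        mean_all=mean_all, mean_interphase=mean_inter, mean_mitotic=mean_mit,
        lewis=pd.DataFrame(lewis_rows, columns=["polygon_class", "mean_normalized_area", "count"]),
        aboav=pd.DataFrame(aboav_rows, columns=["polygon_class", "mean_neighbor_class", "count"]),
        n_interior=n_interior, stable=stable)


# ---------------------------------------------------------------------------
# Pressure and mitotic-rounding readouts
# ---------------------------------------------------------------------------


def cell_pressure(cell, params: np.ndarray | None = None) -> float:
    """2D virial pressure of one cell (nN/um^2): ``(1/2A)`` times the sum of
    ``r_ij . f_ij`` over its II and MI Morse pairs (repulsion positive)."""
    ts = cell.tissue
    _, virial = dyn.net_forces_and_virial(ts, params)
    area = polygon_area(cell.ring)
    if area <= 0:
        return 0.0
    return float(virial[cell.slot] / (2.0 * area))


@dataclass(frozen=True)
class MRReadout:
    """Mitotic-rounding readout for one completed M phase."""

    A_inter: float  # apical area at mitosis entry (um^2)
    A_mit: float  # peak apical area during M (um^2)
    A_ratio: float  # A_mit / A_inter
    R_norm: float  # peak roundness during M / roundness at entry
    delta_P: float  # peak virial pressure minus pressure at entry (nN/um^2)


def mr_readouts(trajectory: pd.DataFrame) -> MRReadout:
    """Readouts from one cell's sampled trajectory across its M phase.

    ``trajectory`` needs columns ``t, area, roundness, pressure, phase``
    (phase in {"interphase", "mitotic"}), sampled from mitosis entry through
    cytokinesis; the first mitotic sample is the entry reference.
    """
    required = {"t", "area", "roundness", "pressure", "phase"}
    if not required.issubset(trajectory.columns):
        raise ValueError(f"trajectory missing columns {sorted(required - set(trajectory.columns))}")
    mit = trajectory[trajectory["phase"] == "mitotic"].sort_values("t")
    if mit.empty:
        raise ValueError("trajectory contains no mitotic samples")
    a0 = float(mit["area"].iloc[0])
    r0 = float(mit["roundness"].iloc[0])
    p0 = float(mit["pressure"].iloc[0])
    if a0 <= 0 or r0 <= 0:
        raise ValueError("degenerate entry geometry")
    return MRReadout(
        A_inter=a0, A_mit=float(mit["area"].max()),
        A_ratio=float(mit["area"].max()) / a0,
        R_norm=float(mit["roundness"].max()) / r0,
        delta_P=float(mit["pressure"].max()) - p0,
    )


# ---------------------------------------------------------------------------
# T1 transitions
# ---------------------------------------------------------------------------


def detect_t1(tissue_before, tissue_after, min_bonds: int | None = None) -> list[tuple]:
    """Neighbor-exchange (T1) events between two snapshots.

    Returns quadruples ``(a, b, c, d)`` of cell ids where the contact (a, b)
    present before is lost and the transverse contact (c, d) — between two
    common neighbors of a and b — is gained.
    """

    def _id_graph(ts):
        nbrs = neighbor_graph(ts, min_bonds)
        ids = ts.cell_id
        return {int(ids[i]): {int(ids[j]) for j in nbrs[i]} for i in range(ts.n_cells)}

    g0 = _id_graph(tissue_before)
    g1 = _id_graph(tissue_after)
    shared = set(g0) & set(g1)
    events = []
    for a in sorted(shared):
        for b in sorted(g0[a]):
            if b <= a or b not in shared or b in g1.get(a, set()):
                continue  # only lost edges (a < b)
            common = sorted((g0[a] & g0[b]) & shared)
            for ci in range(len(common)):
                for di in range(ci + 1, len(common)):
                    c, d = common[ci], common[di]
                    if d not in g0.get(c, set()) and d in g1.get(c, set()):
                        events.append((a, b, c, d))
    return events
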