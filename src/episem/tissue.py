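"""Tissue state, initialization and the main simulation loop.

A :class:`TissueState` holds every node position in one flat array, grouped
by cell: each cell's membrane nodes come first (in ring order) followed by
its internal nodes.  This layout feeds the numba force kernel directly while
:class:`~episem.cell_cycle.CellState` proxies give per-cell access for the
cycle operations.

Simulations start from a small cluster of circular, initially non-adherent
cells on a hexagonal layout (default 7: one center plus a ring).  Each step:
resolve per-cell phase parameters -> recompute adhesion pairing and forces
-> forward-Euler move -> advance every cell's cycle (internal-node
insertions, mitosis entries, divisions).  Everything is reproducible from
(config, seed): one global RNG stream fixes the initial geometry and every
cell carries its own child stream, so adding a cell never perturbs another
cell's draws.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from . import cell_cycle as cc
from . import dynamics as dyn
from .dynamics import IntegratorConfig, L_STIFF, ADH_LMIN
from .mechanics import PhaseParams, param_vector

__all__ = ["TissueState", "initialize_tissue", "run_simulation",
           "run_resilient", "SimulationResult", "hex_centers"]


class TissueState:
    """All cells of the simulated epithelium plus the global clock.

    Construct through :func:`initialize_tissue`; the attributes below are the
    simulation's working arrays.

    Attributes
    ----------
    pos : (N, 2) float array of node positions (um).
    node_cell : (N,) int array, owning cell slot per node.
    node_id, cell_id : stable unique identifiers.
    cell_start, cell_nm, cell_ni : per-cell layout (membrane nodes occupy
        ``[start, start+nm)`` in ring order, internal ``[start+nm, start+nm+ni)``).
    cell_cp, cell_g0, cell_cp_mit, cell_birth, cell_phase, cell_axis :
        per-cell cycle state.
    t : global time (s).
    """

    def __init__(self, phase_params: PhaseParams, growth, n_internal=(20, 40),
                 n_membrane=(100, 200), resolution: float = 1.0):
        self.params = phase_params
        self.growth = growth
        self.resolution = float(resolution)
        self.n_internal_start, self.n_internal_max = map(int, n_internal)
        self.n_membrane_start, self.n_membrane_max = map(int, n_membrane)
        self.p_inter = param_vector(phase_params, "inter")
        self.p_mit = param_vector(phase_params, "mit")
        self.t = 0.0
        self.pos = np.zeros((0, 2))
        self.node_cell = np.zeros(0, dtype=np.int64)
        self.node_id = np.zeros(0, dtype=np.int64)
        self.is_mem = np.zeros(0, dtype=bool)
        self.cell_start = np.zeros(0, dtype=np.int64)
        self.cell_nm = np.zeros(0, dtype=np.int64)
        self.cell_ni = np.zeros(0, dtype=np.int64)
        self.cell_id = np.zeros(0, dtype=np.int64)
        self.cell_cp = np.zeros(0)
        self.cell_g0 = np.zeros(0)
        self.cell_cp_mit = np.zeros(0)
        self.cell_birth = np.zeros(0)
        self.cell_phase = np.zeros(0, dtype=np.uint8)
        self.cell_axis = np.zeros((0, 2))
        self.cell_rng: list[np.random.Generator] = []
        self.cell_seed: list[np.random.SeedSequence] = []
        self.adh_partner = np.zeros(0, dtype=np.int64)
        self._cross_cache = None
        self._next_node_id = 0
        self._next_cell_id = 0
        self.root_seed: int | None = None

    # -- basic queries ----------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.pos)

    @property
    def n_cells(self) -> int:
        return len(self.cell_start)

    def membrane_mask(self) -> np.ndarray:
        return self.is_mem

    def membrane_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_mem)

    def cell(self, slot: int) -> cc.CellState:
        return cc.CellState(self, slot)

    def cells(self):
        return (cc.CellState(self, i) for i in range(self.n_cells))

    def adhesion_L_min(self) -> float:
        return float(self.p_inter[ADH_LMIN])

    def interphase_rest_length(self) -> float:
        return float(self.p_inter[L_STIFF])

    def mitotic_weight(self) -> np.ndarray:
        """Per-cell ramp weight: 0 in interphase, (CP-CP_mit)/(1-CP_mit) in
        mitosis."""
        w = np.zeros(self.n_cells)
        m = self.cell_phase == 1
        if np.any(m):
            w[m] = np.clip(
                (self.cell_cp[m] - self.cell_cp_mit[m]) / (1.0 - self.cell_cp_mit[m]),
                0.0, 1.0,
            )
        return w

    def resolve_params(self) -> np.ndarray:
        """Per-cell (n_cells, 21) parameter matrix with the mitotic ramp
        applied entrywise (interphase rows are served from a cached base)."""
        C = self.n_cells
        base = getattr(self, "_P_base", None)
        if base is None or base.shape[0] != C:
            base = np.tile(self.p_inter, (C, 1))
            self._P_base = base
        m = np.flatnonzero(self.cell_phase == 1)
        if len(m) == 0:
            return base
        P = base.copy()
        w = np.clip((self.cell_cp[m] - self.cell_cp_mit[m])
                    / (1.0 - self.cell_cp_mit[m]), 0.0, 1.0)[:, None]
        P[m] = (1.0 - w) * self.p_inter + w * self.p_mit
        return P

    def current_rest_length(self, slot: int) -> float:
        w = 0.0
        if self.cell_phase[slot]:
            w = float(np.clip((self.cell_cp[slot] - self.cell_cp_mit[slot])
                              / (1.0 - self.cell_cp_mit[slot]), 0.0, 1.0))
        return float((1 - w) * self.p_inter[L_STIFF] + w * self.p_mit[L_STIFF])

    # -- construction and surgery ----------------------------------------
    def append_cell(self, ring: np.ndarray, internal: np.ndarray,
                    seed_seq: np.random.SeedSequence, birth_time: float | None = None,
                    cp: float = 0.0) -> int:
        """Append a cell; draws its base growth rate from its own stream."""
        ring = np.asarray(ring, dtype=float)
        internal = np.asarray(internal, dtype=float)
        slot = self.n_cells
        n_new = len(ring) + len(internal)
        start = self.n_nodes
        self.pos = np.vstack([self.pos, ring, internal])
        self.node_cell = np.concatenate([self.node_cell, np.full(n_new, slot, dtype=np.int64)])
        ids = np.arange(self._next_node_id, self._next_node_id + n_new, dtype=np.int64)
        self._next_node_id += n_new
        self.node_id = np.concatenate([self.node_id, ids])
        self.is_mem = np.concatenate(
            [self.is_mem, np.ones(len(ring), bool), np.zeros(len(internal), bool)])
        self.cell_start = np.append(self.cell_start, start)
        self.cell_nm = np.append(self.cell_nm, len(ring))
        self.cell_ni = np.append(self.cell_ni, len(internal))
        self.cell_id = np.append(self.cell_id, self._next_cell_id)
        self._next_cell_id += 1
        rng = np.random.default_rng(seed_seq)
        g0 = rng.uniform(self.growth.g0_min, self.growth.g0_max)
        self.cell_cp = np.append(self.cell_cp, cp)
        self.cell_g0 = np.append(self.cell_g0, g0)
        self.cell_cp_mit = np.append(self.cell_cp_mit, np.nan)
        self.cell_birth = np.append(self.cell_birth, self.t if birth_time is None else birth_time)
        self.cell_phase = np.append(self.cell_phase, np.uint8(0))
        self.cell_axis = np.vstack([self.cell_axis, [np.nan, np.nan]])
        self.cell_rng.append(rng)
        self.cell_seed.append(seed_seq)
        self.adh_partner = None  # stale after surgery; recomputed next step
        self._cross_cache = None
        return slot

    def _insert_node(self, index: int, p: np.ndarray, slot: int, membrane: bool) -> None:
        self.pos = np.insert(self.pos, index, p, axis=0)
        self.node_cell = np.insert(self.node_cell, index, slot)
        self.node_id = np.insert(self.node_id, index, self._next_node_id)
        self._next_node_id += 1
        self.is_mem = np.insert(self.is_mem, index, membrane)
        # shift starts of all later cells
        later = np.arange(self.n_cells) > slot
        self.cell_start[later] += 1
        self.adh_partner = None
        self._cross_cache = None

    def insert_internal(self, slot: int, p: np.ndarray) -> None:
        idx = int(self.cell_start[slot] + self.cell_nm[slot] + self.cell_ni[slot])
        self._insert_node(idx, p, slot, membrane=False)
        self.cell_ni[slot] += 1

    def insert_membrane(self, slot: int, ring_pos: int, p: np.ndarray) -> None:
        """Insert a membrane node so it becomes ring position ``ring_pos``."""
        ring_pos = int(ring_pos) % (int(self.cell_nm[slot]) + 1)
        idx = int(self.cell_start[slot] + ring_pos)
        self._insert_node(idx, p, slot, membrane=True)
        self.cell_nm[slot] += 1

    def replace_with_daughters(self, slot: int, ring_a, int_a, ss_a, ring_b, int_b, ss_b):
        """Replace the mother in ``slot`` by daughter A and append daughter B."""
        mother_id = int(self.cell_id[slot])
        # remove the mother's nodes
        s, nm, ni = int(self.cell_start[slot]), int(self.cell_nm[slot]), int(self.cell_ni[slot])
        keep = np.ones(self.n_nodes, bool)
        keep[s: s + nm + ni] = False
        self.pos = self.pos[keep]
        self.node_cell = self.node_cell[keep]
        self.node_id = self.node_id[keep]
        self.is_mem = self.is_mem[keep]
        later = self.cell_start > s
        self.cell_start[later] -= nm + ni
        # drop the mother's per-cell state
        for name in ("cell_start", "cell_nm", "cell_ni", "cell_id", "cell_cp",
                     "cell_g0", "cell_cp_mit", "cell_birth", "cell_phase"):
            arr = getattr(self, name)
            setattr(self, name, np.delete(arr, slot, axis=0))
        self.cell_axis = np.delete(self.cell_axis, slot, axis=0)
        self.cell_rng.pop(slot)
        self.cell_seed.pop(slot)
        self.node_cell[self.node_cell > slot] -= 1
        # append daughters (their nodes go at the end of the flat arrays)
        slot_a = self.append_cell(ring_a, int_a, ss_a)
        slot_b = self.append_cell(ring_b, int_b, ss_b)
        self.adh_partner = None
        self._cross_cache = None
        return self.cell(slot_a), self.cell(slot_b), mother_id

    def copy(self) -> "TissueState":
        """Independent copy: arrays are copied and every per-cell RNG stream
        is deep-copied, so advancing the copy never perturbs the original
        (probe harnesses replay many M phases from one base tissue)."""
        import copy as _copy

        new = TissueState.__new__(TissueState)
        new.__dict__.update(self.__dict__)
        for name, val in self.__dict__.items():
            if isinstance(val, np.ndarray):
                setattr(new, name, val.copy())
        new.cell_rng = [_copy.deepcopy(g) for g in self.cell_rng]
        new.cell_seed = list(self.cell_seed)
        new._cross_cache = None
        return new

    # -- convenience geometry ---------------------------------------------
    def cell_centroids(self) -> np.ndarray:
        out = np.empty((self.n_cells, 2))
        for i in range(self.n_cells):
            s, nm = self.cell_start[i], self.cell_nm[i]
            out[i] = self.pos[s: s + nm].mean(axis=0)
        return out


def hex_centers(n: int, spacing: float) -> np.ndarray:
    """First ``n`` sites of a hexagonal spiral (center, then rings of 6k)."""
    pts = [np.zeros(2)]
    ring = 1
    while len(pts) < n:
        # walk the hexagonal ring: start at (ring, 0) direction-corner walk
        corner_dirs = [np.array([math.cos(a), math.sin(a)])
                       for a in (np.arange(6) * math.pi / 3 + 2 * math.pi / 3)]
        p = np.array([ring * spacing, 0.0])
        for d in corner_dirs:
            for _ in range(ring):
                pts.append(p.copy())
                p = p + d * spacing
                if len(pts) >= n:
                    break
            if len(pts) >= n:
                break
        ring += 1
    return np.array(pts[:n])


def initialize_tissue(n_cells: int, cfg, seed: int | None = None) -> TissueState:
    """Circular cells on a hexagonal-center layout, membrane nodes on a
    circle and internal nodes uniform in the interior; CP = 0, t = 0.

    ``cfg`` is a :class:`~episem.io.SimConfig`; its resolution factor sets
    node counts, the initial radius and the scaled parameter set.  Cells are
    laid out ``2 R0 + initial_gap`` apart: not touching (no adhesion yet) but
    within the attraction range that pulls the cluster into a sheet.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    seed = cfg.seed if seed is None else seed
    pp = cfg.effective_phase_params()
    ts = TissueState(pp, cfg.growth, n_internal=cfg.effective_n_internal(),
                     n_membrane=cfg.effective_n_membrane(), resolution=cfg.resolution)
    r0 = cfg.effective_initial_radius()
    spacing = 2.0 * r0 + cfg.initial_gap
    if spacing <= 2.0 * r0:
        raise ValueError("initial circles overlap")
    centers = hex_centers(n_cells, spacing)
    root = np.random.SeedSequence(seed)
    cell_seeds = root.spawn(n_cells)
    nm0 = cfg.effective_n_membrane()[0]
    ni0 = cfg.effective_n_internal()[0]
    th = 2.0 * math.pi * np.arange(nm0) / nm0
    circle = np.stack([np.cos(th), np.sin(th)], axis=1)
    for c, ss in zip(centers, cell_seeds):
        ring = c + r0 * circle
        r_int = np.random.default_rng(ss.spawn(1)[0])
        rr = 0.85 * r0 * np.sqrt(r_int.random(ni0))
        aa = 2.0 * math.pi * r_int.random(ni0)
        internal = c + np.stack([rr * np.cos(aa), rr * np.sin(aa)], axis=1)
        ts.append_cell(ring, internal, ss)
    ts.root_seed = seed
    return ts


@dataclass
class SimulationResult:
    """Output of :func:`run_simulation`."""

    tissue: TissueState
    snapshots: list  # list of (t, TissueState) pairs
    events: pd.DataFrame
    mr_records: pd.DataFrame
    n_steps: int
    aborted: str | None = None


class _MRTrack:
    __slots__ = ("t_entry", "a_inter", "r_inter", "p_entry", "peak_a", "peak_r", "peak_p")

    def __init__(self, t, a, r, p):
        self.t_entry = t
        self.a_inter = a
        self.r_inter = r
        self.p_entry = p
        self.peak_a = a
        self.peak_r = r
        self.peak_p = p


def _poly_area_perim(ring: np.ndarray) -> tuple[float, float]:
    x, y = ring[:, 0], ring[:, 1]
    a = 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    seg = np.roll(ring, -1, axis=0) - ring
    return float(a), float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))


def run_simulation(cfg, t_end: float, seed: int | None = None,
                   snapshot_every: float | None = None,
                   stop_at_cells: int | None = None,
                   n_cells: int = 7,
                   cycle_every: int = 5,
                   membrane_check_every: int = 2,
                   mr_every: int = 4,
                   ext_force: Callable | None = None,
                   tissue: TissueState | None = None) -> SimulationResult:
    """Run the full growth/division simulation.

    Parameters
    ----------
    cfg : SimConfig
    t_end : float
        Simulated end time (s).  With the package's time convention 60 s of
        simulation correspond to one developmental hour.
    seed : int, optional
        Overrides ``cfg.seed``.
    snapshot_every : float, optional
        Cadence (simulated s) at which tissue copies are stored; the initial
        state is always stored when set.
    stop_at_cells : int, optional
        Stop as soon as the cell count reaches this value.
    cycle_every : int
        Cycle bookkeeping (CP updates, insertions, mitosis entries,
        divisions) runs every this many integration steps; the per-round CP
        increment is scaled accordingly.  At the default time step a round
        spans 15 ms of simulated time, vanishingly small against the cycle.
    membrane_check_every, mr_every : int
        Cadence, in bookkeeping rounds, of the over-stretched-segment check
        and of the mitotic-rounding peak tracking.
    ext_force : callable(tissue, forces) -> None, optional
        Hook that may add external forces in place (used by the calibration
        harnesses); selects the unfused integration path.
    tissue : TissueState, optional
        Resume from this state instead of initializing a fresh one.

    Returns a :class:`SimulationResult`; an integrator abort is recorded in
    ``result.aborted`` with the last state preserved rather than raised.
    """
    ts = initialize_tissue(n_cells, cfg, seed) if tissue is None else tissue
    icfg = cfg.integrator
    growth = cfg.growth
    dt = icfg.dt
    snapshots: list = []
    events: list[dict] = []
    mr_tracks: dict[int, _MRTrack] = {}
    mr_rows: list[dict] = []
    next_snap = ts.t
    n_steps = 0
    aborted = None

    def _cell_geom(slot):
        s, nm = ts.cell_start[slot], ts.cell_nm[slot]
        ring = ts.pos[s: s + nm]
        a, p = _poly_area_perim(ring)
        rnd = 4.0 * math.pi * a / (p * p) if p > 0 else 0.0
        return a, rnd

    def _update_tracks(virial):
        for slot in np.flatnonzero(ts.cell_phase == 1):
            cid = int(ts.cell_id[slot])
            a, rnd = _cell_geom(slot)
            p = virial[slot] / (2.0 * a) if a > 0 else 0.0
            tr = mr_tracks.get(cid)
            if tr is None:
                mr_tracks[cid] = _MRTrack(ts.t, a, rnd, p)
            else:
                tr.peak_a = max(tr.peak_a, a)
                tr.peak_r = max(tr.peak_r, rnd)
                tr.peak_p = max(tr.peak_p, p)

    while True:
        if snapshot_every is not None and ts.t >= next_snap - 1e-9:
            snapshots.append((ts.t, ts.copy()))
            next_snap += snapshot_every
        if ts.t >= t_end - 1e-9:
            break
        if stop_at_cells is not None and ts.n_cells >= stop_at_cells:
            break
        P = ts.resolve_params()
        try:
            if ext_force is None:
                virial = dyn.step_tissue(ts, P, icfg)
            else:
                forces, virial = dyn.net_forces_and_virial(ts, P)
                ext_force(ts, forces)
                dyn.euler_step(ts, forces, icfg)
        except dyn.IntegratorInstability as exc:
            aborted = str(exc)
            events.append({"t": ts.t, "event": "abort", "cell_id": -1, "info": str(exc)})
            break
        n_steps += 1
        if n_steps % cycle_every:
            continue

        # ---- cycle bookkeeping (vectorized advance, per-cell events) ----
        dt_c = dt * cycle_every
        g = ts.cell_g0 * math.exp(-growth.k_g * (ts.t - dt_c))
        ts.cell_cp = np.minimum(1.0, ts.cell_cp + g * dt_c)
        # internal-node insertions
        target = np.minimum(
            ts.n_internal_max,
            ts.n_internal_start + np.floor(
                ts.cell_cp * (ts.n_internal_max - ts.n_internal_start) + 1e-12).astype(int),
        )
        for slot in np.flatnonzero(ts.cell_ni < target):
            cell = ts.cell(slot)
            while cell.n_internal < target[slot]:
                cc.insert_internal_node(cell)
        # mitosis entries
        entry = (ts.cell_phase == 0) & (ts.cell_cp >= 1.0 - g * growth.T_mit)
        for slot in np.flatnonzero(entry):
            cp_entry = min(1.0 - g[slot] * growth.T_mit, ts.cell_cp[slot])
            cc.enter_mitosis(ts.cell(slot), ts.t, growth, cp_mit=cp_entry)
            events.append({"t": ts.t, "event": "mitosis_entry",
                           "cell_id": int(ts.cell_id[slot]), "info": ""})
        rounds = n_steps // cycle_every
        # constitutive containment of cytoplasm nodes (rare rescue)
        dyn._rescue_internal(ts.pos, ts.cell_start, ts.cell_nm, ts.cell_ni)
        # mitotic-rounding tracking
        if mr_every and rounds % mr_every == 0:
            _update_tracks(virial)
        # divisions
        due = np.flatnonzero((ts.cell_cp >= 1.0) & (ts.cell_phase == 1))
        if len(due):
            _update_tracks(virial)  # final peak update before any surgery
        for slot in sorted(due, reverse=True):
            cell = ts.cell(slot)
            cid = cell.id
            axis = ts.cell_axis[slot].copy()
            try:
                da, db, mother_id = cc.divide_cell(cell)
            except cc.DivisionAborted as exc:
                events.append({"t": ts.t, "event": "division_retry",
                               "cell_id": cid, "info": str(exc)})
                continue
            events.append({"t": ts.t, "event": "division", "cell_id": mother_id,
                           "info": f"daughters={da.id},{db.id};"
                                   f"axis_angle={math.atan2(axis[1], axis[0]):.6f}"})
            tr = mr_tracks.pop(mother_id, None)
            if tr is not None and tr.a_inter > 0:
                mr_rows.append({
                    "cell_id": mother_id, "t_entry": tr.t_entry, "t_division": ts.t,
                    "A_inter": tr.a_inter, "A_mit": tr.peak_a,
                    "A_ratio": tr.peak_a / tr.a_inter,
                    "R_inter": tr.r_inter, "R_mit": tr.peak_r,
                    "R_norm": tr.peak_r / tr.r_inter if tr.r_inter > 0 else np.nan,
                    "P_entry": tr.p_entry, "P_peak": tr.peak_p,
                    "delta_P": tr.peak_p - tr.p_entry,
                })
        # membrane-node insertion for over-stretched segments
        if membrane_check_every and rounds % membrane_check_every == 0:
            w = ts.mitotic_weight()
            rest = (1 - w) * ts.p_inter[dyn.L_STIFF] + w * ts.p_mit[dyn.L_STIFF]
            flagged = dyn._overstretched_cells(ts.pos, ts.cell_start, ts.cell_nm,
                                               rest, 2.0)
            for slot in np.flatnonzero(flagged):
                cc.insert_membrane_node(ts.cell(slot), rest_length=float(rest[slot]))

    ev = pd.DataFrame(events, columns=["t", "event", "cell_id", "info"])
    mr = pd.DataFrame(mr_rows, columns=[
        "cell_id", "t_entry", "t_division", "A_inter", "A_mit", "A_ratio",
        "R_inter", "R_mit", "R_norm", "P_entry", "P_peak", "delta_P"])
    return SimulationResult(tissue=ts, snapshots=snapshots, events=ev,
                            mr_records=mr, n_steps=n_steps, aborted=aborted)


def run_resilient(cfg, t_end: float, seed: int | None = None,
                  recovery_time: float = 3.0, max_recoveries: int = 200,
                  n_cells: int = 7, tissue: TissueState | None = None,
                  **kwargs) -> SimulationResult:
    """:func:`run_simulation` with explicit abort recovery.

    The integrator guard rejects (never applies) a step whose displacement
    is too large, so the state at an abort is intact.  This driver then
    integrates a short recovery window at a halved time step (halving again
    if needed) before returning to the nominal step.  Every recovery is a
    logged ``recovery`` event; the trajectory remains fully deterministic
    for a given (config, seed).
    """
    from dataclasses import replace

    ts = initialize_tissue(n_cells, cfg, seed) if tissue is None else tissue
    parts: list[SimulationResult] = []
    recoveries = 0
    while True:
        res = run_simulation(cfg, t_end=t_end, tissue=ts, **kwargs)
        parts.append(res)
        ts = res.tissue
        if res.aborted is None or recoveries >= max_recoveries:
            break
        stop = kwargs.get("stop_at_cells")
        if ts.t >= t_end - 1e-9 or (stop is not None and ts.n_cells >= stop):
            break
        # halve the step until a short recovery window integrates cleanly
        dt = cfg.integrator.dt
        for _ in range(4):
            dt *= 0.5
            rcfg = replace(cfg, integrator=replace(cfg.integrator, dt=dt))
            rres = run_simulation(rcfg, t_end=min(t_end, ts.t + recovery_time),
                                  tissue=ts, **kwargs)
            parts.append(rres)
            ts = rres.tissue
            if rres.aborted is None:
                break
        recoveries += 1
        if rres.aborted is not None:
            break
    ev_parts = [p.events for p in parts if len(p.events)]
    events = (pd.concat(ev_parts, ignore_index=True) if ev_parts
              else parts[0].events)
    mr_parts = [p.mr_records for p in parts if len(p.mr_records)]
    mr = (pd.concat(mr_parts, ignore_index=True) if mr_parts
          else parts[0].mr_records)
    snaps = [s for p in parts for s in p.snapshots]
    return SimulationResult(tissue=ts, snapshots=snaps, events=events,
                            mr_records=mr,
                            n_steps=sum(p.n_steps for p in parts),
                            aborted=parts[-1].aborted)
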