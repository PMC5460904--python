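"""Overdamped equations of motion and their forward-Euler integration.

Nodes move in the overdamped regime: ``eta dx/dt = F(x)`` where ``F`` is the
negative gradient of the total potential energy.  Internal nodes feel the MI
(own membrane) and II (own internal) Morse families; membrane nodes feel MI
(own internal), MMS (cortical springs along the ring), MMD (membranes of
other cells) and at most one adhesion spring.  Positions advance by explicit
forward Euler, ``x(t+dt) = x(t) + F dt / eta``.

Cross-cell interactions are found through a uniform spatial hash rebuilt
every step; intra-cell interactions are evaluated directly per cell (cells
hold at most a few hundred nodes).  The force kernel also accumulates the
per-cell pair virial ``sum r_ij . f_ij`` over the II and MI families, which
the metrics module turns into an intracellular pressure estimate.

There is no randomness anywhere in this module: a step is a deterministic
function of positions and parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from numba import njit

__all__ = [
    "IntegratorConfig",
    "IntegratorInstability",
    "neighbor_candidates",
    "net_forces",
    "net_forces_and_virial",
    "euler_step",
]

# Indices into the flat per-cell parameter vector (mechanics.PARAM_NAMES).
II_U, II_W, II_XI, II_GA, II_L = 0, 1, 2, 3, 4
MI_U, MI_W, MI_XI, MI_GA, MI_L = 5, 6, 7, 8, 9
MMD_U, MMD_W, MMD_XI, MMD_GA, MMD_L = 10, 11, 12, 13, 14
K_STIFF, L_STIFF, K_TOR = 15, 16, 17
K_ADH, ADH_LMIN, ADH_LMAX = 18, 19, 20

_CAP = 0.01  # Morse force frozen below this fraction of xi


@dataclass(frozen=True)
class IntegratorConfig:
    """Forward-Euler integrator settings.

    Parameters
    ----------
    eta : float
        Damping coefficient (nN.s/um).
    dt : float
        Time step (s).
    hash_cell_size : float
        Spatial-hash bin width (um); must cover the largest cross-cell
        interaction cutoff.
    max_step_fraction : float
        Abort threshold: the largest per-node displacement allowed in one
        step, expressed as a multiple of the adhesion rest length ``L_min``.
    """

    eta: float = 36.0
    dt: float = 0.003
    hash_cell_size: float = 0.9
    max_step_fraction: float = 0.5

    def __post_init__(self) -> None:
        if self.eta <= 0 or self.dt <= 0 or self.hash_cell_size <= 0:
            raise ValueError("eta, dt and hash_cell_size must be positive")


class IntegratorInstability(RuntimeError):
    """Raised when a step would move a node too far (instability signal)."""


# ---------------------------------------------------------------------------
# Spatial hash
# ---------------------------------------------------------------------------


@njit(cache=True)
def _build_grid(pos, binsize):
    n = pos.shape[0]
    xmin, ymin = pos[0, 0], pos[0, 1]
    xmax, ymax = xmin, ymin
    for i in range(n):
        if pos[i, 0] < xmin:
            xmin = pos[i, 0]
        if pos[i, 0] > xmax:
            xmax = pos[i, 0]
        if pos[i, 1] < ymin:
            ymin = pos[i, 1]
        if pos[i, 1] > ymax:
            ymax = pos[i, 1]
    nx = int((xmax - xmin) / binsize) + 1
    ny = int((ymax - ymin) / binsize) + 1
    nbins = nx * ny
    binned = np.empty(n, dtype=np.int64)
    count = np.zeros(nbins + 1, dtype=np.int64)
    for i in range(n):
        bx = int((pos[i, 0] - xmin) / binsize)
        by = int((pos[i, 1] - ymin) / binsize)
        b = bx + by * nx
        binned[i] = b
        count[b + 1] += 1
    for b in range(nbins):
        count[b + 1] += count[b]
    order = np.empty(n, dtype=np.int64)
    cursor = count[:-1].copy()
    for i in range(n):
        b = binned[i]
        order[cursor[b]] = i
        cursor[b] += 1
    return order, count, nx, ny, xmin, ymin


@njit(cache=True)
def _candidate_pairs(pos, binsize):
    order, start, nx, ny, xmin, ymin = _build_grid(pos, binsize)
    n = pos.shape[0]
    cap = max(16, 32 * n)
    out = np.empty((cap, 2), dtype=np.int64)
    m = 0
    for i in range(n):
        bx = int((pos[i, 0] - xmin) / binsize)
        by = int((pos[i, 1] - ymin) / binsize)
        for dy in range(-1, 2):
            yy = by + dy
            if yy < 0 or yy >= ny:
                continue
            for dx in range(-1, 2):
                xx = bx + dx
                if xx < 0 or xx >= nx:
                    continue
                b = xx + yy * nx
                for k in range(start[b], start[b + 1]):
                    j = order[k]
                    if j <= i:
                        continue
                    if m >= cap:
                        # grow
                        cap2 = cap * 2
                        out2 = np.empty((cap2, 2), dtype=np.int64)
                        out2[:m] = out[:m]
                        out = out2
                        cap = cap2
                    out[m, 0] = i
                    out[m, 1] = j
                    m += 1
    return out[:m]


def neighbor_candidates(positions: np.ndarray, cutoff: float) -> np.ndarray:
    """Candidate interaction pairs from a uniform grid of bin width
    ``cutoff``.

    Guarantees: every pair within ``cutoff`` is present; no returned pair is
    farther apart than ``cutoff * sqrt(8)`` (the diagonal span of the 3x3 bin
    neighborhood).  Returns an (m, 2) int array with ``i < j``.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    positions = np.ascontiguousarray(positions, dtype=np.float64)
    if len(positions) < 2:
        return np.empty((0, 2), dtype=np.int64)
    return _candidate_pairs(positions, cutoff)


# ---------------------------------------------------------------------------
# Adhesion pairing (kernel version of mechanics.pair_membranes)
# ---------------------------------------------------------------------------


@njit(cache=True)
def _nearest_foreign(pos, cell_of, L_max):
    n = pos.shape[0]
    nn = np.full(n, -1, dtype=np.int64)
    nd = np.full(n, np.inf)
    if n == 0:
        return nn, nd
    order, start, nx, ny, xmin, ymin = _build_grid(pos, L_max)
    for i in range(n):
        bx = int((pos[i, 0] - xmin) / L_max)
        by = int((pos[i, 1] - ymin) / L_max)
        best = -1
        bestd = np.inf
        for dy in range(-1, 2):
            yy = by + dy
            if yy < 0 or yy >= ny:
                continue
            for dx in range(-1, 2):
                xx = bx + dx
                if xx < 0 or xx >= nx:
                    continue
                b = xx + yy * nx
                for k in range(start[b], start[b + 1]):
                    j = order[k]
                    if j == i or cell_of[j] == cell_of[i]:
                        continue
                    ddx = pos[i, 0] - pos[j, 0]
                    ddy = pos[i, 1] - pos[j, 1]
                    d = math.sqrt(ddx * ddx + ddy * ddy)
                    if d <= L_max and (d < bestd - 1e-15 or (abs(d - bestd) <= 1e-15 and j < best)):
                        best = j
                        bestd = d
        nn[i] = best
        nd[i] = bestd
    return nn, nd


@njit(cache=True)
def _greedy_accept(order, cand_i, cand_j, partner):
    for k in order:
        i = cand_i[k]
        j = cand_j[k]
        if partner[i] < 0 and partner[j] < 0:
            partner[i] = j
            partner[j] = i


def pair_membranes_fast(pos_mem: np.ndarray, cell_of: np.ndarray, L_max: float) -> np.ndarray:
    """Grid-accelerated version of :func:`episem.mechanics.pair_membranes`
    (identical pairing policy; used by the simulation loop)."""
    pos_mem = np.ascontiguousarray(pos_mem, dtype=np.float64)
    cell_of = np.ascontiguousarray(cell_of, dtype=np.int64)
    n = len(pos_mem)
    partner = np.full(n, -1, dtype=np.int64)
    if n == 0:
        return partner
    nn, nd = _nearest_foreign(pos_mem, cell_of, L_max)
    has = nn >= 0
    cand_i = np.flatnonzero(has)
    cand_j = nn[has]
    cand_d = nd[has]
    order = np.lexsort((cand_j, cand_i, cand_d))
    _greedy_accept(order, cand_i, cand_j, partner)
    return partner


# ---------------------------------------------------------------------------
# Force kernel
# ---------------------------------------------------------------------------


@njit(cache=True)
def _derived_params(P):
    """Per-cell derived constants for the three Morse families: for each of
    II, MI, MMD the tuple (U/xi, 1/xi, W/gamma, 1/gamma, L^2, cap radius)."""
    C = P.shape[0]
    D = np.empty((C, 18))
    for c in range(C):
        for fam in range(3):
            b = 5 * fam
            o = 6 * fam
            U, W, xi, ga, L = P[c, b], P[c, b + 1], P[c, b + 2], P[c, b + 3], P[c, b + 4]
            D[c, o] = U / xi
            D[c, o + 1] = 1.0 / xi
            D[c, o + 2] = W / ga if ga > 0.0 else 0.0
            D[c, o + 3] = 1.0 / ga if ga > 0.0 else 0.0
            D[c, o + 4] = L * L
            D[c, o + 5] = _CAP * xi
    return D


@njit(cache=True, inline="always")
def _morse_fast(r2, Uxi, invxi, Wga, invga, L2, caplo):
    """Radial Morse force from squared distance; returns (f, r)."""
    if r2 > L2:
        return 0.0, 0.0
    r = math.sqrt(r2)
    rc = r if r > caplo else caplo
    f = Uxi * math.exp(-rc * invxi)
    if Wga != 0.0:
        f -= Wga * math.exp(-rc * invga)
    return f, r


@njit(cache=True, inline="always")
def _seg_closest(px, py, ax, ay, bx, by):
    """Closest point of segment ab to p: returns (dx, dy, d2, t) with
    (dx, dy) = p - closest."""
    ex = bx - ax
    ey = by - ay
    ee = ex * ex + ey * ey
    if ee > 0.0:
        t = ((px - ax) * ex + (py - ay) * ey) / ee
        if t < 0.0:
            t = 0.0
        elif t > 1.0:
            t = 1.0
    else:
        t = 0.0
    cx = ax + t * ex
    cy = ay + t * ey
    dx = px - cx
    dy = py - cy
    return dx, dy, dx * dx + dy * dy, t


@njit(cache=True)
def _build_pairs(mpos, mcell, rlist, base_reach, adj):
    """Verlet candidate list: cross-cell membrane pairs, as (i, j) with
    i < j.  ``rlist`` bounds the grid bin; a pair is kept when within
    ``base_reach + max(adj_i, adj_j)/2`` (per-node allowance for the longer
    adjacent membrane segment each node can mediate)."""
    n = mpos.shape[0]
    cap = max(16, 16 * n)
    pi = np.empty(cap, dtype=np.int64)
    pj = np.empty(cap, dtype=np.int64)
    m = 0
    if n < 2:
        return pi[:0], pj[:0]
    order, start, nx, ny, xmin, ymin = _build_grid(mpos, rlist)
    for a in range(n):
        bx = int((mpos[a, 0] - xmin) / rlist)
        by = int((mpos[a, 1] - ymin) / rlist)
        for oy in range(-1, 2):
            yy = by + oy
            if yy < 0 or yy >= ny:
                continue
            for ox in range(-1, 2):
                xx = bx + ox
                if xx < 0 or xx >= nx:
                    continue
                bb = xx + yy * nx
                for k in range(start[bb], start[bb + 1]):
                    b = order[k]
                    if b <= a or mcell[b] == mcell[a]:
                        continue
                    dx = mpos[a, 0] - mpos[b, 0]
                    dy = mpos[a, 1] - mpos[b, 1]
                    half = adj[a] if adj[a] > adj[b] else adj[b]
                    rr = base_reach + 0.5 * half
                    if dx * dx + dy * dy > rr * rr:
                        continue
                    if m >= cap:
                        cap2 = cap * 2
                        pi2 = np.empty(cap2, dtype=np.int64)
                        pj2 = np.empty(cap2, dtype=np.int64)
                        pi2[:m] = pi[:m]
                        pj2[:m] = pj[:m]
                        pi, pj, cap = pi2, pj2, cap2
                    pi[m] = a
                    pj[m] = b
                    m += 1
    return pi[:m], pj[:m]


@njit(cache=True)
def _compute(pos, node_cell, cell_start, cell_nm, cell_ni, P, mem_idx,
             pi, pj, L_max, dt_over_eta, disp_limit, apply_update):
    """Fused pass: adhesion pairing, every force family, per-cell II+MI
    virial, and (optionally) the guarded Euler update.

    ``pi, pj`` is the cached cross-cell candidate pair list (membrane-local
    indices into ``mem_idx``).  Returns
    (forces, partner_g, virial, max_disp, applied).
    """
    n = pos.shape[0]
    ncell = cell_start.shape[0]
    D = _derived_params(P)
    forces = np.zeros((n, 2))
    virial = np.zeros(ncell)
    nmem = mem_idx.shape[0]
    npairs = pi.shape[0]
    partner_g = np.full(n, -1, dtype=np.int64)

    mpos = np.empty((nmem, 2))
    for a in range(nmem):
        mpos[a, 0] = pos[mem_idx[a], 0]
        mpos[a, 1] = pos[mem_idx[a], 1]

    if npairs > 0:
        # ---- adhesion pairing: mutual-nearest within reach, greedy ------
        lmax2 = L_max * L_max
        nn = np.full(nmem, -1, dtype=np.int64)
        nd = np.full(nmem, np.inf)
        d2s = np.empty(npairs)
        for k in range(npairs):
            a = pi[k]
            b = pj[k]
            dx = mpos[a, 0] - mpos[b, 0]
            dy = mpos[a, 1] - mpos[b, 1]
            d2 = dx * dx + dy * dy
            d2s[k] = d2
            if d2 <= lmax2:
                if d2 < nd[a] or (d2 == nd[a] and b < nn[a]):
                    nd[a] = d2
                    nn[a] = b
                if d2 < nd[b] or (d2 == nd[b] and a < nn[b]):
                    nd[b] = d2
                    nn[b] = a
        # shortest-bond-first greedy acceptance via a fine counting sort on
        # squared distance (bucket width ~1e-4 um; ties fall back to node
        # order, matching the reference pairing policy)
        nbuck = 4096
        scale = nbuck / lmax2
        count = np.zeros(nbuck + 1, dtype=np.int64)
        ncand = 0
        for a in range(nmem):
            if nn[a] >= 0:
                b = int(nd[a] * scale)
                if b >= nbuck:
                    b = nbuck - 1
                count[b + 1] += 1
                ncand += 1
        for b in range(nbuck):
            count[b + 1] += count[b]
        cursor = count[:-1].copy()
        ordered = np.empty(ncand, dtype=np.int64)
        for a in range(nmem):
            if nn[a] >= 0:
                b = int(nd[a] * scale)
                if b >= nbuck:
                    b = nbuck - 1
                ordered[cursor[b]] = a
                cursor[b] += 1
        pl = np.full(nmem, -1, dtype=np.int64)
        for k in range(ncand):
            i = ordered[k]
            j = nn[i]
            if pl[i] < 0 and pl[j] < 0:
                pl[i] = j
                pl[j] = i
        for a in range(nmem):
            if pl[a] >= 0:
                partner_g[mem_idx[a]] = mem_idx[pl[a]]

        # per-membrane-node rejection radius: volume-exclusion cutoff plus
        # the longer adjacent segment (a node can only mediate contacts of
        # its own two segments)
        cutmax = 0.0
        for c in range(ncell):
            if D[c, 16] > cutmax:
                cutmax = D[c, 16]
        cutmax = math.sqrt(cutmax)
        maxadj = np.empty(nmem)
        for a in range(nmem):
            j = mem_idx[a]
            cq = node_cell[j]
            sq = cell_start[cq]
            nmq = cell_nm[cq]
            lq = j - sq
            jn = sq + ((lq + 1) % nmq)
            jp = sq + ((lq - 1) % nmq)
            d1 = (pos[j, 0] - pos[jn, 0]) ** 2 + (pos[j, 1] - pos[jn, 1]) ** 2
            d2_ = (pos[j, 0] - pos[jp, 0]) ** 2 + (pos[j, 1] - pos[jp, 1]) ** 2
            d1 = d1 if d1 > d2_ else d2_
            # a node mediates only its own two segments, whose every point
            # lies within half the segment length of it
            r_ = cutmax + 0.5 * math.sqrt(d1)
            maxadj[a] = r_ * r_

        # ---- cross-cell forces: adhesion springs (node-node bonds) and
        # volume exclusion of the *membrane polyline* (node-segment Morse;
        # a node-node wall turns porous once the node spacing exceeds the
        # repulsion range).  Each foreign segment is evaluated through its
        # endpoint closer to the node, so it contributes exactly once.
        for k in range(npairs):
            if d2s[k] > maxadj[pi[k]] and d2s[k] > maxadj[pj[k]] and d2s[k] > lmax2:
                continue
            i = mem_idx[pi[k]]
            j = mem_idx[pj[k]]
            ci = node_cell[i]
            cj = node_cell[j]
            r2 = d2s[k]
            if partner_g[i] == j:
                lmin = 0.5 * (P[ci, ADH_LMIN] + P[cj, ADH_LMIN])
                lmaxp = 0.5 * (P[ci, ADH_LMAX] + P[cj, ADH_LMAX])
                r = math.sqrt(r2)
                if lmin <= r <= lmaxp and r > 1e-12:
                    kadh = 0.5 * (P[ci, K_ADH] + P[cj, K_ADH])
                    fr = -kadh * (r - lmin) / r  # attractive
                    rx = pos[i, 0] - pos[j, 0]
                    ry = pos[i, 1] - pos[j, 1]
                    forces[i, 0] += fr * rx
                    forces[i, 1] += fr * ry
                    forces[j, 0] -= fr * rx
                    forces[j, 1] -= fr * ry
            # volume exclusion: i vs segments adjacent to j, and j vs
            # segments adjacent to i
            Uxi = 0.5 * (D[ci, 12] + D[cj, 12])
            invxi = 0.5 * (D[ci, 13] + D[cj, 13])
            Wga = 0.5 * (D[ci, 14] + D[cj, 14])
            invga = 0.5 * (D[ci, 15] + D[cj, 15])
            L2 = 0.25 * (math.sqrt(D[ci, 16]) + math.sqrt(D[cj, 16])) ** 2
            caplo = 0.5 * (D[ci, 17] + D[cj, 17])
            for direction in range(2):
                if direction == 0:
                    p_ = i
                    q = j
                    cq = cj
                else:
                    p_ = j
                    q = i
                    cq = ci
                sq = cell_start[cq]
                nmq = cell_nm[cq]
                lq = q - sq
                qn = sq + ((lq + 1) % nmq)
                qp = sq + ((lq - 1) % nmq)
                px = pos[p_, 0]
                py = pos[p_, 1]
                d2n = (px - pos[qn, 0]) ** 2 + (py - pos[qn, 1]) ** 2
                d2p = (px - pos[qp, 0]) ** 2 + (py - pos[qp, 1]) ** 2
                d2q = (px - pos[q, 0]) ** 2 + (py - pos[q, 1]) ** 2
                for segsel in range(2):
                    if segsel == 0:
                        if d2q > d2n:  # next segment owned by closer end
                            continue
                        ua, ub = q, qn
                    else:
                        if d2q >= d2p:  # previous segment: strict ownership
                            continue
                        ua, ub = qp, q
                    dxs, dys, ds2, t = _seg_closest(
                        px, py, pos[ua, 0], pos[ua, 1], pos[ub, 0], pos[ub, 1])
                    f, r = _morse_fast(ds2, Uxi, invxi, Wga, invga, L2, caplo)
                    if f == 0.0:
                        continue
                    if r < 1e-12:
                        fx = f
                        fy = 0.0
                    else:
                        fx = f * dxs / r
                        fy = f * dys / r
                    forces[p_, 0] += fx
                    forces[p_, 1] += fy
                    forces[ua, 0] -= (1.0 - t) * fx
                    forces[ua, 1] -= (1.0 - t) * fy
                    forces[ub, 0] -= t * fx
                    forces[ub, 1] -= t * fy

    # ---- intra-cell families ------------------------------------------
    for c in range(ncell):
        s = cell_start[c]
        nm = cell_nm[c]
        ni = cell_ni[c]
        k_st = P[c, K_STIFF]
        L_st = P[c, L_STIFF]
        k_to = P[c, K_TOR]
        shoe = 0.0
        for a in range(nm):
            j = s + a
            jn = s + ((a + 1) % nm)
            shoe += pos[j, 0] * pos[jn, 1] - pos[jn, 0] * pos[j, 1]
            dx = pos[jn, 0] - pos[j, 0]
            dy = pos[jn, 1] - pos[j, 1]
            ell = math.sqrt(dx * dx + dy * dy)
            if ell < 1e-12:
                continue
            f = k_st * (ell - L_st) / ell
            forces[j, 0] += f * dx
            forces[j, 1] += f * dy
            forces[jn, 0] -= f * dx
            forces[jn, 1] -= f * dy
        psi0 = 2.0 * math.pi / nm
        if shoe < 0.0:
            psi0 = -psi0
        for a in range(nm):
            jm = s + ((a - 1) % nm)
            j = s + a
            jp = s + ((a + 1) % nm)
            e1x = pos[j, 0] - pos[jm, 0]
            e1y = pos[j, 1] - pos[jm, 1]
            e2x = pos[jp, 0] - pos[j, 0]
            e2y = pos[jp, 1] - pos[j, 1]
            cr = e1x * e2y - e1y * e2x
            dt_ = e1x * e2x + e1y * e2y
            denom = cr * cr + dt_ * dt_
            if denom < 1e-24:
                continue
            psi = math.atan2(cr, dt_)
            k = k_to * (psi - psi0) / denom
            g1x = k * (dt_ * e2y - cr * e2x)
            g1y = k * (-dt_ * e2x - cr * e2y)
            g2x = k * (-dt_ * e1y - cr * e1x)
            g2y = k * (dt_ * e1x - cr * e1y)
            forces[jm, 0] += g1x
            forces[jm, 1] += g1y
            forces[j, 0] -= g1x - g2x
            forces[j, 1] -= g1y - g2y
            forces[jp, 0] -= g2x
            forces[jp, 1] -= g2y
        # II pairs (internal-internal)
        for a in range(ni):
            i = s + nm + a
            for b2 in range(a + 1, ni):
                j = s + nm + b2
                dx = pos[i, 0] - pos[j, 0]
                dy = pos[i, 1] - pos[j, 1]
                f, r = _morse_fast(dx * dx + dy * dy, D[c, 0], D[c, 1],
                                   D[c, 2], D[c, 3], D[c, 4], D[c, 5])
                if f == 0.0:
                    continue
                if r < 1e-12:
                    forces[i, 0] += f
                    forces[j, 0] -= f
                else:
                    fr = f / r
                    forces[i, 0] += fr * dx
                    forces[i, 1] += fr * dy
                    forces[j, 0] -= fr * dx
                    forces[j, 1] -= fr * dy
                virial[c] += r * f
        # MI: internal nodes vs own membrane *segments* (watertight wall)
        for a in range(ni):
            i = s + nm + a
            px = pos[i, 0]
            py = pos[i, 1]
            for b2 in range(nm):
                j = s + b2
                jn = s + ((b2 + 1) % nm)
                dxs, dys, ds2, t = _seg_closest(
                    px, py, pos[j, 0], pos[j, 1], pos[jn, 0], pos[jn, 1])
                f, r = _morse_fast(ds2, D[c, 6], D[c, 7],
                                   D[c, 8], D[c, 9], D[c, 10], D[c, 11])
                if f == 0.0:
                    continue
                if r < 1e-12:
                    fx = f
                    fy = 0.0
                else:
                    fx = f * dxs / r
                    fy = f * dys / r
                forces[i, 0] += fx
                forces[i, 1] += fy
                forces[j, 0] -= (1.0 - t) * fx
                forces[j, 1] -= (1.0 - t) * fy
                forces[jn, 0] -= t * fx
                forces[jn, 1] -= t * fy
                virial[c] += r * f

    # ---- guarded Euler update -----------------------------------------
    max_disp = 0.0
    for i in range(n):
        dx = forces[i, 0] * dt_over_eta
        dy = forces[i, 1] * dt_over_eta
        d = math.sqrt(dx * dx + dy * dy)
        if d > max_disp or not math.isfinite(d):
            max_disp = d
    applied = False
    if apply_update and math.isfinite(max_disp) and max_disp <= disp_limit:
        applied = True
        for i in range(n):
            pos[i, 0] += forces[i, 0] * dt_over_eta
            pos[i, 1] += forces[i, 1] * dt_over_eta
    return forces, partner_g, virial, max_disp, applied


# Verlet-list skin (um): candidate pairs are collected out to reach + skin
# and reused until accumulated per-step displacements could span skin/2.
NEIGHBOR_SKIN = 0.35


class _CrossCache:
    __slots__ = ("pi", "pj", "n_nodes", "drift")

    def __init__(self, pi, pj, n_nodes):
        self.pi = pi
        self.pj = pj
        self.n_nodes = n_nodes
        self.drift = 0.0


@njit(cache=True)
def _adjacent_segment_lengths(pos, cell_start, cell_nm, mem_idx):
    """Per membrane node: length of its longer adjacent ring segment."""
    nmem = mem_idx.shape[0]
    adj = np.empty(nmem)
    # membrane nodes are stored ring-contiguous per cell, in mem_idx order
    k = 0
    ncell = cell_start.shape[0]
    for c in range(ncell):
        s = cell_start[c]
        nm = cell_nm[c]
        for a in range(nm):
            j = s + a
            jn = s + ((a + 1) % nm)
            jp = s + ((a - 1) % nm)
            d1 = math.sqrt((pos[j, 0] - pos[jn, 0]) ** 2 + (pos[j, 1] - pos[jn, 1]) ** 2)
            d2 = math.sqrt((pos[j, 0] - pos[jp, 0]) ** 2 + (pos[j, 1] - pos[jp, 1]) ** 2)
            adj[k] = d1 if d1 > d2 else d2
            k += 1
    return adj


def _get_pairs(tissue, P, rebuild_only_if_stale=True):
    mem_idx = tissue.membrane_indices()
    L_max = float(np.max(P[:, ADH_LMAX])) if len(P) else 0.4
    # the list must surface every node-segment contact through the
    # segment's closer endpoint: cutoff + half the longer adjacent segment,
    # plus skin margins for node motion and segment stretching in the window
    cutoff = max(float(np.max(P[:, MMD_L])) if len(P) else 0.4, L_max)
    cache = getattr(tissue, "_cross_cache", None)
    stale = (cache is None or cache.n_nodes != tissue.n_nodes
             or cache.drift > 0.5 * NEIGHBOR_SKIN)
    if stale or not rebuild_only_if_stale:
        mpos = np.ascontiguousarray(tissue.pos[mem_idx])
        mcell = np.ascontiguousarray(tissue.node_cell[mem_idx])
        adj = _adjacent_segment_lengths(tissue.pos, tissue.cell_start,
                                        tissue.cell_nm, mem_idx)
        base = cutoff + 1.5 * NEIGHBOR_SKIN
        rlist = base + 0.5 * (float(np.max(adj)) if len(adj) else 0.0)
        pi, pj = _build_pairs(mpos, mcell, rlist, base, adj)
        cache = _CrossCache(pi, pj, tissue.n_nodes)
        tissue._cross_cache = cache
    return mem_idx, L_max, cache


def step_tissue(tissue, params: np.ndarray, cfg: IntegratorConfig) -> np.ndarray:
    """Fused pairing + forces + Euler update used by the simulation loop.
    Returns the per-cell II+MI virial; raises on a guard violation."""
    mem_idx, L_max, cache = _get_pairs(tissue, params)
    limit = cfg.max_step_fraction * tissue.adhesion_L_min()
    _, partner_g, virial, max_disp, applied = _compute(
        tissue.pos, tissue.node_cell, tissue.cell_start, tissue.cell_nm,
        tissue.cell_ni, params, mem_idx, cache.pi, cache.pj,
        L_max, cfg.dt / cfg.eta, limit, True)
    tissue.adh_partner = partner_g
    if not applied:
        raise IntegratorInstability(
            f"max displacement {max_disp:.4g} um exceeds {limit:.4g} um at "
            f"t={tissue.t:.4g}s; reduce dt or check parameters")
    tissue.t += cfg.dt
    cache.drift += max_disp
    return virial


def net_forces_and_virial(tissue, params: np.ndarray | None = None):
    """Forces on every node and the per-cell II+MI pair virial.

    Parameters
    ----------
    tissue : TissueState
    params : (n_cells, 21) array, optional
        Per-cell resolved parameter matrix; defaults to the tissue's current
        phase-resolved parameters.

    Returns
    -------
    forces : (n_nodes, 2) array
    virial : (n_cells,) array of ``sum r_ij . f_ij`` over intra-cell Morse
        pairs (repulsion counts positive).
    """
    P = tissue.resolve_params() if params is None else np.asarray(params, dtype=float)
    mem_idx, L_max, cache = _get_pairs(tissue, P, rebuild_only_if_stale=False)
    forces, partner_g, virial, _, _ = _compute(
        tissue.pos, tissue.node_cell, tissue.cell_start, tissue.cell_nm,
        tissue.cell_ni, P, mem_idx, cache.pi, cache.pj, L_max, 0.0, 0.0, False)
    tissue.adh_partner = partner_g
    return forces, virial


@njit(cache=True)
def _rescue_internal(pos, cell_start, cell_nm, cell_ni):
    """Constitutive containment: any internal node found outside its own
    membrane ring (crossing-number test) is pulled halfway toward the ring
    centroid until inside.  The wall potentials make this rare — it fires
    mainly when a contracting post-division ring squeezes a node through
    the capped soft core.  Returns the number of rescued nodes."""
    ncell = cell_start.shape[0]
    rescued = 0
    for c in range(ncell):
        s = cell_start[c]
        nm = cell_nm[c]
        ni = cell_ni[c]
        if nm < 3 or ni == 0:
            continue
        cx = 0.0
        cy = 0.0
        for a in range(nm):
            cx += pos[s + a, 0]
            cy += pos[s + a, 1]
        cx /= nm
        cy /= nm
        for b in range(ni):
            i = s + nm + b
            for _ in range(10):
                px = pos[i, 0]
                py = pos[i, 1]
                inside = False
                for a in range(nm):
                    j = s + a
                    jn = s + ((a + 1) % nm)
                    y1 = pos[j, 1]
                    y2 = pos[jn, 1]
                    if (y1 > py) != (y2 > py):
                        xint = pos[j, 0] + (py - y1) / (y2 - y1) * (pos[jn, 0] - pos[j, 0])
                        if px < xint:
                            inside = not inside
                if inside:
                    break
                pos[i, 0] = 0.5 * (px + cx)
                pos[i, 1] = 0.5 * (py + cy)
                if _ == 0:
                    rescued += 1
    return rescued


@njit(cache=True)
def _overstretched_cells(pos, cell_start, cell_nm, rest_len, factor):
    """Flags cells having any ring segment longer than factor * rest_len."""
    ncell = cell_start.shape[0]
    out = np.zeros(ncell, dtype=np.uint8)
    for c in range(ncell):
        s = cell_start[c]
        nm = cell_nm[c]
        lim2 = (factor * rest_len[c]) ** 2
        for a in range(nm):
            j = s + a
            jn = s + ((a + 1) % nm)
            dx = pos[jn, 0] - pos[j, 0]
            dy = pos[jn, 1] - pos[j, 1]
            if dx * dx + dy * dy > lim2:
                out[c] = 1
                break
    return out


def net_forces(tissue, params: np.ndarray | None = None) -> np.ndarray:
    """Net force on every node (see :func:`net_forces_and_virial`)."""
    return net_forces_and_virial(tissue, params)[0]


def euler_step(tissue, forces: np.ndarray, cfg: IntegratorConfig) -> None:
    """Advance all node positions by one forward-Euler step in place.

    Every node moves by ``F dt / eta``; the tissue clock advances by ``dt``.
    Raises :class:`IntegratorInstability` if any displacement is non-finite
    or exceeds ``max_step_fraction * L_min`` (default half the adhesion rest
    length) — the signal that ``dt`` is too large for the current stiffness.
    """
    disp = forces * (cfg.dt / cfg.eta)
    mags = np.hypot(disp[:, 0], disp[:, 1])
    limit = cfg.max_step_fraction * tissue.adhesion_L_min()
    worst = float(np.max(mags)) if len(mags) else 0.0
    if not np.isfinite(worst) or worst > limit:
        i = int(np.argmax(np.where(np.isfinite(mags), mags, np.inf)))
        raise IntegratorInstability(
            f"node {i} displacement {worst:.4g} um exceeds {limit:.4g} um at "
            f"t={tissue.t:.4g}s (force {np.linalg.norm(forces[i]):.4g} nN); "
            "reduce dt or check parameters"
        )
    tissue.pos += disp
    tissue.t += cfg.dt
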