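"""In-silico calibration harnesses: single-cell stretch (elastic modulus),
two-cell detachment (adhesion strength) and tissue growth curves.

The stretch harness mimics a single-cell stretching experiment: after the
cell relaxes, a linearly increasing total force is applied to the membrane
nodes within +-15 degrees of the two x poles, pulling the poles apart.
Strain is the relative change of the cell's x extent; stress is the applied
force divided by the current transverse (y) width times a fixed out-of-plane
depth ``depth_h``, giving kPa (nN/um^2).  The elastic modulus E is the
least-squares slope of stress over strain in the linear window.

The detachment harness relaxes two cells into adhesive contact and ramps
opposing forces on the distal poles until the last adhesion bond lets go;
the adhesion strength is the force at separation divided by the junction
length at the onset of the ramp (distance between the outermost
adhesion-bonded membrane nodes).

Both harnesses are deterministic given the configuration (the only
randomness is the seeded initial internal-node placement).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import dynamics as dyn
from .io import SimConfig
from .mechanics import CortexParams, PhasePair
from .tissue import TissueState, initialize_tissue, run_resilient, run_simulation

__all__ = [
    "StretchResult",
    "DetachmentResult",
    "stretch_test",
    "detachment_test",
    "calibrate_stiffness",
    "growth_curve",
]

POLE_HALF_ANGLE = math.radians(15.0)
STRAIN_WINDOW = (0.02, 0.10)


@dataclass
class StretchResult:
    """Stress-strain record of one stretch run."""

    time: np.ndarray  # s
    force: np.ndarray  # total applied force per side (nN)
    strain: np.ndarray
    stress: np.ndarray  # kPa
    modulus_kpa: float  # slope of stress vs strain in the linear window
    depth_h: float


@dataclass
class DetachmentResult:
    """Outcome of a two-cell detachment run."""

    force_at_separation: float  # nN (per side)
    junction_length: float  # um, at ramp onset
    strength: float  # nN/um
    time: np.ndarray
    force: np.ndarray
    strain: np.ndarray
    bonds: np.ndarray


def _relax(ts: TissueState, cfg: SimConfig, duration: float) -> None:
    """Integrate without growth until ``duration`` has passed."""
    steps = int(round(duration / cfg.integrator.dt))
    for _ in range(steps):
        forces, _ = dyn.net_forces_and_virial(ts)
        dyn.euler_step(ts, forces, cfg.integrator)


def _pole_bands(ts: TissueState, slot: int) -> tuple[np.ndarray, np.ndarray]:
    """Global indices of membrane nodes within +-15 deg of the +-x poles."""
    s, nm = ts.cell_start[slot], ts.cell_nm[slot]
    ring = ts.pos[s: s + nm]
    c = ring.mean(axis=0)
    ang = np.arctan2(ring[:, 1] - c[1], ring[:, 0] - c[0])
    plus = np.flatnonzero(np.abs(ang) <= POLE_HALF_ANGLE) + s
    minus = np.flatnonzero(np.abs(np.abs(ang) - math.pi) <= POLE_HALF_ANGLE) + s
    if len(plus) == 0 or len(minus) == 0:
        raise RuntimeError("no membrane nodes in the pole bands")
    return plus, minus


def _extent(ts: TissueState, axis: int) -> float:
    mem = ts.pos[ts.is_mem]
    return float(mem[:, axis].max() - mem[:, axis].min())


def stretch_test(cfg: SimConfig | None = None, ramp_rate: float = 0.05,
                 depth_h: float | None = None, relax_time: float = 80.0,
                 max_strain: float = 0.14, record_every: int = 50,
                 strain_window: tuple[float, float] = STRAIN_WINDOW,
                 max_time: float = 400.0) -> StretchResult:
    """Single-cell stretch: returns the stress-strain series and modulus.

    ``ramp_rate`` is the growth rate of the total force applied to each pole
    band (nN/s), slow enough to stay quasi-static at the default stiffness.
    """
    cfg = SimConfig() if cfg is None else cfg
    depth_h = cfg.depth_h if depth_h is None else depth_h
    ts = initialize_tissue(1, cfg)
    _relax(ts, cfg, relax_time)
    plus, minus = _pole_bands(ts, 0)
    width0 = _extent(ts, 0)
    dt = cfg.integrator.dt
    rows = []
    t_ramp = 0.0
    n_steps = int(round(max_time / dt))
    for k in range(n_steps):
        forces, _ = dyn.net_forces_and_virial(ts)
        f_tot = ramp_rate * t_ramp
        forces[plus, 0] += f_tot / len(plus)
        forces[minus, 0] -= f_tot / len(minus)
        dyn.euler_step(ts, forces, cfg.integrator)
        t_ramp += dt
        if k % record_every == 0:
            strain = (_extent(ts, 0) - width0) / width0
            stress = f_tot / (_extent(ts, 1) * depth_h)
            rows.append((t_ramp, f_tot, strain, stress))
            if strain >= max_strain:
                break
    arr = np.array(rows)
    time, force, strain, stress = arr.T
    lo, hi = strain_window
    sel = (strain >= lo) & (strain <= hi)
    if np.sum(sel) < 3:
        raise RuntimeError("too few samples in the linear strain window")
    slope = np.polyfit(strain[sel], stress[sel], 1)[0]
    return StretchResult(time=time, force=force, strain=strain, stress=stress,
                         modulus_kpa=float(slope), depth_h=depth_h)


def calibrate_stiffness(target_e_kpa: float, cfg: SimConfig | None = None,
                        bracket: tuple[float, float] = (40.0, 1200.0),
                        tol: float = 0.25, max_iter: int = 20,
                        **stretch_kwargs) -> tuple[float, StretchResult]:
    """Bisection on the interphase cortical spring constant until the
    stretch harness reports the target modulus (kPa).

    Returns ``(k_stiff, result)``.  E grows monotonically with ``k_stiff``
    over the physiological bracket, so plain bisection converges.
    """
    cfg = SimConfig() if cfg is None else cfg

    def run(k):
        pp = cfg.phase_params
        pp = replace(pp, cortex=PhasePair(
            replace(pp.cortex.inter, k_stiff=k), pp.cortex.mit))
        return stretch_test(replace(cfg, phase_params=pp), **stretch_kwargs)

    lo, hi = bracket
    res = None
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        res = run(mid)
        if abs(res.modulus_kpa - target_e_kpa) <= tol:
            return mid, res
        if res.modulus_kpa < target_e_kpa:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi), res


def detachment_test(cfg: SimConfig | None = None, ramp_rate: float = 0.01,
                    relax_time: float = 60.0, contact_gap: float = 0.25,
                    record_every: int = 100, max_force: float = 80.0) -> DetachmentResult:
    """Two-cell detachment: ramp opposing pole forces until the adhesion
    bond count reaches zero.

    The defaults let the junction zip to its steady contact length before
    loading (60 s; this makes the junction-length denominator reproducible
    across seeds) and then ramp slowly.  The measured strength is
    loading-rate dependent — faster ramps leave the peeling junction less
    time to relax and re-engage bonds, and read higher — so the default
    rate sits near the quasi-static plateau.

    Raises ``RuntimeError`` if the cells never separate within
    ``max_force`` per side.
    """
    cfg = SimConfig() if cfg is None else cfg
    cfg = replace(cfg, initial_gap=contact_gap)
    ts = initialize_tissue(2, cfg)
    _relax(ts, cfg, relax_time)

    # identify each cell's distal pole band (away from the partner cell)
    cents = ts.cell_centroids()
    # cells sit on the x axis by construction; cell with larger x pulls +x
    right = int(np.argmax(cents[:, 0]))
    left = 1 - right
    plus, _ = _pole_bands(ts, right)
    _, minus = _pole_bands(ts, left)

    forces, _ = dyn.net_forces_and_virial(ts)  # refresh adhesion pairing
    bonded = np.flatnonzero(ts.adh_partner >= 0)
    if len(bonded) == 0:
        junction = 0.0
    else:
        pts = ts.pos[bonded]
        junction = float(np.max(np.hypot(
            pts[:, 0][:, None] - pts[:, 0][None, :],
            pts[:, 1][:, None] - pts[:, 1][None, :])))
    sep0 = _extent(ts, 0)
    dt = cfg.integrator.dt
    rows = []
    t_ramp = 0.0
    f_tot = 0.0
    while f_tot <= max_force:
        forces, _ = dyn.net_forces_and_virial(ts)
        n_bonds = int(np.sum(ts.adh_partner >= 0) // 2)
        f_tot = ramp_rate * t_ramp
        if n_bonds == 0:
            rows.append((t_ramp, f_tot, (_extent(ts, 0) - sep0) / sep0, 0))
            break
        forces[plus, 0] += f_tot / len(plus)
        forces[minus, 0] -= f_tot / len(minus)
        dyn.euler_step(ts, forces, cfg.integrator)
        steps = int(round(t_ramp / dt))
        if steps % record_every == 0:
            rows.append((t_ramp, f_tot, (_extent(ts, 0) - sep0) / sep0, n_bonds))
        t_ramp += dt
    else:
        raise RuntimeError("cells did not separate within the force ramp limit")
    arr = np.array(rows)
    if junction <= 0:
        raise RuntimeError("cells were not adhered at ramp onset")
    return DetachmentResult(
        force_at_separation=float(f_tot), junction_length=junction,
        strength=float(f_tot) / junction,
        time=arr[:, 0], force=arr[:, 1], strain=arr[:, 2],
        bonds=arr[:, 3].astype(int))


def growth_curve(cfg: SimConfig, seeds: list[int], t_end: float,
                 sample_every: float = 60.0, n_cells: int = 7) -> pd.DataFrame:
    """Cell count over time with a 95% normal-approximation band over seeds.

    Returns a tidy frame with columns ``t, mean, lo95, hi95`` plus one
    ``n_seed{k}`` column per replicate.
    """
    times = np.arange(0.0, t_end + 1e-9, sample_every)
    counts = np.empty((len(seeds), len(times)), dtype=float)
    for si, seed in enumerate(seeds):
        res = run_resilient(cfg, t_end=t_end, seed=seed,
                            snapshot_every=sample_every, n_cells=n_cells)
        snap_t = np.array([t for t, _ in res.snapshots])
        snap_n = np.array([s.n_cells for _, s in res.snapshots], dtype=float)
        # step-function interpolation onto the common grid (snapshots land
        # up to one integrator step past their nominal cadence)
        slack = 2.0 * cfg.integrator.dt
        idx = np.clip(np.searchsorted(snap_t, times + slack, side="right") - 1,
                      0, len(snap_t) - 1)
        counts[si] = snap_n[idx]
    mean = counts.mean(axis=0)
    if len(seeds) > 1:
        half = 1.96 * counts.std(axis=0, ddof=1) / math.sqrt(len(seeds))
    else:
        half = np.zeros_like(mean)
    out = pd.DataFrame({"t": times, "mean": mean, "lo95": mean - half, "hi95": mean + half})
    for si, seed in enumerate(seeds):
        out[f"n_seed{seed}"] = counts[si]
    return out
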