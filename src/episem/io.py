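"""Configuration, snapshot/event persistence and run manifests.

The configuration file is YAML.  Energy-function parameters use dotted keys
mirroring the parameter-table symbols (``II.U.inter``, ``II.U.mit``,
``adh.k.inter``, ``stiff.k_tor.mit`` ...) under a ``params:`` block;
implementation constants live under ``integrator:``, ``growth:``, ``nodes:``
and ``run:`` blocks.  Every key is optional — an empty file yields the
calibrated defaults — and unknown keys are rejected loudly.

Snapshots are plain CSV (one row per node: cell_id, node_id, kind,
ring_index, x, y, CP, phase) with a JSON sidecar carrying the schema
version, time stamp, resolution and units; floats are written with 17
significant digits so a read-back reproduces positions bit-exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell_cycle import GrowthConfig
from .dynamics import IntegratorConfig
from .mechanics import (AdhesionParams, CortexParams, MorseParams, PhasePair,
                        PhaseParams, default_phase_params, scale_for_resolution)

__all__ = ["SimConfig", "load_config", "suggested_dt", "write_snapshot",
           "read_snapshot", "write_events", "write_run_manifest"]


def suggested_dt(resolution: float) -> float:
    """Forward-Euler step (s) for a given node resolution.

    The stability-limiting events are transient vertex-force spikes, which
    are largely resolution independent; the full-resolution step is 3 ms.
    Coarse tissues were profiled over long active growth windows (divisions
    included): the largest per-step displacement stayed under a third of
    the abort guard, so desk-scale runs use 7 ms; the resilient driver
    absorbs the rare larger spike.
    """
    return 0.003 if resolution >= 0.5 else 0.007

SCHEMA_VERSION = 1

# Out-of-plane depth (um) converting in-plane force per length to 3D stress
# in the stretch harness.  Fixed once so the calibrated interphase cortical
# stiffness reproduces the target elastic modulus of 19 kPa (raw harness
# slope 12.24 nN/um / 19 kPa); see docs/methods.md.
DEPTH_H_DEFAULT = 0.644


@dataclass(frozen=True)
class SimConfig:
    """Fully resolved simulation configuration.

    ``resolution`` in (0, 1] scales per-cell node counts (and with them the
    per-node rest lengths, spring constants and the time step a run can use);
    1.0 reproduces the full calibrated resolution.  ``deltaP_scale``
    multiplies the mitotic cytoplasmic Morse amplitudes (the pressure factor
    of the response-surface experiments).
    """

    phase_params: PhaseParams = field(default_factory=default_phase_params)
    integrator: IntegratorConfig = field(default_factory=IntegratorConfig)
    growth: GrowthConfig = field(default_factory=GrowthConfig)
    n_internal: tuple[int, int] = (20, 40)
    n_membrane: tuple[int, int] = (100, 200)
    resolution: float = 1.0
    seed: int = 0
    initial_radius: float = 1.2  # um, at resolution 1 (see docs/methods.md)
    initial_gap: float = 0.3  # um between initial circles (adhesion reach)
    depth_h: float = DEPTH_H_DEFAULT
    deltaP_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.resolution <= 1):
            raise ValueError("resolution must lie in (0, 1]")
        if self.initial_radius <= 0 or self.initial_gap <= 0 or self.depth_h <= 0:
            raise ValueError("geometric constants must be positive")

    # -- resolution-scaled views -----------------------------------------
    def effective_phase_params(self) -> PhaseParams:
        pp = self.phase_params
        if self.deltaP_scale != 1.0:
            mit_ii = replace(pp.ii.mit, U=pp.ii.mit.U * self.deltaP_scale)
            mit_mi = replace(pp.mi.mit, U=pp.mi.mit.U * self.deltaP_scale)
            pp = replace(pp, ii=PhasePair(pp.ii.inter, mit_ii),
                         mi=PhasePair(pp.mi.inter, mit_mi))
        return scale_for_resolution(pp, self.resolution)

    def effective_n_internal(self) -> tuple[int, int]:
        s = self.resolution
        lo = max(3, math.ceil(self.n_internal[0] * s))
        hi = max(lo + 1, math.ceil(self.n_internal[1] * s))
        return lo, hi

    def effective_n_membrane(self) -> tuple[int, int]:
        s = self.resolution
        lo = max(8, math.ceil(self.n_membrane[0] * s))
        hi = max(lo + 1, math.ceil(self.n_membrane[1] * s))
        return lo, hi

    def effective_initial_radius(self) -> float:
        # empirical fit of the relaxed single-cell radius across resolutions
        # (coarser cells relax slightly smaller, far less than sqrt(s))
        return self.initial_radius * self.resolution ** 0.125

    def with_mitotic_factors(self, k_adh_mit: float | None = None,
                             k_stiff_mit: float | None = None,
                             deltaP_scale: float | None = None) -> "SimConfig":
        """Copy of this config with response-surface factor values applied to
        the mitotic column."""
        pp = self.phase_params
        if k_adh_mit is not None:
            pp = replace(pp, adhesion=PhasePair(
                pp.adhesion.inter, replace(pp.adhesion.mit, k_adh=k_adh_mit)))
        if k_stiff_mit is not None:
            pp = replace(pp, cortex=PhasePair(
                pp.cortex.inter, replace(pp.cortex.mit, k_stiff=k_stiff_mit)))
        out = replace(self, phase_params=pp)
        if deltaP_scale is not None:
            out = replace(out, deltaP_scale=deltaP_scale)
        return out

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return enc(self)

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Config file parsing
# ---------------------------------------------------------------------------

_FAMILY_KEYS = {"II": "ii", "MI": "mi", "MMD": "mmd"}
_MORSE_FIELDS = {"U", "W", "xi", "gamma", "L"}


def _set_param(pp: PhaseParams, dotted: str, value: float) -> PhaseParams:
    parts = dotted.split(".")
    if len(parts) != 3 or parts[2] not in ("inter", "mit"):
        raise ValueError(f"malformed parameter key: {dotted!r}")
    fam, fld, phase = parts
    if not isinstance(value, (int, float)):
        raise ValueError(f"parameter {dotted!r} must be a number")
    if fam in _FAMILY_KEYS:
        if fld not in _MORSE_FIELDS:
            raise ValueError(f"unknown Morse field in key {dotted!r}")
        pair = getattr(pp, _FAMILY_KEYS[fam])
        new = replace(getattr(pair, phase), **{fld: float(value)})
        pair = PhasePair(**{**{"inter": pair.inter, "mit": pair.mit}, phase: new})
        return replace(pp, **{_FAMILY_KEYS[fam]: pair})
    if fam == "adh":
        mapping = {"k": "k_adh", "L_min": "L_min", "L_max": "L_max"}
    elif fam == "stiff":
        mapping = {"k": "k_stiff", "L": "L_stiff", "k_tor": "k_tor"}
    else:
        raise ValueError(f"unknown parameter family in key {dotted!r}")
    if fld not in mapping:
        raise ValueError(f"unknown field in key {dotted!r}")
    attr = "adhesion" if fam == "adh" else "cortex"
    pair = getattr(pp, attr)
    new = replace(getattr(pair, phase), **{mapping[fld]: float(value)})
    pair = PhasePair(**{**{"inter": pair.inter, "mit": pair.mit}, phase: new})
    return replace(pp, **{attr: pair})


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> SimConfig:
    """Load a :class:`SimConfig` from YAML, filling every missing key with
    the calibrated defaults; unknown keys raise ``ValueError`` naming the
    key."""
    raw: dict = {}
    if path is not None:
        text = Path(path).read_text()
        raw = yaml.safe_load(text) or {}
        if not isinstance(raw, dict):
            raise ValueError("config root must be a mapping")
    if overrides:
        for k, v in overrides.items():
            raw.setdefault(k, {}).update(v) if isinstance(v, dict) else raw.__setitem__(k, v)

    known_blocks = {"params", "integrator", "growth", "nodes", "run"}
    unknown = set(raw) - known_blocks
    if unknown:
        raise ValueError(f"unknown config block(s): {sorted(unknown)}")

    pp = default_phase_params()
    for key, value in (raw.get("params") or {}).items():
        pp = _set_param(pp, key, value)

    def _block(name, cls, defaults):
        blk = raw.get(name) or {}
        fields = {f.name for f in dataclasses.fields(cls)}
        bad = set(blk) - fields
        if bad:
            raise ValueError(f"unknown key(s) in {name}: {sorted(bad)}")
        return cls(**{**defaults, **blk})

    integ = _block("integrator", IntegratorConfig, {})
    growth = _block("growth", GrowthConfig, {})

    nodes = raw.get("nodes") or {}
    bad = set(nodes) - {"internal", "membrane"}
    if bad:
        raise ValueError(f"unknown key(s) in nodes: {sorted(bad)}")
    n_int = tuple(nodes.get("internal", (20, 40)))
    n_mem = tuple(nodes.get("membrane", (100, 200)))

    run = raw.get("run") or {}
    run_fields = {"resolution", "seed", "initial_radius", "initial_gap",
                  "depth_h", "deltaP_scale"}
    bad = set(run) - run_fields
    if bad:
        raise ValueError(f"unknown key(s) in run: {sorted(bad)}")

    return SimConfig(phase_params=pp, integrator=integ, growth=growth,
                     n_internal=n_int, n_membrane=n_mem, **run)


# ---------------------------------------------------------------------------
# Snapshots and run outputs
# ---------------------------------------------------------------------------


def snapshot_frame(state) -> pd.DataFrame:
    """Tabular view of a tissue state (one row per node)."""
    rows = []
    for slot in range(state.n_cells):
        s, nm, ni = state.cell_start[slot], state.cell_nm[slot], state.cell_ni[slot]
        cid = int(state.cell_id[slot])
        cp = float(state.cell_cp[slot])
        ph = "mitotic" if state.cell_phase[slot] else "interphase"
        for a in range(nm + ni):
            idx = s + a
            rows.append((cid, int(state.node_id[idx]),
                         "membrane" if a < nm else "internal",
                         a if a < nm else -1,
                         state.pos[idx, 0], state.pos[idx, 1], cp, ph))
    return pd.DataFrame(rows, columns=["cell_id", "node_id", "kind",
                                       "ring_index", "x", "y", "CP", "phase"])


def write_snapshot(state, path: str | Path) -> None:
    """Write a tissue snapshot as CSV plus a JSON sidecar header."""
    path = Path(path)
    snapshot_frame(state).to_csv(path, index=False, float_format="%.17g")
    sidecar = {
        "schema_version": SCHEMA_VERSION,
        "t": state.t,
        "resolution": state.resolution,
        "n_cells": state.n_cells,
        "units": {"length": "um", "force": "nN", "time": "s"},
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_snapshot(path: str | Path, cfg: SimConfig | None = None):
    """Reconstruct a :class:`~episem.tissue.TissueState` from a snapshot.

    Positions, CP, phases and ring order round-trip bit-exactly.  The
    mechanical parameter set is taken from ``cfg`` (scaled to the sidecar's
    resolution) or the defaults.
    """
    from .tissue import TissueState

    path = Path(path)
    side_path = path.with_suffix(path.suffix + ".json")
    if not side_path.exists():
        raise ValueError(f"missing snapshot sidecar {side_path}")
    side = json.loads(side_path.read_text())
    if side.get("schema_version") != SCHEMA_VERSION:
        raise ValueError("snapshot schema version mismatch")
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"cell_id", "node_id", "kind", "ring_index", "x", "y", "CP", "phase"}
    if not required.issubset(df.columns):
        raise ValueError(f"snapshot missing columns {sorted(required - set(df.columns))}")
    if df[["x", "y", "CP"]].isna().any().any():
        raise ValueError("snapshot contains missing values")
    res = float(side.get("resolution", 1.0))
    cfg = replace(cfg if cfg is not None else SimConfig(), resolution=res)
    ts = TissueState(cfg.effective_phase_params(), cfg.growth,
                     n_internal=cfg.effective_n_internal(),
                     n_membrane=cfg.effective_n_membrane(), resolution=res)
    ts.t = float(side.get("t", 0.0))
    for cid, grp in df.groupby("cell_id", sort=True):
        mem = grp[grp["kind"] == "membrane"].sort_values("ring_index")
        ints = grp[grp["kind"] == "internal"]
        ss = np.random.SeedSequence(int(cid))
        slot = ts.append_cell(mem[["x", "y"]].to_numpy(float),
                              ints[["x", "y"]].to_numpy(float), ss,
                              birth_time=0.0)
        ts.cell_cp[slot] = float(grp["CP"].iloc[0])
        ts.cell_phase[slot] = np.uint8(grp["phase"].iloc[0] == "mitotic")
        if ts.cell_phase[slot]:
            # ramp weight is part of the state; without the entry point we
            # conservatively restart the ramp at the stored CP
            ts.cell_cp_mit[slot] = min(float(grp["CP"].iloc[0]), 1.0 - 1e-9)
        ts.cell_id[slot] = int(cid)
        ts.node_id[ts.cell_start[slot]: ts.cell_start[slot] + len(grp)] = (
            np.concatenate([mem["node_id"].to_numpy(np.int64),
                            ints["node_id"].to_numpy(np.int64)]))
    ts._next_cell_id = int(ts.cell_id.max()) + 1 if ts.n_cells else 0
    ts._next_node_id = int(ts.node_id.max()) + 1 if ts.n_nodes else 0
    return ts


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    pd.DataFrame(events).to_csv(path, index=False)


def write_run_manifest(cfg: SimConfig, seed: int, path: str | Path, extra: dict | None = None) -> None:
    """JSON manifest sufficient to re-run a simulation bit-identically."""
    from . import __version__

    manifest = {
        "config": cfg.to_dict(),
        "config_hash": cfg.content_hash(),
        "seed": seed,
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    Path(path).write_text(json.dumps(manifest, indent=1, default=float))
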