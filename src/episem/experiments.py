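"""Response-surface methodology over the three mitotic factors.

The factors are the mitotic cell-cell adhesion constant ``k_adh_mit``
(nN/um), the mitotic cortical stiffness ``k_stiff_mit`` (nN/um) and the
cytoplasmic-pressure multiplier ``deltaP_scale`` (dimensionless scale on the
mitotic cytoplasmic Morse amplitudes; the realized pressure change is
measured post hoc by the virial estimate).  The responses are the
mitotic-rounding readouts ``A_ratio`` and ``R_norm``.

A three-level full factorial design (27 points) explores the space; a
rotatable central composite design (15 distinct points, axial distance
``alpha = 8^(1/4)``) refines the region of interest.  Full second-order
polynomials in coded units are fit per response (weighted least squares
when replicate standard errors are available), reduced by backward stepwise
elimination at a p-value cutoff, and differentiated for local sensitivities.
The Pareto front of runs closest to user-supplied experimental targets in
both responses picks the calibration region.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm

from . import cell_cycle as cc
from .io import SimConfig
from .tissue import initialize_tissue, run_simulation

__all__ = [
    "FACTORS",
    "ffd_design",
    "ccd_design",
    "mr_probe",
    "run_batch",
    "SurfaceModel",
    "fit_surface",
    "stepwise_reduce",
    "sensitivity",
    "pareto_front",
    "default_center",
    "default_half_ranges",
]

FACTORS = ("k_adh_mit", "k_stiff_mit", "deltaP_scale")

_TERMS = ("1", "x1", "x2", "x3", "x1^2", "x2^2", "x3^2", "x1*x2", "x1*x3", "x2*x3")


def default_center() -> dict[str, float]:
    """Calibrated mitotic point (the parameter-table mitotic column)."""
    return {"k_adh_mit": 8.0, "k_stiff_mit": 450.0, "deltaP_scale": 1.0}


def default_half_ranges() -> dict[str, float]:
    """+-50% of the calibrated mitotic values."""
    return {"k_adh_mit": 4.0, "k_stiff_mit": 225.0, "deltaP_scale": 0.5}


def _design_frame(coded: np.ndarray, center: dict, half: dict) -> pd.DataFrame:
    rows = []
    for levels in coded:
        row = {"run_id": len(rows)}
        for f, c in zip(FACTORS, levels):
            row[f"coded_{f}"] = float(c)
            row[f] = center[f] + c * half[f]
        rows.append(row)
    return pd.DataFrame(rows)


def ffd_design(center: dict | None = None, half_ranges: dict | None = None) -> pd.DataFrame:
    """Three-level full factorial design: all 27 combinations of coded
    levels {-1, 0, +1} mapped affinely to physical factor values."""
    center = default_center() if center is None else center
    half = default_half_ranges() if half_ranges is None else half_ranges
    coded = np.array(list(itertools.product((-1.0, 0.0, 1.0), repeat=3)))
    return _design_frame(coded, center, half)


def ccd_design(center: dict | None = None, half_ranges: dict | None = None,
               alpha: float = 8.0 ** 0.25, n_center_reps: int = 1) -> pd.DataFrame:
    """Central composite design: 8 factorial corners, 6 axial points at
    +-alpha and a (possibly replicated) center — 15 distinct points.
    ``alpha = 8^(1/4) ~ 1.682`` makes the design rotatable for 3 factors."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    center = default_center() if center is None else center
    half = default_half_ranges() if half_ranges is None else half_ranges
    corners = np.array(list(itertools.product((-1.0, 1.0), repeat=3)))
    axial = []
    for k in range(3):
        for s in (-alpha, alpha):
            v = np.zeros(3)
            v[k] = s
            axial.append(v)
    coded = np.vstack([corners, np.array(axial)] + [np.zeros((1, 3))] * max(1, n_center_reps))
    return _design_frame(coded, center, half)


# ---------------------------------------------------------------------------
# Batch simulation
# ---------------------------------------------------------------------------


def grow_probe_tissue(cfg: SimConfig, seed: int = 0, n_cells: int = 30,
                      t_max: float = 2500.0):
    """Grow a small packed tissue for mitotic-rounding probes.

    Probes measure a *confined, polygonal* interior cell (a relaxed
    free-standing cluster would start round already and show no rounding).
    The base tissue is grown with the calibrated configuration so that every
    factor combination is probed against the same packing.
    """
    from .tissue import run_resilient

    res = run_resilient(cfg, t_end=t_max, seed=seed, stop_at_cells=n_cells,
                        mr_every=0)
    if res.aborted:
        raise RuntimeError(f"probe tissue growth aborted: {res.aborted}")
    return res.tissue


def mr_probe(cfg: SimConfig, seed: int = 0, base_tissue=None,
             g_probe: float = 1.0 / 300.0, keep_states: bool = False):
    """Mitotic-rounding readout of the centermost interior cell of a grown
    tissue.

    The chosen cell is driven through one M phase at constant growth rate
    ``g_probe`` (ramp duration = ``T_mit``) while every other cell idles;
    ``cfg`` may carry mitotic factor overrides
    (:meth:`~episem.io.SimConfig.with_mitotic_factors`).  Returns a dict
    with A_ratio, R_norm and delta_P (plus the pre/post tissue states and
    probed slot when ``keep_states``).
    """
    from dataclasses import replace

    from . import metrics
    from .mechanics import param_vector

    if base_tissue is None:
        base_tissue = grow_probe_tissue(replace(cfg, deltaP_scale=1.0), seed)
    ts = base_tissue.copy()
    if abs(ts.resolution - cfg.resolution) > 1e-12:
        raise ValueError("probe tissue resolution does not match the config")
    quiet = replace(cfg, growth=cc.GrowthConfig(
        g0_min=1e-9, g0_max=2e-9, k_g=0.0, T_mit=cfg.growth.T_mit))
    eff = quiet.effective_phase_params()
    ts.p_inter = param_vector(eff, "inter")
    ts.p_mit = param_vector(eff, "mit")
    ts._P_base = None

    interior = metrics.interior_cells(ts)
    if not interior.any():
        raise RuntimeError("probe tissue has no interior cells")
    cents = ts.cell_centroids()
    cand = np.flatnonzero(interior)
    mid = cents.mean(axis=0)
    slot = int(cand[np.argmin(np.hypot(*(cents[cand] - mid).T))])

    cp_entry = 1.0 - g_probe * quiet.growth.T_mit
    ts.cell_g0[:] = 1e-9
    ts.cell_g0[slot] = g_probe
    ts.cell_cp[slot] = cp_entry
    before = ts.copy() if keep_states else None
    cc.enter_mitosis(ts.cell(slot), ts.t, quiet.growth, cp_mit=cp_entry)
    cid = int(ts.cell_id[slot])
    from .tissue import run_resilient

    res = run_resilient(quiet, t_end=ts.t + quiet.growth.T_mit + 10.0, tissue=ts)
    if res.aborted:
        raise RuntimeError(f"probe M phase aborted: {res.aborted}")
    if res.mr_records.empty:
        raise RuntimeError("probe cell did not complete division")
    row = res.mr_records.iloc[0]
    out = {"A_ratio": float(row.A_ratio), "R_norm": float(row.R_norm),
           "delta_P": float(row.delta_P)}
    if keep_states:
        out["before"] = before
        out["after"] = res.tissue
        out["cell_id"] = cid
        out["slot"] = slot
    return out


def run_batch(design: pd.DataFrame, base_config: SimConfig, reps: int = 5,
              seed: int = 0, out_path: str | Path | None = None,
              **probe_kwargs) -> pd.DataFrame:
    """Run seeded replicate simulations for every design row.

    Returns one record per row with replicate means and standard errors of
    the responses.  When ``out_path`` is given, per-replicate results are
    appended there as they finish and completed (run_id, rep) pairs are
    skipped on re-entry, making long batches resumable.  Failed replicates
    are recorded with ``ok = False`` and excluded from the means.
    """
    done = pd.DataFrame()
    out_path = Path(out_path) if out_path is not None else None
    if out_path is not None and out_path.exists():
        done = pd.read_csv(out_path)
    raw_rows = [] if done.empty else done.to_dict("records")
    bases: dict[int, object] = {}  # one grown probe tissue per replicate
    for _, drow in design.iterrows():
        for rep in range(reps):
            rid = int(drow["run_id"])
            if not done.empty and ((done.run_id == rid) & (done.rep == rep)).any():
                continue
            cfg = base_config.with_mitotic_factors(
                k_adh_mit=float(drow["k_adh_mit"]),
                k_stiff_mit=float(drow["k_stiff_mit"]),
                deltaP_scale=float(drow["deltaP_scale"]))
            rec = {"run_id": rid, "rep": rep,
                   **{f: float(drow[f]) for f in FACTORS},
                   **{f"coded_{f}": float(drow[f"coded_{f}"]) for f in FACTORS}}
            try:
                if rep not in bases:
                    bases[rep] = grow_probe_tissue(base_config, seed + rep)
                out = mr_probe(cfg, base_tissue=bases[rep], **probe_kwargs)
                rec.update(out)
                rec["ok"] = True
            except RuntimeError as exc:
                rec.update({"A_ratio": np.nan, "R_norm": np.nan,
                            "delta_P": np.nan, "ok": False, "error": str(exc)})
            raw_rows.append(rec)
            if out_path is not None:
                pd.DataFrame(raw_rows).to_csv(out_path, index=False)
    raw = pd.DataFrame(raw_rows)
    recs = []
    for rid, grp in raw.groupby("run_id"):
        ok = grp[grp["ok"] == True]  # noqa: E712
        rec = {"run_id": int(rid), "n_ok": len(ok), "n_fail": len(grp) - len(ok)}
        for f in FACTORS:
            rec[f] = float(grp[f].iloc[0])
            rec[f"coded_{f}"] = float(grp[f"coded_{f}"].iloc[0])
        for resp in ("A_ratio", "R_norm", "delta_P"):
            vals = ok[resp].to_numpy(float)
            rec[resp] = float(np.mean(vals)) if len(vals) else np.nan
            rec[f"{resp}_se"] = (float(np.std(vals, ddof=1) / math.sqrt(len(vals)))
                                 if len(vals) > 1 else np.nan)
        recs.append(rec)
    return pd.DataFrame(recs)


# ---------------------------------------------------------------------------
# Quadratic response surfaces
# ---------------------------------------------------------------------------


def _model_matrix(coded: np.ndarray, terms=_TERMS) -> np.ndarray:
    x1, x2, x3 = coded.T
    cols = {"1": np.ones(len(coded)), "x1": x1, "x2": x2, "x3": x3,
            "x1^2": x1 * x1, "x2^2": x2 * x2, "x3^2": x3 * x3,
            "x1*x2": x1 * x2, "x1*x3": x1 * x3, "x2*x3": x2 * x3}
    return np.column_stack([cols[t] for t in terms])


@dataclass
class SurfaceModel:
    """A fitted (possibly reduced) second-order response surface."""

    response: str
    terms: tuple[str, ...]
    coef: pd.Series
    pvalues: pd.Series
    r_squared: float
    records: pd.DataFrame
    weighted: bool

    def predict(self, coded: np.ndarray) -> np.ndarray:
        X = _model_matrix(np.atleast_2d(coded), self.terms)
        return X @ self.coef.to_numpy()

    def contour_grid(self, pair: tuple[int, int] = (0, 1), n: int = 41,
                     span: float = 1.0, fixed: float = 0.0) -> pd.DataFrame:
        """Response over a coded-unit grid of one factor pair, the third
        factor held at ``fixed``."""
        g = np.linspace(-span, span, n)
        a, b = np.meshgrid(g, g)
        pts = np.full((n * n, 3), fixed)
        pts[:, pair[0]] = a.ravel()
        pts[:, pair[1]] = b.ravel()
        return pd.DataFrame({
            FACTORS[pair[0]]: pts[:, pair[0]],
            FACTORS[pair[1]]: pts[:, pair[1]],
            self.response: self.predict(pts),
        })


def fit_surface(records: pd.DataFrame, response: str = "A_ratio",
                order: int = 2, weighted: bool = True,
                terms: tuple[str, ...] | None = None,
                outlier_refit: bool = False) -> SurfaceModel:
    """Least-squares fit of a full second-order polynomial in coded units.

    Uses WLS with weights ``1/se^2`` when replicate standard errors are
    available (and ``weighted=True``), else OLS.  Raises on rank-deficient
    designs, naming the unsupported terms.  With ``outlier_refit`` (off by
    default), records whose externally studentized residual exceeds |t| > 3
    are dropped once and the model refit.
    """
    if terms is None:
        terms = _TERMS if order == 2 else ("1", "x1", "x2", "x3")
    data = records.dropna(subset=[response])
    if outlier_refit:
        first = fit_surface(records, response, order=order, weighted=False,
                            terms=terms, outlier_refit=False)
        X = _model_matrix(data[[f"coded_{f}" for f in FACTORS]].to_numpy(float),
                          terms)
        from statsmodels.stats.outliers_influence import OLSInfluence

        infl = OLSInfluence(sm.OLS(data[response].to_numpy(float), X).fit())
        keep = np.abs(infl.resid_studentized_external) <= 3.0
        if keep.all():
            return first if not weighted else fit_surface(
                records, response, order=order, weighted=weighted, terms=terms)
        data = data[keep]
        records = data
    coded = data[[f"coded_{f}" for f in FACTORS]].to_numpy(float)
    if len(data) < len(terms):
        raise ValueError(f"need >= {len(terms)} distinct design points for terms {terms}")
    X = _model_matrix(coded, terms)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify offending columns by greedy inclusion
        bad = []
        keep: list[int] = []
        for k in range(X.shape[1]):
            if np.linalg.matrix_rank(X[:, keep + [k]]) > len(keep):
                keep.append(k)
            else:
                bad.append(terms[k])
        raise ValueError(f"design cannot estimate terms: {bad}")
    y = data[response].to_numpy(float)
    se_col = f"{response}_se"
    if weighted and se_col in data.columns and data[se_col].notna().all() and (data[se_col] > 0).all():
        w = 1.0 / data[se_col].to_numpy(float) ** 2
        fit = sm.WLS(y, X, weights=w).fit()
        used_w = True
    else:
        fit = sm.OLS(y, X).fit()
        used_w = False
    coef = pd.Series(fit.params, index=list(terms))
    pvals = pd.Series(fit.pvalues, index=list(terms))
    return SurfaceModel(response=response, terms=tuple(terms), coef=coef,
                        pvalues=pvals, r_squared=float(fit.rsquared),
                        records=data, weighted=used_w)


def _protected(term: str, terms: tuple[str, ...]) -> bool:
    """Hierarchy: a linear term stays while any of its quadratic or
    interaction descendants remain."""
    if term == "1":
        return True
    if term in ("x1", "x2", "x3"):
        return any(term in t and t != term for t in terms)
    return False


def stepwise_reduce(model: SurfaceModel, p_cutoff: float = 0.01) -> SurfaceModel:
    """Backward stepwise elimination: repeatedly drop the least significant
    droppable term with p > cutoff and refit, until all remaining terms pass.
    The intercept and hierarchy-protected linear terms are never dropped."""
    terms = model.terms
    while True:
        fit = fit_surface(model.records, model.response, terms=terms,
                          weighted=model.weighted)
        droppable = [t for t in fit.terms
                     if not _protected(t, fit.terms) and fit.pvalues[t] > p_cutoff]
        if not droppable:
            return fit
        worst = max(droppable, key=lambda t: (fit.pvalues[t], t))
        terms = tuple(t for t in terms if t != worst)


def sensitivity(model: SurfaceModel, point: np.ndarray | None = None) -> pd.DataFrame:
    """Partial derivatives of the response per factor in coded units at
    ``point`` (default: the design center).  Emits a warning outside the
    coded design cube."""
    import warnings

    point = np.zeros(3) if point is None else np.asarray(point, dtype=float)
    if np.any(np.abs(point) > 2.0):
        warnings.warn("sensitivity point lies outside the design region")
    c = model.coef
    out = []
    for k, f in enumerate(FACTORS):
        xk = f"x{k + 1}"
        d = c.get(xk, 0.0) + 2.0 * c.get(f"{xk}^2", 0.0) * point[k]
        for j in range(3):
            if j == k:
                continue
            a, b = sorted((k + 1, j + 1))
            d += c.get(f"x{a}*x{b}", 0.0) * point[j]
        out.append({"factor": f, "d_response_d_factor": float(d)})
    return pd.DataFrame(out)


def pareto_front(records: pd.DataFrame, targets: tuple[float, float],
                 scales: tuple[float, float] = (1.0, 1.0)) -> pd.DataFrame:
    """Non-dominated records under the two objectives
    ``|A_ratio - target| / scale`` and ``|R_norm - target| / scale``.

    A record is dominated when another is no worse in both objectives and
    strictly better in at least one.  Implemented as a sort-and-sweep; the
    result carries the objective columns ``obj_A`` and ``obj_R``.
    """
    df = records.dropna(subset=["A_ratio", "R_norm"]).copy()
    df["obj_A"] = np.abs(df["A_ratio"] - targets[0]) / scales[0]
    df["obj_R"] = np.abs(df["R_norm"] - targets[1]) / scales[1]
    df = df.sort_values(["obj_A", "obj_R"], kind="mergesort")
    keep = []
    best_r = np.inf  # best obj_R among points with strictly smaller obj_A
    group_a = None
    group_min_r = np.inf
    for idx, row in df.iterrows():
        a, r = row["obj_A"], row["obj_R"]
        if group_a is None or a > group_a:
            best_r = min(best_r, group_min_r)
            group_a = a
            group_min_r = np.inf
        if r < best_r and r <= group_min_r:
            keep.append(idx)
            group_min_r = min(group_min_r, r)
        elif r == group_min_r and r < best_r:
            keep.append(idx)
    return df.loc[keep]
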