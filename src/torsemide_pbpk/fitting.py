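"""Nonlinear least-squares estimation of PD and PK parameters.

Both fitters use the same two-stage strategy: a derivative-free simplex
(Nelder-Mead) multistart from a Latin-hypercube sample inside the bounds,
followed by local trust-region refinement (``scipy.optimize.least_squares``)
from the best start.  Randomness is confined to the seeded multistart
design, so results are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares, minimize
from scipy.stats import qmc

from .model import MG_TO_UG, DoseEvent, SimulationSpec, simulate
from .nca import FitQuality, fit_quality
from .params import DrugParams, PDParams, PhysiologyParams
from .pd_model import evaluate_pd, pd_preset_for, pd_timecourse
from .populations import resolve_population
from .synthetic import ObservedSeries


@dataclass
class FitResult:
    estimates: Dict[str, float]
    stderr: Dict[str, float]
    ssr: float
    quality: FitQuality
    converged: bool
    n_obs: int
    n_params: int
    trace: List[float] = field(default_factory=list)


def _lhs_starts(bounds: np.ndarray, n_starts: int, seed: int) -> np.ndarray:
    if n_starts <= 0:
        return np.empty((0, bounds.shape[0]))
    sampler = qmc.LatinHypercube(d=bounds.shape[0], seed=seed)
    unit = sampler.random(n=n_starts)
    return qmc.scale(unit, bounds[:, 0], bounds[:, 1])


def _multistart(ssr_fn, starts: np.ndarray, bounds: np.ndarray,
                trace: List[float], maxiter: int) -> np.ndarray:
    """Penalized Nelder-Mead from each start; returns the best point."""

    def penalized(theta: np.ndarray) -> float:
        if np.any(theta < bounds[:, 0]) or np.any(theta > bounds[:, 1]):
            clipped = np.clip(theta, bounds[:, 0], bounds[:, 1])
            overshoot = np.linalg.norm(theta - clipped)
            return ssr_fn(clipped) * (1.0 + overshoot) + overshoot
        return ssr_fn(theta)

    best_theta, best_val = None, np.inf
    for theta0 in starts:
        res = minimize(penalized, theta0, method="Nelder-Mead",
                       options={"maxiter": maxiter, "xatol": 1e-8,
                                "fatol": 1e-12})
        if res.fun < best_val:
            best_theta, best_val = res.x, res.fun
            trace.append(float(best_val))
    return np.clip(best_theta, bounds[:, 0], bounds[:, 1])


def _stderr_from_jac(jac: np.ndarray, ssr: float, n: int,
                     k: int) -> Tuple[np.ndarray, bool]:
    jtj = jac.T @ jac
    identifiable = (np.linalg.cond(jtj) < 1e12) if np.all(np.isfinite(jtj)) else False
    dof = max(n - k, 1)
    cov = np.linalg.pinv(jtj) * (ssr / dof)
    return np.sqrt(np.maximum(np.diag(cov), 0.0)), identifiable


# --------------------------------------------------------------------------
# PD fitting
# --------------------------------------------------------------------------

PD_NAMES = ("E0", "E_max", "EC50", "P")


def fit_pd(pairs: Sequence[Tuple[float, float]],
           init: Optional[PDParams] = None,
           n_starts: int = 10, seed: int = 0,
           maxiter: int = 400) -> FitResult:
    """Fit the baseline sigmoid Emax model to (x, E) pairs.

    Requires at least 6 pairs with non-degenerate x spread.  Bounds:
    ``E0 >= 0``, ``E_max > 0``, ``EC50 > 0``, ``P < 0``.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 6:
        raise ValueError("need at least 6 (x, E) pairs")
    x, e_obs = arr[:, 0], arr[:, 1]
    if np.any(x < 0):
        raise ValueError("x must be non-negative")
    x_pos = x[x > 0]
    if x_pos.size < 2 or np.ptp(x_pos) == 0.0:
        raise ValueError("x values are degenerate; parameters unidentifiable")

    e_scale = float(e_obs.max())
    bounds = np.array([
        [0.0, 2.0 * e_scale],
        [1e-6 * e_scale, 4.0 * e_scale],
        [x_pos.min() / 10.0, x_pos.max() * 100.0],
        [-10.0, -0.1],
    ])

    def residuals(theta: np.ndarray) -> np.ndarray:
        pd_params = PDParams(E0=max(theta[0], 0.0), E_max=max(theta[1], 1e-12),
                             EC50=max(theta[2], 1e-12), P=min(theta[3], -1e-6))
        return evaluate_pd(x, pd_params) - e_obs

    def ssr_fn(theta: np.ndarray) -> float:
        return float(np.sum(residuals(theta) ** 2))

    starts = _lhs_starts(bounds, n_starts, seed)
    if init is not None:
        starts = np.vstack([[init.E0, init.E_max, init.EC50, init.P], starts])
    trace: List[float] = []
    best = _multistart(ssr_fn, starts, bounds, trace, maxiter)

    refined = least_squares(residuals, best, bounds=(bounds[:, 0], bounds[:, 1]),
                            xtol=1e-12, ftol=1e-12, gtol=1e-12)
    theta = refined.x
    ssr = float(np.sum(refined.fun ** 2))
    trace.append(ssr)
    stderr, identifiable = _stderr_from_jac(refined.jac, ssr, x.size, 4)
    fitted = evaluate_pd(x, PDParams(*theta))
    return FitResult(
        estimates=dict(zip(PD_NAMES, map(float, theta))),
        stderr=dict(zip(PD_NAMES, map(float, stderr))),
        ssr=ssr,
        quality=fit_quality(e_obs, fitted, n_params=4),
        converged=bool(refined.success and identifiable),
        n_obs=int(x.size), n_params=4,
        trace=trace)


# --------------------------------------------------------------------------
# PK fitting
# --------------------------------------------------------------------------

_PK_DRUG = ("V_max", "K_m", "K_a", "K_e", "K_u", "F_r", "P_r")
_PK_PHYS = ("V_rb", "Q_rb")


def _apply_free(phys: PhysiologyParams, drug: DrugParams,
                names: Sequence[str], values: np.ndarray,
                ) -> Tuple[PhysiologyParams, DrugParams]:
    drug_changes: Dict[str, float] = {}
    kp = None
    phys_changes: Dict[str, float] = {}
    for name, value in zip(names, values):
        if name in _PK_DRUG:
            drug_changes[name] = float(value)
        elif name.startswith("K_p."):
            kp = dict(kp if kp is not None else drug.K_p)
            kp[name.split(".", 1)[1]] = float(value)
        elif name == "V_rb":
            phys_changes["V_rb"] = float(value)
        elif name == "Q_rb":
            q_rb = float(value)
            q_lu = phys.Q_ki + phys.Q_gi + phys.Q_liar + q_rb
            phys_changes.update(Q_rb=q_rb, Q_lu=q_lu, Q_bl=q_lu)
        else:
            raise ValueError(f"unknown free parameter {name!r}")
    if kp is not None:
        drug_changes["K_p"] = kp
    new_drug = drug.with_(**drug_changes) if drug_changes else drug
    new_phys = phys.with_(**phys_changes) if phys_changes else phys
    return new_phys, new_drug


def _parse_schedule(schedule: str, dose_mg: float, route: str) -> List[DoseEvent]:
    if schedule == "single":
        return [DoseEvent(time=0.0, amount=dose_mg * MG_TO_UG, route=route)]
    interval_s, n_s = schedule.lstrip("q").split("x")
    interval, n = float(interval_s), int(n_s)
    return [DoseEvent(time=i * interval, amount=dose_mg * MG_TO_UG, route=route)
            for i in range(n)]


def _predict_series(series: ObservedSeries, phys: PhysiologyParams,
                    drug: DrugParams, rel_tol: float) -> np.ndarray:
    doses = _parse_schedule(series.schedule, series.dose, series.route)
    grid = np.unique(np.concatenate(([0.0], series.times)))
    t_end = max(grid[-1], doses[-1].time)
    spec = SimulationSpec(physiology=phys, drug=drug, doses=doses,
                          t_end=t_end, output_grid=grid,
                          rel_tol=rel_tol, abs_tol=rel_tol * 1e-2)
    traj = simulate(spec)
    if series.observable == "sodium_excretion_rate":
        traj = pd_timecourse(traj, pd_preset_for(series.group))
    sel = np.isin(grid, series.times)
    return {"plasma_conc": traj.C_plasma,
            "cumulative_urine_amount": traj.A_u,
            "sodium_excretion_rate": traj.E}[series.observable][sel]


def fit_pk(observed: Sequence[ObservedSeries], free: Sequence[str],
           init: Optional[Dict[str, float]] = None,
           bounds: Optional[Dict[str, Tuple[float, float]]] = None,
           base: Optional[Tuple[PhysiologyParams, DrugParams]] = None,
           n_starts: int = 5, seed: int = 0, maxiter: int = 300,
           rel_tol: float = 1e-6, weight_floor_frac: float = 0.05) -> FitResult:
    """Fit PK constants to observed concentration/urine/natriuresis series.

    Weighted least squares across all series jointly, weights
    ``1/max(prediction, floor)`` per point with the floor at
    ``weight_floor_frac`` of each series' maximum prediction; the model is
    re-simulated at every objective evaluation.
    """
    observed = list(observed)
    free = list(free)
    if not free:
        raise ValueError("free parameter set must be non-empty")
    if not any(s.observable == "plasma_conc" for s in observed):
        raise ValueError("need at least one plasma concentration series")
    phys0, drug0 = base if base is not None else resolve_population(observed[0].group)

    def default_init(name: str) -> float:
        if name in _PK_DRUG:
            return getattr(drug0, name)
        if name.startswith("K_p."):
            return drug0.K_p[name.split(".", 1)[1]]
        return getattr(phys0, name)

    init = dict(init or {})
    theta0 = np.array([init.get(name, default_init(name)) for name in free])
    bounds = dict(bounds or {})
    bnds = np.array([bounds.get(name, (theta0[i] / 5.0, theta0[i] * 5.0))
                     for i, name in enumerate(free)])

    obs_concat = np.concatenate([s.values for s in observed])

    def weighted_residuals(theta: np.ndarray) -> np.ndarray:
        phys, drug = _apply_free(phys0, drug0, free, theta)
        chunks = []
        for series in observed:
            pred = _predict_series(series, phys, drug, rel_tol)
            floor = weight_floor_frac * max(float(pred.max()), 1e-12)
            chunks.append((series.values - pred) / np.maximum(pred, floor))
        return np.concatenate(chunks)

    def ssr_fn(theta: np.ndarray) -> float:
        try:
            return float(np.sum(weighted_residuals(theta) ** 2))
        except (ValueError, RuntimeError):
            return 1e30  # invalid parameter region

    starts = np.vstack([theta0, _lhs_starts(bnds, n_starts, seed)])
    trace: List[float] = []
    best = _multistart(ssr_fn, starts, bnds, trace, maxiter)
    refined = least_squares(weighted_residuals, best,
                            bounds=(bnds[:, 0], bnds[:, 1]),
                            xtol=1e-10, ftol=1e-10,
                            diff_step=1e-4)
    theta = refined.x
    ssr = float(np.sum(refined.fun ** 2))
    trace.append(ssr)
    stderr, identifiable = _stderr_from_jac(refined.jac, ssr,
                                            obs_concat.size, len(free))

    phys, drug = _apply_free(phys0, drug0, free, theta)
    pred_concat = np.concatenate(
        [_predict_series(s, phys, drug, rel_tol) for s in observed])
    return FitResult(
        estimates=dict(zip(free, map(float, theta))),
        stderr=dict(zip(free, map(float, stderr))),
        ssr=ssr,
        quality=fit_quality(obs_concat, pred_concat, n_params=len(free)),
        converged=bool(refined.success and identifiable and np.isfinite(ssr)),
        n_obs=int(obs_concat.size), n_params=len(free),
        trace=trace)
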