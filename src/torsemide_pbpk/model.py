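"""Whole-body flow-limited PBPK model of torsemide and its integrator.

The body is represented by a venous/arterial blood pool, the lung in
series with it, and four perfusion-limited tissues (kidney, liver, GI
tract, rest of body).  Oral doses enter a GI depot that feeds the GI
tissue by first-order absorption (``K_a``) and loses drug irreversibly at
``K_e``; IV boluses enter the blood pool.  The liver clears drug by
Michaelis-Menten metabolism driven by the unbound hepatic venous
concentration, and the kidney excretes drug into urine at the first-order
rate ``K_u``.  Urine, metabolite and GI-loss sinks are carried as states
so that total mass is conserved identically.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import DrugParams, PhysiologyParams

MG_TO_UG = 1000.0

#: state-vector layout
STATE_NAMES = ("depot", "blood", "lung", "liver", "kidney", "gi",
               "rest_of_body", "urine", "metabolized", "gi_loss")
_DEPOT, _BL, _LU, _LI, _KI, _GI, _RB, _AU, _MET, _LOSS = range(10)


@dataclass(frozen=True)
class DoseEvent:
    """A single administration: ``amount`` in ug at ``time`` h."""

    time: float
    amount: float
    route: str  # "oral" | "iv_bolus"

    def __post_init__(self) -> None:
        if self.amount <= 0:
            raise ValueError("dose amount must be positive")
        if self.time < 0:
            raise ValueError("dose time must be non-negative")
        if self.route not in ("oral", "iv_bolus"):
            raise ValueError(f"unknown route {self.route!r}")


@dataclass(frozen=True)
class SimulationSpec:
    """Everything needed for one deterministic simulation run."""

    physiology: PhysiologyParams
    drug: DrugParams
    doses: Sequence[DoseEvent]
    t_end: float
    output_grid: np.ndarray
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        grid = np.asarray(self.output_grid, dtype=float)
        object.__setattr__(self, "output_grid", grid)
        if grid.ndim != 1 or grid.size < 2:
            raise ValueError("output_grid must be 1-D with at least 2 points")
        if np.any(np.diff(grid) <= 0):
            raise ValueError("output_grid must be strictly increasing")
        if grid[0] < 0 or grid[-1] > self.t_end + 1e-12:
            raise ValueError("output_grid must lie within [0, t_end]")
        if self.doses and max(d.time for d in self.doses) > self.t_end:
            raise ValueError("t_end must cover every dose time")


@dataclass
class Trajectory:
    """Simulated time course on the requested output grid.

    ``amounts`` holds one ug series per compartment/sink; ``C_plasma`` is
    the plasma concentration derived from the blood pool; ``x`` is the
    urinary torsemide excretion rate K_u*A_kidney (ug/h); ``E`` is filled
    by the PD layer (mEq/h).
    """

    times: np.ndarray
    amounts: Dict[str, np.ndarray]
    C_plasma: np.ndarray
    x: np.ndarray
    dosed: np.ndarray            # cumulative administered amount, ug
    E: Optional[np.ndarray] = None
    meta: Dict[str, object] = field(default_factory=dict)

    @property
    def A_u(self) -> np.ndarray:
        return self.amounts["urine"]

    def mass_balance_error(self) -> np.ndarray:
        """Relative mass-balance defect at each output time."""
        total = sum(self.amounts.values())
        scale = np.maximum(self.dosed, 1.0)
        return (total - self.dosed) / scale


def plasma_from_blood(C_blood: float, hematocrit: float, P_r: float) -> float:
    """Convert whole-blood to plasma concentration.

    Partitioning drug between plasma (fraction ``1 - hct``) and blood
    cells (concentration ratio ``P_r`` to plasma) gives
    ``C_plasma = C_blood / ((1 - hct) + P_r * hct)``.
    """
    denom = (1.0 - hematocrit) + P_r * hematocrit
    if denom <= 0:
        raise ValueError("non-positive plasma partition denominator")
    return C_blood / denom


def urinary_excretion_rate(A_ki, K_u: float):
    """Urinary torsemide excretion rate x = K_u * A_kidney (ug/h)."""
    return K_u * np.maximum(np.asarray(A_ki, dtype=float), 0.0)


def rhs(state: np.ndarray, physiology: PhysiologyParams,
        drug: DrugParams) -> np.ndarray:
    """Time derivatives (ug/h) of all compartments and sinks.

    Each perfusion-limited tissue receives arterial blood at its regional
    flow and returns venous blood at concentration C_tissue/K_p; the liver
    additionally receives the portal (GI venous) stream and loses drug to
    metabolism at ``V_max*V_li*C_u/(K_m + C_u)`` with the unbound hepatic
    venous concentration ``C_u = F_r*C_li/K_li``.
    """
    state = np.asarray(state, dtype=float)
    if np.any(state < -1e-6 * max(1.0, np.abs(state).max())):
        raise ValueError("negative compartment amount beyond tolerance")
    p, d = physiology, drug
    kp = d.K_p

    c_bl = state[_BL] / p.V_bl
    c_lu_out = state[_LU] / (p.V_lu * kp["lung"])      # arterial conc
    c_ki_out = state[_KI] / (p.V_ki * kp["kidney"])
    c_li_out = state[_LI] / (p.V_li * kp["liver"])
    c_gi_out = state[_GI] / (p.V_gi * kp["gi"])
    c_rb_out = state[_RB] / (p.V_rb * kp["rest_of_body"])

    c_u = d.F_r * c_li_out
    metab = d.V_max * p.V_li * c_u / (d.K_m + c_u) if d.V_max > 0 else 0.0
    urine = d.K_u * state[_KI]
    absorb = d.K_a * state[_DEPOT]
    gi_loss = d.K_e * state[_DEPOT]

    out = np.empty(10)
    out[_DEPOT] = -(absorb + gi_loss)
    out[_LU] = p.Q_bl * c_bl - p.Q_lu * c_lu_out
    out[_KI] = p.Q_ki * c_lu_out - p.Q_ki * c_ki_out - urine
    out[_GI] = p.Q_gi * c_lu_out + absorb - p.Q_gi * c_gi_out
    out[_LI] = (p.Q_liar * c_lu_out + p.Q_gi * c_gi_out
                - p.Q_live * c_li_out - metab)
    out[_RB] = p.Q_rb * c_lu_out - p.Q_rb * c_rb_out
    out[_BL] = (p.Q_ki * c_ki_out + p.Q_live * c_li_out
                + p.Q_rb * c_rb_out - p.Q_bl * c_bl)
    out[_AU] = urine
    out[_MET] = metab
    out[_LOSS] = gi_loss
    return out


def simulate(spec: SimulationSpec) -> Trajectory:
    """Integrate the model with dose events handled by restarts.

    Uses the stiff-capable LSODA integrator segment-by-segment between
    dose times; an IV bolus is added to the blood pool and an oral dose to
    the depot at its event time, and grid points at a dose time report the
    post-dose state.
    """
    p, d = spec.physiology, spec.drug
    grid = spec.output_grid

    def fun(t: float, y: np.ndarray) -> np.ndarray:
        return rhs(y, p, d)

    dose_times = sorted({dose.time for dose in spec.doses})
    boundaries = sorted({0.0, spec.t_end, *dose_times})
    doses_at: Dict[float, List[DoseEvent]] = {}
    for dose in spec.doses:
        doses_at.setdefault(dose.time, []).append(dose)

    y = np.zeros(10)
    dosed_total = 0.0
    out = np.full((grid.size, 10), np.nan)
    dosed = np.zeros(grid.size)

    def apply_doses(t: float) -> None:
        nonlocal dosed_total
        for dose in doses_at.get(t, ()):
            idx = _DEPOT if dose.route == "oral" else _BL
            y[idx] += dose.amount
            dosed_total += dose.amount

    for seg_start, seg_end in zip(boundaries[:-1], boundaries[1:]):
        apply_doses(seg_start)
        at_start = np.isclose(grid, seg_start, rtol=0, atol=1e-12)
        out[at_start] = y
        dosed[at_start] = dosed_total
        mask = (grid > seg_start + 1e-12) & (grid <= seg_end + 1e-12)
        t_eval = np.clip(grid[mask], None, seg_end)
        if seg_end > seg_start:
            sol = solve_ivp(fun, (seg_start, seg_end), y, method="LSODA",
                            rtol=spec.rel_tol, atol=spec.abs_tol,
                            t_eval=t_eval if t_eval.size else None,
                            dense_output=False)
            if not sol.success:
                raise RuntimeError(f"integration failed on "
                                   f"[{seg_start}, {seg_end}]: {sol.message}")
            if t_eval.size:
                out[mask] = sol.y.T
                dosed[mask] = dosed_total
            y = sol.y[:, -1].copy()
    apply_doses(spec.t_end)
    at_end = np.isclose(grid, spec.t_end, rtol=0, atol=1e-12)
    out[at_end] = y
    dosed[at_end] = dosed_total

    amounts = {name: out[:, i].copy() for i, name in enumerate(STATE_NAMES)}
    c_blood = amounts["blood"] / p.V_bl
    c_plasma = np.array([plasma_from_blood(c, p.hematocrit, d.P_r)
                         for c in c_blood])
    x = urinary_excretion_rate(amounts["kidney"], d.K_u)
    return Trajectory(times=grid.copy(), amounts=amounts, C_plasma=c_plasma,
                      x=x, dosed=dosed,
                      meta={"rel_tol": spec.rel_tol, "abs_tol": spec.abs_tol})


def single_dose_spec(physiology: PhysiologyParams, drug: DrugParams,
                     dose_mg: float, route: str = "oral",
                     t_end: float = 24.0,
                     n_points: int = 241, rel_tol: float = 1e-8,
                     abs_tol: float = 1e-10) -> SimulationSpec:
    """Convenience builder for a single dose at t = 0 on a uniform grid."""
    return SimulationSpec(
        physiology=physiology, drug=drug,
        doses=[DoseEvent(time=0.0, amount=dose_mg * MG_TO_UG, route=route)],
        t_end=t_end, output_grid=np.linspace(0.0, t_end, n_points),
        rel_tol=rel_tol, abs_tol=abs_tol)
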