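"""Direct-effect natriuresis model and PK-PD hysteresis diagnostics.

The urinary sodium excretion rate E (mEq/h) responds instantaneously to
the urinary torsemide excretion rate x (ug/h) through a baseline sigmoid
Emax model,

    E = E0 + E_max / (1 + (x / EC50)**P),        P < 0,

which is a Hill function with exponent |P|: E rises from the basal rate
E0 at x = 0 (the power term diverges, so E(0) := E0 by continuity) to the
plateau E0 + E_max, passing E0 + E_max/2 exactly at x = EC50.
"""

from __future__ import annotations

import logging
from typing import Dict

import numpy as np

from .model import Trajectory
from .params import PDParams

log = logging.getLogger(__name__)

#: fitted population parameter sets (healthy / cirrhosis CP-B / CHF
#: mild-moderate); cirrhosis severity classes and CHF severities reuse the
#: single fitted set of their group, mirroring the source extrapolation.
PD_PRESETS: Dict[str, PDParams] = {
    "healthy": PDParams(E0=4.39, E_max=105.1, EC50=345.5, P=-2.13),
    "cirrhosis": PDParams(E0=4.33, E_max=65.24, EC50=388.8, P=-2.82),
    "chf": PDParams(E0=3.25, E_max=83.45, EC50=3985.0, P=-1.16),
}


def pd_preset_for(label: str) -> PDParams:
    """PD parameter set for a population label.

    CKD has no fitted natriuresis model; the healthy set is applied (with
    a logged warning), as in the source group-comparison simulations.
    """
    if label.startswith("CP-"):
        return PD_PRESETS["cirrhosis"]
    if label.startswith("CHF-"):
        return PD_PRESETS["chf"]
    if label.startswith("CKD-"):
        log.warning("no fitted PD model exists for CKD; applying the "
                    "healthy-adult natriuresis parameters to %s", label)
        return PD_PRESETS["healthy"]
    return PD_PRESETS["healthy"]


def evaluate_pd(x, pd: PDParams):
    """Sodium excretion rate E (mEq/h) at torsemide excretion rate x (ug/h).

    Accepts scalars or arrays; strictly increasing in x, bounded by
    ``[E0, E0 + E_max]``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("x must be non-negative")
    with np.errstate(divide="ignore", over="ignore"):
        ratio = np.where(x_arr > 0, x_arr / pd.EC50, np.inf) ** pd.P
    e = pd.E0 + pd.E_max / (1.0 + ratio)
    e = np.where(x_arr > 0, e, pd.E0)
    return float(e) if np.isscalar(x) or x_arr.ndim == 0 else e


def pd_timecourse(traj: Trajectory, pd: PDParams) -> Trajectory:
    """Fill the trajectory's E(t) series pointwise (no effect lag)."""
    traj.E = evaluate_pd(traj.x, pd)
    return traj


def hysteresis_area(u, v) -> float:
    """Signed shoelace area of the closed (u(t), v(t)) loop.

    Positive area means the path is traversed counterclockwise; a pure
    single-valued functional relationship gives (numerically) zero area.
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape or u.ndim != 1:
        raise ValueError("u and v must be equal-length 1-D series")
    if u.size < 3:
        raise ValueError("need at least 3 points to form a loop")
    return 0.5 * float(np.sum(u * np.roll(v, -1) - np.roll(u, -1) * v))
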