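"""Non-compartmental analysis and model-validation metrics.

Provides the standard exposure metrics (trapezoidal AUC, Cmax/Tmax,
terminal slope and half-life), fit-quality statistics (RMSE, least-squares
AIC, two-fold error check) and a normalized local parameter-sensitivity
analysis of the PBPK model.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Sequence, Tuple

import numpy as np

from .model import SimulationSpec, simulate
from .params import DrugParams, PhysiologyParams


@dataclass(frozen=True)
class NCAMetrics:
    C_max: float      # ug/mL
    T_max: float      # h
    AUC_0_t: float    # ug*h/mL
    AUC_0_inf: float  # ug*h/mL
    lambda_z: float   # 1/h
    t_half: float     # h
    n_lambda_points: int = 3
    r_squared_adj: float = float("nan")


@dataclass(frozen=True)
class FitQuality:
    rmse: float
    aic: float
    correlation: float
    two_fold_ratios: Tuple[float, ...] = ()

    @property
    def two_fold_pass(self) -> bool:
        return all(0.5 <= r <= 2.0 for r in self.two_fold_ratios)


def auc_trapezoid(times: Sequence[float], values: Sequence[float]) -> float:
    """Linear trapezoidal AUC over the sampled interval."""
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points for a trapezoidal AUC")
    if np.any(np.diff(t) <= 0):
        raise ValueError("times must be strictly increasing")
    return float(np.trapezoid(y, t))


def _loglinear_fit(t: np.ndarray, logc: np.ndarray) -> Tuple[float, float, float]:
    """Slope, intercept and adjusted R^2 of a log-linear terminal fit."""
    n = t.size
    slope, intercept = np.polyfit(t, logc, 1)
    pred = slope * t + intercept
    ss_res = float(np.sum((logc - pred) ** 2))
    ss_tot = float(np.sum((logc - logc.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - 2) if n > 2 else r2
    return slope, intercept, r2_adj


def nca(times: Sequence[float], conc: Sequence[float],
        max_lambda_points: int = 8) -> NCAMetrics:
    """Non-compartmental metrics from a concentration-time profile.

    The terminal slope lambda_z is estimated by log-linear least squares
    on the last 3..``max_lambda_points`` post-Tmax samples, keeping the
    window with the best adjusted R^2; AUC extrapolation to infinity uses
    ``C_last / lambda_z``.
    """
    t = np.asarray(times, dtype=float)
    c = np.asarray(conc, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 points for NCA")
    i_max = int(np.argmax(c))
    c_max, t_max = float(c[i_max]), float(t[i_max])

    tail = (np.arange(t.size) > i_max) & (c > 0)
    tail_idx = np.flatnonzero(tail)
    if tail_idx.size < 3:
        raise ValueError("not enough positive post-Tmax points for lambda_z")

    best = None
    for n_pts in range(3, min(max_lambda_points, tail_idx.size) + 1):
        idx = tail_idx[-n_pts:]
        slope, _, r2_adj = _loglinear_fit(t[idx], np.log(c[idx]))
        if best is None or r2_adj > best[2]:
            best = (slope, n_pts, r2_adj)
    slope, n_pts, r2_adj = best
    lambda_z = -slope
    if lambda_z <= 0:
        raise ValueError("terminal phase is not decaying (lambda_z <= 0)")

    auc_t = auc_trapezoid(t, c)
    c_last = float(c[tail_idx[-1]])
    return NCAMetrics(
        C_max=c_max, T_max=t_max, AUC_0_t=auc_t,
        AUC_0_inf=auc_t + c_last / lambda_z,
        lambda_z=lambda_z, t_half=float(np.log(2) / lambda_z),
        n_lambda_points=n_pts, r_squared_adj=r2_adj)


def rmse(observed: Sequence[float], predicted: Sequence[float]) -> float:
    """Root mean squared error between paired series."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape:
        raise ValueError("series must have equal length")
    return float(np.sqrt(np.mean((obs - pred) ** 2)))


def aic(ssr: float, n: int, k: int) -> float:
    """Least-squares Akaike information criterion n*ln(SSR/n) + 2k."""
    if k < 1 or n <= k:
        raise ValueError("require n > k >= 1")
    if ssr <= 0:
        raise ValueError("SSR must be positive")
    return float(n * np.log(ssr / n) + 2 * k)


def two_fold(predicted_metric: float, observed_metric: float) -> Tuple[float, bool]:
    """Predicted/observed ratio and whether it falls in [0.5, 2]."""
    if predicted_metric <= 0 or observed_metric <= 0:
        raise ValueError("metrics must be positive")
    ratio = predicted_metric / observed_metric
    return ratio, 0.5 <= ratio <= 2.0


def fit_quality(observed: Sequence[float], predicted: Sequence[float],
                n_params: int,
                two_fold_ratios: Sequence[float] = ()) -> FitQuality:
    """Bundle RMSE, AIC and correlation for an observed/predicted pair."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    ssr = float(np.sum((obs - pred) ** 2))
    corr = float(np.corrcoef(obs, pred)[0, 1]) if obs.size > 1 else float("nan")
    return FitQuality(rmse=rmse(obs, pred),
                      aic=aic(max(ssr, 1e-300), obs.size, n_params),
                      correlation=corr,
                      two_fold_ratios=tuple(two_fold_ratios))


# --------------------------------------------------------------------------
# Normalized parameter sensitivity
# --------------------------------------------------------------------------

#: drug parameters perturbable directly
_DRUG_PARAMS = ("V_max", "K_m", "K_a", "K_e", "K_u", "F_r", "P_r")
_KP_PARAMS = tuple(f"K_p.{t}" for t in
                   ("lung", "kidney", "liver", "gi", "rest_of_body"))
_VOLUME_PARAMS = ("V_bl", "V_lu", "V_ki", "V_li", "V_gi", "V_rb")
#: regional flows; dependent totals (Q_lu, Q_bl, Q_live) are re-derived
_FLOW_PARAMS = ("Q_ki", "Q_gi", "Q_liar", "Q_rb")

SENSITIVITY_PARAMETERS = _DRUG_PARAMS + _KP_PARAMS + _VOLUME_PARAMS + _FLOW_PARAMS


def _perturbed(spec: SimulationSpec, name: str, factor: float) -> SimulationSpec:
    phys, drug = spec.physiology, spec.drug
    if name in _DRUG_PARAMS:
        drug = drug.with_(**{name: getattr(drug, name) * factor})
    elif name.startswith("K_p."):
        tissue = name.split(".", 1)[1]
        kp = dict(drug.K_p)
        kp[tissue] = kp[tissue] * factor
        drug = drug.with_(K_p=kp)
    elif name in _VOLUME_PARAMS:
        phys = phys.with_(**{name: getattr(phys, name) * factor})
    elif name in _FLOW_PARAMS:
        flows = {q: getattr(phys, q) for q in _FLOW_PARAMS}
        flows[name] *= factor
        q_lu = sum(flows.values())
        phys = phys.with_(Q_bl=q_lu, Q_lu=q_lu,
                          Q_live=flows["Q_gi"] + flows["Q_liar"], **flows)
    else:
        raise ValueError(f"unknown or non-perturbable parameter {name!r}")
    return replace(spec, physiology=phys, drug=drug)


def normalized_sensitivity(spec: SimulationSpec, parameter: str,
                           perturbation: float = 0.10) -> Dict[str, float]:
    """Normalized local sensitivity S = (dY/Y)/(dp/p) by central difference.

    Returned for Y in {AUC_0_inf, C_max} of the plasma profile.  Perturbing
    a regional blood flow re-derives the dependent totals (lung/total flow
    and hepatic venous outflow) so the circulatory balance is preserved;
    a perturbation that violates a parameter invariant raises.
    """
    results: Dict[str, Dict[str, float]] = {}
    for sign, factor in (("up", 1.0 + perturbation), ("down", 1.0 - perturbation)):
        m = nca(spec.output_grid, simulate(_perturbed(spec, parameter, factor)).C_plasma)
        results[sign] = {"AUC_0_inf": m.AUC_0_inf, "C_max": m.C_max}
    base = nca(spec.output_grid, simulate(spec).C_plasma)
    baseline = {"AUC_0_inf": base.AUC_0_inf, "C_max": base.C_max}
    return {
        metric: ((results["up"][metric] - results["down"][metric])
                 / baseline[metric]) / (2.0 * perturbation)
        for metric in ("AUC_0_inf", "C_max")
    }


def sensitivity_profile(spec: SimulationSpec,
                        parameters: Sequence[str] = SENSITIVITY_PARAMETERS,
                        perturbation: float = 0.10) -> Dict[str, Dict[str, float]]:
    """Normalized sensitivities of AUC and Cmax for every listed parameter."""
    return {name: normalized_sensitivity(spec, name, perturbation)
            for name in parameters}
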