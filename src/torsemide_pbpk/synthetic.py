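"""Synthetic observed-series generator.

Emulates the kind of digitized clinical mean profiles the model is meant
to describe: plasma torsemide concentration, cumulative urinary torsemide
excretion and urinary sodium excretion rate, for single- and multiple-dose
oral/IV designs.  Values are the model's own predictions perturbed by a
configurable measurement-noise model, so parameter-recovery tests close
the loop over the whole pipeline.

The noise model is a stand-in for inter-study and digitization scatter:
independent Gaussian proportional noise (default CV 15%) plus an additive
floor (default 2% of the series maximum), truncated at zero.  It does not
emulate inter-individual variability, sparse/irregular clinical sampling,
or assay LLOQ censoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np

from .model import MG_TO_UG, DoseEvent, SimulationSpec, simulate
from .pd_model import pd_preset_for, pd_timecourse
from .populations import resolve_population
from .scenarios import Regimen

OBSERVABLES = ("plasma_conc", "cumulative_urine_amount", "sodium_excretion_rate")

#: default sampling grids (h): dense early plasma sampling, urine windows
PLASMA_TIMES = (0.25, 0.5, 0.75, 1.0, 1.5, 2.0, 2.5, 3.0, 4.0, 6.0,
                8.0, 10.0, 12.0, 16.0, 20.0, 24.0)
URINE_TIMES = (1.0, 2.0, 3.0, 4.0, 6.0, 8.0, 12.0, 18.0, 24.0)


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian measurement noise: proportional CV + additive SD, seeded."""

    proportional_cv: float = 0.15
    additive_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.proportional_cv < 0 or self.additive_sd < 0:
            raise ValueError("noise magnitudes must be non-negative")


@dataclass
class ObservedSeries:
    """One observable's time-value series with its design metadata."""

    observable: str
    group: str
    dose: float          # mg per administration
    route: str
    schedule: str        # "single" or "q<interval>x<n>"
    times: np.ndarray
    values: np.ndarray
    meta: Dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.observable not in OBSERVABLES:
            raise ValueError(f"unknown observable {self.observable!r}")
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.size != self.values.size:
            raise ValueError("times and values must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("values must be non-negative")
        if (self.observable == "cumulative_urine_amount"
                and np.any(np.diff(self.values) < 0)):
            raise ValueError("cumulative urine series must be non-decreasing")


def _regimen_doses(regimen: Regimen) -> List[DoseEvent]:
    n = regimen.n_doses or 1
    return [DoseEvent(time=i * regimen.interval,
                      amount=regimen.dose * MG_TO_UG, route=regimen.route)
            for i in range(n)]


def _schedule_label(regimen: Regimen) -> str:
    n = regimen.n_doses or 1
    return "single" if n == 1 else f"q{regimen.interval:g}x{n}"


def predict_observables(population: str, regimen: Regimen,
                        times: Sequence[float],
                        drug_overrides: Optional[Dict[str, float]] = None,
                        rel_tol: float = 1e-8) -> Dict[str, np.ndarray]:
    """Noise-free model predictions of every observable at ``times``."""
    phys, drug = resolve_population(population)
    if drug_overrides:
        drug = drug.with_(**drug_overrides)
    times = np.asarray(times, dtype=float)
    grid = np.unique(np.concatenate(([0.0], times)))
    doses = _regimen_doses(regimen)
    t_end = max(grid[-1], doses[-1].time)
    spec = SimulationSpec(physiology=phys, drug=drug, doses=doses,
                          t_end=t_end, output_grid=grid,
                          rel_tol=rel_tol, abs_tol=rel_tol * 1e-2)
    traj = pd_timecourse(simulate(spec), pd_preset_for(population))
    sel = np.isin(grid, times)
    return {
        "plasma_conc": traj.C_plasma[sel],
        "cumulative_urine_amount": traj.A_u[sel],
        "sodium_excretion_rate": traj.E[sel],
    }


def generate_observed(population: str, regimen: Regimen,
                      observables: Sequence[str],
                      times: Sequence[float],
                      noise: NoiseModel) -> List[ObservedSeries]:
    """Model predictions plus seeded measurement noise, one series each.

    ``value = prediction * (1 + eps_p) + eps_a`` with independent Gaussian
    draws, truncated at zero; cumulative series are re-monotonized by a
    running maximum.  Identical inputs and seed give identical output.
    """
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        raise ValueError("sampling times must be non-empty")
    unknown = set(observables) - set(OBSERVABLES)
    if unknown:
        raise ValueError(f"unknown observables: {sorted(unknown)}")
    preds = predict_observables(population, regimen, times)
    rng = np.random.default_rng(noise.seed)
    out = []
    for obs_name in observables:
        pred = preds[obs_name]
        eps_p = rng.normal(0.0, noise.proportional_cv, size=pred.size)
        eps_a = rng.normal(0.0, noise.additive_sd, size=pred.size)
        values = np.maximum(pred * (1.0 + eps_p) + eps_a, 0.0)
        if obs_name == "cumulative_urine_amount":
            values = np.maximum.accumulate(values)
        out.append(ObservedSeries(
            observable=obs_name, group=population, dose=regimen.dose,
            route=regimen.route, schedule=_schedule_label(regimen),
            times=times.copy(), values=values,
            meta={"seed": noise.seed,
                  "proportional_cv": noise.proportional_cv,
                  "additive_sd": noise.additive_sd}))
    return out


@dataclass(frozen=True)
class ScenarioPreset:
    name: str
    population: str
    regimen: Regimen
    observables: tuple
    times: tuple


def scenario_library() -> Dict[str, ScenarioPreset]:
    """Named generator presets covering the fitted/simulated study designs."""
    presets: Dict[str, ScenarioPreset] = {}

    def add(name: str, population: str, regimen: Regimen,
            observables=OBSERVABLES, times=PLASMA_TIMES) -> None:
        presets[name] = ScenarioPreset(name=name, population=population,
                                       regimen=regimen,
                                       observables=tuple(observables),
                                       times=tuple(times))

    for dose in (5, 10, 20):
        add(f"healthy_oral_{dose}mg", "healthy",
            Regimen(dose=dose, route="oral", interval=24.0, n_doses=1))
        add(f"healthy_iv_{dose}mg", "healthy",
            Regimen(dose=dose, route="iv_bolus", interval=24.0, n_doses=1))
    add("healthy_oral_10mg_q24h", "healthy",
        Regimen(dose=10, route="oral", interval=24.0, n_doses=4),
        times=tuple(t + 72.0 for t in PLASMA_TIMES if t <= 12.0))
    for pheno in ("EM", "IM", "PM"):
        add(f"{pheno.lower()}_oral_10mg", pheno,
            Regimen(dose=10, route="oral", interval=24.0, n_doses=1))
    add("cirrhosis_cpb_oral_10mg", "CP-B",
        Regimen(dose=10, route="oral", interval=24.0, n_doses=1))
    add("cirrhosis_cpb_iv_10mg", "CP-B",
        Regimen(dose=10, route="iv_bolus", interval=24.0, n_doses=1))
    for stage in ("mild", "moderate", "severe"):
        add(f"ckd_{stage}_oral_100mg", f"CKD-{stage}",
            Regimen(dose=100, route="oral", interval=24.0, n_doses=1),
            observables=("plasma_conc", "cumulative_urine_amount"))
    for dose in (50, 100, 200):
        add(f"chf_moderate_oral_{dose}mg", "CHF-moderate",
            Regimen(dose=dose, route="oral", interval=24.0, n_doses=1))
    for dose in (5, 10, 20):
        add(f"chf_severe_iv_{dose}mg", "CHF-severe",
            Regimen(dose=dose, route="iv_bolus", interval=24.0, n_doses=1))
    return presets
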