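"""Tidy-CSV readers/writers and YAML parameter configuration.

Interchange format for observed series is long-format CSV with columns
``group, dose_mg, route, observable, time_h, value`` (plus an optional
``schedule`` column, written on export so round trips are lossless).
Trajectories export as tidy ``time_h, variable, value, unit`` rows.
Every file written here embeds a provenance header (resolved parameters,
seed) as ``#``-prefixed comment lines.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Union

import numpy as np
import pandas as pd
import yaml

from .model import Trajectory
from .params import DrugParams, PDParams, PhysiologyParams
from .synthetic import OBSERVABLES, ObservedSeries

PathLike = Union[str, Path]

OBSERVED_COLUMNS = ["group", "dose_mg", "route", "observable", "time_h", "value"]


def _manifest_lines(manifest: Optional[Dict[str, object]]) -> str:
    if not manifest:
        return ""
    return "".join(f"# {key}: {value}\n" for key, value in manifest.items())


def write_observed_csv(series: Sequence[ObservedSeries], path: PathLike,
                       manifest: Optional[Dict[str, object]] = None) -> None:
    """Write observed series as tidy CSV (lossless round trip)."""
    frames = []
    for s in series:
        frames.append(pd.DataFrame({
            "group": s.group, "dose_mg": s.dose, "route": s.route,
            "schedule": s.schedule, "observable": s.observable,
            "time_h": s.times, "value": s.values,
        }))
    table = pd.concat(frames, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_manifest_lines(manifest))
        table.to_csv(fh, index=False)


def read_observed_csv(path: PathLike) -> List[ObservedSeries]:
    """Read observed series from tidy CSV, validating schema and invariants."""
    table = pd.read_csv(path, comment="#")
    missing = [c for c in OBSERVED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"missing required column(s): {', '.join(missing)}")
    bad_obs = set(table["observable"]) - set(OBSERVABLES)
    if bad_obs:
        rows = table.index[table["observable"].isin(bad_obs)] + 2  # header line
        raise ValueError(f"unknown observable label(s) {sorted(bad_obs)} "
                         f"at line(s) {list(rows)}")
    bad_rows = table.index[table[["time_h", "value"]].isna().any(axis=1)] + 2
    if len(bad_rows):
        raise ValueError(f"malformed row(s) at line(s) {list(bad_rows)}")
    has_schedule = "schedule" in table.columns
    out = []
    keys = ["group", "dose_mg", "route", "observable"] + (
        ["schedule"] if has_schedule else [])
    for key, sub in table.groupby(keys, sort=False):
        key = dict(zip(keys, key))
        times = sub["time_h"].to_numpy(dtype=float)
        if np.any(np.diff(times) <= 0):
            raise ValueError(
                f"non-monotone times within series {key}")
        out.append(ObservedSeries(
            observable=key["observable"], group=str(key["group"]),
            dose=float(key["dose_mg"]), route=str(key["route"]),
            schedule=str(key.get("schedule", "single")),
            times=times, values=sub["value"].to_numpy(dtype=float)))
    return out


_TRAJ_UNITS = {"C_plasma": "ug/mL", "x": "ug/h", "E": "mEq/h"}


def write_trajectory_csv(traj: Trajectory, path: PathLike,
                         manifest: Optional[Dict[str, object]] = None) -> None:
    """Export a trajectory as tidy time/variable/value/unit rows."""
    rows = []
    for name, values in traj.amounts.items():
        rows.append(pd.DataFrame({"time_h": traj.times, "variable": name,
                                  "value": values, "unit": "ug"}))
    rows.append(pd.DataFrame({"time_h": traj.times, "variable": "C_plasma",
                              "value": traj.C_plasma, "unit": "ug/mL"}))
    rows.append(pd.DataFrame({"time_h": traj.times, "variable": "x",
                              "value": traj.x, "unit": "ug/h"}))
    if traj.E is not None:
        rows.append(pd.DataFrame({"time_h": traj.times, "variable": "E",
                                  "value": traj.E, "unit": "mEq/h"}))
    table = pd.concat(rows, ignore_index=True)
    with open(path, "w") as fh:
        fh.write(_manifest_lines(manifest))
        table.to_csv(fh, index=False)


# --------------------------------------------------------------------------
# YAML parameter configuration
# --------------------------------------------------------------------------

def params_to_dict(phys: PhysiologyParams, drug: DrugParams,
                   pd_params: Optional[PDParams] = None) -> Dict[str, dict]:
    """Serialize parameter objects to the sectioned config mapping."""
    out = {"physiology": dataclasses.asdict(phys),
           "drug": dataclasses.asdict(drug)}
    if pd_params is not None:
        out["pd"] = dataclasses.asdict(pd_params)
    return out


def params_from_dict(config: Dict[str, dict]):
    """Build parameter objects from a sectioned config mapping.

    Returns ``(PhysiologyParams, DrugParams)`` or, when a ``pd`` section
    is present, ``(PhysiologyParams, DrugParams, PDParams)``.
    """
    phys = PhysiologyParams(**config["physiology"])
    drug = DrugParams(**config["drug"])
    if "pd" in config:
        return phys, drug, PDParams(**config["pd"])
    return phys, drug


def dump_params_yaml(path: PathLike, phys: PhysiologyParams, drug: DrugParams,
                     pd_params: Optional[PDParams] = None) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(phys, drug, pd_params), fh,
                       sort_keys=False)


def load_params_yaml(path: PathLike):
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh))
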