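"""Population rescaling of the healthy-adult parameter set.

Implements the published parameter-substitution rules for CYP2C9
phenotypes (extensive / intermediate / poor metabolizers), liver cirrhosis
(Child-Pugh A/B/C), chronic kidney disease (mild/moderate/severe by GFR)
and congestive heart failure (NYHA mild/moderate/severe).

Each transform returns new parameter objects; the inputs are never
mutated, and the circulatory mass-balance invariants are re-validated by
construction of the returned :class:`~torsemide_pbpk.params.PhysiologyParams`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Tuple

from .params import (
    HEALTHY_CYP2C9_ABUNDANCE,
    HEALTHY_HEMATOCRIT,
    HEALTHY_TOTAL_PROTEIN,
    DrugParams,
    PhysiologyParams,
    healthy_reference,
)

log = logging.getLogger(__name__)

# --- CYP2C9 phenotype metabolic constants (microsomal Vmax ug/mL/h, Km ug/mL)
CYP2C9_TABLE: Dict[str, Tuple[float, float]] = {
    "EM": (2.216, 1.951),
    "IM": (0.886, 5.073),
    "PM": (0.222, 8.242),
}

# --- Cirrhosis scaling table (fractions of healthy unless noted)
CIRRHOSIS_TABLE: Dict[str, Dict[str, float]] = {
    "CP-A": {
        "liver_volume_fraction": 0.81,
        "cardiac_output_fraction": 1.16,
        "kidney_blood_flow_fraction": 0.70,
        "portal_blood_flow_fraction": 0.91,
        "hepatic_arterial_blood_flow_fraction": 1.41,
        "villous_blood_flow_fraction": 1.29,
        "hematocrit_pct": 38.46,
        "total_protein_g_per_L": 46.33,
        "cyp2c9_pmol_per_mg": 50.4,
        "kp_multiplier": 1.05,
    },
    "CP-B": {
        "liver_volume_fraction": 0.65,
        "cardiac_output_fraction": 1.32,
        "kidney_blood_flow_fraction": 0.58,
        "portal_blood_flow_fraction": 0.63,
        "hepatic_arterial_blood_flow_fraction": 1.62,
        "villous_blood_flow_fraction": 1.52,
        "hematocrit_pct": 34.51,
        "total_protein_g_per_L": 38.18,
        "cyp2c9_pmol_per_mg": 38.0,
        "kp_multiplier": 1.08,
    },
    "CP-C": {
        "liver_volume_fraction": 0.53,
        "cardiac_output_fraction": 1.41,
        "kidney_blood_flow_fraction": 0.55,
        "portal_blood_flow_fraction": 0.55,
        "hepatic_arterial_blood_flow_fraction": 1.91,
        "villous_blood_flow_fraction": 1.99,
        "hematocrit_pct": 33.51,
        "total_protein_g_per_L": 29.69,
        "cyp2c9_pmol_per_mg": 24.1,
        "kp_multiplier": 1.12,
    },
}

# --- CKD scaling table
CKD_TABLE: Dict[str, Dict[str, float]] = {
    "mild": {
        "kidney_volume_fraction": 0.99,
        "kidney_blood_flow_fraction": 0.99,
        "liver_intrinsic_clearance_fraction": 1.00,
        "renal_elimination_rate_fraction": 0.99,
    },
    "moderate": {
        "kidney_volume_fraction": 0.93,
        "kidney_blood_flow_fraction": 0.86,
        "liver_intrinsic_clearance_fraction": 0.69,
        "renal_elimination_rate_fraction": 0.68,
    },
    "severe": {
        "kidney_volume_fraction": 0.87,
        "kidney_blood_flow_fraction": 0.72,
        "liver_intrinsic_clearance_fraction": 0.52,
        "renal_elimination_rate_fraction": 0.37,
    },
}

# --- CHF scaling table
CHF_TABLE: Dict[str, Dict[str, float]] = {
    "mild": {
        "cardiac_output_fraction": 0.69,
        "kidney_blood_flow_fraction": 0.78,
        "portal_blood_flow_fraction": 0.76,
        "hepatic_arterial_blood_flow_fraction": 0.76,
        "other_tissues_blood_flow_fraction": 0.57,
        "liver_intrinsic_clearance_fraction": 0.76,
    },
    "moderate": {
        "cardiac_output_fraction": 0.50,
        "kidney_blood_flow_fraction": 0.55,
        "portal_blood_flow_fraction": 0.54,
        "hepatic_arterial_blood_flow_fraction": 0.54,
        "other_tissues_blood_flow_fraction": 0.44,
        "liver_intrinsic_clearance_fraction": 0.54,
    },
    "severe": {
        "cardiac_output_fraction": 0.42,
        "kidney_blood_flow_fraction": 0.63,
        "portal_blood_flow_fraction": 0.46,
        "hepatic_arterial_blood_flow_fraction": 0.46,
        "other_tissues_blood_flow_fraction": 0.28,
        "liver_intrinsic_clearance_fraction": 0.46,
    },
}


@dataclass(frozen=True)
class PopulationScalers:
    """A population class label with its parameter-fraction table."""

    label: str
    fractions: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, value in self.fractions.items():
            if value <= 0:
                raise ValueError(f"scaler {key!r} must be positive")


def intrinsic_clearance(drug: DrugParams) -> float:
    """Liver intrinsic clearance Vmax/Km on the per-mL-liver basis (1/h)."""
    if drug.K_m <= 0:
        raise ValueError("K_m must be positive")
    return drug.V_max / drug.K_m


def apply_cyp2c9(drug: DrugParams, phenotype: str) -> DrugParams:
    """Replace (V_max, K_m) by the CYP2C9 phenotype pair; all else unchanged."""
    try:
        v_max, k_m = CYP2C9_TABLE[phenotype]
    except KeyError:
        raise ValueError(
            f"unknown CYP2C9 phenotype {phenotype!r}; expected one of "
            f"{sorted(CYP2C9_TABLE)}") from None
    return drug.with_(V_max=v_max, K_m=k_m)


def fr_diseased(fr_healthy: float, pt_healthy: float, pt_diseased: float) -> float:
    """Unbound fraction rescaled for a changed total plasma protein level.

    Assumes binding-site concentration proportional to total protein at
    fixed affinity, which gives
    ``1 / (1 + (1 - Fr_h) * PT_d / (PT_h * Fr_h))``.
    """
    if not 0.0 < fr_healthy <= 1.0:
        raise ValueError("fr_healthy must be in (0, 1]")
    if pt_healthy <= 0 or pt_diseased <= 0:
        raise ValueError("protein concentrations must be positive")
    return 1.0 / (1.0 + (1.0 - fr_healthy) * pt_diseased / (pt_healthy * fr_healthy))


def pr_diseased(pr_healthy: float, hct_healthy: float, hct_diseased: float) -> float:
    """Plasma-to-blood-cell partition ratio rescaled by the hematocrit ratio."""
    if pr_healthy <= 0 or hct_healthy <= 0 or hct_diseased <= 0:
        raise ValueError("inputs must be positive")
    return pr_healthy * (hct_diseased / hct_healthy)


def apply_cirrhosis(
    phys: PhysiologyParams, drug: DrugParams, cp_class: str
) -> Tuple[PhysiologyParams, DrugParams]:
    """Rescale parameters for a Child-Pugh cirrhosis class (A, B or C).

    Liver volume, regional flows, hematocrit, total protein and the
    drug-side constants (K_e via villous flow, V_max via CYP2C9 abundance,
    F_r/P_r via protein and hematocrit, K_p via a uniform class multiplier)
    are replaced; the rest-of-body flow is the remainder that closes the
    circulatory balance.
    """
    key = cp_class if cp_class.startswith("CP-") else f"CP-{cp_class}"
    try:
        t = CIRRHOSIS_TABLE[key]
    except KeyError:
        raise ValueError(f"unknown Child-Pugh class {cp_class!r}; "
                         f"expected A, B or C") from None

    q_lu = phys.Q_lu * t["cardiac_output_fraction"]
    q_ki = phys.Q_ki * t["kidney_blood_flow_fraction"]
    q_gi = phys.Q_gi * t["portal_blood_flow_fraction"]
    q_liar = phys.Q_liar * t["hepatic_arterial_blood_flow_fraction"]
    q_rb = q_lu - (q_ki + q_gi + q_liar)
    if q_rb <= 0:
        raise ValueError(f"inconsistent scaler table for {key}: "
                         "remainder rest-of-body flow is non-positive")

    new_phys = phys.with_(
        V_li=phys.V_li * t["liver_volume_fraction"],
        Q_bl=q_lu, Q_lu=q_lu, Q_ki=q_ki, Q_gi=q_gi, Q_liar=q_liar,
        Q_live=q_gi + q_liar, Q_rb=q_rb,
        hematocrit=t["hematocrit_pct"] / 100.0,
        total_protein=t["total_protein_g_per_L"],
    )
    new_drug = drug.with_(
        V_max=drug.V_max * t["cyp2c9_pmol_per_mg"] / HEALTHY_CYP2C9_ABUNDANCE,
        K_e=drug.K_e * t["villous_blood_flow_fraction"],
        F_r=fr_diseased(drug.F_r, phys.total_protein, t["total_protein_g_per_L"]),
        P_r=pr_diseased(drug.P_r, phys.hematocrit, t["hematocrit_pct"] / 100.0),
        K_p={k: v * t["kp_multiplier"] for k, v in drug.K_p.items()},
    )
    return new_phys, new_drug


def apply_ckd(
    phys: PhysiologyParams, drug: DrugParams, stage: str
) -> Tuple[PhysiologyParams, DrugParams]:
    """Rescale parameters for a CKD severity stage (mild/moderate/severe).

    The renal blood flow decrement is routed to the rest of the body so
    that total circulating flow is preserved (compensatory redistribution).
    """
    try:
        t = CKD_TABLE[stage]
    except KeyError:
        raise ValueError(f"unknown CKD stage {stage!r}; expected one of "
                         f"{sorted(CKD_TABLE)}") from None
    q_ki = phys.Q_ki * t["kidney_blood_flow_fraction"]
    q_rb = phys.Q_rb + (phys.Q_ki - q_ki)  # compensation keeps Q_lu fixed
    new_phys = phys.with_(
        V_ki=phys.V_ki * t["kidney_volume_fraction"],
        Q_ki=q_ki, Q_rb=q_rb,
    )
    new_drug = drug.with_(
        V_max=drug.V_max * t["liver_intrinsic_clearance_fraction"],
        K_u=drug.K_u * t["renal_elimination_rate_fraction"],
    )
    return new_phys, new_drug


def apply_chf(
    phys: PhysiologyParams, drug: DrugParams, stage: str
) -> Tuple[PhysiologyParams, DrugParams]:
    """Rescale parameters for a CHF severity stage (mild/moderate/severe).

    Regional flows are scaled by their tabulated fractions and the total
    (lung) flow is recomputed as their sum; the tabulated cardiac-output
    fraction is logged as a consistency diagnostic rather than imposed,
    since the regional fractions do not sum to it exactly.
    """
    try:
        t = CHF_TABLE[stage]
    except KeyError:
        raise ValueError(f"unknown CHF stage {stage!r}; expected one of "
                         f"{sorted(CHF_TABLE)}") from None
    q_ki = phys.Q_ki * t["kidney_blood_flow_fraction"]
    q_gi = phys.Q_gi * t["portal_blood_flow_fraction"]
    q_liar = phys.Q_liar * t["hepatic_arterial_blood_flow_fraction"]
    q_rb = phys.Q_rb * t["other_tissues_blood_flow_fraction"]
    q_lu = q_ki + q_gi + q_liar + q_rb
    implied = q_lu / phys.Q_lu
    if abs(implied - t["cardiac_output_fraction"]) > 1e-12:
        log.info("CHF %s: summed regional flows imply cardiac-output fraction "
                 "%.3f vs tabulated %.2f (conservation takes precedence)",
                 stage, implied, t["cardiac_output_fraction"])
    new_phys = phys.with_(
        Q_bl=q_lu, Q_lu=q_lu, Q_ki=q_ki, Q_gi=q_gi, Q_liar=q_liar,
        Q_live=q_gi + q_liar, Q_rb=q_rb,
    )
    new_drug = drug.with_(
        V_max=drug.V_max * t["liver_intrinsic_clearance_fraction"],
    )
    return new_phys, new_drug


#: labels resolvable by :func:`resolve_population`
POPULATION_LABELS = (
    "healthy", "EM", "IM", "PM",
    "CP-A", "CP-B", "CP-C",
    "CKD-mild", "CKD-moderate", "CKD-severe",
    "CHF-mild", "CHF-moderate", "CHF-severe",
)


def resolve_population(label: str) -> Tuple[PhysiologyParams, DrugParams]:
    """Return the (physiology, drug) parameter set for a population label.

    Disease transforms start from the healthy reference; CYP2C9 phenotype
    labels replace only the metabolic constants.
    """
    phys, drug = healthy_reference()
    if label == "healthy":
        return phys, drug
    if label in CYP2C9_TABLE:
        return phys, apply_cyp2c9(drug, label)
    if label.startswith("CP-"):
        return apply_cirrhosis(phys, drug, label)
    if label.startswith("CKD-"):
        return apply_ckd(phys, drug, label.split("-", 1)[1])
    if label.startswith("CHF-"):
        return apply_chf(phys, drug, label.split("-", 1)[1])
    raise ValueError(
        f"unknown population label {label!r}; valid labels: "
        + ", ".join(POPULATION_LABELS))
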