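"""Parameter containers for the whole-body torsemide model.

Units are fixed package-wide: amounts in ug, volumes in mL, blood flows in
mL/h, concentrations in ug/mL, time in h, urinary torsemide excretion rate
in ug/h, urinary sodium excretion rate in mEq/h.  Doses supplied in mg at
the public interfaces are converted (1 mg = 1000 ug).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict

#: relative tolerance for the blood-flow mass-balance invariants
FLOW_RTOL = 1e-9

TISSUES = ("lung", "kidney", "liver", "gi", "rest_of_body")


def _close(a: float, b: float, rtol: float = FLOW_RTOL) -> bool:
    scale = max(abs(a), abs(b), 1.0)
    return abs(a - b) <= rtol * scale


@dataclass(frozen=True)
class PhysiologyParams:
    """Tissue volumes, regional blood flows and blood composition.

    Flows must satisfy the circulatory mass balance: the lung (total) flow
    equals the sum of the regional arterial supplies, and the hepatic venous
    outflow equals portal plus hepatic-arterial inflow.
    """

    V_bl: float   # blood volume, mL
    V_lu: float   # lung, mL
    V_ki: float   # kidneys, mL
    V_li: float   # liver, mL
    V_gi: float   # GI tract, mL
    V_rb: float   # rest of body, mL
    Q_bl: float   # total circulating blood flow, mL/h
    Q_lu: float   # lung flow (= Q_bl), mL/h
    Q_ki: float   # renal blood flow, mL/h
    Q_gi: float   # portal (GI) blood flow, mL/h
    Q_liar: float  # hepatic arterial blood flow, mL/h
    Q_live: float  # hepatic venous outflow (= Q_gi + Q_liar), mL/h
    Q_rb: float   # rest-of-body blood flow, mL/h
    hematocrit: float      # fraction, 0-1
    total_protein: float   # albumin + alpha1-acid glycoprotein, g/L

    def __post_init__(self) -> None:
        for name in ("V_bl", "V_lu", "V_ki", "V_li", "V_gi", "V_rb",
                     "Q_bl", "Q_lu", "Q_ki", "Q_gi", "Q_liar", "Q_live",
                     "Q_rb", "total_protein"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0.0 < self.hematocrit < 1.0:
            raise ValueError("hematocrit must be in (0, 1)")
        if not _close(self.Q_lu, self.Q_ki + self.Q_gi + self.Q_liar + self.Q_rb):
            raise ValueError("lung outflow balance violated: "
                             "Q_lu != Q_ki + Q_gi + Q_liar + Q_rb")
        if not _close(self.Q_live, self.Q_gi + self.Q_liar):
            raise ValueError("hepatic outflow balance violated: "
                             "Q_live != Q_gi + Q_liar")
        if not _close(self.Q_bl, self.Q_lu):
            raise ValueError("total circulating flow must equal lung flow")

    def with_(self, **changes) -> "PhysiologyParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class DrugParams:
    """Torsemide-specific constants.

    ``V_max`` is the maximum hepatic metabolic rate per mL of liver
    (ug/mL/h); ``K_m`` the Michaelis constant (ug/mL); ``K_a``/``K_e`` the
    first-order oral absorption and pre-absorptive GI loss constants (1/h);
    ``K_u`` the first-order renal excretion constant (1/h); ``F_r`` the
    plasma unbound fraction; ``P_r`` the plasma-to-blood-cell partition
    ratio; ``K_p`` the tissue-to-blood partition coefficients.
    """

    V_max: float
    K_m: float
    K_a: float
    K_e: float
    K_u: float
    F_r: float
    P_r: float
    K_p: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("V_max", "K_m", "K_a", "K_u"):
            if getattr(self, name) <= 0 and not (name == "V_max" and self.V_max == 0):
                # V_max = 0 is allowed to switch metabolism off in analyses
                raise ValueError(f"{name} must be strictly positive")
        if self.V_max < 0:
            raise ValueError("V_max must be non-negative")
        if self.K_e < 0:
            raise ValueError("K_e must be non-negative")
        if not 0.0 < self.F_r <= 1.0:
            raise ValueError("F_r must be in (0, 1]")
        if self.P_r < 0:
            raise ValueError("P_r must be non-negative")
        if set(self.K_p) != set(TISSUES):
            raise ValueError(f"K_p must map exactly the tissues {TISSUES}")
        for tissue, kp in self.K_p.items():
            if kp <= 0:
                raise ValueError(f"K_p[{tissue!r}] must be strictly positive")

    def with_(self, **changes) -> "DrugParams":
        return replace(self, **changes)


@dataclass(frozen=True)
class PDParams:
    """Baseline sigmoid Emax constants of the natriuresis model.

    ``E0`` basal urinary sodium excretion rate (mEq/h); ``E_max`` the
    maximal increment above basal (mEq/h); ``EC50`` the urinary torsemide
    excretion rate at half-maximal effect (ug/h); ``P`` the (negative)
    slope constant.
    """

    E0: float
    E_max: float
    EC50: float
    P: float

    def __post_init__(self) -> None:
        if self.E0 < 0:
            raise ValueError("E0 must be non-negative")
        if self.E_max <= 0:
            raise ValueError("E_max must be strictly positive")
        if self.EC50 <= 0:
            raise ValueError("EC50 must be strictly positive")
        if self.P >= 0:
            raise ValueError("P must be negative (sigmoid slope convention)")

    def with_(self, **changes) -> "PDParams":
        return replace(self, **changes)


# --------------------------------------------------------------------------
# Healthy-adult reference set
#
# Tissue volumes and regional flows follow standard reference-adult
# physiology (blood ~5.2 L, liver 1.69 L, kidneys 0.31 L; total blood flow
# 390 L/h split ~19% kidney, ~17% portal, ~6.5% hepatic artery, remainder
# rest-of-body).  Hematocrit and total protein are the healthy-control
# values of the cirrhosis scaling table.  V_max/K_m are the extensive-
# metabolizer (EM) CYP2C9 microsomal constants; F_r = 0.05 (95% protein
# bound) and P_r = 0.279 are literature in-vitro values.  K_a, K_e, K_u,
# V_rb and the per-tissue K_p (all <= 1) were calibrated once so that a
# single 10 mg oral dose yields Tmax in 2-3 h and a terminal half-life in
# 3-6 h; see docs/methods.md.
# --------------------------------------------------------------------------

HEALTHY_HEMATOCRIT = 0.43
HEALTHY_TOTAL_PROTEIN = 50.34  # g/L
HEALTHY_CYP2C9_ABUNDANCE = 73.0  # pmol/mg microsomal protein

_Q_TOTAL = 390_000.0  # mL/h
_Q_KI = 0.19 * _Q_TOTAL
_Q_GI = 0.17 * _Q_TOTAL
_Q_LIAR = 0.065 * _Q_TOTAL
_Q_RB = _Q_TOTAL - (_Q_KI + _Q_GI + _Q_LIAR)

HEALTHY_PHYSIOLOGY = PhysiologyParams(
    V_bl=5200.0,
    V_lu=500.0,
    V_ki=310.0,
    V_li=1690.0,
    V_gi=1200.0,
    V_rb=30000.0,
    Q_bl=_Q_TOTAL,
    Q_lu=_Q_TOTAL,
    Q_ki=_Q_KI,
    Q_gi=_Q_GI,
    Q_liar=_Q_LIAR,
    Q_live=_Q_GI + _Q_LIAR,
    Q_rb=_Q_RB,
    hematocrit=HEALTHY_HEMATOCRIT,
    total_protein=HEALTHY_TOTAL_PROTEIN,
)

HEALTHY_DRUG = DrugParams(
    V_max=2.216,   # ug/mL liver/h, EM phenotype
    K_m=1.951,     # ug/mL, EM phenotype
    K_a=0.85,      # 1/h, calibrated
    K_e=0.15,      # 1/h, calibrated
    K_u=9.5,       # 1/h, calibrated
    F_r=0.05,
    P_r=0.279,
    K_p={"lung": 0.60, "kidney": 0.70, "liver": 0.90,
         "gi": 0.70, "rest_of_body": 0.15},
)


def healthy_reference() -> tuple[PhysiologyParams, DrugParams]:
    """Return the calibrated healthy-adult (physiology, drug) defaults."""
    return HEALTHY_PHYSIOLOGY, HEALTHY_DRUG
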