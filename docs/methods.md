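# Methods

## Model structure

The pharmacokinetic core is a whole-body, flow-limited (perfusion-rate-
limited) compartment model with a merged venous/arterial blood pool, the
lung in series with it, and four tissues — kidney, liver, GI tract and a
lumped rest-of-body — each connected by regional blood flows. Amounts are
tracked in µg; a tissue with volume `V_t` and tissue-to-blood partition
coefficient `K_t` receives arterial drug at `Q_t · C_art` and returns
venous drug at `Q_t · A_t/(V_t · K_t)`. The arterial concentration is the
lung outflow `A_lu/(V_lu · K_lu)`; the liver additionally receives the GI
venous (portal) stream, so hepatic venous outflow runs at
`Q_live = Q_gi + Q_liar`.

Dosing: an IV bolus adds to the blood pool; an oral dose enters a depot
that feeds the GI tissue at the first-order absorption rate `K_a` and
loses drug irreversibly at `K_e` (pre-absorptive GI loss), making oral
bioavailability `K_a/(K_a + K_e)`. Elimination is (i) hepatic
Michaelis–Menten metabolism at rate `V_max · V_li · C_u/(K_m + C_u)`,
driven by the unbound hepatic venous concentration
`C_u = F_r · C_li/K_li` (the Michaelis constant is a microsomal, i.e.
low-protein, in-vitro quantity, so the unbound concentration is the
appropriate driver), and (ii) first-order renal excretion `K_u · A_ki`
from the kidney compartment into a urine sink. Urine, metabolite and
GI-loss sinks are integrated as states, so total mass is conserved
identically by construction; the integrator reproduces that balance to
~1e-14 relative.

The reported observable is the plasma concentration
`C_plasma = C_blood / ((1 − hct) + P_r · hct)`, which partitions whole-
blood drug between plasma water+proteins and blood cells with cell-to-
plasma ratio `P_r`.

A consequence of the unbound-concentration driver worth stating plainly:
with 95% protein binding (`F_r = 0.05`) the unbound concentration stays
far below `K_m` at clinical doses, so the model is PK-linear up to 200 mg
and the metabolic share of total clearance is small. CYP2C9 phenotype and
disease effects on hepatic clearance are therefore directionally correct
but modest in magnitude; the dominant elimination route in the calibrated
healthy model is renal.

## Pharmacodynamics

The natriuretic effect is a simple direct-effect model: the urinary
sodium excretion rate responds instantaneously to the urinary torsemide
excretion rate `x = K_u · A_ki` through a baseline sigmoid Emax function

    E(x) = E0 + E_max / (1 + (x/EC50)^P),   P < 0,

equivalent to a Hill function with exponent `|P|` (unit-tested
equivalence). `E(0) := E0` by right-limit continuity. The fitted
population sets are healthy adults, cirrhosis (fitted on Child-Pugh B,
reused for A and C) and CHF (fitted on mild–moderate, reused for all
severities); that reuse mirrors the provenance of the published fits and
carries no claim of severity-specific accuracy. No CKD natriuresis model
exists; CKD simulations apply the healthy set and log a warning.

The direct-effect assumption is checked, not just asserted: after an oral
dose the (C_plasma, E) loop is counterclockwise (absorption delay), while
the (x, E) loop area, normalized by the series ranges, is below 0.01 for
both routes. Loop areas use the signed shoelace formula; resolving the
post-IV-bolus upstroke of x (a time scale of seconds, set by
`Q_ki/(V_ki·K_ki)`) requires a log-dense early output grid, otherwise the
discrete polygon cuts a spurious chord across the response curve.

## Parameters

Units package-wide: amounts µg, volumes mL, flows mL/h, concentrations
µg/mL, time h, sodium excretion mEq/h; doses in mg at interfaces.

Healthy reference physiology is a standard reference adult: blood 5.2 L,
liver 1.69 L, kidneys 0.31 L, lung 0.5 L, GI 1.2 L, rest-of-body 30 L;
total blood flow 390 L/h split 19% kidney, 17% portal, 6.5% hepatic
artery, remainder rest-of-body; hematocrit 0.43; total binding protein
(albumin + α1-acid glycoprotein) 50.34 g/L. Drug constants with direct
in-vitro provenance: `V_max = 2.216 µg/mL/h`, `K_m = 1.951 µg/mL`
(extensive-metabolizer microsomal values, per mL liver), `F_r = 0.05`,
`P_r = 0.279`.

`K_a = 0.85/h`, `K_e = 0.15/h`, `K_u = 9.5/h` and the per-tissue `K_p`
(0.15–0.9, all ≤ 1) have no printed source values; they were calibrated
once, before any acceptance measurement, against the only published
constraints on the healthy profile — oral Tmax within 2–3 h and terminal
half-life within 3–6 h — and then frozen. The calibrated defaults give
Tmax 2.2 h, t½ 4.15 h, Cmax 0.68 µg/mL and AUC0–∞ 5.86 µg·h/mL for a
10 mg oral dose. All defaults are plain dataclass constants and can be
overridden via the YAML config (`physiology`/`drug`/`pd` sections, keys
named as the dataclass fields, units fixed by the convention above).

## Population rescaling

Each transform copies the healthy objects and revalidates the
circulatory invariants (`Q_lu = Q_ki + Q_gi + Q_liar + Q_rb`,
`Q_live = Q_gi + Q_liar`, `Q_bl = Q_lu`, all to 1e-9 relative).

- **CYP2C9 phenotypes** replace `(V_max, K_m)` by the phenotype pair;
  each step EM→IM→PM multiplies intrinsic clearance `V_max/K_m` by ~0.15.
- **Cirrhosis (CP-A/B/C)** scales liver volume, cardiac output, renal,
  portal and hepatic-arterial flows by the class fractions;
  `Q_rb` is defined as the remainder closing the lung balance (an error is
  raised if it would go non-positive); `K_e` scales with villous flow;
  `V_max` scales with CYP2C9 abundance (healthy 73 pmol/mg);
  `F_r` is recomputed from total protein assuming binding-site
  concentration proportional to protein at fixed affinity,
  `F_r' = 1/[1 + (1 − F_r)·PT'/(PT·F_r)]`; `P_r` scales with the
  hematocrit ratio. Per-tissue diseased `K_p` values are not published
  individually; a single uniform multiplier per class (1.05/1.08/1.12,
  matching the published ~5–12% range) is applied and user-overridable —
  an acknowledged approximation.
- **CKD (mild/moderate/severe)** scales kidney volume and flow, `V_max`
  by the liver-intrinsic-clearance fraction and `K_u` by the renal-
  elimination fraction; the renal flow decrement is added to the
  rest-of-body flow, preserving total flow (compensatory redistribution).
- **CHF (mild/moderate/severe)** scales all four regional flows by their
  tabulated fractions and recomputes the total as their sum; the
  tabulated cardiac-output fraction is generally inconsistent with that
  sum, so conservation wins and the implied fraction is logged as a
  diagnostic. `V_max` scales with the hepatic blood-flow fraction.

## Numerics

Integration uses LSODA (stiff-capable, adaptive) with `rtol 1e-8` /
`atol 1e-10` defaults, restarted at each dose event; grid points at a
dose time report the post-dose state. The fast lung and kidney exchange
rates (~10³/h) make the system mildly stiff. Verified properties:
tolerance refinement changes the plasma profile < 0.1% pointwise; a
fixed-step RK4 oracle at h = 0.001 h agrees within 0.5%; with metabolism
and GI loss disabled an IV dose is fully recovered in urine.

NCA: linear trapezoidal AUC; `lambda_z` by log-linear least squares over
the last 3–8 post-Tmax points choosing the window with the best adjusted
R²; `AUC0–∞ = AUC0–t + C_last/lambda_z`. AIC uses the least-squares form
`n·ln(SSR/n) + 2k`. Sensitivities are ±10% central differences of
normalized AUC0–∞ and Cmax; perturbing a regional flow re-derives the
dependent totals so the balance invariants hold. Note that the AUC
sensitivity to `K_u` in a renal-only configuration is −0.96 rather than
the one-compartment closed-form −1: renal extraction is mildly
flow-limited in a whole-body model (`K_u·V_ki·K_ki` is not negligible
against `Q_ki`).

Steady state is declared when successive dosing-interval plasma AUCs
change by < 1e-3 relative (cap 40 intervals; with t½ ≈ 4 h, q12h dosing
converges in ~5 intervals). Metrics are computed over the final interval.

Fitting uses a seeded Latin-hypercube multistart of penalized
Nelder-Mead followed by bounded trust-region least-squares refinement;
standard errors come from the Gauss-Newton curvature at the solution and
a condition number > 1e12 flags unidentifiability. PK objectives are
weighted `1/max(prediction, floor)` per point with the floor at 5% of
each series' maximum prediction, and re-simulate the model (at relaxed
`rtol 1e-6`) every evaluation. The objective/weighting used in the
original multi-tool fits is not published; these are this package's own
documented choices.

## Synthetic data

The generator produces model-predicted mean profiles for the study
designs in the scenario library (healthy 5–20 mg oral/IV single doses
and 10 mg q24h multiple dosing; phenotype 10 mg oral; CP-B 10 mg
oral/IV; CKD 100 mg oral; CHF-moderate 50–200 mg oral; CHF-severe
5–20 mg IV) and perturbs them with independent Gaussian noise —
proportional CV 15% by default plus an optional additive floor —
truncated at zero, with cumulative urine re-monotonized by running
maximum. The true scatter of the digitized literature profiles is
unknown; this default is a labelled placeholder for bioanalytical plus
digitization error. Passing recovery tests on these data demonstrates
internal consistency of the pipeline (generator → fitter closes the
loop), not predictive accuracy against real clinical profiles, which are
not packaged.

## Problem sizes

Default test/analysis runs use 24–48 h horizons with 100–500 output
points, 5-dose linearity scans, ≤ 40-interval steady-state runs and
30–40-point fitting datasets; these sizes keep every result well inside
the numerical tolerances above while the full suite stays fast.

## Known limitations

- No permeability-limited tissues, transporter (OATP1B1) effects,
  enterohepatic recirculation, or drug–drug interactions.
- Group means only: no inter-individual variability or virtual-population
  sampling.
- Severity-specific PD for CP-A/CP-C and mild/severe CHF is extrapolated
  from the single fitted set per disease group.
- The calibrated `K_a/K_e/K_u/K_p` defaults are constrained only by Tmax
  and half-life; other defensible combinations exist, and the resulting
  renal-dominant elimination split is a model property, not a measured
  one.
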