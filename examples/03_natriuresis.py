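"""Link the PK simulation to the natriuresis (sodium excretion) response.

The urinary torsemide excretion rate x(t) drives the sodium excretion
rate E(t) through a baseline sigmoid Emax model with no effect delay.
The loop area diagnostics confirm the direct-effect behaviour: plotting
E against plasma concentration after an oral dose gives a counter-
clockwise hysteresis loop (absorption delay), while E against x itself
traces a nearly closed curve.
"""

import numpy as np

import torsemide_pbpk as tp

phys, drug = tp.healthy_reference()
traj = tp.simulate(tp.single_dose_spec(phys, drug, 10.0, t_end=24.0))
traj = tp.pd_timecourse(traj, tp.PD_PRESETS["healthy"])

i_peak = int(np.argmax(traj.E))
print(f"baseline E0          {traj.E[0]:.2f} mEq/h")
print(f"peak E               {traj.E[i_peak]:.2f} mEq/h at {traj.times[i_peak]:.1f} h "
      f"(x = {traj.x[i_peak]:.0f} ug/h)")
print(f"E back near baseline {traj.E[-1]:.2f} mEq/h at {traj.times[-1]:.0f} h")

area_ce = tp.hysteresis_area(traj.C_plasma, traj.E)
area_xe = tp.hysteresis_area(traj.x, traj.E)
norm = np.ptp(traj.x) * np.ptp(traj.E)
print(f"(C_plasma, E) loop area {area_ce:+.3f}  -> counterclockwise (positive)")
print(f"(x, E) normalized area  {abs(area_xe) / norm:.4f}  -> ~0, direct effect")
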