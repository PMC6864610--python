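"""Temporal-spatial variables and hand-rim kinetics of one trial.

Runs the full pipeline (filter, synchronize, detect pushes at 1 Nm,
select five cycles) and prints the propulsion-style variables and the
push-phase force summary.
"""

import warnings

from rimdyn import SimParams, StudyConfig, analyze_trial, simulate_propulsion

warnings.filterwarnings("ignore", category=UserWarning)

params = SimParams(seed=3)  # default 1 mm marker / 0.5 N force noise
trial = simulate_propulsion(params, duration=5.2)
report = analyze_trial(trial.markers, trial.rim, StudyConfig(),
                       trial.geometry, params.anthropometry)

ts = report["temporal_spatial"]
print("temporal-spatial (averages over 5 cycles):")
print(f"  cadence PF        {ts['PF']:.3f} strokes/s")
print(f"  distance per cycle {ts['Dist']:.3f} m  "
      f"(PF x Dist = {ts['PF'] * ts['Dist']:.3f} m/s treadmill speed)")
print(f"  push / recovery    {ts['Pphase']:.3f} s / {ts['Rphase']:.3f} s "
      f"(ratio {ts['Pphase/Rphase']:.2f})")
print(f"  contact angle CA   {ts['CA']:.1f} deg, release angle RA {ts['RA']:.1f} deg")

hr = report["handrim"]
print("hand-rim kinetics (push phase):")
print(f"  Ftot max  {hr['Ftotmax']:.1f} N   Ftang max {hr['Ftangmax']:.1f} N")
print(f"  Feff      {hr['Feff']:.2f}  (fraction of force that propels)")
print(f"  ERF       {hr['ERF']:.0f} N/s   Mtot max {hr['Mtotmax']:.2f} Nm")
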