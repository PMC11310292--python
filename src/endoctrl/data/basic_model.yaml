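# Calibrated parameters of the untreated tumor-estrogen-fat model and the
# per-diet initial conditions of the 15-day mouse experiment.
parameters:
  k1: 0.55        # 1/day, calibrated
  a1: 43.0        # pg/g, calibrated
  m1: 0.0005      # 1/mm^3 (carrying capacity 2000 mm^3), assumed
  r: 20.0         # pg/g/mm^3/day, assumed from steady-state estrogen range
  mu: 5.94        # 1/day, from a 2.8 h estrogen half-life
  alpha: 1.7e-06  # 1/day/mm^3, calibrated
initial_conditions:
  CD:
    T0: 1.0       # mm^3
    E0: 170.0     # pg/g (rounded steady state r*F0/mu)
    F0: 50.0      # mm^3
  HFD:
    T0: 1.0
    E0: 1200.0
    F0: 360.0
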