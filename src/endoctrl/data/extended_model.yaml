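# Parameters of the sensitive/resistant treatment model shared by all
# simulated scenarios, plus the per-scenario threshold presets.
parameters:
  k1: 0.55
  a1: 43.0
  m1: 0.0005
  r: 20.0
  mu: 5.94
  alpha: 1.7e-06
  eta: 1.0        # competition intensity
  c: 1.0          # 1/day, maximum death rate
  l: 10.0         # Hill coefficient
  k2: 0.05        # 1/day, fat growth rate
  m2: 0.002711    # 1/mm^3, inverse fat carrying capacity
  p: 1.0          # no constant treatment by default
  a2: 20.0        # placeholder; scenario presets override
  a3: 1.0
  k3: 0.275
presets:
  Ia:   {a2: 20.0, a3: 1.0,  k3: 0.275,  R0_fraction: 0.0}
  Ib:   {a2: 20.0, a3: 1.0,  k3: 0.275,  R0_fraction: 0.25}
  II:   {a2: 10.0, a3: 1.0,  k3: 0.275,  R0_fraction: 0.0}
  III:  {a2: 10.0, a3: 10.0, k3: 0.1375, R0_fraction: 0.0}
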