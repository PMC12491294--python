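# Active-defense outbreak (dimensionless model): resistant mutants grow in
# response to infection and suppress the effective contact rate.
label: active
params:
  beta0: 5.0     # scaled effective contact rate beta0' [1/day]
  gamma: 5.0     # scaled defense effectivity gamma' = gamma * Rm
  alpha: 1.0     # scaled resistant growth rate alpha' = alpha * Sst0 / Rm
  Rm: 1.0
  q: 0.2         # scaled model: phage production = k1 (1:1 I -> p transition)
  k1: 0.2
  k2: 1.0
  mu: 0.0
  K: 1.0
fixed_point:
  S: 1.0
  R: 0.01
perturbation:
  P: 0.001       # phage inoculum at t = 0
integration:
  dt: 0.001
  horizon: 7.0
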