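# Preset "Set A": small-vessel benchtop configuration (isolated-calyx scale).
# 5.89 mL test tube in a 37 degC water bath, room-temperature irrigation fluid,
# wall heat-loss coefficient from the still-fluid 40 W identification fit.
name: setA
volume_ml: 5.89
t0_c: 37.0
t_in_c: 23.0
flow_ml_min: 0.0
beta_w_per_c: 1.15
fluid:
  k: 0.606
  rho: 1000.0
  c: 4180.0
firing_s: 60.0
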