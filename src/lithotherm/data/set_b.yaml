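# Preset "Set B": kidney-scale benchtop configuration.
# 38.3 mL cylindrical vessel submerged in a room-temperature bath, irrigation
# at the bath temperature, wall heat-loss coefficient from the still-fluid
# 40 W identification fit.
name: setB
volume_ml: 38.3
t0_c: 22.0
t_in_c: 22.0
flow_ml_min: 0.0
beta_w_per_c: 1.36
fluid:
  k: 0.606
  rho: 1000.0
  c: 4180.0
firing_s: 60.0
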