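# Moving-stimulus tracking in the anticipatory regime.
model:
  alpha: 0.02
  beta: 0.1
stimulus:
  A: 2.0
  mode: moving
  v_ext: 0.003
integrator:
  t_max: 6000.0
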