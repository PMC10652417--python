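# Stimulus jumps from 0 to 1 rad at t = 0; with plasticity the bump
# overshoots the destination before settling.
model:
  alpha: 0.02
  beta: 0.1
stimulus:
  A: 3.0
  mode: abrupt
  z0_initial: 0.0
  z0_after: 1.0
  t_jump: 0.0
integrator:
  t_max: 1500.0
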