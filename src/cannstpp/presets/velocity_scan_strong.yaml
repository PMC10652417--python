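# Velocity scan of the strong-plasticity regime; reports the interval of
# stimulus velocities that the bump anticipates.
model:
  alpha: 0.02
  beta: 0.1
stimulus:
  A: 3.0
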