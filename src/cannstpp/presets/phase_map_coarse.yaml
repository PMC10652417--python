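# Desk-scale (alpha, beta) maps of intrinsic speed and maximal
# anticipatory time; pair with the phase-map subcommand's --coarse flag.
stimulus:
  A: 3.0
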