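# Non-stationary mean-field run: balanced network under common sinusoidal
# drive (coarse grid preset for a quick look).
kind: dmft
seed: 1
network:
  N: 2000
  g: 2.0
  J0: 1.0
  I0: 1.0
input:
  kind: common_sin
  I1: 35.0
  f: 0.05
grid:
  dt: 0.05
  transient: 20.0
  duration: 40.0
analysis:
  max_lag: 8.0
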