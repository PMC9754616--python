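# Direct network simulation of the same driven balanced network.
kind: simulate
seed: 1
network:
  N: 2000
  g: 2.0
input:
  kind: common_sin
  I1: 35.0
  f: 0.05
integration:
  T: 80.0
  dt: 0.02
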