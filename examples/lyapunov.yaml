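# Tangent-space Lyapunov exponent of the autonomous balanced network.
kind: lyapunov
seed: 1
network:
  N: 1000
  g: 2.0
lyapunov:
  method: tangent
  T_measure: 150.0
  dt: 0.02
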