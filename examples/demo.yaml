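# Demo pipeline configuration: two-replica paired A+B simulation, transport
# quantification on synthetic GUV traces, and the fate table.
seed: 5
simulation:
  n_replicas: 2
  n_steps: 20000        # 400 ns at dt = 0.02 ns
  frame_stride: 10
  barrier_height: 4.0
  n_a: 1
  n_b: 1
  epsilon: 6.0
  kappa: 4.0
transport:
  n_guvs: 20
  noise_sd: 0.02
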