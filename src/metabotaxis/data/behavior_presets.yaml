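# Optimised behavior parameter presets shipped with the package.
# method: how each value was identified (exhaustive lattice sampling for
# the 2-parameter behaviors, microbial genetic algorithm for the hybrid).
B1:
  method: Lattice Sampling
  params:
    theta_F: 1.12
    k_F: 9.4
  ranges:
    theta_F: [0.0, 4.0]
    k_F: [0.0, 10.0]
B2:
  method: Lattice Sampling
  params:
    theta_A: 4.0
    k_A: 10.0
  ranges:
    theta_A: [0.0, 8.0]
    k_A: [0.0, 10.0]
B3:
  method: Lattice Sampling
  params:
    theta_D: 0.0
    k_D: 10.0
  ranges:
    theta_D: [-2.0, 2.0]
    k_D: [0.0, 10.0]
B4:
  method: Genetic Algorithm
  params:
    theta_SF: 1.1033
    k_SF: 2.7381
    theta_SD: 0.2894
    k_SD: 2.9981
    k_sigma: 2.6494
    k_r: 6.0630
  ranges:
    theta_SF: [0.0, 4.0]
    k_SF: [0.0, 5.0]
    theta_SD: [-1.0, 1.0]
    k_SD: [0.0, 5.0]
    k_sigma: [0.0, 4.0]
    k_r: [0.0, 10.0]
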