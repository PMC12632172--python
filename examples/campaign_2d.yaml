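space:
  total_flow: 100.0
  variables:
  - name: polyrA
    stock_concentration: 20.0
    unit: g/L
    flow_min: 0.0
    flow_max: 50.0
  - name: KCl
    stock_concentration: 4.0
    unit: M
    flow_min: 0.0
    flow_max: 50.0
model:
  kind: logistic_linear
  weights:
  - 0.05
  - 1.0
  offset: 1.0
  steepness: 8.0
acquisition:
  mode: hybrid
  target: 0.5
  epsilon: 0.5
  n_starts: 100
  batch_size: 3
  penalty_amplitude: null
  penalty_width_fraction: 0.1
droplet_range:
- 50
- 250
observation_mode: direct
n_iterations: 2
monitor_resolution: 11
convergence_threshold: 1.0
patience: 2
early_stop: false
master_seed: 0
n_restarts: 25
noise_level: null
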