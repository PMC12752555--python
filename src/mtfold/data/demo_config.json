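{
 "seed": 7,
 "constructs": ["LE-CSP-GS"],
 "equilibrium": {
  "forces": [4.5, 5.0, 5.5, 6.0, 6.5],
  "duration_s": 400,
  "sampling_rate": 100,
  "noise_sigma": 6.0
 },
 "ramp": {
  "n_traces": 80,
  "start": 2.0,
  "end": 42.0,
  "rate": 1.0,
  "round_trip": false,
  "sampling_rate": 100,
  "noise_sigma": 6.0
 },
 "jump": {
  "forces": [12.0, 16.0, 20.0, 25.0],
  "hold_s": 30.0,
  "n_traces": 25,
  "sampling_rate": 100,
  "noise_sigma": 6.0
 },
 "analysis": {
  "smooth_window": 20,
  "threshold_sigma": 5.0,
  "n_bootstrap": 25
 }
}
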