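# Demo run: synthesize one paired control/EAAT-block recording, fit both
# conditions, and analyze a synthetic modulated spike response.
outdir: out/demo
seed: 7
temperature_c: 34.0
rate_table: null          # use the shipped calibrated table
stimulus: {rate_hz: 50.0, n_events: 10, start_ms: 100.0, t_end_ms: 1500.0}
synth: {n_trials: 6, noise_sd: 2.0}
fit: {restarts: 2}
phase: {offset_gain: 40.0, offset_phase_deg: 206.0, baseline_rate: 2.0, n_sweeps: 10}
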