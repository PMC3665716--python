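# Demo scene: one Dall's-type porpoise scanning the array from 30 m
# under British Columbia recording conditions.
scene:
  top_depth: 2.0
  environment:
    temperature: 9.2
    salinity: 33.9
    depth: 5.0
  noise_spectral_level: 55.0
  seed: 7
  sources:
    - position: [30.0, 0.0, 4.25]
      fc_khz: 137.0
      duration_10db_us: 104.0
      sl_pp_db: 183.0
      aperture_cm: 10.0
      ici_sequence_ms: [60.0, 60.0, 60.0, 60.0, 60.0, 60.0]
      aim_sweep: [[0.0, 0.0, 1.0], [0.0, 0.0, 7.5]]
gates:
  max_range_m: 65.0
  tl_error_db: 3.0
  beam_range_m: 20.0
mode: six_channel
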