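# Degraded stand: 20% missing seedlings plus wheel-rut intervals on the
# central pair in the near field (below the default ROI band).
scene:
  crop: cotton
  miss_prob: 0.2
  rut_segments:
    - [2, [168.0, 178.0]]
    - [3, [168.0, 178.0]]
  seed: 1
drift_cm_per_frame: 0.5
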