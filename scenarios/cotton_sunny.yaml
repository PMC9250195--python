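# Seedling cotton in wide-narrow (10/66 cm) rows on mulch film, sunny day.
scene:
  crop: cotton
  illumination: sunny
  seed: 1
camera:
  height_cm: 100.0
  tilt_deg: 65.0
  image_size: [640, 480]
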