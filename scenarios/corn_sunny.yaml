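# Double-row maize: long narrow leaves; pair with the "corn" pipeline
# preset (Canny Gaussian radius 0.5) when detecting.
scene:
  crop: corn
  illumination: sunny
  seed: 1
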