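# Forced far-field adhesion: canopies of the central pair overlap near
# the image top and merge into one thresholded domain.
scene:
  crop: cotton
  adhesion_scale: 2.4
  seed: 1
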