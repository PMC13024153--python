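# Calibrated reference anatomy for the knee extensor mechanism.
#
# gamma runs linearly from +20 deg at terminal extension to -10 deg at
# 120 deg flexion; the aF anchors are pinned so that the case-study
# worked values are reproduced exactly by the model equations.
interpolation: linear
anchors:
  - {flexion_deg: 0.0,   aF_m: 0.0470, gamma_deg: 20.0}
  - {flexion_deg: 16.4,  aF_m: 0.0481, gamma_deg: 15.9}
  - {flexion_deg: 60.0,  aF_m: 0.0550, gamma_deg: 5.0}
  - {flexion_deg: 120.0, aF_m: 0.0570, gamma_deg: -10.0}
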