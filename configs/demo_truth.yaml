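n_participants: 24
seasons:
- W1
- S
hst_mean: 0.12666666666666604
hst_sd: 0.9
wake_span_mean: 16.0
wake_span_sd: 0.6
seed: 0
params:
  MEL:
    W1:
      mesor: 0.87
      amplitude: 3.155
      acrophase: 3.99
      sd_mesor: 0.51
      sd_amplitude: 0.59
      sd_acrophase: 0.5
      resid_sd: 0.35
    S:
      mesor: 1.04
      amplitude: 2.952
      acrophase: 3.14
      sd_mesor: 0.51
      sd_amplitude: 0.59
      sd_acrophase: 0.5
      resid_sd: 0.35
  IOP:
    W1:
      mesor: 13.36
      amplitude: 2.81
      acrophase: -10.1
      sd_mesor: 2.79
      sd_amplitude: 0.94
      sd_acrophase: 0.5
      resid_sd: 1.0
    S:
      mesor: 13.09
      amplitude: 2.76
      acrophase: -10.27
      sd_mesor: 2.79
      sd_amplitude: 0.94
      sd_acrophase: 0.5
      resid_sd: 1.0
  ACD:
    W1:
      mesor: 3.73
      amplitude: 0.019
      acrophase: 2.44
      sd_mesor: 0.27
      sd_amplitude: 0.0063
      sd_acrophase: 0.5
      resid_sd: 0.008
    S:
      mesor: 3.74
      amplitude: 0.026
      acrophase: 1.64
      sd_mesor: 0.27
      sd_amplitude: 0.0063
      sd_acrophase: 0.5
      resid_sd: 0.008
  LT:
    W1:
      mesor: 3.55
      amplitude: 0.015
      acrophase: 2.64
      sd_mesor: 0.24
      sd_amplitude: 0.005
      sd_acrophase: 0.5
      resid_sd: 0.008
    S:
      mesor: 3.56
      amplitude: 0.013
      acrophase: 3.18
      sd_mesor: 0.24
      sd_amplitude: 0.005
      sd_acrophase: 0.5
      resid_sd: 0.008
  VCD:
    W1:
      mesor: 16.41
      amplitude: 0.055
      acrophase: -9.0
      sd_mesor: 1.4
      sd_amplitude: 0.018
      sd_acrophase: 0.5
      resid_sd: 0.012
    S:
      mesor: 16.44
      amplitude: 0.063
      acrophase: -9.53
      sd_mesor: 1.4
      sd_amplitude: 0.018
      sd_acrophase: 0.5
      resid_sd: 0.012
  AL:
    W1:
      mesor: 23.92
      amplitude: 0.019
      acrophase: -8.79
      sd_mesor: 1.37
      sd_amplitude: 0.0063
      sd_acrophase: 0.5
      resid_sd: 0.004
    S:
      mesor: 23.96
      amplitude: 0.022
      acrophase: -9.81
      sd_mesor: 1.37
      sd_amplitude: 0.0063
      sd_acrophase: 0.5
      resid_sd: 0.004
  RT:
    W1:
      mesor: 261.0
      amplitude: 2.0
      acrophase: -9.47
      sd_mesor: 13.7
      sd_amplitude: 0.67
      sd_acrophase: 0.5
      resid_sd: 0.8
    S:
      mesor: 263.0
      amplitude: 2.0
      acrophase: -11.32
      sd_mesor: 13.7
      sd_amplitude: 0.67
      sd_acrophase: 0.5
      resid_sd: 0.8
  ChT:
    W1:
      mesor: 354.0
      amplitude: 2.0
      acrophase: 3.1
      sd_mesor: 108.0
      sd_amplitude: 0.67
      sd_acrophase: 0.5
      resid_sd: 2.0
    S:
      mesor: 343.0
      amplitude: 4.0
      acrophase: 3.42
      sd_mesor: 108.0
      sd_amplitude: 0.67
      sd_acrophase: 0.5
      resid_sd: 2.0
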