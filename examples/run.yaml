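# End-to-end synthetic microTMA study: a control arm and three doxorubicin
# doses with decreasing tumor burden and rising apoptosis fractions.
mode: end-to-end
seed: 7
section:
  pixel_size_um: 1.0
  n_cells: 400
  tumor_fraction: 0.5
  marker_frac_tumor: 0.1
  marker_frac_normal: 0.01
treatments:
  control: {}
  dox_0.05:
    marker_frac_tumor: 0.25
    marker_frac_normal: 0.04
  dox_0.1:
    n_cells: 340
    tumor_fraction: 0.41
    marker_frac_tumor: 0.45
    marker_frac_normal: 0.07
  dox_0.3:
    n_cells: 240
    tumor_fraction: 0.17
    marker_frac_tumor: 0.6
    marker_frac_normal: 0.10
spheroids_per_treatment: 16
grid_cols: 12
spot_pitch_um: 500.0
control: control
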