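# Mid-stiffness hydrogel phantom (manufacturer E = 0.30 MPa), 450 um thick,
# mounted at 15 mmHg. Used by: corneafit simulate / synth / recover / fit.
geometry:
  posterior_radius_mm: 8.60
  thickness_mm: 0.45
  aperture_radius_mm: 5.5
material:            # ground truth for synth/recover; initial guess is not needed
  c10_mpa: 0.033333
  c01_mpa: 0.016667
iop_mmhg: 15.0
load:
  peak_pressure_mpa: 0.0045
  spatial_sigma_mm: 1.5
  duration_ms: 30.0
  n_frames: 140
noise:
  displacement_noise_mm: 0.010
seed: 7
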