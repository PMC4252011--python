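# A full-rotation integrated acquisition of a machine with typical
# gravity-driven deformations (the MachineModel defaults), rendered on an
# aS500-format panel.  Curves are Fourier coefficients in the gantry angle;
# every curve is re-zeroed at gantry zero.
model:
  sdd0_mm: 1500.0
  epid_sag_y: {cos: [0.0, 0.5]}        # in-plane imager sag, range 1.0 mm
  epid_sag_x: {sin: [0.0, 0.1]}        # cross-plane, range 0.2 mm
  gantry_sag_y: {cos: [0.0, 0.35]}     # range 0.7 mm
  gantry_sag_x: {sin: [0.2]}
  sdd_variation: {sin: [1.7]}          # mm, amplitude 1.7
  skew: {sin: [0.15]}                  # degrees
  tilt_y: {sin: [0.1]}
  tilt_x: {sin: [0.04]}
  carriage_offset_L: {sin: [-0.41]}    # left bank, extremum at gantry -90
  carriage_offset_R: {sin: [0.49]}
  carriage_offset_G: {cos: [0.0, 0.17]}
  carriage_offset_T: {cos: [0.0, -0.16]}
  e_marker_offset: [0.8, -0.5]         # set-up offset of the isocentre ball
  noise: {gaussian_sd: 3.0, salt_fraction: 0.001}
  seed: 7
plan:
  mode: integrated
  step_deg: 10.0
  direction: CW
  collimator_deg: 0.0
panel:
  rows: 384
  cols: 512
  pixel_spacing_mm: 0.784
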