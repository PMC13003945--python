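# Body segment inertial parameters for a 15-segment model (adult male
# population table). mass_fraction is the fraction of whole-body mass;
# com_ratio locates the segment COM along its longitudinal axis measured
# from the proximal endpoint; gyration radii are fractions of segment
# length about transverse / longitudinal axes.
#
# This file is a replaceable asset: pass an alternative path to
# load_segment_model() to swap the anthropometric table.
segments:
  head:        {mass_fraction: 0.0694}
  trunk:       {mass_fraction: 0.3229, com_ratio: 0.4486, r_gyr_transverse: 0.372, r_gyr_longitudinal: 0.191}
  pelvis:      {mass_fraction: 0.1117}
  upper_arm:   {mass_fraction: 0.0271, bilateral: true}
  forearm:     {mass_fraction: 0.0162, bilateral: true}
  hand:        {mass_fraction: 0.0061, bilateral: true}
  thigh:       {mass_fraction: 0.1416, com_ratio: 0.4095, r_gyr_transverse: 0.329, r_gyr_longitudinal: 0.149, bilateral: true}
  shank:       {mass_fraction: 0.0433, com_ratio: 0.4416, r_gyr_transverse: 0.251, r_gyr_longitudinal: 0.102, bilateral: true}
  foot:        {mass_fraction: 0.0137, com_ratio: 0.4415, r_gyr_transverse: 0.257, r_gyr_longitudinal: 0.124, bilateral: true}

# COM placement of segments rigidly attached to the trunk frame (arms are
# modelled rigid with the trunk: hands stay on the hips throughout the
# jump). Offsets are [x, y, z] coefficients of trunk length in the trunk
# frame, measured from the upper trunk origin; y is mirrored for the left
# side.
hat_offsets:
  head:      [0.02, 0.0, 0.22]
  upper_arm: [0.00, -0.42, -0.30]
  forearm:   [0.10, -0.45, -0.62]
  hand:      [0.16, -0.38, -0.80]

# Pelvis segment COM offset, [x, y, z] coefficients of the inter-ASIS
# distance in the pelvis frame, measured from the mid-hip point.
pelvis_com_offset: [0.0, 0.0, 0.12]
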