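# Default planar-arm model: published segment and Hill-muscle constants plus
# the package's default straight-line attachment geometry.
#
# Units are explicit in the key names (mm, kg, kg.cm^2, deg); geometry points
# are metres in the frame of the named segment (x along the segment toward the
# distal joint, origin at the proximal joint; ground frame origin at the
# shoulder, x to the subject's right, y anterior).
#
# Attachment coordinates and optimal fibre lengths are NOT published for this
# model (they were tuned against a 3-D shoulder model that is not available);
# the points below are the package defaults, chosen to give constant-sign
# moment arms of roughly 2-4 cm magnitude over the motion range.  A null
# optimal_fiber_mm means "calibrate so the fibre is at optimal length at the
# reference posture" (shoulder 44 deg, elbow 58 deg).  Attachment points are
# placed so the operating fibre length stays within roughly [0.7, 1.35] of
# optimal across the motion range: short paths would turn the muscles into
# stiff passive springs around the calibration posture.

arm:
  segments:
    upper_arm: {mass_kg: 1.93, inertia_kg_cm2: 141, length_mm: 290, com_mm: 145}
    forearm:   {mass_kg: 1.52, inertia_kg_cm2: 188, length_mm: 300, com_mm: 150}
  joint_damping_Nms_per_rad: 0.0

muscles:
  - name: shoulder_flexor            # muscle 1
    f0max_N: 2525
    tendon_slack_mm: 29.2
    pennation_deg: 21.6
    origin:    {segment: ground,    xy_m: [-0.060, 0.000]}
    insertion: {segment: upper_arm, xy_m: [0.120, 0.000]}
    optimal_fiber_mm: null
  - name: shoulder_extensor          # muscle 2
    f0max_N: 1672
    tendon_slack_mm: 0.0
    pennation_deg: 19.5
    origin:    {segment: ground,    xy_m: [0.040, -0.010]}
    insertion: {segment: upper_arm, xy_m: [0.120, 0.000]}
    optimal_fiber_mm: null
  - name: elbow_flexor               # muscle 3
    f0max_N: 1452
    tendon_slack_mm: 18.1
    pennation_deg: 1.4
    origin:    {segment: upper_arm, xy_m: [0.100, 0.015]}
    insertion: {segment: forearm,   xy_m: [0.050, 0.000]}
    optimal_fiber_mm: null
  - name: elbow_extensor             # muscle 4
    f0max_N: 1577
    tendon_slack_mm: 7.2
    pennation_deg: 7.8
    origin:    {segment: upper_arm, xy_m: [0.100, -0.015]}
    insertion: {segment: forearm,   xy_m: [-0.030, 0.000]}
    optimal_fiber_mm: null
  - name: biarticular_flexor         # muscle 5
    f0max_N: 972
    tendon_slack_mm: 187.6
    pennation_deg: 0.0
    origin:    {segment: ground,    xy_m: [-0.040, 0.010]}
    insertion: {segment: forearm,   xy_m: [0.050, 0.000]}
    optimal_fiber_mm: null
  - name: biarticular_extensor       # muscle 6
    f0max_N: 798
    tendon_slack_mm: 119.2
    pennation_deg: 12.0
    origin:    {segment: ground,    xy_m: [0.050, 0.000]}
    insertion: {segment: forearm,   xy_m: [-0.025, 0.000]}
    optimal_fiber_mm: null
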