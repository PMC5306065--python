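# lamsim default run configuration.
# Reference values reproduce the study conditions of the packaged model:
# a 50th-percentile fetal head delivered through a reference female pelvis
# with cardinal-movement kinematics.  Units: mm, MPa, N, degrees.

material:
  # reference two-term Ogden set fitted to levator uniaxial tension
  mu: [8.0e-5, 1.7e-4]        # MPa
  alpha: [1.81, 17.25]        # dimensionless
  poisson: 0.499              # bulk modulus derived from this
  density_kg_per_l: 1.06      # skeletal muscle (dynamic fallback only)

geometry:
  head:                        # principal fetal head diameters, mm
    suboccipitobregmatic: 100.3
    occipitofrontal: 105.7
    occipitomental: 131.9
    biparietal: 93.7
  pelvis:                      # principal bony pelvis diameters, mm
    inlet_ap: 113.4
    outlet_ap: 145.1
    transverse_inlet: 148.8
    interspinous: 146.7
  levator:
    shell_thickness: 6.0       # mm (calibrated synthetic value)
    hiatus_ap: 75.0            # urogenital hiatus extent, mm (calibrated)
    hiatus_width: 60.0
  mesh_edge: 6.0               # target element edge length, mm

trajectory:
  start_station: -3.0
  end_descent_station: 5.0
  rotation_complete_station: 3.0
  lateral_straight_station: 0.0
  frames_per_station: 2
  extension_frames: 10
  anterior_displacement: 100.0  # net anterior centroid translation, mm
  extension_angle: 80.25        # deg
  lateral_deviation: 28.66      # deg
  internal_rotation: 40.13      # deg
  carus_radius: 200.0           # mm
  extension_descent_mm: 50.0    # extra vertex descent while extending

solver:
  contact_penalty: 5.0          # N/mm per node (adapted upward as needed)
  newton_tol: 1.0e-5            # residual norm, N
  max_iterations: 140
  max_substep_depth: 6
  mean_dilatation: true
  tether_stiffness: 0.05        # N/mm, ATML coupling to the obturator wall

output:
  write_vtk_series: true

seed: 0
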