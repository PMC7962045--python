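# Foot-insole study reproduction configuration (lengths in mm).
#
# Layered slab: 5 plantar tissue layers over the 4-layer smart insole and a
# 15 mm rubber shoe sole.  The foot contacts the insole over a ~112 cm^2
# rectangular patch; the remaining insole surface and the foot's side walls
# exchange heat with the 20 degC environment.  Lesions (inflammation or
# ischemia, height 2.5 mm, volume 1.5 cm^3) are embedded at six center
# depths below the plantar skin, laterally centered under sensor S4.

units:
  length: mm

footprint: [260, 90]
contact_patch: [22.5, 237.5, 19, 71]
foot_length: 260
rubber_thickness: 15

resolution:
  dx: 4
  dy: 4
  dz_fine: 0.5
  fine_band: 12
  dz_coarse: 2.5
  min_cells_per_layer: 3

blood:
  density: 1050.0        # kg/m^3
  specific_heat: 3617.0  # J/kg/K

boundary:
  floor_h: 5.0           # W/m^2/K at the shoe-floor face
  floor_T_env: 20.0      # degC
  top: adiabatic         # deep (proximal) tissue face
  sock_resistance: 0.02  # m^2 K/W at the skin-insole interface

sensors:
  detection_threshold: 0.1  # degC (temperature-sensor resolution)

lesion:
  height: 2.5
  volume: 1500           # mm^3 = 1.5 cm^3
  center: null           # defaults to the S4 sensor position
  types: [inflammation, ischemia]
  depths: [1.6, 2.6, 3.4, 5.9, 8.4, 9.7]

sweep:
  sock_settings: [true, false]

solver:
  tol: 1.0e-10
  method: auto
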