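# Bupivacaine liposome-alginate transwell release parameters.
# The two diffusivities were printed with concentration units in the source
# report ("1E-10 mol/m^3", "8.5E-15 mol/m^3"); they are interpreted here as
# m^2/s (standard diffusivity units) and the original strings are kept in
# metadata. The 24-well transwell dimensions are catalog-typical (0.33 cm^2
# insert / 1.9 cm^2 well, 100/600 uL fluid); the alginate-liposome depot is
# a 50 uL layer at the top of the insert.
metadata:
  description: 1 mM bupivacaine in a liposome-alginate depot, 24-well transwell
  diffusivity_media_printed: "1E-10 mol/m^3"
  effective_diffusivity_printed: "8.5E-15 mol/m^3"
geometry:
  plate_format: well24
  insert_membrane_area: {value: 0.33, unit: cm^2}
  insert_fluid_depth: {value: 3.0303030303e-3, unit: m}
  well_cross_area: {value: 1.9, unit: cm^2}
  well_fluid_depth: {value: 3.1578947368e-3, unit: m}
  depot_thickness: {value: 1.5151515152e-3, unit: m}
drug:
  name: bupivacaine
  diffusivity_media: {value: 1.0e-10, unit: m^2/s}
  molar_mass: {value: 288.43, unit: g/mol}
construct:
  form: liposome_alginate
  initial_concentration: {value: 1.0, unit: mM}
  effective_diffusivity: {value: 8.5e-15, unit: m^2/s}
  depot_volume: {value: 50.0, unit: uL}
simulation:
  dt: {value: 10, unit: s}
  t_end: {value: 96, unit: h}
  output_times: {value: [0, 1, 2, 4, 12, 24, 48, 96], unit: h}
  nodes_depot: 20
  nodes_media: 40
  scheme: backward_euler
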