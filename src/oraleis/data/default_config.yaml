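# Default configuration for the oral-mucosa EIS simulator.
#
# Units are explicit in key suffixes: _um micrometres, _mm millimetres,
# _nm nanometres, _ohm_m ohm-metres, _hz hertz, _ua microamperes.
#
# PROVENANCE NOTES
# - cases: layer thicknesses measured from oral histology (mean, SD in um).
# - compartments: provisional values averaged from the cervical-epithelium
#   modelling literature; placeholders to be overridden when oral-specific
#   measurements become available.
# - morphologies: cell dimensions consistent with oral histology; ECS
#   half-widths are provisional, borrowed from cervical modelling with the
#   CINII ~ moderate and CINIII ~ severe dysplasia equivalence, and
#   calibrated so the normal superficial layer reproduces its published
#   low-frequency resistivity anchor (~0.96 kOhm-m).
# - electrodes: the clinical probe geometry is not published; this
#   collinear placeholder was calibrated once against the published
#   low- and high-frequency impedance anchors of the normal keratinised
#   template and should be replaced with device values when available.

frequencies_hz: null          # null -> 14 geometric points, 76 Hz - 625 kHz
mesh_resolution: coarse       # coarse | standard

electrodes:
  arrangement: collinear      # drive, m1, m2, receive along x
  pitch_mm: 2.4
  radius_mm: 0.3
  drive_current_ua: 6.08      # AC peak

keratin:
  hydration_factor: 40.0      # divides stratum-corneum resistivity

compartments:
  ecs:              {resistivity_ohm_m: 0.7,   rel_permittivity: 72}
  membrane:         {resistivity_ohm_m: 1.0e7, rel_permittivity: 9}
  cytoplasm:        {resistivity_ohm_m: 2.0,   rel_permittivity: 72}
  nucleoplasm:      {resistivity_ohm_m: 1.1,   rel_permittivity: 72}
  nuclear_membrane: {resistivity_ohm_m: 1.0e5, rel_permittivity: 20}

morphologies:
  normal:
    superficial: {size_um: [45, 45, 3],   ecs_half_um: 0.012}
    prickle:     {size_um: [18, 18, 11],  ecs_half_um: 0.04}
    basal:       {size_um: [12, 12, 12],  ecs_half_um: 0.09}
  moderate:
    superficial: {size_um: [32, 32, 6],   ecs_half_um: 0.016}
    prickle:     {size_um: [16, 16, 12],  ecs_half_um: 0.045}
    basal:       {size_um: [12, 12, 12],  ecs_half_um: 0.085}
  severe:
    superficial: {size_um: [22, 22, 9],   ecs_half_um: 0.02}
    prickle:     {size_um: [14, 14, 13],  ecs_half_um: 0.05}
    basal:       {size_um: [12, 12, 12],  ecs_half_um: 0.08}

cases:
  - id: 1
    diagnosis: Normal
    keratinisation: Non-keratinised
    site: Buccal mucosa
    basal_um: [12.4, 4.5]
    prickle_um: [150.4, 28.8]
    superficial_um: [274.9, 46.3]
    keratinised_um: null
    cell_grade: normal
  - id: 2
    diagnosis: Normal
    keratinisation: Orthokeratinised
    site: Hard palate
    basal_um: [15.7, 2.9]
    prickle_um: [100.5, 8.5]
    superficial_um: [182.0, 45.8]
    keratinised_um: [14.0, 1.8]
    cell_grade: normal
  - id: 3
    diagnosis: Severe dysplasia
    keratinisation: Parakeratinised
    site: Ventral tongue
    basal_um: [22.1, 4.6]
    prickle_um: [73.9, 13.5]
    superficial_um: [261.7, 58.2]
    keratinised_um: [86.6, 34.0]
    cell_grade: severe
  - id: 4
    diagnosis: Severe dysplasia
    keratinisation: Parakeratinised
    site: Lateral tongue
    basal_um: [25.4, 4.6]
    prickle_um: [225.5, 36.6]
    superficial_um: [289.5, 102.9]
    keratinised_um: [22.8, 7.0]
    cell_grade: severe
  - id: 5
    diagnosis: Moderate dysplasia
    keratinisation: Parakeratinised
    site: Lateral tongue
    basal_um: [15.6, 4.1]
    prickle_um: [168.0, 83.8]
    superficial_um: [287.3, 102.9]
    keratinised_um: [42.9, 17.9]
    cell_grade: moderate
  - id: 6
    diagnosis: Hyperkeratosis, no dysplasia
    keratinisation: Orthokeratinised
    site: Hard palate
    basal_um: [15.1, 3.4]
    prickle_um: [222.1, 16.2]
    superficial_um: [363.3, 85.8]
    keratinised_um: [88.9, 21.5]
    cell_grade: normal
  - id: 7
    diagnosis: Severe dysplasia
    keratinisation: Parakeratinised
    site: Lateral tongue
    basal_um: [28.0, 6.8]
    prickle_um: [387.7, 53.8]
    superficial_um: [356.9, 68.3]
    keratinised_um: [17.3, 8.4]
    cell_grade: severe

output_dir: results
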