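# Per-activity energy statistics of the 11-activity protocol.
#
# duration: mean ± sd of the activity bout length, in energy-window (tau)
#   units (tau = 0.66 s by default, so a walking bout of ~20 units is ~13 s
#   and an impact of ~3 units is ~2 s).
# e_m: mean ± sd of the segment mean energy E_m on the dominant axis,
#   E_avg scale, g.
# e_ac_max: largest instantaneous windowed energy observed for the
#   activity (E_avg scale, g); the ratio e_ac_max / e_m_mean seeds the
#   impact peak factor.
# axis_mix: relative energy weights for (x1 horizontal-sagittal,
#   y1 vertical, y2 lateral); walking concentrates on the vertical axis,
#   falls excite the horizontal axes strongly.
#
# The "personalized" block describes set-to-set variation of a single
# subject; the "non_personalized" block pools 12 subjects (one set each)
# and is kept for reference — study-level between-subject spread is
# modelled separately by lognormal subject factors.

personalized:
  slow_walking:        {label: non_impact, duration: [62.5, 10.7], e_m: [0.023, 0.002], e_ac_max: 0.038, axis_mix: [0.25, 0.55, 0.20]}
  normal_walking:      {label: non_impact, duration: [29.1, 1.8],  e_m: [0.046, 0.004], e_ac_max: 0.082, axis_mix: [0.25, 0.55, 0.20]}
  fast_walking:        {label: non_impact, duration: [22.1, 1.7],  e_m: [0.103, 0.012], e_ac_max: 0.200, axis_mix: [0.25, 0.55, 0.20]}
  upstairs:            {label: non_impact, duration: [17.1, 1.9],  e_m: [0.048, 0.005], e_ac_max: 0.081, axis_mix: [0.30, 0.50, 0.20]}
  downstairs:          {label: non_impact, duration: [14.4, 2.9],  e_m: [0.094, 0.012], e_ac_max: 0.191, axis_mix: [0.30, 0.50, 0.20]}
  vertical_jump:       {label: impact,     duration: [3.2, 0.4],   e_m: [0.130, 0.022], e_ac_max: 0.257, axis_mix: [0.30, 0.45, 0.25]}
  knee_fall:           {label: impact,     duration: [2.9, 0.6],   e_m: [0.072, 0.010], e_ac_max: 0.163, axis_mix: [0.45, 0.35, 0.20]}
  horizontal_fall:     {label: impact,     duration: [3.2, 1.3],   e_m: [0.115, 0.026], e_ac_max: 0.284, axis_mix: [0.50, 0.30, 0.20]}
  vertical_jump_sf:    {label: impact,     duration: [4.6, 2.0],   e_m: [0.121, 0.032], e_ac_max: 0.264, axis_mix: [0.30, 0.45, 0.25]}
  knee_fall_sf:        {label: impact,     duration: [2.9, 1.0],   e_m: [0.096, 0.020], e_ac_max: 0.203, axis_mix: [0.45, 0.35, 0.20]}
  horizontal_fall_sf:  {label: impact,     duration: [3.2, 1.3],   e_m: [0.125, 0.043], e_ac_max: 0.373, axis_mix: [0.50, 0.30, 0.20]}

non_personalized:
  slow_walking:        {label: non_impact, duration: [29.6, 19.0], e_m: [0.038, 0.014], e_ac_max: 0.101, axis_mix: [0.25, 0.55, 0.20]}
  normal_walking:      {label: non_impact, duration: [21.4, 8.5],  e_m: [0.056, 0.014], e_ac_max: 0.142, axis_mix: [0.25, 0.55, 0.20]}
  fast_walking:        {label: non_impact, duration: [15.8, 6.3],  e_m: [0.102, 0.033], e_ac_max: 0.252, axis_mix: [0.25, 0.55, 0.20]}
  upstairs:            {label: non_impact, duration: [18.4, 1.7],  e_m: [0.051, 0.014], e_ac_max: 0.127, axis_mix: [0.30, 0.50, 0.20]}
  downstairs:          {label: non_impact, duration: [15.0, 4.1],  e_m: [0.103, 0.039], e_ac_max: 0.312, axis_mix: [0.30, 0.50, 0.20]}
  vertical_jump:       {label: impact,     duration: [7.2, 8.6],   e_m: [0.097, 0.048], e_ac_max: 0.298, axis_mix: [0.30, 0.45, 0.25]}
  knee_fall:           {label: impact,     duration: [3.9, 3.3],   e_m: [0.078, 0.034], e_ac_max: 0.239, axis_mix: [0.45, 0.35, 0.20]}
  horizontal_fall:     {label: impact,     duration: [14.2, 27.7], e_m: [0.083, 0.046], e_ac_max: 0.315, axis_mix: [0.50, 0.30, 0.20]}
  # e_m mean printed in the source table as 0.0105, an order of magnitude
  # below every peer value; read as 0.105 (flagged, not silently dropped).
  vertical_jump_sf:    {label: impact,     duration: [4.4, 2.4],   e_m: [0.105, 0.027], e_ac_max: 0.282, axis_mix: [0.30, 0.45, 0.25]}
  knee_fall_sf:        {label: impact,     duration: [3.9, 2.6],   e_m: [0.069, 0.021], e_ac_max: 0.189, axis_mix: [0.45, 0.35, 0.20]}
  horizontal_fall_sf:  {label: impact,     duration: [5.4, 3.7],   e_m: [0.103, 0.048], e_ac_max: 0.380, axis_mix: [0.50, 0.30, 0.20]}
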