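# Admissible contact-coverage bands per disorder x World Bank income group.
#
# RECONSTRUCTED PLACEHOLDERS — the published threshold table is not
# machine-readable, so these defaults encode the documented *structure*
# (psychosis: lower bounds only, from the lowest severe-disorder 12-month
# service-use estimates of community surveys; bipolar and depression:
# upper bounds only, from the highest such estimates) with plausible
# values.  Edit freely; `null` (or an omitted key) means no bound.
psychosis:
  low:          {lower: 0.005, upper: null}
  lower_middle: {lower: 0.010, upper: null}
  upper_middle: {lower: 0.020, upper: null}
  high:         {lower: 0.050, upper: null}
bipolar:
  low:          {lower: null, upper: 0.284}
  lower_middle: {lower: null, upper: 0.284}
  upper_middle: {lower: null, upper: 0.284}
  high:         {lower: null, upper: 0.284}
depression:
  low:          {lower: null, upper: 0.25}
  lower_middle: {lower: null, upper: 0.30}
  upper_middle: {lower: null, upper: 0.45}
  high:         {lower: null, upper: 0.65}
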