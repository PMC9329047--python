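# Published field-study summary values used as default inputs for budget
# calculations and for the seasonal scenario presets.  Cumulative fluxes are
# per replicate core over the whole anoxic incubation; inventory changes are
# ascorbate-extractable pools in the upper 1 cm.
cumulative_flux_mmol_m2:
  dAs:
    march: [0.24, 0.20, 0.06]
    may: [0.28, 0.48, 0.18]
    august: [0.004, 0.005, 0.007]
  dFe:
    march: [134.0, 112.0, 69.0]
    may: [52.0, 60.0, 40.0]
    august: [0.33, 0.0, 0.21]
  H2S:
    march: [335.0, 106.0, 450.0]
    may: [100.0, 29.0, 23.0]
    august: [368.0, 385.0, 242.0]
inventory_change_mmol_m2:
  dAs: {march: 0.841, may: 0.436, august: 0.135}
  dFe: {march: 491.0, may: 14.1, august: -45.4}
as_budget:
  production_umol_m2_d: 0.85
  upward_fraction: 0.45
  trapped_umol_m2_d: 0.3
mixed_layer_height_m: 15.0
guideline_nM: 920.0
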