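# Published farm-gate results for the five fertilizer treatments, used as
# calibration anchors (N0 column) and as the validation surface for the
# other treatments.  Units as printed.

fertilizer_rates:        # kg N/ha/yr
  N0: 0
  N20: 220
  N40: 440
  N60: 660
  N80: 880

milk_yield_t_ecm_ha:     # potential pasture milk yield
  N0: 14.8
  N20: 16.6
  N40: 16.5
  N60: 17.5
  N80: 18.0

gwp_gross_t_co2eq_ha:
  N0: 22.1
  N20: 25.3
  N40: 29.6
  N60: 36.6
  N80: 50.7

gwp_net_t_co2eq_ha:      # including the soil-carbon offset
  N0: 18.4
  N20: 21.2
  N40: 25.4
  N60: 32.2
  N80: 46.2

cf_net_kg_co2eq_kg_ecm:
  N0: 1.3
  N20: 1.3
  N40: 1.6
  N60: 1.9
  N80: 2.6

farm_n_balance_kg_ha:
  N0: 31
  N20: 241
  N40: 462
  N60: 677
  N80: 899

field_n_balance_kg_ha:
  N0: -119
  N20: 86
  N40: 299
  N60: 501
  N80: 706

enteric_ch4_share_pct:
  N0: 65
  N20: 58
  N40: 50
  N60: 41
  N80: 30

soc_sequestration_t_c_ha:
  N0: 0.85
  N20: 0.85
  N40: 0.87
  N60: 0.89
  N80: 0.91

mean_dm_yield_t_ha:
  N0: 18.5
  N20: 20.2
  N40: 20.1
  N60: 20.9
  N80: 21.5

mean_n_yield_kg_ha:
  N0: 537
  N20: 580
  N40: 640
  N60: 738
  N80: 833
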