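# Model constants and sub-model coefficients for the farm-gate pasture
# carbon-footprint / nitrogen-balance model.  Internal units are kg, kg N,
# MJ per hectare per year unless stated otherwise.  Fields marked
# "calibrated at run time" are solved from the reference anchors in
# reference.yaml and are therefore null here.

gwp_n2o: 265.0          # kg CO2eq per kg N2O, 100-year horizon
gwp_ch4: 28.0           # kg CO2eq per kg CH4, 100-year horizon

grazing_proportion: 0.83        # fraction of excreta deposited on pasture
tan_fraction_of_excreta: 0.65   # TAN share of excreted N (dairy)
tan_emission_factor: 0.19       # NH3-N emitted per unit TAN during grazing
frac_leach: 0.24                # fraction of positive field surplus leached
ef_volatilization_n2o: 0.01     # kg N2O-N per kg NH3-N volatilized (indirect)
ef_leaching_n2o: 0.011          # kg N2O-N per kg N leached (indirect)

milk_n_divisor: 6.38    # milk protein -> N
cp_factor: 6.25         # N -> crude protein
meat_n_export: 8.0      # kg N/ha/yr exported as live weight
irrigation_volume: 4200.0   # m3/ha/yr
pasture_utilization_fraction: 1.0   # share of grown herbage actually grazed
milk_grazing_adjustment: false      # apply grazing_proportion to pasture milk

# Soil N2O response to the field-N-balance x (kg N/ha):
#   N2O (kg/ha) = intercept + scale * exp(rate * x)
n2o_intercept: 1.99
n2o_scale: 1.39
n2o_rate: 0.00488
n2o_output_species: n2o    # 'n2o' (kg N2O) or 'n2o_n' (kg N2O-N)

herd:
  milk_fat_pct: 4.9
  milk_protein_pct: 3.7
  live_weight: 380.0        # kg
  stocking_rate: 4.7        # LU/ha
  cows: 454
  farm_area: 121.0          # ha
  replacement_rate: 0.25
  supplement_dm_per_day: 3.2    # kg DM/cow/day concentrate
  supplement_cp_content: null   # g CP/kg DM, calibrated at run time

# Daily dry-matter intake, kg DM/cow/day:
#   DMI = lw_coeff * LW(kg) + milk_coeff * milk(kg ECM/day) + intercept
intake_model:
  lw_coeff: 0.02
  milk_coeff: 0.28
  intercept: 4.0

# Daily N excretion, g N/cow/day:
#   Nex = excreted_fraction * N-intake(g/day) + lw_coeff * LW + intercept
excretion_model:
  excreted_fraction: 0.84
  lw_coeff: 0.0
  intercept: 0.0

# Enteric methane yields, g CH4 per kg DM intake; `scale` is a single
# multiplier on both yields, calibrated at run time.
methane_model:
  herbage_yield: 21.6
  concentrate_yield: 14.0
  scale: null

# Soil organic carbon: C input = DM * herbage_c_content * root_c_fraction;
# sequestration = C input * retention_coefficient (calibrated at run time).
soc_model:
  herbage_c_content: 0.45
  root_c_fraction: 0.25
  retention_coefficient: null

# Manure collected during the non-grazing share of the year.
manure_storage:
  manure_ch4_yield: 4.0       # g CH4 per kg DM intake during housed time
  slurry_m3_per_lu_day: 0.05  # slurry volume produced per LU per housed day

supplement_emission_factor: 0.40  # kg CO2eq per kg concentrate DM delivered

renovation_interval_years: 3
seed_rate_kg_ha: 25.0
mulching_passes_per_year: 1
dressings_per_year: 12
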