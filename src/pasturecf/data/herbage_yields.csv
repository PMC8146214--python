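# Per-treatment, per-year herbage records from the three-year grazing trial.
# Columns:
#   treatment          fertilizer treatment label (N0, N20, N40, N60, N80)
#   year               experimental year index (1-3)
#   dm_yield_t_ha      total herbage production, t DM ha-1 yr-1
#   sem_dm             standard error of the mean for dm_yield (same units)
#   n_yield_kg_ha      herbage nitrogen yield, kg N ha-1 yr-1
#   sem_n              SEM for n_yield
#   energy_yield_gj_ha herbage net-energy-lactation yield, GJ NEL ha-1 yr-1
#   sem_energy         SEM for energy_yield
treatment,year,dm_yield_t_ha,sem_dm,n_yield_kg_ha,sem_n,energy_yield_gj_ha,sem_energy
N0,1,19.3,9.3,519,26.8,123,5.7
N0,2,17.4,4.7,511,24.6,112,2.7
N0,3,18.7,11.4,582,38.9,119,7.5
N20,1,21.5,14.6,586,51.9,140,9.3
N20,2,18.4,6.4,510,18.7,120,3.6
N20,3,20.6,6.5,645,17.7,133,5.0
N40,1,21.1,9.0,657,34.4,137,6.5
N40,2,18.9,0.3,557,16.6,123,2.1
N40,3,20.3,0.4,707,13.5,132,3.0
N60,1,22.9,0.4,788,11.0,151,2.5
N60,2,19.2,0.2,630,33.3,126,1.3
N60,3,20.6,1.9,797,13.0,134,3.2
N80,1,22.6,0.5,849,29.0,148,2.9
N80,2,20.5,0.4,749,9.7,135,3.1
N80,3,21.5,0.7,900,35.3,141,4.9
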