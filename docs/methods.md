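# Methods

This note documents the model implemented in `pasturecf`: its structure,
the parameters that matter, the calibration strategy, what the synthetic
generator does and does not emulate, and the numerical and design choices
made where the problem was genuinely open.

## System and scope

The model represents an irrigated, rotationally grazed dairy-pasture
system: a kikuyu base over-sown annually with Italian ryegrass, grazed
year-round by a Jersey herd (380 kg live weight, 4.7 LU ha⁻¹, 454 cows on
121 ha, milk at 4.9% fat / 3.7% protein), fertilized with limestone
ammonium nitrate in 12 split dressings per year at annual rates of 0, 220,
440, 660 or 880 kg N ha⁻¹.  The driving data are per-treatment, per-year
herbage records: dry-matter yield (t DM ha⁻¹), nitrogen yield (kg N ha⁻¹)
and net-energy-lactation yield (GJ NEL ha⁻¹) for three years.

Everything is an annual, per-hectare aggregate.  There is no seasonal or
lactation dynamics, no paddock geometry, no soil process simulation (the
exponential N₂O response *is* the soil model), and no economics.

## Stage 1 — herbage energy to milk

The energy needed per kg energy-corrected milk is linear in composition,
NEL = 0.38·fat% + 0.21·protein% + 1.05 (3.689 MJ kg⁻¹ at the herd's
composition).  Dividing a treatment's herbage energy yield by this
requirement overpredicts grossly (118 GJ ha⁻¹ would make ~32 t ECM ha⁻¹),
because grazing losses, maintenance, activity and pregnancy consume most
of the energy.  Rather than stacking unverifiable sub-factors, a single
utilization scalar *u* closes the stage; it is calibrated once so the
control treatment yields its reference milk yield (14.8 t ECM ha⁻¹ from
118 GJ ha⁻¹ gives u ≈ 0.463) and applied unchanged to all treatments.
The fertilized treatments' predicted yields (16.4, 16.4, 17.2, 17.7
t ECM ha⁻¹) then track the reference values (16.6, 16.5, 17.5, 18.0)
within ~2%, preserving their ordering — an out-of-sample check of the
linear energy→milk mapping.

Daily DM intake per cow is a linear stand-in for the usual intake
regressions, DMI = 0.02·LW + 0.28·milk + 4.0 (kg DM day⁻¹), with
coefficients exposed in the constants file and chosen so the herd falls in
the 14–15 kg DM day⁻¹ band typical of grazing Jerseys; the concentrate
allowance (3.2 kg DM day⁻¹) is fixed and pasture intake is the remainder.
Per-cow ↔ per-hectare conversions always go through the stocking rate
(4.7 LU ha⁻¹) in one helper.

## Stage 2 — the nitrogen cycle

All flows in kg N ha⁻¹ yr⁻¹:

* milk N = milk protein yield / 6.38; meat N export fixed at 8;
* diet N intake = herbage N yield (all grown herbage grazed; a
  utilization fraction < 1 is config-exposed) plus supplement N;
* excreta returned to pasture = (intake N − milk N) × 0.83, the annual
  proportion of grazing days; the housed remainder goes to storage;
* NH₃-N volatilized during grazing = excreta × TAN fraction × EF.  The
  TAN share of dairy excreta is 0.65; the grazing emission factor on TAN
  defaults to 0.19 (grazing EFs are far lower than for stored or spread
  slurry because urine infiltrates quickly).  The effective loss is thus
  ~12% of excreted N, consistent with field reviews of grazing systems.
  With these defaults the model reproduces the reference paddock balances
  (−119 … +706 kg N ha⁻¹) to within a few percent of their span, which a
  39%-of-excreta loss (0.60 × 0.65, the plausible alternative reading)
  cannot;
* field-N-balance = fertilizer + excreta − NH₃ − herbage N (may be
  negative: an unfertilized sward mines soil N);
* leached N = 0.24 × max(0, field balance) — deficits are clipped to zero
  rather than producing negative leaching;
* farm-N-balance = fertilizer + supplement N − milk N − meat N; gaseous
  losses are deliberately not deducted at the farm gate.

The supplement N import (equivalently the concentrate CP content, which
the driving data do not include) is the stage's calibrated closure: solved
once from the control treatment's farm balance (31 kg N ha⁻¹), giving
~125 kg N ha⁻¹ yr⁻¹, i.e. a concentrate of ~178 g CP kg⁻¹ DM — an
ordinary 18%-CP dairy mix, which is the main internal plausibility check
of that closure.

A second, per-animal excretion path (Nex = 0.84 × daily N intake,
g N day⁻¹, coefficients config-exposed) exists for manure-management
accounting and is cross-checked against the areal intake-minus-milk path
(agreement within 10% on the control treatment).

The N-footprint is (NH₃-N + leached N + N₂O-N, direct and indirect) per
kg ECM.

## Stage 3 — GHG inventory

Direct soil N₂O follows the exponential surplus response
N₂O (kg ha⁻¹) = 1.99 + 1.39·exp(0.00488·x) with x the field-N-balance;
the output species is read as kg N₂O (a config flag selects the N₂O-N
reading, since the unit does not disambiguate).  Indirect N₂O uses
volatilization and leaching factors of 0.010 and 0.011 kg N₂O-N per kg N.

Enteric CH₄ uses feed-specific yields (21.6 g CH₄ kg⁻¹ DM herbage,
14 g kg⁻¹ concentrate) times a single calibrated scale — solved so
enteric CH₄ is 65% of the control treatment's gross GWP (scale ≈ 0.79,
~81 kg CH₄ cow⁻¹ yr⁻¹, inside the 60–160 kg plausibility band).  The
fertilized treatments' shares (56.3, 48.5, 40.6, 31.4%) against the
reference sequence (58, 50, 41, 30%) are out-of-sample.

Embodied and operational items come from an emission-factor table
(fertilizer N 8.60 kg CO₂eq kg⁻¹; renovation every 3 years: tillage 75.42
+ sowing 22.76 + 25 kg seed × 2.03, annualized; 25.33 per fertilizer
dressing; mulching 21.24; irrigation 4200 m³ × 0.43; milking 0.02 per kg
milk; shed 436 per LU scaled by the 17% housed time; slurry store 0.06
per m³).  Concentrate production is charged at 0.40 kg CO₂eq kg⁻¹ DM (a
global-market mix) as its own line item; the "inputs" category in share
reporting is fertilizer + seeds/renovation, averaging ~14% of gross GWP.
Manure storage (slurry handling plus a small storage-CH₄ term of
4 g CH₄ kg⁻¹ DM intake during housed time) stays a ~2–4% item, as
expected for year-round grazing.

Soil organic carbon: below-ground C input = DM yield × 0.45 g C g⁻¹ ×
0.25 (root/exudate fraction of above-ground C); sequestration = input ×
retention, with retention calibrated on the control's 0.85 t C ha⁻¹ yr⁻¹
(≈ 0.41).  The credit is −44/12 × sequestration and reduces the footprint
by ~15% on average.  The linear DM scaling slightly overpredicts the
reference sequestration at high N (0.99 vs 0.91 t C ha⁻¹, within 15%),
which bounds what the one-parameter model can capture.

GWP₁₀₀ aggregation: CH₄ × 28, N₂O × 265, CO₂ × 1; net GWP adds the SOC
offset.

## Stage 4 — footprints and relationships

The carbon footprint per treatment is the mean of yearly ratios (each
year's net GWP over that year's milk), not the ratio of means; the ratio
of means is also reported.  With yearly spread the two differ by a few
hundredths, and the mean-of-ratios convention is the one under which the
control and lowest-N treatments agree within 0.1 kg CO₂eq kg⁻¹ ECM.

Land requirement is reported as 10,000 m² over kg ECM ha⁻¹ (0.56–0.68
m² kg⁻¹ across treatments).  Published figures for comparable systems are
often ~1.5× higher (per liter raw milk, or including non-grazed support
area — the convention is rarely stated), so only the ordering across
treatments is treated as checkable.

Cross-treatment relationships are fit by least squares: areal GHG vs
farm-N-balance (exponential a·e^{bx} beats linear by residual sum of
squares) and milk vs farm-N-balance (linear beats exponential).  The
exponential fit seeds `scipy.optimize.curve_fit` with log-linear
regression estimates; constant inputs are rejected as degenerate.

## Calibration summary

| closure | anchor (control treatment) | solved value |
|---|---|---|
| utilization | milk yield 14.8 t ECM ha⁻¹ | ≈ 0.4627 |
| supplement N | farm-N-balance 31 kg N ha⁻¹ | ≈ 124.8 kg N ha⁻¹ (178 g CP kg⁻¹) |
| CH₄ yield scale | enteric share 65% of gross GWP | ≈ 0.79 |
| SOC retention | sequestration 0.85 t C ha⁻¹ | ≈ 0.41 |

All four are solved at run time from the packaged reference table, never
hard-coded; fixing any of them in the constants file bypasses its solve.
Everything reported for the fertilized treatments is out-of-sample with
respect to these anchors.

## Synthetic data

The generator emulates the trial's statistical structure: a linear-plateau
DM response (base 18.5 t DM ha⁻¹, slope 0.0077 t per kg N, plateau at
220 kg N ha⁻¹ — fertilization beyond the lowest rate buys essentially no
DM), herbage N content rising linearly with the rate (29 g N kg⁻¹ base,
+0.011 per kg N), near-flat energy density (6.4 ± 0.15 MJ NEL kg⁻¹), a
year effect shared by all treatments within a year (sd 1.2 t DM ha⁻¹, the
dominant variance component in the measured table) and small
within-treatment residuals (sd 0.4 t DM ha⁻¹).  The measured table's
per-cell SEMs are stored verbatim but are too erratic (9.3 next to 0.4 t
DM ha⁻¹) to be credible per-cell dispersions; the pooled residual sd is
used instead.  Draws are clipped into the record invariants (N content
≤ 6% DM, energy density within 4–9 MJ kg⁻¹).

The generator supports a parameter-recovery experiment: the forward model
produces the control treatment's observable outputs under known closures,
and the calibration estimators invert them against the generator's
expected (noiseless) yields — mimicking calibration against published
treatment-level means.  Recovery is exact at zero noise and unbiased
(<5% over 100 replicates) at default noise; noise widens the RMSE without
introducing bias.  What this does *not* show: robustness to structural
error (a wrong intake model, non-plateau responses) or to the measurement
conventions of real trials.

## Numerical choices and degenerate inputs

* Negative field surpluses: zero leaching; the N₂O response still applies
  (it is bounded below by its 1.99 intercept).
* Milk N exceeding diet N intake is rejected as infeasible rather than
  clipped.
* Intake and excretion outputs outside their plausibility bands
  ([5, 30] kg DM day⁻¹, [150, 600] g N day⁻¹, [60, 160] kg CH₄ cow⁻¹
  yr⁻¹) raise or warn instead of passing silently.
* Balance identities are enforced in the `NitrogenBalance` constructor to
  1e-6 and verified against a brute-force signed-ledger oracle to 1e-9 in
  the tests.
* All randomness flows through `numpy.random.default_rng(seed)`; repeated
  runs are byte-identical.

## Known limitations

* The intake, excretion, methane and SOC sub-models are deliberately
  simple parameterized forms; their published counterparts' coefficients
  are not part of the driving data, so exact reproduction of quantities
  downstream of them (notably the paddock N balances) is not attainable —
  those are validated on sign, ordering and band instead.
* One utilization scalar cannot represent treatment-specific grazing
  efficiency; biological N fixation by unsown legumes (which matters for
  an unfertilized sward's true balance) is not modelled.
* The SOC model is a one-parameter linear scaling of DM yield compared to
  a reference state; it has no decay dynamics and should not be
  extrapolated outside the observed yield range.
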