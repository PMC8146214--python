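# Emission factors for purchased inputs and farm management activities
# (ecoinvent v3.3 derived).  `basis` documents what one unit of `factor`
# applies to.
activity,factor,unit,basis
grass_seeds,2.03,kg CO2eq/kg,per kg seed sown
ammonium_nitrate_n,8.60,kg CO2eq/kg,per kg fertilizer N
tillage,75.42,kg CO2eq/ha,per renovation pass (rotary cultivator)
sowing,22.76,kg CO2eq/ha,per renovation pass
fertilizing_broadcaster,25.33,kg CO2eq/ha,per fertilizer dressing
mulching,21.24,kg CO2eq/ha,per annual mulching pass
irrigation,0.43,kg CO2eq/m3,per m3 water applied
milking,0.02,kg CO2eq/kg,per kg milk
shed_operation,436.00,kg CO2eq/LU,per livestock unit per year (full housing)
slurry_store,0.06,kg CO2eq/m3,per m3 slurry stored and processed
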