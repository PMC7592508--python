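index,component,amount_column,denominator_column,direction,max_points,zero_score,full_score,basis,unit,energy_per_unit,special_rule,band_full_low,band_full_high,band_zero_high,abstainer_points
ahei2010,vegetables,veg_servings,,adequacy,10,0,5,per_day,servings,,none,,,,
ahei2010,fruit,fruit_servings,,adequacy,10,0,4,per_day,servings,,none,,,,
ahei2010,whole_grains,whole_grains_g,,adequacy,10,0,75,per_day,g,,none,,,,
ahei2010,nuts_and_legumes,nuts_legumes_servings,,adequacy,10,0,1,per_day,servings,,none,,,,
ahei2010,long_chain_omega3,omega3_mg,,adequacy,10,0,250,per_day,mg,,none,,,,
ahei2010,pufa,pufa_g,,adequacy,10,2,10,percent_energy,pct_energy,9,none,,,,
ahei2010,ssb_and_juice,ssb_juice_servings,,moderation,10,1,0,per_day,servings,,none,,,,
ahei2010,red_processed_meat,red_meat_servings,,moderation,10,1.5,0,per_day,servings,,none,,,,
ahei2010,sodium,sodium_g,,moderation,10,3.4,1.1,per_day,g,,none,,,,
ahei2010,alcohol,alcohol_drinks,,adequacy,10,0,0.5,per_day,drinks,,alcohol_band,0.5,1.5,2.5,2.5
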