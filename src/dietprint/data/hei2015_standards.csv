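index,component,amount_column,denominator_column,direction,max_points,zero_score,full_score,basis,unit,energy_per_unit,special_rule,band_full_low,band_full_high,band_zero_high,abstainer_points
hei2015,total_fruits,fruit_total_cup,,adequacy,5,0,0.8,per_1000_kcal,cup_eq,,none,,,,
hei2015,whole_fruits,fruit_whole_cup,,adequacy,5,0,0.4,per_1000_kcal,cup_eq,,none,,,,
hei2015,total_vegetables,veg_total_cup,,adequacy,5,0,1.1,per_1000_kcal,cup_eq,,none,,,,
hei2015,greens_and_beans,greens_beans_cup,,adequacy,5,0,0.2,per_1000_kcal,cup_eq,,none,,,,
hei2015,whole_grains,whole_grains_oz,,adequacy,10,0,1.5,per_1000_kcal,oz_eq,,none,,,,
hei2015,dairy,dairy_cup,,adequacy,10,0,1.3,per_1000_kcal,cup_eq,,none,,,,
hei2015,total_protein_foods,protein_total_oz,,adequacy,5,0,2.5,per_1000_kcal,oz_eq,,none,,,,
hei2015,seafood_plant_proteins,protein_seafood_plant_oz,,adequacy,5,0,0.8,per_1000_kcal,oz_eq,,none,,,,
hei2015,fatty_acids,unsat_fat_g,sat_fat_g,adequacy,10,1.2,2.5,ratio,ratio,,none,,,,
hei2015,refined_grains,refined_grains_oz,,moderation,10,4.3,1.8,per_1000_kcal,oz_eq,,none,,,,
hei2015,sodium,sodium_g,,moderation,10,2.0,1.1,per_1000_kcal,g,,none,,,,
hei2015,added_sugars,added_sugar_g,,moderation,10,26,6.5,percent_energy,pct_energy,4,none,,,,
hei2015,saturated_fats,sat_fat_g,,moderation,10,16,8,percent_energy,pct_energy,9,none,,,,
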