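taxon_id,nutrient,value,unit,source
pooled,energy,110,kcal/100g,synthetic default observation
pooled,energy,125,kcal/100g,synthetic default observation
pooled,energy,132,kcal/100g,synthetic default observation
pooled,energy,118,kcal/100g,synthetic default observation
pooled,protein,20.5,g/100g,synthetic default observation
pooled,protein,22.1,g/100g,synthetic default observation
pooled,protein,21.4,g/100g,synthetic default observation
pooled,protein,19.8,g/100g,synthetic default observation
pooled,protein,23.0,g/100g,synthetic default observation
pooled,total_fat,2.1,g/100g,synthetic default observation
pooled,total_fat,3.4,g/100g,synthetic default observation
pooled,total_fat,4.0,g/100g,synthetic default observation
pooled,total_fat,2.8,g/100g,synthetic default observation
pooled,iron,3.1,mg/100g,synthetic default observation
pooled,iron,3.9,mg/100g,synthetic default observation
pooled,iron,3.4,mg/100g,synthetic default observation
pooled,zinc,2.7,mg/100g,synthetic default observation
pooled,zinc,3.3,mg/100g,synthetic default observation
pooled,selenium,9.5,ug/100g,synthetic default observation
pooled,selenium,11.0,ug/100g,synthetic default observation
pooled,vitamin_b1,0.09,mg/100g,synthetic default observation
pooled,vitamin_b1,0.12,mg/100g,synthetic default observation
pooled,vitamin_b2,0.22,mg/100g,synthetic default observation
pooled,vitamin_b2,0.28,mg/100g,synthetic default observation
pooled,vitamin_b3,4.6,mg/100g,synthetic default observation
pooled,vitamin_b3,5.5,mg/100g,synthetic default observation
pooled,vitamin_b12,1.7,ug/100g,synthetic default observation
pooled,vitamin_b12,2.4,ug/100g,synthetic default observation
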