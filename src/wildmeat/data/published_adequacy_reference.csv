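nutrient,adequacy_pct_mean,adequacy_pct_sd,adequacy_pct_q10,adequacy_pct_q90,note
protein,50.7,13.6,36.5,66.6,published continental estimate; reference metadata only
total_fat,5.6,1.5,3.3,8.7,published continental estimate; reference metadata only
energy,5.7,1.5,3.9,7.7,published continental estimate; reference metadata only
vitamin_b12,126.4,33.8,59.6,218.7,published continental estimate; reference metadata only
iron,39.2,10.5,22.7,61.1,published continental estimate; reference metadata only
vitamin_b2,36.8,9.8,23.9,52.7,published continental estimate; reference metadata only
vitamin_b3,33.5,9.0,20.4,50.5,published continental estimate; reference metadata only
selenium,31.6,8.5,22.9,41.4,published continental estimate; reference metadata only
zinc,23.3,6.2,11.5,39.2,published continental estimate; reference metadata only
vitamin_b1,18.1,4.8,10.5,28.4,published continental estimate; reference metadata only
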