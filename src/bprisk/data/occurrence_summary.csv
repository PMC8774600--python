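food_category,analyte,n,detection_rate_pct,min_ng_g,min_is_censored,max_ng_g,mean_ng_g,sd_ng_g,gm_ng_g
cereal_I_rice_flour,BP,59,100,17,0,108,38,20,34
cereal_I_rice_flour,4-MBP,59,85,0.01,1,12,2.1,1.5,1.9
cereal_I_rice_flour,4-OHBP,59,5.1,0.51,1,33,17,15,12
cereal_I_rice_flour,PBZ,59,1.7,0.07,1,0.94,0.94,,0.94
cereal_II_wheat,BP,61,100,14,0,68,21,8.4,20
cereal_II_wheat,4-MBP,61,100,1.2,0,66,4.2,8.3,2.8
cereal_II_wheat,PBZ,61,1.6,0.05,1,0.42,0.42,,0.42
cereal_III_processed,BP,60,100,22,0,1084,89,199,47
cereal_III_processed,4-MBP,60,100,0.90,0,12,2.6,1.8,2.3
cereal_III_processed,4-OHBP,60,17,0.05,1,9.7,4.9,2.2,4.5
cereal_III_processed,M2BB,60,8.3,0.29,1,17.3,5.3,6.9,2.8
juice_fresh_100,BP,14,100,8.0,0,29,12,5.4,12
juice_fresh_100,4-MBP,14,100,0.20,0,0.50,0.30,0.08,0.30
juice_fresh_100,M2BB,14,93,0.44,0,0.74,0.57,0.09,1.7
juice_fresh_100,PBZ,14,79,0.14,0,2.3,0.48,0.63,1.5
juice_reconstituted_100,BP,63,100,7.3,0,51,16,9.2,14
juice_reconstituted_100,4-MBP,63,87,0.11,0,1.5,0.20,0.20,0.15
juice_reconstituted_100,4-OHBP,63,1.6,0.82,0,0.82,0.82,,0.05
juice_reconstituted_100,M2BB,63,100,0.34,0,0.84,0.48,0.10,0.47
juice_reconstituted_100,PBZ,63,47.6,0.14,0,1.6,0.38,0.36,1.2
juice_10pct_plus,BP,59,100,5.2,0,37,13,5.5,12
juice_10pct_plus,4-MBP,59,95,0.12,0,8.5,0.70,1.4,0.34
juice_10pct_plus,M2BB,59,100,0.37,0,0.81,0.54,0.11,0.52
juice_10pct_plus,PBZ,59,54,0.14,0,0.95,0.29,0.19,1.2
milk_full_fat,BP,37,100,4.5,0,16,8.1,2.3,7.8
milk_full_fat,4-MBP,37,30,0.34,0,101,28,32,0.17
milk_full_fat,4-OHBP,37,5.4,8.2,0,12,9.9,2.3,0.14
milk_full_fat,M2BB,37,35,0.22,0,0.46,0.29,0.09,0.14
milk_full_fat,PBZ,37,57,0.41,0,2.6,1.6,0.70,0.22
milk_low_fat,BP,9,100,4.2,0,15,8.2,3.6,7.6
milk_low_fat,4-MBP,9,22,21,0,150,85,91,0.16
milk_low_fat,4-OHBP,9,11,9.1,0,9.1,9.1,,0.17
milk_low_fat,M2BB,9,22,0.26,0,0.29,0.27,0.02,0.13
milk_low_fat,PBZ,9,78,0.60,0,2.3,1.6,0.65,0.55
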