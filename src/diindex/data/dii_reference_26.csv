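name,unit,global_mean,global_sd,effect_score
alcohol,g,13.98,3.72,-0.278
vitamin_b12,ug,5.15,2.70,0.106
vitamin_b6,mg,1.47,0.74,-0.365
beta_carotene,ug,3718.0,1720.0,-0.584
caffeine,g,8.05,6.67,-0.110
carbohydrate,g,272.2,40.0,0.097
cholesterol,mg,279.4,51.2,0.110
energy,kcal,2056.0,338.0,0.180
total_fat,g,71.4,19.4,0.298
fiber,g,18.8,4.9,-0.663
folic_acid,ug,273.0,70.7,-0.190
iron,mg,13.35,3.71,0.032
magnesium,mg,310.1,139.4,-0.484
mufa,g,27.0,6.1,-0.009
niacin,mg,25.90,11.77,-0.246
n3_fatty_acids,g,1.06,1.06,-0.436
protein,g,79.4,13.9,0.021
pufa,g,13.88,3.76,-0.337
riboflavin,mg,1.70,0.79,-0.068
saturated_fat,g,28.6,8.0,0.373
selenium,ug,67.0,25.1,-0.191
thiamin,mg,1.70,0.66,-0.098
vitamin_a,RE,983.9,518.6,-0.401
vitamin_c,mg,118.2,43.46,-0.424
vitamin_e,mg,8.73,1.49,-0.419
zinc,mg,9.84,2.19,-0.313
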