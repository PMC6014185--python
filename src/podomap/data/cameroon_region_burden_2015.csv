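region,population_at_risk,population_lower,population_upper,cases_mean,cases_low,cases_high
Adamawa,381666,361913,420270,2305,49,13831
Central,400747,306628,431475,7303,176,43138
East,80736,72706,97824,899,22,5293
Extreme North,547793,493820,613170,5134,112,30902
Littoral,618549,491969,749893,6186,237,34237
North,595335,504622,757766,5840,128,35152
North West,1678461,1649810,1719003,6089,271,32011
South,126695,120569,131644,840,19,5043
South West,203965,193811,229278,2521,59,14867
West,583260,546435,652894,4441,99,26519
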