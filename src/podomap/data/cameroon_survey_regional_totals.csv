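region,clusters,total_screened,cases
Adamawa,2,320,0
Central,10,1932,4
East,8,1195,4
Extreme North,5,803,5
Littoral,9,1228,4
North,5,692,7
North West,681,205664,849
South,2,435,1
South West,14,1137,3
West,12,1323,5
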