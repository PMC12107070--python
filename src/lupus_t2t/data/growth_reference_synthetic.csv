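sex,age_years,median_weight_kg
female,0,3.2
female,1,8.9
female,2,11.5
female,3,13.9
female,4,16.1
female,5,18.2
female,6,20.2
female,7,22.4
female,8,25.0
female,9,28.2
female,10,31.9
female,11,36.0
female,12,40.2
female,13,44.5
female,14,48.0
female,15,50.8
female,16,52.7
female,17,54.0
female,18,55.0
male,0,3.3
male,1,9.6
male,2,12.2
male,3,14.3
male,4,16.3
male,5,18.3
male,6,20.5
male,7,22.9
male,8,25.4
male,9,28.1
male,10,31.2
male,11,34.7
male,12,38.9
male,13,43.9
male,14,49.4
male,15,54.5
male,16,58.8
male,17,61.8
male,18,63.8
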