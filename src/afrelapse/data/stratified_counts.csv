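variable,state,total,relapse,af_free
sex,female,185,55,130
sex,male,295,111,184
age,le45,57,9,48
age,46to65,234,84,150
age,over65,189,73,116
alcoholism,false,455,151,304
alcoholism,true,25,15,10
smoking,false,345,109,236
smoking,true,135,57,78
diabetes,false,434,150,284
diabetes,true,46,16,30
hbp,false,188,61,127
hbp,true,292,105,187
osa,false,430,131,299
osa,true,50,35,15
bmi,normal,151,35,116
bmi,overweight,218,74,144
bmi,obese,111,57,54
af_type,paroxysmal,374,98,276
af_type,persistent,106,68,38
la_volume,le100,168,39,129
la_volume,100to125,172,56,116
la_volume,over125,140,71,69
epicardial_fat,le2.7,162,18,144
epicardial_fat,2.7to4.6,166,48,118
epicardial_fat,over4.6,152,100,52
relapse,false,314,0,314
relapse,true,166,166,0
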