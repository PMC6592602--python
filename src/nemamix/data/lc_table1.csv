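compound,lc_level,conc_mg_per_L,conc_spread
Zn,2,0.445,0.314
Zn,5,1.416,0.771
Zn,20,9.501,2.841
Zn,40,31.495,6.186
Zn,60,84.823,17.601
Cu,5,0.226,0.104
Cu,20,1.299,0.409
Cd,5,0.474,0.289
Cd,20,7.110,2.315
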