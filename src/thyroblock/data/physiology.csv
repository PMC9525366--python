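quantity,w0,w3,w8,w12,w16,w24,w32,w36,w38
vd_maternal_blood_l,7,7,7,7,7,7,7,7,7
thyroid_weight_maternal_g,16.0,16.0,16.0,16.93,16.93,16.93,18.38,18.38,19.83
lobe_radius_maternal_cm,1.270,1.270,1.270,1.294,1.294,1.294,1.330,1.330,1.364
fetal_weight_g,,,,90,222,902,2312,3186,3617
vd_fetal_l,,,,0.045,0.111,0.451,1.156,1.593,1.8085
thyroid_weight_fetal_g,,,,0.101,0.166,0.475,1.05,1.25,1.30
lobe_radius_fetal_cm,,,,0.197,0.252,0.392,0.471,0.502,0.516
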