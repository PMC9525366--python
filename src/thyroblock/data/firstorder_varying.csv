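flow,w0,w3,w8,w12,w16,w24,w32,w36,w38
Blood to kidneys,6.4,7.0,8.9,10.0,12.0,13.0,12.0,12.0,12.0
Blood to amniotic fluid iodide,0,0.75,0.75,0.75,0.75,0.75,0.75,0.75,0.75
Organic iodine in other to iodide in other,0.03,0.038,0.038,0.038,0.038,0.038,0.038,0.038,0.038
Organic iodine in other to upper large intestine,0.0074,0.0094,0.0094,0.0094,0.0094,0.0094,0.0094,0.0094,0.0094
Organic iodine in other to uteroplacental unit organic iodine,0,0,18,20,24,31,40,46,51
Organic iodine in other to amniotic fluid organic iodine,0,5.5,5.5,5.5,5.5,5.5,5.5,5.5,5.5
Uteroplacental unit iodide to blood,11000,11000,11000,3600,1400,510,270,190,160
Uteroplacental unit iodide to fetal iodide,0,0,0,33,33,33,33,33,33
Uteroplacental unit organic iodine to organic iodine in other,18000,18000,18000,7600,3900,1900,1500,1500,1600
Fetal iodide to uteroplacental unit iodide,0,0,0,100,60,35,20,15,12
Thyroid organic iodine to organic iodine in other,0.0063,0.013,0.013,0.013,0.013,0.013,0.013,0.013,0.013
Amniotic fluid iodide to blood,130,130,130,43,17,6,3.2,2.2,1.9
Amniotic fluid iodide to fetal iodide,0,0,0,0.25,0.25,0.25,0.25,0.25,0.25
Amniotic fluid organic iodine to organic iodine in other,6400,6400,6400,2300,990,380,230,200,190
Amniotic fluid organic iodine to fetal iodide,0,0,0,0.25,0.25,0.25,0.25,0.25,0.25
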