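flow,k
Stomach to blood,40
Stomach to small intestine,24
Small intestine to blood,300
Small intestine to upper large intestine,6
Blood to iodide in other,48
Blood to thyroid iodide,2.3
Blood to ovaries,17
Iodide in other to blood,19
Thyroid iodide to blood,1.6
Ovaries to blood,590
Salivary glands to stomach,10
Gastric secretory cells to stomach,20
Kidneys to urinary bladder,10
Fetal thyroid to fetal organic iodine,0.035
Fetal organic iodine to fetal iodide,0.13
Upper large intestine to lower large intestine,1.8
Lower large intestine to feces,1
Urinary bladder to urine,12
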