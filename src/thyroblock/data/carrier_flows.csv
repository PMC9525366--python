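flow,param,w0,w3,w8,w12,w16,w24,w32,w36,w38
Blood to thyroid iodide,k,2.3,2.3,2.3,2.3,2.3,2.3,2.3,2.3,2.3
Blood to thyroid iodide,km_abs,63,63,63,63,63,63,63,63,63
Blood to thyroid iodide,tmax,144.9,144.9,144.9,144.9,144.9,144.9,144.9,144.9,144.9
Blood to thyroid organic iodine,k,2.3,5.1,6.5,7.5,8.4,9.3,9.1,8.8,8.7
Blood to thyroid organic iodine,km_abs,63,63,63,63,63,63,63,63,63
Blood to thyroid organic iodine,tmax,144.9,321.3,409.5,472.5,529.2,585.9,573.3,554.4,548.1
Blood to salivary gland,k,3.0,3.0,3.0,3.0,3.0,3.0,3.0,3.0,3.0
Blood to salivary gland,km_abs,63,63,63,63,63,63,63,63,63
Blood to salivary gland,tmax,189,189,189,189,189,189,189,189,189
Blood to gastric secretory cells,k,8.6,8.6,8.6,8.6,8.6,8.6,8.6,8.6,8.6
Blood to gastric secretory cells,km_abs,63,63,63,63,63,63,63,63,63
Blood to gastric secretory cells,tmax,541.8,541.8,541.8,541.8,541.8,541.8,541.8,541.8,541.8
Blood to placenta iodide,k,0,0,33,33,33,33,33,33,33
Blood to placenta iodide,km_abs,,,63,63,63,63,63,63,63
Blood to placenta iodide,tmax,,,2079,2079,2079,2079,2079,2079,2079
Fetal iodide to fetal thyroid,k,0,0,0,1.8,3.5,5.0,6.0,6.0,6.0
Fetal iodide to fetal thyroid,km_abs,,,,0.405,0.999,4.059,10.404,14.337,16.2765
Fetal iodide to fetal thyroid,tmax,,,,0.729,3.4965,20.295,62.424,86.022,97.659
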