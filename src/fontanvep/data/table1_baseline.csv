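# Baseline (no device) caval pressures per TCPC model, mmHg, v1
label,P_IVC,P_SVC
0-DO,11.006,11.228
0.5-DO,10.825,10.999
1-DO,10.850,10.868
PSC1,10.187,10.185
PSC2,10.284,10.355
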