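# Nozzle-study anchors (1-DO model, throat 8 mm, discharge 4 mm), v1
# Q_AoG: measured graft flow, L/min; dP_IVC: measured IVC pressure drop, mmHg
D_N,Q_AoG,dP_IVC
1.5,0.315,0.8
3.0,1.555,6.5
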