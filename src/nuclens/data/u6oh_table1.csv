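geom_id,state,E_eV,f
0,1,2.29,0.0002
0,2,2.90,0.0238
0,3,3.91,0.0020
0,4,3.96,0.0053
0,5,4.51,0.0027
0,6,4.74,0.0022
0,7,5.70,0.0150
0,8,6.03,0.0004
0,9,6.04,0.0004
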