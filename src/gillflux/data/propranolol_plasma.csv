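nominal_water_ug_per_L,in_silico_ng_per_mL,in_vivo_ng_per_mL,in_vivo_sem,in_vitro_ng_per_mL,in_vitro_sem
0.1,0.087,,,0.04,0.002
1.0,0.87,0.94,,0.10,0.001
10,8.7,3.3,0.4,0.72,0.02
100,87,16,7,7.5,0.3
1000,870,280,116,79.5,7.3
10000,8700,5200,1333,812,158
100000,87000,,,5545,313
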