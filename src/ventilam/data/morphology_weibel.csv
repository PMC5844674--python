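gn,radius_m,length_m,t_epi_m,t_conn_m,t_asm_m
0,0.009,0.12,0.00045,0.0009,0.00135
1,0.0061,0.0476,0.000305,0.00061,0.000915
2,0.00415,0.019,0.0002075,0.000415,0.0006225
3,0.0028,0.0076,0.00014,0.00028,0.00042
4,0.00225,0.0127,0.0001125,0.000225,0.0003375
5,0.00175,0.0107,8.75e-05,0.000175,0.0002625
6,0.0014,0.009,7e-05,0.00014,0.00021
7,0.00115,0.0076,5.75e-05,0.000115,0.0001725
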