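frequency_hz,resistivity_ohm_m,rel_permittivity
76,16.0,150000
1000,15.0,24000
10000,14.0,1100
100000,13.0,240
625000,12.0,90
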