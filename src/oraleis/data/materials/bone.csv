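frequency_hz,resistivity_ohm_m,rel_permittivity
76,20.0,10000
1000,18.0,2600
10000,16.0,1000
100000,15.0,460
625000,14.0,300
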