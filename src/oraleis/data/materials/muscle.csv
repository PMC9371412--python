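frequency_hz,resistivity_ohm_m,rel_permittivity
76,3.7,8000000
1000,3.1,400000
10000,2.9,25000
100000,2.8,8000
625000,2.0,4000
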