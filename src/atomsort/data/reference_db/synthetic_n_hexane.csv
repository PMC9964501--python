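# SYNTHETIC stand-in peak list: typical CH correlations of n-hexane
h_ppm,c_ppm
0.9000,14.4000
1.2900,23.7000
1.2900,32.7000
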