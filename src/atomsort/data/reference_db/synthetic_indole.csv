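# SYNTHETIC stand-in peak list: typical aromatic CH correlations of indole
h_ppm,c_ppm
7.1800,124.3000
6.4300,101.5000
7.5600,120.9000
6.9700,119.8000
7.0800,122.2000
7.3600,111.8000
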