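# SYNTHETIC stand-in peak list: typical CH correlations of cyclo(Pro-Tyr)
h_ppm,c_ppm
7.0500,132.3000
6.7800,116.2000
4.2100,57.6000
3.1200,37.3000
2.9500,37.3000
4.0800,59.9000
3.5500,45.9000
3.3800,45.9000
2.1000,29.1000
1.2500,29.1000
1.8000,22.5000
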