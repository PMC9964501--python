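# SYNTHETIC stand-in peak list: typical CH correlations of
# cyclo(Ile-Pro-Leu-Pro)
h_ppm,c_ppm
4.3000,58.0000
1.9000,37.5000
1.5000,25.5000
1.2000,25.5000
0.9300,15.5000
0.8700,11.3000
4.4000,61.0000
2.1800,29.8000
1.9000,29.8000
2.0500,25.4000
1.9800,25.4000
3.6000,47.8000
3.4800,47.8000
4.2500,53.5000
1.7500,40.5000
1.5500,40.5000
1.6800,25.2000
0.9500,23.4000
0.9100,21.6000
4.3300,61.3000
2.2200,30.1000
1.8800,30.1000
2.0800,25.6000
1.9600,25.6000
3.7000,48.0000
3.5200,48.0000
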