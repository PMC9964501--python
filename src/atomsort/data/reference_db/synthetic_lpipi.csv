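# SYNTHETIC stand-in peak list: typical CH correlations of the linear
# pentapeptide Leu-Pro-Ile-Pro-Ile
h_ppm,c_ppm
3.9500,52.3000
1.6500,41.2000
1.5800,41.2000
1.7000,25.6000
0.9600,23.1000
0.9400,21.9000
4.3800,61.5000
2.2000,30.2000
1.9500,30.2000
2.0000,25.8000
3.6500,48.3000
3.5500,48.3000
4.4200,57.5000
1.8500,37.8000
1.4800,25.9000
0.9200,15.8000
0.8800,11.5000
4.3500,61.8000
2.2500,30.0000
2.0200,25.7000
3.7200,48.5000
3.5800,48.5000
4.1800,59.3000
1.8800,38.2000
1.4500,26.0000
0.9000,16.0000
0.8600,11.8000
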