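h_ppm,c_ppm
3.6100,40.3000
2.4300,40.3000
4.0500,67.6000
3.9700,56.6000
2.0000,34.9000
0.9800,14.5000
0.9700,12.1000
4.1200,49.2000
1.3000,15.9000
5.0500,81.9000
2.3200,31.0000
0.8700,17.0000
0.9300,19.2000
4.7800,50.6000
1.6400,42.2000
1.2300,42.2000
1.5200,25.7000
0.9200,21.2000
0.9600,23.8000
4.8000,58.4000
2.1900,28.7000
1.7000,28.7000
2.0600,25.5000
3.7400,47.9000
3.5800,47.9000
4.0100,66.3000
3.1500,34.6000
3.2900,34.6000
7.1400,131.8000
6.8800,114.7000
3.7800,55.3000
2.6200,39.1000
4.5400,59.1000
5.3700,71.1000
1.3500,16.6000
5.3900,55.9000
1.8000,37.0000
1.4700,25.5000
0.8900,21.3000
0.9500,23.8000
3.1900,31.5000
4.8400,58.0000
2.2800,29.2000
1.8500,29.2000
2.1600,26.6000
2.0300,26.6000
3.8800,48.1000
3.6400,48.1000
4.4700,67.3000
1.3800,19.9000
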