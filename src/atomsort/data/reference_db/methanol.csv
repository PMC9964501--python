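# CD3OD-referenced methanol correlation (dH 3.31, dC 49.0)
h_ppm,c_ppm
3.3100,49.0000
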