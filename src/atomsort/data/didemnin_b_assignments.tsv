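# Tabulated 1H/13C NMR assignments of didemnin B in CD3OD.
# position	h_shift	c_shift
# Rows with an empty c_shift inherit the carbon of their diastereotopic
# partner (same position label up to the trailing a/b). N-H rows carry no
# carbon and are excluded when building the HSQC peak list. No 13C shift is
# tabulated for either Ist7 methylene proton.
position	h_shift	c_shift
Ist2a	3.61	40.3
Ist2b	2.43
Ist3	4.05	67.6
Ist4	3.97	56.6
Ist5	2.00	34.9
Ist6	0.98	14.5
Ist7a	1.40
Ist7b	1.26
Ist8	0.97	12.1
IstNH	7.35
Hip2	4.12	49.2
Hip3	1.30	15.9
Hip5	5.05	81.9
Hip6	2.32	31.0
Hip7	0.87	17.0
Hip8	0.93	19.2
Leu2	4.78	50.6
Leu3a	1.64	42.2
Leu3b	1.23
Leu4	1.52	25.7
Leu5	0.92	21.2
Leu6	0.96	23.8
LeuNH	8.1
Pro2	4.80	58.4
Pro3a	2.19	28.7
Pro3b	1.70
Pro4	2.06	25.5
Pro5a	3.74	47.9
Pro5b	3.58
MTyr2	4.01	66.3
MTyr3a	3.15	34.6
MTyr3b	3.29
MTyr5	7.14	131.8
MTyr6	6.88	114.7
MTyr8	3.78	55.3
MTyrNMe	2.62	39.1
Thr2	4.54	59.1
Thr3	5.37	71.1
Thr4	1.35	16.6
ThrNH	7.94
MLeu2	5.39	55.9
MLeu3	1.80	37.0
MLeu4	1.47	25.5
MLeu5	0.89	21.3
MLeu6	0.95	23.8
MLeuNMe	3.19	31.5
HPro2	4.84	58.0
HPro3a	2.28	29.2
HPro3b	1.85
HPro4a	2.16	26.6
HPro4b	2.03
HPro5a	3.88	48.1
HPro5b	3.64
HP2	4.47	67.3
HP3	1.38	19.9
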