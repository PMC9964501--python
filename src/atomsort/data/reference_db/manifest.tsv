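name	formula	mol_weight	file
methanol	CH4O	32.04	methanol.csv
indole	C8H7N	117.15	synthetic_indole.csv
didemnin B	C57H89N7O15		didemnin_b.csv
cyclo(Pro–Tyr)	C14H16N2O3	260.29	synthetic_cyclo_pro_tyr.csv
Leu–Pro–Ile–Pro–Ile	C28H49N5O6	551.72	synthetic_lpipi.csv
cyclo(Ile–Pro–Leu–Pro)	C22H36N4O4	420.6	synthetic_cyclo_ile_pro_leu_pro.csv
n–hexane	C6H14	86.18	synthetic_n_hexane.csv
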