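name	mass_shift	charge
M+H[1+]	1.007276	1
M+Na[1+]	22.989218	1
M+NH3[1+]	18.033823	1
M+K[1+]	38.963158	1
M-H2O[1+]	-17.003289	1
M-NH3[1+]	-16.019274	1
M+2H[2+]	2.014552	2
M+H+Na[2+]	23.996494	2
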