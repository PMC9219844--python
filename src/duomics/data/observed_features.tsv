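compound	adduct	mz	rt	fold_change	p_value	fraction	verified
alpha-linolenate	M-H2O[1+]	261.2201	1.4	32.2	2.2e-7	pellet	true
alpha-linolenate	M+H[1+]	279.2305	1.39	42.5	2e-6	pellet	true
HPETE	M+2H[2+]	169.1215	0.85	2.5	6e-6	pellet	true
S-3-methyl-2-oxopentanoate	M-H2O[1+]	113.0591	0.75	11.1	4.4e-7	pellet	true
2-trans-hexadecenal	M+Na[1+]	261.2201	0.87	15.8	1.2e-5	pellet	true
2-trans-hexadecenal	M+Na[1+]	261.2201	1.4	32.2	2.2e-7	pellet	true
3-ureido-isobutyrate	M+Na[1+]	169.0579	1.06	18.4	3.6e-5	pellet	true
4-hydroxy-2-nonenal-glutathione conjugate	M+H[1+]	465.2138	5.09	15	1.2e-6	pellet	false
glutathione disulfide	M+2H[2+]	308.0897	0.52	236.6	1.6e-5	pellet	false
hypoxanthine	M-H2O[1+]	119.0346	0.52	42.3	7.7e-5	pellet	true
hypoxanthine	M+H[1+]	137.0451	0.53	583.7	7.7e-6	pellet	true
laurate	M+Na[1+]	223.1667	0.79	4.9	3e-5	pellet	true
methylhistamine	M+NH3[1+]	144.1374	0.77	3.9	3.4e-7	pellet	false
N-acetylputrescine	M+K[1+]	170.081	0.73	3	1.8e-6	pellet	false
oleate	M+NH3[1+]	300.2884	3.19	2	5.5e-5	pellet	true
oleate	M+H+Na	153.1264	1.37	10.2	4e-5	pellet	true
palmitate	M+Na[1+]	263.2354	1.34	43.8	8e-7	pellet	false
palmitate	M+Na[1+]	279.2305	1.39	42.5	2e-6	pellet	true
pyridoxine	M+H[1+]	170.081	0.73	3	1.8e-6	pellet	true
S-methyl-5'-thioadenosine	M+H[1+]	298.0963	0.54	43.4	7.2e-5	pellet	true
urocanate	M+NH3+	156.076	0.5	3.7	2e-7	pellet	true
1-pyrroline-3-hydroxy-5-carboxylate	M+H[1+]	130.0493	0.5	-3.7	1.3e-5	media	true
S-dihydroorotate	M+NH3[1+]	176.066	1.21	-20.5	1.8e-5	media	true
3-4-dihydroxy-5-all-trans-decaprenylbenzoate	M+H[1+]	835.659	8.84	-3	1.9e-5	media	true
3-ureido-isobutyrate	M-NH3[1+]	130.0493	0.5	-3.7	1.3e-5	media	true
5S-hydroperoxy-18R-hydroxy-eicosapentaenoate	M-H2O[1+]	333.2044	1.57	-138.8	4e-5	media	true
all-trans-retinoate	M-H2O[1+]	283.2043	2.22	-4.2	2.5e-8	media	true
all-trans-retinoate	M+Na[1+]	323.1968	1.11	-33.9	1.2e-5	media	true
all-trans-retinoate	M+Na[1+]	323.1966	1.53	-141.3	4.2e-6	media	true
biliverdin-IX	M+NH3[1+]	600.2797	1.28	-3281.8	5.3e-6	media	true
codeine	M+NH3[1+]	318.1929	0.84	-3.7	8.2e-5	media	false
D-sorbitol	M+Na[1+]	205.0675	1.16	-5	3.1e-5	media	true
N-formylkynurenine	M+NH3[1+]	255.1223	0.86	-4.3	5e-5	media	false
resolvin E1	M-H2O[1+]	333.2044	1.57	-138.8	4e-5	media	true
resolvin E2	M-H2O[1+]	317.2101	0.88	-8.8	2.6e-5	media	true
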