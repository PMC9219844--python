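name	formula	cas	kegg	ec_links	pathways	verified
alpha-linolenate	C18H30O2	463-40-1	C06427	6.2.1.3	eicosapentaenoate biosynthesis II	true
HPETE	C20H32O4	70608-72-9	C05356	1.13.11.34	leukotriene biosynthesis	true
S-3-methyl-2-oxopentanoate	C6H10O3	1460-34-0	C00671	1.2.4.4	isoleucine degradation	true
2-trans-hexadecenal	C16H30O			1.2.1.3	sphingosine metabolism	true
3-ureido-isobutyrate	C5H10N2O3		C05100	3.5.1.6	thymine degradation	true
4-hydroxy-2-nonenal-glutathione conjugate	C19H33N3O8S			2.5.1.18	4-hydroxy-2-nonenal detoxification	false
glutathione disulfide	C20H32N6O12S2	27025-41-8	C00127	1.8.1.7	glutaredoxin ascorbate recycling	false
hypoxanthine	C5H4N4O	68-94-0	C00262	1.17.1.4;2.4.2.8	purine degradation	true
laurate	C12H24O2	143-07-7	C02679	6.2.1.3	palmitate biosynthesis	true
methylhistamine	C6H11N3	501-75-7	C05127	1.4.3.22	histamine degradation	false
N-acetylputrescine	C6H14N2O	18233-70-0	C02714	1.4.3.6	putrescine degradation III	false
oleate	C18H34O2	112-80-1	C00712	6.2.1.3	oleate biosynthesis	true
palmitate	C16H32O2	57-10-3	C00249	6.2.1.3	palmitate biosynthesis-stearate biosynthesis	true
pyridoxine	C8H11NO3	65-23-6	C00314	2.7.1.35	pyridoxal 5'-phosphate salvage	true
S-methyl-5'-thioadenosine	C11H15N5O3S	2457-80-9	C00170	2.4.2.28	wyosine biosynthesis	true
urocanate	C6H6N2O2	104-98-3	C00785	4.2.1.49	histidine degradation	true
1-pyrroline-3-hydroxy-5-carboxylate	C5H7NO3		C04282	1.5.1.12	4-hydroxyproline degradation	true
S-dihydroorotate	C5H6N2O4	5988-19-2	C00337	1.3.5.2	UMP biosynthesis	true
3-4-dihydroxy-5-all-trans-decaprenylbenzoate	C57H86O4		C05848	2.1.1.64	ubiquinol-10 biosynthesis	true
5S-hydroperoxy-18R-hydroxy-eicosapentaenoate	C20H30O5			1.13.11.34	resolvin E biosynthesis	true
all-trans-retinoate	C20H28O2	302-79-4	C00777	1.2.1.36	retinoate biosynthesis	true
biliverdin-IX	C33H34N4O6	114-25-0	C00500	1.3.1.24	heme degradation	true
codeine	C18H21NO3	76-57-3	C06174		morphine biosynthesis	false
D-sorbitol	C6H14O6	50-70-4	C00794	1.1.1.14	sorbitol degradation I	true
N-formylkynurenine	C11H12N2O4	1022-31-7	C02700	3.5.1.9	tryptophan degradation	false
resolvin E1	C20H30O5			1.13.11.34	resolvin E biosynthesis	true
resolvin E2	C20H30O4			1.13.11.34	resolvin E biosynthesis	true
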