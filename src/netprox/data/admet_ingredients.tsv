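mol_id	name	molecular_formula	pubchem_cid	gi_absorption	bioavailability_pct
MOL01	Gallic acid	C7H6O5	370	High	7.73
MOL02	2,5-Dimethyl-7-hydroxy chromone	C11H10O3	5316891	High	99.36
MOL03	Cacticin	C22H22O12	5318644	Low	6.98
MOL04	Physcion	C16H12O5	10639	High	75.28
MOL05	Chimaphylin	C12H10O2	101211	High	89.68
MOL06	Chrysophanol	C15H10O4	10208	High	72.78
MOL07	Rhein	C15H8O6	10168	High	97.68
MOL08	Kaempferide	C16H12O6	5281666	High	98.78
MOL09	Villosolside	C16H26O9	127454	Low	3.69
MOL10	Scopoletin	C10H8O4	5280460	High	99.43
MOL11	4'-Hydroxyacetophenone	C8H8O2	7469	High	99.52
MOL12	7-Methoxycoumarin	C10H8O3	10748	High	99.57
MOL13	Safflor yellow A	C27H30O15	6448299	Low	0.02
MOL14	5,6-Dimethoxy-7-hydroxy coumarin	C11H10O5	5316862	High	99.5
MOL15	Isofraxidin	C11H15O5	5318565	High	99.41
MOL16	Isoquercitrin	C21H20O12	5280804	Low	2.58
MOL17	Salicylic acid	C7H6O3	338	High	83.24
MOL18	Isorhamnetin-3-glucoside	C22H22O12	14704554	Low	7.84
MOL19	Scoparone	C11H10O4	8417	High	99.61
MOL20	Azelaic acid	C9H16O4	2266	High	10.58
MOL21	6-Demethoxycapillarisin	C15H10O6	5316511	High	99.2
MOL22	Capillarisin	C16H12O7	5281342	High	97.83
MOL23	Cirsimaritin	C17H14O6	188323	High	99.37
MOL24	Capillartemisin	C19H24O4	6439717	High	98.77
MOL25	Rhamnocitrin	C16H12O6	5320946	High	99.2
MOL26	Gardenoside B	C17H24O11	24721095	Low	1.68
MOL27	Picrocrocinic acid	C16H26O8	5320582	Low	1.6
MOL28	Genipingentiobioside	C23H34O15	3082301	Low	0.35
MOL29	Geniposide	C17H24O10	107848	Low	5.72
MOL30	2,4-Decadienal	C10H16O	5283349	High	99.66
MOL31	2-Ethyl-2-hexenal	C8H14O	5354264	High	99.69
MOL32	Isosyringinoside	C23H34O14	131752947	Low	0.22
MOL33	Naringenin	C15H12O5	667495	High	98.38
MOL34	Neochlorogenic acid	C16H18O9	7067335	Low	0.48
MOL35	Chlorogenic acid	C16H18O9	1794427	Low	0.48
MOL36	6-Hydroxy-7-methoxy-2H-chromen-2-one	C10H8O4	69894	High	99.36
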