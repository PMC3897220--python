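# Empirical amino-acid replacement model: symmetric exchangeabilities and
# equilibrium frequencies. Amino-acid order: A R N D C Q E G H I L K M F P S T W Y V
pi	0.07674792325	0.05169094831	0.04264495735	0.05154394846	0.0198029802	0.04075195925	0.06182993817	0.07315192685	0.02294397706	0.05376094624	0.0919039081	0.05867594132	0.02382597617	0.04012595987	0.0509009491	0.06876493124	0.05856494144	0.01426098574	0.0321019679	0.066004934
A	0	58	54	81	56	57	105	179	27	36	30	35	54	15	194	378	475	9	11	298
R	58	0	45	16	113	310	29	137	328	22	38	646	44	5	74	101	64	126	20	17
N	54	45	0	528	34	86	58	81	391	47	12	263	30	10	15	503	232	8	70	16
D	81	16	528	0	10	49	767	130	112	11	7	26	15	4	15	59	38	4	46	31
C	56	113	34	10	0	9	5	59	69	17	23	7	31	78	14	223	42	115	209	62
Q	57	310	86	49	9	0	323	26	597	9	72	292	43	4	164	53	51	18	24	20
E	105	29	58	767	5	323	0	119	26	12	9	181	18	5	18	30	32	10	7	45
G	179	137	81	130	59	26	119	0	23	6	6	27	14	5	24	201	33	55	8	47
H	27	328	391	112	69	597	26	23	0	16	56	45	33	40	115	73	46	8	573	11
I	36	22	47	11	17	9	12	6	16	0	229	21	479	89	10	40	245	9	32	961
L	30	38	12	7	23	72	9	6	56	229	0	14	388	248	102	59	25	52	24	180
K	35	646	263	26	7	292	181	27	45	21	14	0	65	4	21	47	103	10	8	14
M	54	44	30	15	31	43	18	14	33	479	388	65	0	43	16	29	226	24	18	323
F	15	5	10	4	78	4	5	5	40	89	248	4	43	0	17	92	12	53	536	62
P	194	74	15	15	14	164	18	24	115	10	102	21	16	17	0	285	118	6	10	23
S	378	101	503	59	223	53	30	201	73	40	59	47	29	92	285	0	477	35	63	38
T	475	64	232	38	42	51	32	33	46	245	25	103	226	12	118	477	0	12	21	112
W	9	126	8	4	115	18	10	55	8	9	52	10	24	53	6	35	12	0	71	25
Y	11	20	70	46	209	24	7	8	573	32	24	8	18	536	10	63	21	71	0	16
V	298	17	16	31	62	20	45	47	11	961	180	14	323	62	23	38	112	25	16	0
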