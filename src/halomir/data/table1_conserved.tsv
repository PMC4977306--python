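family	name	sequence	strand	control_rpm	salt_rpm	mature_length	hairpin_length	mfe	amfe	gc_percent	mfei	star_sequence
miR156/157	mcr-miR156a	TGACAGAAGAGAGTGAGCAC	-	7306.1	11515.7	20	126	-55.9	-43.33	44.96	0.96	GCTCACTGCTCTTGCTGTCAGC
miR156/157	mcr-miR156b	TGACAGAAGAGAGTGAGCAC	-	6151.2	9904.6	20	110	-57.1	-57.10	52.00	1.10	GCTCACCCTCTCTCTGTCACC
miR156/157	mcr-miR156c	CTGACAGAAGATAGAGAGCAC	+	613.1	543.4	21	128	-45.5	-56.88	45.00	1.26	GCTCTCTATCTTCTGTCATC
miR156/157	mcr-miR156d	TTGACAGAAGATAGAGAGCAC	-	206.5	245.4	21	154	-86.61	-50.06	44.51	1.12	GCTCTCTATGCTTCTGTCATC
miR156/157	mcr-miR156e	TGACAGAAGAGAGAGAGCAC	+	11	19.6	20	155	-67.4	-43.48	45.16	0.96	GCTCTCTCTTCTTCTGTCAAC
miR159	mcr-miR159a	TTTGGATTGAAGGGAGCTCC	-	3792.7	3910.2	20	209	-95.4	-45.65	40.67	1.12	AGCTCCCTTTGGTCCGAAAA
miR159	mcr-miR159b	TTTGGATTGAAGGGAGCTCTA	+	1561.2	1307.6	21	194	-78.5	-44.10	42.70	1.03	GAGCTCCTTGAAGTCCAAAAG
miR160	mcr-miR160	TGCCTGGCTCCCTGTATGCCA	-	1.3	1	21	129	-52.2	-40.47	49.61	0.82	ND
miR162	mcr-miR162	TCGATAAACCTCTGCATCCAG	-	140.5	157.1	21	125	-43.9	-45.73	48.96	0.93	GGAGGCAGCGGTTCATCGATC
miR164	mcr-miR164	TGGAGAAGCAGGGCACGTGCA	-	2.3	1	21	258	-92	-35.66	39.53	0.90	CATGTGCCCCTCTTCACCATC
miR166	mcr-miR166a	TCGGACCAGGCTTCATTCCCC	+	56364.4	68848.6	21	132	-78	-59.09	54.55	1.08	GGATTGTTGTCTGGCTCGAGG
miR166	mcr-miR166b	TCTCGGACCAGGCTTCATTCC	+	52852.6	58209.2	21	194	-79.1	-39.75	38.69	1.03	ND
miR168	mcr-miR168	TCGCTTGGTGCAGGTCGGGAA	-	104.2	101.3	21	164	-82.21	-50.13	56.10	0.89	CCCGCCTTGCATCAACTGAAT
miR169	mcr-miR169a	TAGCCAAGGATGACTTGCCT	-	116.5	151.4	20	143	-54.7	-38.25	42.66	0.90	GCAGTCATCATTGGCTAAG
miR169	mcr-miR169b	CAGCCAAGGATGACTTGCCGG	+	1.6	1.9	21	126	-51.4	-40.79	46.83	0.87	GGCAAGTTGTCCTTGGCTACA
miR171	mcr-miR171	TGATTGAGCCGTGCCAATATC	-	49.8	39.9	21	116	-54	-59.34	39.56	1.50	GATATTGGTGCGGTTCAATC
miR319	mcr-miR319	TTGGACTGAAGGGAGCTCCCT	+	2410.9	2310	21	294	-103.1	-35.07	41.84	0.84	AGAGCTTTCTTCAGTCCACTC
miR396	mcr-miR396	TTCCACAGCTTTCTTGAACTG	+	439.9	509.6	21	215	-83	-38.60	31.63	1.22	GTTCAATAAAGCTGTGGGAAG
miR403	mcr-miR403	TTAGATTCACGCACAAACTCG	-	1321.3	1255.1	21	147	-64	-43.54	40.82	1.07	GATTTGTGCGTGAATCTAACG
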