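name	sequence	strand	control_rpm	salt_rpm	mature_length	hairpin_length	mfe	amfe	gc_percent	mfei	star_sequence
mcr-miR1	TCAATTTGGGTTCTAGGGTTT	-	141.1	122.9	21	317	-135.5	-42.74	37.85	1.13	ACCCTAGATCCCAAATTGAAT
mcr-miR2	CCACCCGGGATCGTTTCGTGCAAC	-	70.2	67.1	24	286	-152.12	-53.19	36.36	1.46	AGTTGCATGAGACAGTCTTAGGTG
mcr-miR3	TGACGATGAGAGAGAGCACGC	-	65.4	50.4	21	111	-60.1	-54.14	45.95	1.18	GTGCTCTCTCTTGTCGTCATA
mcr-miR4	AATTAGGCCTAACGTCGGGTACCC	-	54.7	64	24	399	-210.6	-52.78	33.08	1.60	TTGGGTACCCGACGTTAGGTCTA
mcr-miR5	AGTGTCACCTTGTTTGTAGAACGG	-	38.5	24.4	24	106	-82.7	-78.02	49.06	1.59	CTCCGTTCTCTAAAGAAGGTGACG
mcr-miR6	TTCGTGCTGATAACGTGTTGAA	-	32.7	26.6	22	233	-139.3	-59.79	28.33	2.11	CAACACTTTATCAGCACGAATC
mcr-miR7	CACCTTGTTTGTAGAACGGAGGGA	+	25.6	17.4	24	102	-50.9	-49.90	44.12	1.13	TACTCCCTCCGTTCTCTAAAGAA
mcr-miR8	TCTTTTTATAGAGGAATGCCTC	-	24	25.7	22	108	-45.11	-41.77	33.33	1.25	GGCCTTCCTCTTAAAAAGATG
mcr-miR9	TCGGAAAATGACTTAAGGGGT	+	16.2	10.1	21	300	-134.2	-55.92	36.25	1.54	CACCTTAAGTCGTTTTTCGCC
mcr-miR10	CCCGGACCATGTAATAATTGCTC	+	17.8	14.3	23	173	-98.1	-56.71	45.09	1.26	GAAATTATTGTATGGTCCCGGAC
mcr-miR11	TTCCGGCAGGTTGTCCTTGGC	+	18.1	15.8	21	194	-54.95	-28.32	36.60	0.77	CAGCCAAGGATGACTTGCCGG
mcr-miR12	ATAGGGCGAGATTGACAAACC	-	11	12	21	164	-78.7	-55.82	40.43	1.38	TTGGTTTGTCAATCTCGATCT
mcr-miR13	CCTAAAGGTTGGATTATTGGCATC	+	12	13	24	412	-234.19	-56.84	35.68	1.59	ATGCCAATAATCCAACCTTTGGGC
mcr-miR14	TTGGCCGGAAAATTGAACAAG	-	9.1	14.3	21	313	-176.99	-56.55	35.46	1.59	CCCTTGTTCAATTTTCTGACC
mcr-miR15	CTGAAGCGTTTGGGGGAACTC	-	7.1	4.4	21	104	-44.95	-43.22	48.08	0.90	GTTCCTCACAGCACTTCATTG
mcr-miR16	AAGGGCTCGCTTGGATTGGGGGGA	-	6.2	11.1	24	372	-240.3	-64.60	45.70	1.41	TTTCCCTCAATCCAAGCGGGGCCT
mcr-miR17	ATCACCGGTGGCGAATTTTTGGGC	-	4.2	4.8	24	360	-197.87	-54.96	35.28	1.56	GAGCCCAAAAATTCGCCGCCGGTG
mcr-miR18	ACACCAACGAGGACTTTGAAACAC	+	3.2	4.4	24	176	-131.1	-74.49	47.16	1.58	GTTTCAAAGTCTTCGTTGGTGTCC
mcr-miR19	CTAAAGCGACAGTTATTTTGAGAC	-	2.9	2.2	24	168	-53.17	-31.65	33.33	0.95	CCGTCTCAAAATAACTGTCGCTTT
mcr-miR20	ATCACCGGTGGCGAATTTTTGGAC	-	2.9	1.9	24	360	-199.6	-55.44	36.94	1.50	GAGTCCAAAAATTCGCCGTCGGTG
mcr-miR21	TTTCGTGCAACTATAGTGAAAGGT	-	2.3	1	24	261	-122.72	-47.02	35.63	1.32	TTTCACTATAGTTGCATGAGACAG
mcr-miR22	TAAAGTTGGGATGTTCCTACC	-	1.9	2.2	21	309	-173.3	-56.08	47.25	1.19	TAGGAACATCCCGACTTTACT
mcr-miR23	GGACAAATAATTTGGGACGGAGGG	+	1.6	0.3	24	127	-67.1	-52.83	39.37	1.34	CTCCGTGTCCAATTATTTGTCTGC
mcr-miR24	TGTGAGAGAAGGGACCATAGGTTC	+	0.6	4.1	24	145	-44.8	-30.90	34.48	0.90	TCGGACCAATGCTCCCTCTTTCAT
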