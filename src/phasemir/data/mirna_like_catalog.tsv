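# Catalog of Arabidopsis miRNA precursors producing multiple small RNAs,
# transcribed from the published summary table of the source study
# (19 precursors, 10 families; 35 newly identified miRNA-like RNAs).
# is_new = 1 marks newly identified miRNA-like RNAs (bold in the original),
# 0 marks the previously annotated miRNA/miRNA* entries shown for context.
# Transcription notes: the precursor row printed "miR519b" carries miR159b.*
# entries and is recorded as miR159b; the 6,587-read miR159a entry is printed
# with a stray star although its sequence is the annotated mature miR159a,
# recorded here as miR159a.1; a stray trailing " *" on the miR159b.1 sequence
# was dropped.
precursor	loci_class	name	is_new	sequence	reads	ago_list	pare_targets
miR159a	+	miR159a.1*	0	GAGCTCCTTAAAGTTCAAACA	9
miR159a	+	miR159a.2-5p	1	AGCTGCTAAGCTATGGATCCC	36	2,7
miR159a	+	miR159a.3	1	TAAAAAAGGATTTGGTTATA	6
miR159a	+	miR159a.2-3p	1	ATTGCATATCTCAGGAGCTTT	9	1,2,7	At5g24620
miR159a	+	miR159a.1	0	TTTGGATTGAAGGGAGCTCTA	6587
miR159b	+	miR159b.2	1	AGCTGCTAAGCTATGGATCCC	36	7
miR159b	+	miR159b.2*	1	ATGCCATATCTCAGGAGCTTT	14	1,2,7
miR159b	+	miR159b.1	0	TTTGGATTGAAGGGAGCTC	2481
miR168a	+	miR168a.1	0	TCGCTTGGTGCAGGTCGGGAA	266020
miR168a	+	miR168a.2	1	ATTGGTTTGTGAGCAGGGATTGGAT	10	2
miR168a	+	miR168a.1*	0	CCCGCCTTGCATCAACTGAAT	1497
miR169b	-	miR169b.2	1	TGAAGTGGAGTAGAGTATAATG	7		At4g17420
miR169b	-	miR169b.1	0	CAGCCAAGGATGACTTGCCGG	4444
miR169b	-	miR169b.1*	0	GGCAAGTTGTCCTTCGGCTACA	8
miR169f	-	miR169f.2	1	TGAAGGAATAACGAATGGAAT	108	1
miR169f	-	miR169f.1	0	TGAGCCAAGGATGACTTGCCG	5779
miR169f	-	miR169f.1*	0	GCAAGTTGACCTTGGCTCTGC	2505
miR169i	-	miR169i.2-5p	1	TGAATAGAAGAATCATATTTGG	32
miR169i	-	miR169i.1	0	TAGCCAAGGATGACTTGCCTG	44477
miR169i	-	miR169i.1*	0	GGCAGTCTCCTTGGCTATC	360
miR169i	-	miR169i.2-3p	1	TTATATGTTCTTCTCTTTCATC	9		At5g02710
miR169j	-	miR169j.1	0	TAGCCAAGGATGACTTGCCTG	44458
miR169j	-	miR169j.1*	0	AATCTTGCGGGTTAGGTTTCA	9
miR169j	-	miR169j.2	1	GGCAGTCTCCTTGGCTATC	224	4	At5g48300
miR169l	-	miR169l.1	0	TAGCCAAGGATGACTTGCCTG	44392
miR169l	-	miR169l.1*	0	AATCTTGCGGGTTAGGTTTCA	9
miR169l	-	miR169l.2	1	AGGCAGTCTCTTTGGCTATC	366
miR169m	-	miR169m.2	1	TGAATAGAAGAATCATATTTGG	32
miR169m	-	miR169m.1	0	TAGCCAAGGATGACTTGCCTG	39650
miR169m	-	miR169m.1*	0	GGCAGTCTCCTTGGCTATC	361
miR169n	-	miR169n.2*	1	TGGCGGAAAGCGTCATGTTTAG	10	4
miR169n	-	miR169n.1	0	TAGCCAAGGATGACTTGCCTG	44458
miR169n	-	miR169n.1*	0	AATCTTGCGGGTTAGGTTTCA	9
miR169n	-	miR169n.2	1	AGGCAGTCTCTTTGGCTATC	366
miR319a	+	miR319a.2	1	AATGAATGATGCGGTAGACAAA	8	1,2,4,5
miR319a	+	miR319a.1	0	TTGGACTGAAGGGAGCTCCCT	27
miR319b	+	miR319b.1*	0	GAGCTTTCTTCGGTCCACTC	28
miR319b	+	miR319b.2	1	AATGAATGATGCGAGAGACAA	491	1,2
miR319b	+	miR319b.1	0	TTGGACTGAAGGGAGCTCCCT	30
miR447a	-	miR447a.2-5p	1	ACCCCTTACAATGTCGAGTAA	106	2,4,5
miR447a	-	miR447a.1	0	TTGGGGACGAGATGTTTTGTTG	198
miR447a	-	miR447a.2-3p	1	ACTCGATATAAGAAGGGGCTT	94	1,2,4,5,7
miR447a	-	miR447a.3	1	TATGGAAGAAATTGTAGTATT	96	1,2,4,5,7
miR447b	-	miR447b.1*	0	AGTAAACGAAGCATCTGTCCCC	8
miR447b	-	miR447b.1	0	TTGGGGACGAGATGTTTTGTTG	198
miR447b	-	miR447b.2	1	ACTCGATATAAGAAGGGGCTT	94	2,5,7
miR447b	-	miR447b.3	1	TATGGAAGAAATTGTAGTATT	96	2,4,7
miR775	+	miR775.1*	0	GCACTACGTGACATTGAAAC	8
miR775	+	miR775.2	1	TTTGGTTTGTTCAAAGACATT	10	5
miR775	+	miR775.1	0	TTCGATGTCTAGCAGTGCCA	3136
miR822	+/-	miR822.2*	1	CGACCTTAAGTATAAGTAGAT	6
miR822	+/-	miR822.3*	1	GATGTAACGCATGTTGTTTTCT	149	2,4,7
miR822	+/-	miR822.1	0	TGCGGGAAGCATTTGCACATGT	4153
miR822	+/-	miR822.4-5p	1	TTTCGTGGAGAATGAAATCAC	10	1,4	At1g62030,At2g04680
miR822	+/-	miR822.5	1	CATACATGAATAATAATTACC	9	1,5
miR822	+/-	miR822.4-3p	1	TATGATTTTATCCTCCATAAAA	11	5
miR822	+/-	miR822.1*	0	ATGTGCAAATGCTTTCTACAG	693
miR822	+/-	miR822.3	1	AAACAATATACGTTGCATCCC	1691	1,2,4,7
miR822	+/-	miR822.2	1	ATCTACTTACACTTAAGGTCG	363	1,2,4,5
miR839	+/-	miR839.2	1	TCATGTGAGCAGAAAGAGTAG	10	1
miR839	+/-	miR839.1	0	TACCAACCTTTCATCGTTCCC	5
miR839	+/-	miR839.3	1	TGCAAAACCGTGATAGTGCTGA	13	1,2,4,7	At1g65960
miR839	+/-	miR839.1*	0	GAACGCATGAGAGGTTGGTAAA	33
miR841	-	miR841.2	1	TGTTCTTAAGTTGCTTGTGAA	8	1
miR841	-	miR841.1	0	TACGAGCCACTTGAAACTGAA	59
miR841	-	miR841.1*	0	ATTTCTAGTGGGTCGTATTCA	3904
miR846	+	miR846.1*	0	CATTCAAGGACTTCTATTCAG	59
miR846	+	miR846.2	1	AATTGGATATGATAAATGGTAA	34
miR846	+	miR846.2*	1	ACTTTTATCATATCCCATCAG	18
miR846	+	miR846.1	0	TTGAATTGAAGTGCTTGAATT	37
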