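name	chromosome	position_bp	motif	pic_seq	k	ho	he	pic	ae	min_len	max_len	selected	note
Pav_chr1_028	1	56439028	AAT	0.721	4	0.796	0.736	0.686	3.784	209	221	0	No amplification in multiplex
Pav_chr1_073	1	52114073	AT	0.829	8	0.776	0.807	0.780	5.175	115	133	1
Pav_chr2_274	2	44310274	CT	0.833	7	0.878	0.837	0.816	6.125	415	438	1
Pav_chr2_995	2	44515995	AG	0.855	8	0.898	0.790	0.762	4.754	124	167	0	In close proximity to Pav_chr2_274
Pav_chr3_002	3	24943002	CT	0.902	11	0.898	0.850	0.833	6.651	300	324	1
Pav_chr3_706	3	21366706	AG	0.835	10	0.918	0.827	0.804	5.772	221	247	1
Pav_chr3_765	3	5316765	TAT	0.711	7	0.735	0.736	0.696	3.790	235	264	0
Pav_chr4_217	4	3209217	GT	0.81	5	0.898	0.747	0.709	3.952	406	433	1
Pav_chr4_499	4	275499	TCTAGT	0.734	4	0.755	0.712	0.657	3.477	227	245	1
Pav_chr5_059	5	16156059	AT	0.853	11	0.816	0.846	0.828	6.507	215	243	0	No amplification in multiplex
Pav_chr5_144	5	32811144	CT	0.856	9	0.796	0.826	0.804	5.744	332	362	1
Pav_chr5_198	5	16788198	TTGC	0.640	3	0.755	0.712	0.657	3.477	395	425	0	Low PIC, Ho, He, Ae
Pav_chr5_903	5	32741903	AG	0.846	8	0.837	0.830	0.808	5.892	290	312	0	In close proximity to Pav_chr5_144
Pav_chr6_178	6	10235178	AG	0.825	7	0.878	0.820	0.797	5.545	104	126	1
Pav_chr6_363	6	37421363	AGA	0.749	7	0.816	0.760	0.724	4.168	121	141	0
Pav_chr6_387	6	25964387	AG	0.830	7	0.837	0.763	0.728	4.227	127	155	0
Pav_chr6_418	6	29689418	AGTT	0.691	5	0.816	0.711	0.655	3.460	177	208	0
Pav_chr6_505	6	3361505	AG	0.829	7	0.857	0.798	0.769	4.951	304	323	1
Pav_chr6_641	6	25614641	ATT	0.812	9	0.915	0.798	0.769	4.953	410	465	0	No amplification in multiplex
Pav_chr6_989	6	35139989	AG	0.854	6	0.857	0.720	0.682	3.570	250	281	0	Lower Ho, He, Ae
Pav_chr7_259	7	23664259	CT	0.832	8	0.878	0.828	0.806	5.828	112	128	0	Lower He, PIC, Ae
Pav_chr7_286	7	13399286	AT	0.825	9	0.851	0.826	0.805	5.753	132	152	0	No amplification in multiplex
Pav_chr7_444	7	19590444	CT	0.821	6	0.714	0.713	0.671	3.480	417	455	0
Pav_chr7_737	7	29755737	AAAG	0.786	8	0.837	0.771	0.741	4.361	89	117	0	Lower Ho, He, Ae
Pav_chr7_798	7	12815798	AG	0.85	8	0.837	0.831	0.809	5.928	308	330	1
Pav_chr7_863	7	28148863	ATAA	0.648	3	0.571	0.608	0.540	2.553	187	195	0
Pav_chr7_867	7	23682867	CT	0.846	9	0.878	0.838	0.818	6.180	423	460	1
Pav_chr7_906	7	6627906	ATGT	0.666	3	0.735	0.661	0.587	2.953	279	292	0
Pav_chr8_224	8	29212224	AAT	0.762	10	0.796	0.790	0.763	4.759	197	255	0	No amplification in multiplex
Pav_chr8_438	8	25182438	CT	0.836	8	0.776	0.831	0.808	5.907	386	416	1
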