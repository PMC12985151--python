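name	chromosome	position_bp	motif	dye	window_min	window_max
BPPCT037	5			6-FAM	100	150
EMPA005	1			6-FAM	200	250
Pav_chr6_505	6	3361505	AG	6-FAM	300	350
Pav_chr4_217	4	3209217	GT	6-FAM	400	450
Pav_chr1_073	1	52114073	AT	VIC	100	150
Pav_chr3_706	3	21366706	AG	VIC	200	250
Pav_chr5_144	5	32811144	CT	VIC	300	350
Pav_chr2_274	2	44310274	CT	VIC	400	450
UCD_CH11	2			NED	100	150
Pav_chr4_499	4	275499	TCTAGT	NED	200	250
Pav_chr3_002	3	24943002	CT	NED	300	350
Pav_chr8_438	8	25182438	CT	NED	400	450
Pav_chr6_178	6	10235178	AG	PET	100	150
CPPCT006	8			PET	200	250
Pav_chr7_798	7	12815798	AG	PET	300	350
Pav_chr7_867	7	23682867	CT	PET	400	450
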