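marker	k	ho	he	pic	ae
BPPCT037	11	0.867	0.804	0.775	5.101
EMPA005	10	0.633	0.647	0.606	2.832
Pav_chr4_217	5	0.759	0.702	0.662	3.352
Pav_chr6_505	9	0.786	0.806	0.779	5.160
Pav_chr1_073	11	0.827	0.825	0.802	5.705
Pav_chr3_706	13	0.884	0.824	0.802	5.677
Pav_chr5_144	10	0.891	0.845	0.826	6.457
Pav_chr2_274	11	0.837	0.823	0.799	5.642
UCD_CH11	11	0.810	0.799	0.769	4.980
Pav_chr4_499	4	0.776	0.735	0.685	3.770
Pav_chr3_002	13	0.867	0.862	0.846	7.223
Pav_chr8_438	9	0.857	0.825	0.802	5.724
Pav_chr6_178	10	0.816	0.829	0.806	5.850
CPPCT006	9	0.748	0.718	0.676	3.550
Pav_chr7_798	12	0.847	0.842	0.822	6.323
Pav_chr7_867	10	0.898	0.841	0.821	6.291
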