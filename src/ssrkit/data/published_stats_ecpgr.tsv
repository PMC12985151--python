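marker	k	ho	he	pic	ae
EMPaS12	7	0.765	0.754	0.713	4.068
EMPA003	4	0.466	0.436	0.342	1.773
EMPaS02	8	0.701	0.679	0.650	3.118
EMPA017	7	0.245	0.248	0.235	1.329
EMPaS10	14	0.588	0.598	0.562	2.488
EMPaS14	5	0.663	0.577	0.491	2.367
UDP98-412	8	0.643	0.623	0.595	2.656
EMPaS06	10	0.860	0.828	0.806	5.813
UDP98-410	8	0.527	0.525	0.476	2.104
EMPaS01	8	0.674	0.654	0.592	2.891
UDP98-411	7	0.762	0.708	0.666	3.419
EMPA026	3	0.609	0.581	0.491	2.387
EMPA002	4	0.609	0.493	0.373	1.971
CPPCT006	10	0.748	0.718	0.676	3.550
BPPCT037	12	0.867	0.804	0.775	5.101
CPPCT022	11	0.704	0.650	0.587	2.856
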