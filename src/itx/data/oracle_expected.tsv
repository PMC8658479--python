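gene	t	lmr	p_t	p_lmr
OR1	4.7158425509199695	0.70313101389109178	0.0091743119266055051	0.33944954128440369
OR2	-1.9982402718597392	-0.42420059632122076	0.10091743119266056	0.44954128440366975
OR3	0	0	1	1
OR4	1.9999999999999918	0.42420059632122076	0.064220183486238536	0.44954128440366975
OR5	-6.8579518264721342	-0.70313101389109178	0.0091743119266055051	0.33944954128440369
OR6	0.99999999999999012	0	0.26605504587155965	1
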