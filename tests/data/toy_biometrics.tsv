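animal_id	stage	TL_cm	TW_g	BW_g
a1	glass	6.5	0.23	0.004
a2	elver	8.1	0.77	0.005
a3	elver	7.9	0.70	0.005
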