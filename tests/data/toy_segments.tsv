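segment_id	stage	animal_id	arc_length_um	n_spines
seg1	glass	a1	12.5	8
seg2	glass	a1	10.0	0
seg3	elver	a2	20.0	4
seg4	elver	a3	10.0	0
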